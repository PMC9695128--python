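"""Lorenz-Mie optics of a phosphor grain embedded in a binder medium.

Each grain is modeled as a homogeneous sphere of complex refractive index
``n_p = 2.3 + 1e-5 i`` (Gd2O2S at its emission lines) inside a binder of
real index 1.35.  The embedded-sphere convention is used throughout: the
size parameter carries the in-medium wavelength, x = pi d n_med / lambda,
and the relative index is m = n_p / n_med.

The Mie coefficients a_n, b_n are evaluated with the standard stable
scheme: downward recurrence for the logarithmic derivative D_n(mx),
upward recurrence for the Riccati-Bessel functions of the real argument,
series truncated at N = ceil(x + 4 x^(1/3) + 2).  The start order of the
downward recurrence is max(N, |mx|) + 48, which holds the efficiencies
and asymmetry factor to ~1e-13 relative over the grain sizes of interest
(the customary +15 start loses digits beyond x ~ 50).

From Q_ext and the packing fraction follows the per-length extinction
coefficient of the granular bed,
``m_ext = 3 f Q_ext / (2 d)``  [1/um],
i.e. sphere number density (6 f / pi d^3) times geometric cross-section
(pi d^2 / 4) times Q_ext.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gsd import GrainSizeDistribution
from .samples import Activator, EMISSION_WAVELENGTH_NM

__all__ = [
    "OpticalConstants",
    "MieResult",
    "MieTable",
    "size_parameter",
    "mie_single",
    "extinction_coefficient",
    "mie_table",
]

#: Maximum size parameter accepted by the series evaluation.
X_MAX = 1e4

#: Default grain index: real part 2.3, absorption index 1e-5.
DEFAULT_PARTICLE_INDEX = 2.3 + 1e-5j
DEFAULT_MEDIUM_INDEX = 1.35


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelength and refractive indices for one activator emission line."""

    wavelength_nm: float
    particle_index: complex = DEFAULT_PARTICLE_INDEX
    medium_index: float = DEFAULT_MEDIUM_INDEX

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.particle_index.real <= 0 or self.particle_index.imag < 0:
            raise ValueError("particle index needs Re > 0 and Im >= 0")
        if self.medium_index < 1:
            raise ValueError("medium index must be >= 1")

    @classmethod
    def for_activator(cls, activator: Activator | str, **kw) -> "OpticalConstants":
        return cls(EMISSION_WAVELENGTH_NM[Activator(activator)], **kw)

    @property
    def relative_index(self) -> complex:
        return self.particle_index / self.medium_index


@dataclass(frozen=True)
class MieResult:
    diameter_um: float
    x: float
    q_ext: float
    q_sca: float
    q_abs: float
    g: float
    albedo: float


def size_parameter(diameter_um: float, optics: OpticalConstants) -> float:
    """Size parameter x = pi d n_med / lambda (lambda in vacuum)."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return np.pi * diameter_um * optics.medium_index / (optics.wavelength_nm * 1e-3)


def _mie_series(m: complex, x: float) -> tuple[float, float, float]:
    """Q_ext, Q_sca, g for relative index m and size parameter x."""
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x
    nmx = int(max(nmax, abs(mx))) + 48
    d_log = np.zeros(nmx + 1, dtype=complex)
    for n in range(nmx, 0, -1):
        d_log[n - 1] = n / mx - 1.0 / (d_log[n] + n / mx)

    an = np.empty(nmax, dtype=complex)
    bn = np.empty(nmax, dtype=complex)
    psi0, psi1 = np.cos(x), np.sin(x)
    chi0, chi1 = -np.sin(x), np.cos(x)
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi1 - psi0
        chi = (2 * n - 1) / x * chi1 - chi0
        xi, xi1 = psi - 1j * chi, psi1 - 1j * chi1
        ta = d_log[n] / m + n / x
        tb = d_log[n] * m + n / x
        an[n - 1] = (ta * psi - psi1) / (ta * xi - xi1)
        bn[n - 1] = (tb * psi - psi1) / (tb * xi - xi1)
        psi0, psi1 = psi1, psi
        chi0, chi1 = chi1, chi

    n = np.arange(1, nmax + 1)
    q_ext = 2.0 / x**2 * np.sum((2 * n + 1) * (an.real + bn.real))
    q_sca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(an) ** 2 + np.abs(bn) ** 2))
    k = n[:-1]
    g_sum = np.sum(
        k * (k + 2) / (k + 1)
        * (an[:-1] * np.conj(an[1:]) + bn[:-1] * np.conj(bn[1:])).real
    ) + np.sum((2 * n + 1) / (n * (n + 1)) * (an * np.conj(bn)).real)
    g = 4.0 / (x**2 * q_sca) * g_sum
    return float(q_ext), float(q_sca), float(g)


def mie_single(diameter_um: float, optics: OpticalConstants) -> MieResult:
    """Mie efficiencies, albedo and asymmetry factor for one grain size."""
    x = size_parameter(diameter_um, optics)
    if x > X_MAX:
        raise ValueError(f"size parameter {x:.3g} exceeds stability bound {X_MAX:g}")
    m = optics.relative_index
    q_ext, q_sca, g = _mie_series(m, x)
    if m.imag == 0:
        q_sca = q_ext  # non-absorbing sphere: enforce exact energy identity
    q_abs = max(q_ext - q_sca, 0.0)
    return MieResult(
        diameter_um=float(diameter_um), x=x, q_ext=q_ext, q_sca=q_sca,
        q_abs=q_abs, g=g, albedo=q_sca / q_ext,
    )


def extinction_coefficient(mie: MieResult, packing_fraction: float) -> float:
    """Extinction coefficient of the bed, 1/um, at the given packing fraction."""
    if not 0 < packing_fraction < 1:
        raise ValueError("packing fraction must be in (0, 1)")
    return 3.0 * packing_fraction * mie.q_ext / (2.0 * mie.diameter_um)


@dataclass(frozen=True)
class MieTable:
    """Mie optics tabulated on a uniform diameter grid over a GSD support.

    Transport interpolates linearly between grid nodes; at the default
    0.001 um step the interpolation error in Q_ext is below 1% for ~95%
    of diameters.  Narrow morphology-dependent resonances (sub-nm widths
    in diameter for this refractive index) are not resolved by any
    practical grid and can locally exceed that figure; they occupy a
    negligible measure of the size distribution.
    """

    diameters_um: np.ndarray
    q_ext: np.ndarray
    q_sca: np.ndarray
    q_abs: np.ndarray
    g: np.ndarray
    albedo: np.ndarray
    m_ext: np.ndarray  # 1/um, at the table's packing fraction
    packing_fraction: float
    optics: OpticalConstants

    @property
    def grid_step(self) -> float:
        d = self.diameters_um
        return float(d[1] - d[0]) if d.size > 1 else 0.0

    def nearest_index(self, diameter_um) -> np.ndarray:
        d = np.asarray(diameter_um, dtype=float)
        if self.diameters_um.size == 1:
            return np.zeros(d.shape, dtype=np.int64)
        idx = np.rint((d - self.diameters_um[0]) / self.grid_step).astype(np.int64)
        return np.clip(idx, 0, self.diameters_um.size - 1)

    def lookup(self, diameter_um: float) -> MieResult:
        i = int(self.nearest_index(diameter_um))
        return MieResult(
            diameter_um=float(self.diameters_um[i]),
            x=size_parameter(float(self.diameters_um[i]), self.optics),
            q_ext=float(self.q_ext[i]), q_sca=float(self.q_sca[i]),
            q_abs=float(self.q_abs[i]), g=float(self.g[i]),
            albedo=float(self.albedo[i]),
        )

    def interpolate(self, diameter_um: float) -> tuple[float, float, float]:
        """(m_ext, albedo, g) linearly interpolated at a diameter (um).

        This is the lookup rule the transport engines use.
        """
        if self.diameters_um.size == 1:
            return float(self.m_ext[0]), float(self.albedo[0]), float(self.g[0])
        pos = (diameter_um - self.diameters_um[0]) / self.grid_step
        j = int(min(max(pos, 0.0), self.diameters_um.size - 2))
        f = pos - j
        return (
            float(self.m_ext[j] * (1 - f) + self.m_ext[j + 1] * f),
            float(self.albedo[j] * (1 - f) + self.albedo[j + 1] * f),
            float(self.g[j] * (1 - f) + self.g[j + 1] * f),
        )

    def to_frame(self) -> pd.DataFrame:
        """Sweep table (diameter, x, Q_ext, Q_sca, g, albedo, m_ext) for CSV export."""
        x = np.array([size_parameter(d, self.optics) for d in self.diameters_um])
        return pd.DataFrame({
            "diameter_um": self.diameters_um, "x": x, "q_ext": self.q_ext,
            "q_sca": self.q_sca, "q_abs": self.q_abs, "g": self.g,
            "albedo": self.albedo, "m_ext_per_um": self.m_ext,
        })


def mie_table(
    gsd: GrainSizeDistribution,
    optics: OpticalConstants,
    packing_fraction: float = 0.5,
    grid_step_um: float = 0.001,
) -> MieTable:
    """Tabulate Mie optics on a uniform grid covering the GSD support."""
    if grid_step_um <= 0:
        raise ValueError("grid step must be positive")
    lo, hi = gsd.lower_um, gsd.upper_um
    n = max(int(np.ceil((hi - lo) / grid_step_um)) + 1, 1)
    d = lo + grid_step_um * np.arange(n) if n > 1 else np.array([lo])
    res = [mie_single(float(di), optics) for di in d]
    q_ext = np.array([r.q_ext for r in res])
    return MieTable(
        diameters_um=d, q_ext=q_ext,
        q_sca=np.array([r.q_sca for r in res]),
        q_abs=np.array([r.q_abs for r in res]),
        g=np.array([r.g for r in res]),
        albedo=np.array([r.albedo for r in res]),
        m_ext=3.0 * packing_fraction * q_ext / (2.0 * d),
        packing_fraction=packing_fraction, optics=optics,
    )
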