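"""Monte Carlo random walk of optical photons through the granular slab.

Each photon is born at depth z inside a laterally infinite slab of
thickness T, with an isotropic initial direction (unpolarized
luminescence).  The walk alternates free flights and single-grain
interactions:

* a grain diameter is drawn fresh from the GSD at every interaction
  (number-weighted traversal of a polydisperse bed); its optics come
  from linear interpolation of a precomputed Mie table;
* the free-path length is exponential with the per-diameter extinction
  coefficient, s = -ln(u) / m_ext(d);
* if the flight crosses z = 0 the photon escapes through the irradiated
  face (reflection mode); crossing z = T is transmission mode; the exit
  point is where the final straight segment meets the face;
* otherwise the photon interacts: it is absorbed with probability
  1 - albedo(d), else scattered into a new direction drawn from the
  Henyey-Greenstein phase function with asymmetry g(d).

No Fresnel reflection or refraction is applied at the faces (a photon
escapes on its first boundary crossing) and there is no reflective
backing: the tallies are free-standing-screen budgets.

Two engines implement the identical algorithm with the identical draw
order: a compiled per-photon loop (numba, MT19937) and a plain-Python
reference loop.  Given the same seed their outputs are bit-identical,
which the test suite asserts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numba
import numpy as np

from . import deposition
from .deposition import LayerSpec
from .gsd import GrainSizeDistribution
from .mie import MieTable, OpticalConstants, mie_table

__all__ = [
    "EmissionSummary",
    "sample_scatter_direction",
    "propagate_photon",
    "run_simulation",
]

#: Outcome codes shared by both engines.
ABSORBED, REFLECTED, TRANSMITTED = 0, 1, 2
OUTCOME_NAMES = {ABSORBED: "absorbed", REFLECTED: "reflected", TRANSMITTED: "transmitted"}

DEFAULT_CAP = 1_000_000
_G_ISO_EPS = 1e-6   # |g| below this: sample isotropically
_UZ_POLAR_EPS = 1e-9  # polar-singularity guard on |1 - uz^2|


def _hg_cos(g: float, u: float) -> float:
    if abs(g) < _G_ISO_EPS:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - t * t) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


def _rotate(ux: float, uy: float, uz: float, ct: float, phi: float):
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = np.cos(phi), np.sin(phi)
    denom2 = 1.0 - uz * uz
    if denom2 < _UZ_POLAR_EPS:
        sign = 1.0 if uz >= 0.0 else -1.0
        vx, vy, vz = st * cp, st * sp, ct * sign
    else:
        denom = np.sqrt(denom2)
        vx = st * (ux * uz * cp - uy * sp) / denom + ux * ct
        vy = st * (uy * uz * cp + ux * sp) / denom + uy * ct
        vz = -denom * st * cp + uz * ct
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


def sample_scatter_direction(
    incoming: np.ndarray, g: float, rng: np.random.Generator
) -> np.ndarray:
    """Scatter ``incoming`` (unit vector) by a Henyey-Greenstein deflection.

    The polar cosine comes from the HG inverse CDF; the azimuth is
    uniform.  Isotropic sampling is used for |g| < 1e-6.
    """
    v = np.asarray(incoming, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ValueError("incoming direction must be a unit vector")
    if not -1.0 < g < 1.0:
        raise ValueError("asymmetry factor must lie in (-1, 1)")
    ct = _hg_cos(g, float(rng.random()))
    phi = 2.0 * np.pi * float(rng.random())
    return np.array(_rotate(v[0], v[1], v[2], ct, phi))


@numba.njit(cache=True)
def _kernel(seed, birth_z, thickness, dquant, d0, dstep, ngrid,
            m_ext, albedo, g_arr, cap):  # pragma: no cover - mirrored in Python
    np.random.seed(seed)
    n = birth_z.shape[0]
    nq = dquant.shape[0] - 1
    fates = np.empty(n, dtype=np.int8)
    exit_x = np.full(n, np.nan)
    exit_y = np.full(n, np.nan)
    n_int = np.zeros(n, dtype=np.int64)
    cap_hits = 0
    for i in range(n):
        z = birth_z[i]
        x = 0.0
        y = 0.0
        uz = 2.0 * np.random.random() - 1.0
        phi = 2.0 * np.pi * np.random.random()
        st = np.sqrt(max(0.0, 1.0 - uz * uz))
        ux = st * np.cos(phi)
        uy = st * np.sin(phi)
        k = 0
        while True:
            if k >= cap:
                fates[i] = 0
                cap_hits += 1
                break
            # fresh grain diameter -> nearest Mie node
            q = np.random.random() * nq
            j = int(q)
            if j >= nq:
                j = nq - 1
            d = dquant[j] + (q - j) * (dquant[j + 1] - dquant[j])
            if ngrid == 1:
                mex = m_ext[0]
                alb = albedo[0]
                gg = g_arr[0]
            else:
                pos = (d - d0) / dstep
                if pos < 0.0:
                    pos = 0.0
                elif pos > ngrid - 1:
                    pos = ngrid - 1.0
                jj = int(pos)
                if jj > ngrid - 2:
                    jj = ngrid - 2
                fr = pos - jj
                mex = m_ext[jj] * (1.0 - fr) + m_ext[jj + 1] * fr
                alb = albedo[jj] * (1.0 - fr) + albedo[jj + 1] * fr
                gg = g_arr[jj] * (1.0 - fr) + g_arr[jj + 1] * fr
            s = -np.log(np.random.random()) / mex
            znew = z + uz * s
            if znew < 0.0:
                t = -z / uz
                fates[i] = 1
                exit_x[i] = x + ux * t
                exit_y[i] = y + uy * t
                break
            if znew > thickness:
                t = (thickness - z) / uz
                fates[i] = 2
                exit_x[i] = x + ux * t
                exit_y[i] = y + uy * t
                break
            x += ux * s
            y += uy * s
            z = znew
            k += 1
            if np.random.random() < 1.0 - alb:
                fates[i] = 0
                break
            if abs(gg) < 1e-6:
                ct = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            phi = 2.0 * np.pi * np.random.random()
            sct = np.sqrt(max(0.0, 1.0 - ct * ct))
            cp = np.cos(phi)
            sp = np.sin(phi)
            denom2 = 1.0 - uz * uz
            if denom2 < 1e-9:
                sign = 1.0 if uz >= 0.0 else -1.0
                vx = sct * cp
                vy = sct * sp
                vz = ct * sign
            else:
                denom = np.sqrt(denom2)
                vx = sct * (ux * uz * cp - uy * sp) / denom + ux * ct
                vy = sct * (uy * uz * cp + ux * sp) / denom + uy * ct
                vz = -denom * sct * cp + uz * ct
            norm = np.sqrt(vx * vx + vy * vy + vz * vz)
            ux = vx / norm
            uy = vy / norm
            uz = vz / norm
        n_int[i] = k
    return fates, exit_x, exit_y, n_int, cap_hits


def _python_engine(seed, birth_z, thickness, dquant, d0, dstep, ngrid,
                   m_ext, albedo, g_arr, cap):
    """Reference per-photon loop; draw-for-draw identical to the kernel."""
    rs = np.random.RandomState(seed)
    rand = lambda: float(rs.random_sample())
    n = len(birth_z)
    nq = len(dquant) - 1
    fates = np.empty(n, dtype=np.int8)
    exit_x = np.full(n, np.nan)
    exit_y = np.full(n, np.nan)
    n_int = np.zeros(n, dtype=np.int64)
    cap_hits = 0
    for i in range(n):
        z, x, y = float(birth_z[i]), 0.0, 0.0
        uz = 2.0 * rand() - 1.0
        phi = 2.0 * np.pi * rand()
        st = np.sqrt(max(0.0, 1.0 - uz * uz))
        ux, uy = st * np.cos(phi), st * np.sin(phi)
        k = 0
        while True:
            if k >= cap:
                fates[i] = ABSORBED
                cap_hits += 1
                break
            q = rand() * nq
            j = min(int(q), nq - 1)
            d = dquant[j] + (q - j) * (dquant[j + 1] - dquant[j])
            if ngrid == 1:
                mex, alb, gg = m_ext[0], albedo[0], g_arr[0]
            else:
                pos = min(max((d - d0) / dstep, 0.0), ngrid - 1.0)
                jj = min(int(pos), ngrid - 2)
                fr = pos - jj
                mex = m_ext[jj] * (1.0 - fr) + m_ext[jj + 1] * fr
                alb = albedo[jj] * (1.0 - fr) + albedo[jj + 1] * fr
                gg = g_arr[jj] * (1.0 - fr) + g_arr[jj + 1] * fr
            s = -np.log(rand()) / mex
            znew = z + uz * s
            if znew < 0.0:
                t = -z / uz
                fates[i] = REFLECTED
                exit_x[i], exit_y[i] = x + ux * t, y + uy * t
                break
            if znew > thickness:
                t = (thickness - z) / uz
                fates[i] = TRANSMITTED
                exit_x[i], exit_y[i] = x + ux * t, y + uy * t
                break
            x, y, z = x + ux * s, y + uy * s, znew
            k += 1
            if rand() < 1.0 - alb:
                fates[i] = ABSORBED
                break
            ct = _hg_cos(float(gg), rand())
            phi = 2.0 * np.pi * rand()
            ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
        n_int[i] = k
    return fates, exit_x, exit_y, n_int, cap_hits


def propagate_photon(
    birth_z: float,
    gsd: GrainSizeDistribution,
    table: MieTable,
    layer: LayerSpec,
    seed: int,
    cap: int = DEFAULT_CAP,
):
    """Propagate a single photon with the reference engine.

    Returns (outcome name, exit_x, exit_y, n_interactions); exit
    coordinates are NaN for absorbed photons.
    """
    dquant = gsd.quantile_table()
    fates, ex, ey, ni, _ = _python_engine(
        seed, np.array([birth_z]), layer.thickness_um, dquant,
        float(table.diameters_um[0]), table.grid_step or 1.0,
        len(table.diameters_um), table.m_ext, table.albedo, table.g, cap,
    )
    return OUTCOME_NAMES[int(fates[0])], float(ex[0]), float(ey[0]), int(ni[0])


@dataclass
class EmissionSummary:
    """Aggregate absorption/reflection/transmission budget of one run."""

    n_photons: int
    n_absorbed: int
    n_reflected: int
    n_transmitted: int
    transmitted_offsets_um: np.ndarray  # (n_transmitted, 2) exit (x, y)
    reflected_offsets_um: np.ndarray
    n_interactions_total: int
    cap_hits: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_absorbed + self.n_reflected + self.n_transmitted != self.n_photons:
            raise ValueError("outcome counts must conserve the photon number")

    @property
    def absorbed_pct(self) -> float:
        return 100.0 * self.n_absorbed / self.n_photons

    @property
    def reflected_pct(self) -> float:
        return 100.0 * self.n_reflected / self.n_photons

    @property
    def transmitted_pct(self) -> float:
        return 100.0 * self.n_transmitted / self.n_photons

    def report(self) -> dict:
        """Run report in the 2-decimal budget-table format."""
        return {
            "config": self.config,
            "seed": self.seed,
            "n_photons": self.n_photons,
            "absorbed_pct": round(self.absorbed_pct, 2),
            "reflected_pct": round(self.reflected_pct, 2),
            "transmitted_pct": round(self.transmitted_pct, 2),
            "mean_interactions": self.n_interactions_total / self.n_photons,
            "cap_hits": self.cap_hits,
        }

    def to_json(self) -> str:
        return json.dumps(self.report(), indent=2)


def run_simulation(
    gsd: GrainSizeDistribution,
    optics: OpticalConstants,
    layer: LayerSpec,
    n_photons: int = 1_000_000,
    seed: int = 0,
    cap: int = DEFAULT_CAP,
    table: MieTable | None = None,
    engine: str = "numba",
    config: dict | None = None,
) -> EmissionSummary:
    """Full slab simulation: birth depths, transport, aggregate budget.

    The user seed feeds a :class:`numpy.random.SeedSequence`; one child
    stream draws the birth depths, a second (31-bit) child seeds the
    transport kernel, so the whole run is reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed)
    depth_state, kernel_state = ss.generate_state(2)
    depth_rng = np.random.default_rng(int(depth_state))
    kernel_seed = int(kernel_state) % (2**31)

    birth_z = deposition.sample_birth_depths(layer, n_photons, depth_rng)
    if table is None:
        table = mie_table(gsd, optics, packing_fraction=layer.packing_fraction)
    dquant = gsd.quantile_table()
    run = _kernel if engine == "numba" else _python_engine
    fates, ex, ey, n_int, cap_hits = run(
        kernel_seed, birth_z, layer.thickness_um, dquant,
        float(table.diameters_um[0]), table.grid_step or 1.0,
        len(table.diameters_um), table.m_ext, table.albedo, table.g, cap,
    )
    trans = fates == TRANSMITTED
    refl = fates == REFLECTED
    return EmissionSummary(
        n_photons=n_photons,
        n_absorbed=int(np.sum(fates == ABSORBED)),
        n_reflected=int(np.sum(refl)),
        n_transmitted=int(np.sum(trans)),
        transmitted_offsets_um=np.column_stack([ex[trans], ey[trans]]),
        reflected_offsets_um=np.column_stack([ex[refl], ey[refl]]),
        n_interactions_total=int(np.sum(n_int)),
        cap_hits=int(cap_hits),
        seed=seed,
        config=config or {},
    )
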