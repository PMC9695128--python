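"""Imaging metrics: point-spread tallies to MTF and limiting resolution.

All photons in a run are born on one vertical axis, so the transmission-
side exit offsets directly sample the point spread function (PSF).  The
chain is the standard one: the PSF's x-marginal histogram is the line
spread function (LSF); the modulus of its Fourier transform, normalized
at zero frequency, is the modulation transfer function (MTF); limiting
resolution is quoted at the first downward crossing of a modulation
level (10% by convention), in cycles/mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LineSpreadFunction", "MTFCurve", "build_lsf", "mtf_from_lsf",
           "resolution_at", "mtf_for_run"]

MIN_EXIT_EVENTS = 1000


@dataclass(frozen=True)
class LineSpreadFunction:
    """Unit-area LSF on a uniform position grid (um)."""

    centers_um: np.ndarray
    amplitude: np.ndarray   # 1/um; sum * bin_width == 1
    bin_width_um: float

    def __post_init__(self) -> None:
        if np.any(self.amplitude < 0):
            raise ValueError("LSF amplitudes must be non-negative")
        area = float(np.sum(self.amplitude) * self.bin_width_um)
        if abs(area - 1.0) > 1e-9:
            raise ValueError(f"LSF must integrate to 1, got {area}")

    def fwhm_um(self) -> float:
        """Full width at half maximum by linear interpolation."""
        a = self.amplitude
        half = a.max() / 2.0
        above = np.nonzero(a >= half)[0]
        i, j = above[0], above[-1]
        c, w = self.centers_um, self.bin_width_um
        left = c[i] if i == 0 else c[i] - w * (a[i] - half) / (a[i] - a[i - 1])
        right = c[j] if j == len(a) - 1 else c[j] + w * (a[j] - half) / (a[j] - a[j + 1])
        return float(right - left)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_um": self.centers_um,
                             "lsf_per_um": self.amplitude})


@dataclass(frozen=True)
class MTFCurve:
    """Modulation versus spatial frequency (cycles/mm), MTF(0) = 1."""

    frequency_cyc_mm: np.ndarray
    modulation: np.ndarray

    def __post_init__(self) -> None:
        if self.frequency_cyc_mm[0] != 0 or abs(self.modulation[0] - 1.0) > 1e-12:
            raise ValueError("MTF must start at (0, 1)")
        if np.any(np.diff(self.frequency_cyc_mm) <= 0):
            raise ValueError("frequencies must ascend")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_cyc_mm": self.frequency_cyc_mm,
                             "mtf": self.modulation})


def build_lsf(
    exit_offsets_um: np.ndarray,
    bin_width_um: float = 1.0,
    window_um: float = 500.0,
) -> LineSpreadFunction:
    """Project 2D exit offsets onto x and histogram into a unit-area LSF.

    ``exit_offsets_um`` is (n, 2) or a 1D array of x offsets.  Offsets
    beyond +-window are clipped into the edge bins so that no light is
    lost from the normalization.
    """
    pts = np.asarray(exit_offsets_um, dtype=float)
    x = pts[:, 0] if pts.ndim == 2 else pts
    if x.size < MIN_EXIT_EVENTS:
        raise ValueError(
            f"only {x.size} exit events (< {MIN_EXIT_EVENTS}); increase the photon count"
        )
    n_bins = int(round(2 * window_um / bin_width_um))
    edges = -window_um + bin_width_um * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.clip(x, edges[0], edges[-1] - 1e-12), bins=edges)
    amp = counts / (counts.sum() * bin_width_um)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return LineSpreadFunction(centers_um=centers, amplitude=amp,
                              bin_width_um=bin_width_um)


def mtf_from_lsf(lsf: LineSpreadFunction) -> MTFCurve:
    """MTF as the normalized Fourier modulus of the LSF, up to Nyquist."""
    spec = np.abs(np.fft.rfft(lsf.amplitude))
    mod = spec / spec[0]
    freq_per_um = np.fft.rfftfreq(len(lsf.amplitude), d=lsf.bin_width_um)
    return MTFCurve(frequency_cyc_mm=freq_per_um * 1000.0, modulation=mod)


def resolution_at(mtf: MTFCurve, level: float = 0.10) -> float:
    """Frequency (cycles/mm) of the first downward crossing of ``level``."""
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    f, m = mtf.frequency_cyc_mm, mtf.modulation
    if level == 1.0:
        return 0.0
    below = np.nonzero(m < level)[0]
    if below.size == 0:
        raise ValueError(
            f"MTF never falls below {level} within Nyquist "
            f"(minimum modulation {m.min():.4f})"
        )
    j = int(below[0])
    i = j - 1
    return float(f[i] + (f[j] - f[i]) * (m[i] - level) / (m[i] - m[j]))


def mtf_for_run(summary, bin_width_um: float = 1.0, window_um: float = 500.0):
    """Convenience chain: run summary -> (LSF, MTF, 10% resolution)."""
    lsf = build_lsf(summary.transmitted_offsets_um, bin_width_um, window_um)
    mtf = mtf_from_lsf(lsf)
    return lsf, mtf, resolution_at(mtf, 0.10)
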