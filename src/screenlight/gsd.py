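"""Grain-size distributions: descriptive statistics, fitting, sampling.

Powder phosphor screens are beds of polydisperse grains.  The grain-size
distribution (GSD) is represented either empirically (a set of measured
Feret diameters or a weighted support) or parametrically as a lognormal
truncated to the observed [min, max] window — a right-skewed,
positive-support shape matching the SEM grain counts of all six
characterized samples.  Sampling is number-weighted: each counted grain
is equally likely, as in manual SEM counting.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import ndtr, ndtri

from .samples import Activator, SampleRecord, get_sample

__all__ = [
    "GrainMeasurementSet",
    "DescriptiveStats",
    "GrainSizeDistribution",
    "GSDFitError",
    "compute_descriptive_stats",
    "fit_truncated_lognormal",
    "fit_sample",
    "sample_diameter",
    "generate_sample_measurements",
    "read_diameters",
    "write_diameters",
    "stats_report",
]

#: Bin width (um) used for the mode of continuous diameter data.
MODE_BIN_UM = 0.1


class GSDFitError(ValueError):
    """Raised when no truncated lognormal can match the target moments."""


@dataclass(frozen=True)
class GrainMeasurementSet:
    """A set of per-grain Feret diameters for one powder sample."""

    sample_id: str
    activator: Activator
    diameters_um: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_um, dtype=float)
        object.__setattr__(self, "diameters_um", d)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("need at least 2 grain diameters")
        if not np.all(d > 0):
            raise ValueError("grain diameters must be positive")

    @property
    def n(self) -> int:
        return int(self.diameters_um.size)


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary statistics in the layout of the published sample table.

    ``kurtosis`` is excess kurtosis and ``skewness`` the adjusted
    Fisher–Pearson coefficient, both with the small-sample corrections
    used by common spreadsheet software (and by :meth:`pandas.Series.kurt`
    / :meth:`pandas.Series.skew`).  ``mode_um`` is ``None`` when no value
    (or no 0.1 um bin) clearly repeats.
    """

    mean_um: float
    standard_error_um: float
    median_um: float
    mode_um: float | None
    sd_um: float
    variance_um2: float
    kurtosis: float
    skewness: float
    range_um: float
    min_um: float
    max_um: float
    n: int


def _mode_estimate(d: np.ndarray) -> float | None:
    # Exact repeats first (discrete data); else most populated 0.1 um bin.
    counts = Counter(d.tolist())
    top_val, top_ct = counts.most_common(1)[0]
    if top_ct >= 2 and sum(1 for c in counts.values() if c == top_ct) == 1:
        return float(top_val)
    edges = np.arange(np.floor(d.min() / MODE_BIN_UM) * MODE_BIN_UM,
                      d.max() + MODE_BIN_UM, MODE_BIN_UM)
    if len(edges) < 2:
        return float(np.median(d))
    hist, _ = np.histogram(d, bins=edges)
    top = hist.max()
    if top < 2 or np.sum(hist == top) != 1:
        return None
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2)


def compute_descriptive_stats(measurements: GrainMeasurementSet) -> DescriptiveStats:
    """Compute the full summary-statistics row for a diameter set."""
    d = measurements.diameters_um
    s = pd.Series(d)
    n = len(d)
    sd = float(s.std(ddof=1))
    return DescriptiveStats(
        mean_um=float(s.mean()),
        standard_error_um=sd / np.sqrt(n),
        median_um=float(s.median()),
        mode_um=_mode_estimate(d),
        sd_um=sd,
        variance_um2=sd**2,
        kurtosis=float(s.kurt()) if n > 3 else float("nan"),
        skewness=float(s.skew()) if n > 2 else float("nan"),
        range_um=float(d.max() - d.min()),
        min_um=float(d.min()),
        max_um=float(d.max()),
        n=n,
    )


@dataclass(frozen=True)
class GrainSizeDistribution:
    """Number-weighted diameter distribution, empirical or parametric.

    Parametric form: ``d = exp(Y)`` with ``Y`` normal(mu, sigma) truncated
    to ``[ln lower, ln upper]``.  Empirical form: an atom per support
    diameter with the given probability weight.
    """

    kind: str  # "empirical" | "truncated_lognormal"
    # empirical
    support_um: np.ndarray | None = None
    weights: np.ndarray | None = None
    # parametric
    mu: float | None = None       # log-mean (log um)
    sigma: float | None = None    # log-sd
    lower_um: float | None = None
    upper_um: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "empirical":
            s = np.asarray(self.support_um, dtype=float)
            w = np.asarray(self.weights, dtype=float)
            if s.size == 0 or s.size != w.size:
                raise ValueError("support and weights must be non-empty, equal length")
            if not np.all(s > 0):
                raise ValueError("support diameters must be positive")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be >= 0 and sum to 1")
            order = np.argsort(s)
            object.__setattr__(self, "support_um", s[order])
            object.__setattr__(self, "weights", w[order])
            object.__setattr__(self, "lower_um", float(s.min()))
            object.__setattr__(self, "upper_um", float(s.max()))
        elif self.kind == "truncated_lognormal":
            if self.lower_um is None or self.upper_um is None:
                raise ValueError("parametric GSD needs truncation bounds")
            if not (0 < self.lower_um < self.upper_um):
                raise ValueError("need 0 < lower < upper truncation")
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("sigma must be > 0 (use an empirical atom for a spike)")
        else:
            raise ValueError(f"unknown GSD kind {self.kind!r}")

    # -- truncated-normal helpers (parametric kind) ---------------------
    def _alpha_beta(self) -> tuple[float, float]:
        a = (np.log(self.lower_um) - self.mu) / self.sigma
        b = (np.log(self.upper_um) - self.mu) / self.sigma
        return a, b

    def _raw_moment(self, k: int) -> float:
        a, b = self._alpha_beta()
        z = ndtr(b) - ndtr(a)
        return float(
            np.exp(k * self.mu + 0.5 * k**2 * self.sigma**2)
            * (ndtr(b - k * self.sigma) - ndtr(a - k * self.sigma)) / z
        )

    def mean(self) -> float:
        """Analytic mean diameter, um."""
        if self.kind == "empirical":
            return float(np.sum(self.support_um * self.weights))
        return self._raw_moment(1)

    def sd(self) -> float:
        """Analytic standard deviation, um."""
        if self.kind == "empirical":
            m = self.mean()
            return float(np.sqrt(np.sum(self.weights * (self.support_um - m) ** 2)))
        m1, m2 = self._raw_moment(1), self._raw_moment(2)
        return float(np.sqrt(max(m2 - m1**2, 0.0)))

    def ppf(self, q):
        """Inverse CDF; maps uniforms on [0, 1] to diameters in um."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantiles must lie in [0, 1]")
        if self.kind == "empirical":
            cum = np.cumsum(self.weights)
            idx = np.searchsorted(cum, q, side="left")
            idx = np.clip(idx, 0, len(self.support_um) - 1)
            return self.support_um[idx]
        a, b = self._alpha_beta()
        fa, fb = ndtr(a), ndtr(b)
        y = self.mu + self.sigma * ndtri(np.clip(fa + q * (fb - fa), 1e-300, 1.0))
        return np.clip(np.exp(y), self.lower_um, self.upper_um)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` diameters (um) by inverse-CDF sampling."""
        return self.ppf(rng.random(n))

    def quantile_table(self, n: int = 4096) -> np.ndarray:
        """Inverse-CDF lookup table on n+1 equispaced quantiles.

        Linear interpolation of this table is the sampling rule used by
        the compiled transport kernel.
        """
        return np.asarray(self.ppf(np.linspace(0.0, 1.0, n + 1)), dtype=float)


def fit_truncated_lognormal(
    target: DescriptiveStats | SampleRecord,
    mean_rtol: float = 0.01,
    sd_rtol: float = 0.05,
) -> GrainSizeDistribution:
    """Fit a lognormal truncated to [min, max] matching the target mean/sd.

    Only mean, sd, min and max are fit targets; higher moments follow from
    the shape.  The (log-mean, log-sd) pair is found by least-squares
    root-finding on the analytic truncated moments and is deterministic
    given the target.  A target sd below 1e-9 um returns a degenerate
    single-atom (spike) distribution at the mean.

    Raises
    ------
    GSDFitError
        If no parameter pair reaches the target within ``mean_rtol`` on
        the mean and ``sd_rtol`` on the sd; the message reports the best
        achievable sd.
    """
    mean = float(getattr(target, "mean_um"))
    sd = float(getattr(target, "sd_um"))
    lo = float(getattr(target, "min_um"))
    hi = float(getattr(target, "max_um"))
    if not (mean > 0 and sd >= 0 and 0 < lo < hi):
        raise ValueError("target needs positive mean/sd and 0 < min < max")
    if sd <= 1e-9:
        return GrainSizeDistribution(
            kind="empirical", support_um=np.array([mean]), weights=np.array([1.0])
        )

    def make(params):
        mu, log_sigma = params
        return GrainSizeDistribution(
            kind="truncated_lognormal", mu=float(mu),
            sigma=float(np.exp(log_sigma)), lower_um=lo, upper_um=hi,
        )

    def resid(params):
        g = make(params)
        return [g.mean() / mean - 1.0, g.sd() / sd - 1.0]

    sigma0 = np.sqrt(np.log1p((sd / mean) ** 2))
    x0 = [np.log(mean) - sigma0**2 / 2, np.log(sigma0)]
    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    g = make(sol.x)
    if abs(g.mean() / mean - 1.0) > mean_rtol or abs(g.sd() / sd - 1.0) > sd_rtol:
        raise GSDFitError(
            f"cannot reach mean={mean} sd={sd} on [{lo}, {hi}]; "
            f"best achievable mean={g.mean():.4g}, sd={g.sd():.4g}"
        )
    return g


def fit_sample(sample_id: str) -> GrainSizeDistribution:
    """Fitted truncated-lognormal surrogate GSD for a registered sample."""
    return fit_truncated_lognormal(get_sample(sample_id))


def sample_diameter(gsd: GrainSizeDistribution, rng: np.random.Generator) -> float:
    """Draw one diameter (um) from the distribution."""
    return float(gsd.sample(1, rng)[0])


def generate_sample_measurements(
    sample_id: str, n: int | None = None, rng: np.random.Generator | None = None
) -> GrainMeasurementSet:
    """Synthesize a Feret-diameter measurement set for a registered sample.

    Stands in for SEM grain counting: draws ``n`` diameters (default: the
    published counted-grain number) from the fitted surrogate GSD.
    """
    rec = get_sample(sample_id)
    n = rec.n if n is None else int(n)
    if n < 2:
        raise ValueError("need n >= 2 grains")
    rng = np.random.default_rng() if rng is None else rng
    d = fit_sample(sample_id).sample(n, rng)
    return GrainMeasurementSet(sample_id=sample_id, activator=rec.activator,
                               diameters_um=np.asarray(d))


# -- plain-text I/O ------------------------------------------------------

def read_diameters(path: str | Path) -> np.ndarray:
    """Read one-diameter-per-line text, or two-column CSV (diameter, weight).

    Returns a diameter array; CSV weights are returned by
    :func:`read_weighted` instead.
    """
    return np.loadtxt(path, ndmin=1, usecols=0, delimiter=None)


def read_weighted(path: str | Path) -> GrainSizeDistribution:
    """Read a two-column CSV (diameter_um, weight) as an empirical GSD."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    w = arr[:, 1] / arr[:, 1].sum()
    return GrainSizeDistribution(kind="empirical", support_um=arr[:, 0], weights=w)


def write_diameters(path: str | Path, diameters_um: np.ndarray) -> None:
    np.savetxt(path, np.asarray(diameters_um), fmt="%.6f")


_STAT_ROWS = [
    ("Mean grain size (um)", "mean_um"),
    ("Standard error", "standard_error_um"),
    ("Median grain size (um)", "median_um"),
    ("Mode grain size (um)", "mode_um"),
    ("Standard deviation", "sd_um"),
    ("Sample variance", "variance_um2"),
    ("Kurtosis", "kurtosis"),
    ("Skewness", "skewness"),
    ("Range (um)", "range_um"),
    ("Minimum grain size (um)", "min_um"),
    ("Maximum grain size (um)", "max_um"),
    ("Counted grains", "n"),
]


def stats_report(stats_by_sample: dict[str, DescriptiveStats]) -> pd.DataFrame:
    """Summary-statistics table, one column per sample (publication layout)."""
    data = {}
    for sid, st in stats_by_sample.items():
        d = dataclasses.asdict(st)
        data[sid] = ["N/A" if d[key] is None else d[key] for _, key in _STAT_ROWS]
    return pd.DataFrame(data, index=[label for label, _ in _STAT_ROWS])
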