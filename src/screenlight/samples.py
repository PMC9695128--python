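"""Registry of the six characterized Gd2O2S powder samples.

Six commercial Gd2O2S phosphor powders, doped with Tb, Eu, or Pr,Ce,F,
were characterized by SEM grain counting (Feret diameters).  This module
stores their published summary statistics and the emission wavelength of
each activator, which together parameterize every downstream simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Activator(str, Enum):
    """Rare-earth dopant of the Gd2O2S host; fixes the emission line."""

    TB = "Tb"
    EU = "Eu"
    PRCEF = "PrCeF"


#: Vacuum emission wavelength per activator, nm.
EMISSION_WAVELENGTH_NM: dict[Activator, float] = {
    Activator.TB: 545.0,
    Activator.EU: 623.0,
    Activator.PRCEF: 513.0,
}


@dataclass(frozen=True)
class SampleRecord:
    """Published grain-size summary for one commercial powder sample."""

    sample_id: str
    activator: Activator
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

    @property
    def wavelength_nm(self) -> float:
        return EMISSION_WAVELENGTH_NM[self.activator]


SAMPLES: dict[str, SampleRecord] = {
    r.sample_id: r
    for r in [
        SampleRecord("UKL65/UF-R1", Activator.TB, 1.232, 0.046, 1.105, None,
                     0.424, 0.180, 8.809, 2.163, 2.925, 0.566, 3.492, 83),
        SampleRecord("UKL65/F-R1", Activator.TB, 2.377, 0.081, 2.170, 1.473,
                     1.031, 1.064, 1.589, 1.286, 5.000, 0.894, 5.894, 162),
        SampleRecord("UKL63/UF-R1", Activator.EU, 1.769, 0.050, 1.604, 1.435,
                     0.701, 0.491, 0.038, 0.760, 3.118, 0.609, 3.727, 196),
        SampleRecord("UKL63/N-R1", Activator.EU, 3.644, 0.117, 3.582, None,
                     1.170, 1.368, 1.621, 0.804, 6.552, 1.422, 7.974, 100),
        SampleRecord("UKL59CF/F-R1", Activator.PRCEF, 1.784, 0.051, 1.675, 1.766,
                     0.566, 0.321, 2.082, 1.130, 3.183, 0.884, 4.067, 125),
        SampleRecord("UKL59CF/S-R1", Activator.PRCEF, 3.677, 0.139, 3.338, 3.326,
                     1.542, 2.377, 2.885, 1.362, 8.817, 1.162, 9.979, 123),
    ]
}

#: "Small-grain" set (similar means near 1.2-1.8 um) and "large-grain" set.
SMALL_GRAIN_SET = ("UKL65/UF-R1", "UKL63/UF-R1", "UKL59CF/F-R1")
LARGE_GRAIN_SET = ("UKL65/F-R1", "UKL63/N-R1", "UKL59CF/S-R1")


def get_sample(sample_id: str) -> SampleRecord:
    """Look up a sample by its commercial code.

    Raises
    ------
    KeyError
        With the list of valid codes, when the code is unknown.
    """
    try:
        return SAMPLES[sample_id]
    except KeyError:
        raise KeyError(
            f"unknown sample code {sample_id!r}; valid codes: "
            + ", ".join(sorted(SAMPLES))
        ) from None


def sample_by_mean(mean_um: float, tol: float = 1e-6) -> SampleRecord:
    """Look up a sample by its published mean grain size (unique here)."""
    for rec in SAMPLES.values():
        if abs(rec.mean_um - mean_um) <= tol:
            return rec
    raise KeyError(f"no sample with mean grain size {mean_um} um")
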