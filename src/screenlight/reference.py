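"""Published emission budgets for the six samples, and label reconciliation.

The original study prints per-sample absorption/reflection/transmission
budgets for the 100 um and 200 um screens, plus derived transmission
increases between the two thicknesses.  The printed 200 um table carries
a row-labeling error: one sample label appears twice and one sample is
missing.  The discussion's derived percentages (the thickness contrasts
and an absorption pair) pin down the unique consistent relabeling, which
:func:`reconcile_budget_labels` recovers by exhaustive search over all
row-to-sample assignments.  Downstream comparisons use the corrected
mapping; both versions are exported so the discrepancy stays visible.
"""

from __future__ import annotations

from itertools import permutations

__all__ = [
    "Budget",
    "BUDGETS_100",
    "BUDGETS_200_PRINTED",
    "BUDGETS_200_CORRECTED",
    "REPORTED_TRANSMISSION_INCREASE_PCT",
    "REPORTED_RESOLUTION_CYC_MM",
    "reconcile_budget_labels",
]

#: (absorption %, reflection %, transmission %)
Budget = tuple[float, float, float]

#: 100 um screen budgets; row labels are consistent as printed.
BUDGETS_100: dict[str, Budget] = {
    "UKL65/UF-R1": (24.51, 43.30, 32.19),   # Tb, 1.232 um
    "UKL63/UF-R1": (25.45, 42.74, 31.81),   # Eu, 1.769 um
    "UKL59CF/F-R1": (19.23, 45.94, 34.83),  # Pr,Ce,F, 1.784 um
    "UKL65/F-R1": (12.44, 49.33, 38.23),    # Tb, 2.377 um
    "UKL63/N-R1": (8.17, 51.37, 40.46),     # Eu, 3.644 um
    "UKL59CF/S-R1": (8.46, 51.10, 40.44),   # Pr,Ce,F, 3.677 um
}

#: 200 um budgets in printed row order with the printed (faulty) labels.
BUDGETS_200_PRINTED: list[tuple[str, Budget]] = [
    ("UKL65/UF-R1", (50.52, 34.28, 15.20)),
    ("UKL63/UF-R1", (42.15, 38.92, 18.93)),
    ("UKL65/F-R1", (46.35, 36.57, 17.08)),
    ("UKL63/N-R1", (31.98, 44.49, 23.53)),
    ("UKL59CF/S-R1", (22.82, 49.19, 27.89)),
    ("UKL65/F-R1", (21.89, 49.69, 28.32)),   # duplicate label as printed
]

#: Reported transmission increase 100 um vs 200 um, percent, per sample.
REPORTED_TRANSMISSION_INCREASE_PCT: dict[str, float] = {
    "UKL65/UF-R1": 111.8,
    "UKL65/F-R1": 62.5,
    "UKL63/UF-R1": 68.0,
    "UKL63/N-R1": 45.1,
    "UKL59CF/F-R1": 103.9,
    "UKL59CF/S-R1": 42.8,
}

#: Reported absorption pair at 200 um for the two large-grain Eu / Pr,Ce,F samples.
REPORTED_ABSORPTION_200_PAIR: dict[str, float] = {
    "UKL63/N-R1": 22.82,
    "UKL59CF/S-R1": 21.89,
}

#: Reported 10%-MTF limiting resolutions, cycles/mm, keyed (sample, thickness um).
REPORTED_RESOLUTION_CYC_MM: dict[tuple[str, int], float] = {
    ("UKL65/UF-R1", 100): 12.9,
    ("UKL65/UF-R1", 200): 11.6,
    ("UKL65/F-R1", 100): 12.1,
    ("UKL65/F-R1", 200): 9.6,
}


def transmission_increase_pct(t_thin: float, t_thick: float) -> float:
    """Derived thickness contrast, 100*(T_thin - T_thick)/T_thick."""
    return 100.0 * (t_thin / t_thick - 1.0)


def reconcile_budget_labels(
    budgets_100: dict[str, Budget] | None = None,
    rows_200: list[tuple[str, Budget]] | None = None,
    reported_increase: dict[str, float] | None = None,
    reported_absorption: dict[str, float] | None = None,
    tol_increase: float = 2.0,
    tol_absorption: float = 0.005,
) -> dict[str, Budget]:
    """Recover the unique sample-to-row mapping of the 200 um budget table.

    Tries every assignment of the six 200 um rows to the six samples and
    keeps those for which (a) every derived transmission increase matches
    the reported contrast within ``tol_increase`` percentage points and
    (b) the reported 200 um absorption pair lands on the right samples.

    Returns the corrected mapping; raises if no assignment or more than
    one assignment survives.
    """
    budgets_100 = budgets_100 or BUDGETS_100
    rows = [b for _, b in (rows_200 or BUDGETS_200_PRINTED)]
    inc = reported_increase or REPORTED_TRANSMISSION_INCREASE_PCT
    absorb = reported_absorption or REPORTED_ABSORPTION_200_PAIR
    samples = list(budgets_100)

    matches = []
    for perm in permutations(range(len(rows))):
        mapping = {sid: rows[perm[i]] for i, sid in enumerate(samples)}
        ok = all(
            abs(transmission_increase_pct(budgets_100[sid][2], mapping[sid][2])
                - inc[sid]) <= tol_increase
            for sid in samples
        ) and all(
            abs(mapping[sid][0] - a) <= tol_absorption for sid, a in absorb.items()
        )
        if ok:
            matches.append(mapping)
    if len(matches) != 1:
        raise ValueError(
            f"expected a unique consistent relabeling, found {len(matches)}"
        )
    return matches[0]


#: Corrected 200 um budgets (the unique reconciliation result, spelled out).
BUDGETS_200_CORRECTED: dict[str, Budget] = {
    "UKL65/UF-R1": (50.52, 34.28, 15.20),
    "UKL63/UF-R1": (42.15, 38.92, 18.93),
    "UKL59CF/F-R1": (46.35, 36.57, 17.08),
    "UKL65/F-R1": (31.98, 44.49, 23.53),
    "UKL63/N-R1": (22.82, 49.19, 27.89),
    "UKL59CF/S-R1": (21.89, 49.69, 28.32),
}
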