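"""Bilateral-asymmetry statistics for small two-group thickness cohorts.

The unit of analysis is the percent bilateral asymmetry of a per-hemisphere
ROI measurement,

    asym% = 100 * |L - R| / ((L + R) / 2),

which is symmetric in the hemispheres, scale-invariant, and bounded in
[0, 200) for positive inputs.  Groups are compared with the Kruskal-Wallis
rank test (exact by enumeration at small N, chi-square approximation
otherwise), and a two-sample t-test power model gives the minimal detectable
group difference at a target power.

A reference cohort of four lower-limb amputees and four age/sex-matched
controls (precentral leg-area ROI means, mm) ships with the module as
:func:`example_cohort`, so the statistics path can be exercised without any
imaging data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import tt_ind_solve_power

COHORT_COLUMNS = ("subject_id", "group", "metric", "left", "right", "asym_percent")

ALPHA_DEFAULT = 0.05
EXACT_N_MAX = 12  # auto-select complete enumeration up to this pooled size


def bilateral_asymmetry(left, right):
    """Percent bilateral asymmetry: 100 * |L - R| / mean(L, R).

    Accepts scalars or arrays; both hemispheres must be strictly positive.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("hemisphere measurements must be strictly positive")
    out = 100.0 * np.abs(left - right) / ((left + right) / 2.0)
    return float(out) if out.ndim == 0 else out


def round_half_up(x, decimals: int = 0):
    """Round to ``decimals`` places with ties rounded up, elementwise."""
    arr = np.asarray(x, dtype=float)
    f = 10.0**decimals
    out = np.floor(arr * f + 0.5) / f
    if arr.ndim == 0:
        return int(out) if decimals <= 0 else float(out)
    return out.astype(int) if decimals <= 0 else out


def cohort_table(records) -> pd.DataFrame:
    """Build a cohort table, recomputing the asym_percent column."""
    df = pd.DataFrame(records)
    missing = set(COHORT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df = df.copy()
    df["asym_percent"] = bilateral_asymmetry(df["left"].to_numpy(), df["right"].to_numpy())
    return df[list(COHORT_COLUMNS)]


# Reference cohort: per-subject left/right ROI means (mm) in the leg area of
# the primary motor cortex, four controls and four amputees, two metrics.
_EXAMPLE_ROWS = [
    # (subject, group, myelinated L, myelinated R, cortical L, cortical R)
    ("control_1", "control", 4.0, 3.1, 4.6, 4.2),
    ("control_2", "control", 3.1, 3.2, 3.9, 4.2),
    ("control_3", "control", 2.6, 3.1, 3.4, 3.9),
    ("control_4", "control", 4.1, 3.3, 4.5, 4.5),
    ("amputee_1", "amputee", 3.5, 2.8, 4.4, 4.0),
    ("amputee_2", "amputee", 3.6, 3.2, 4.9, 4.1),
    ("amputee_3", "amputee", 3.5, 3.0, 4.4, 3.9),
    ("amputee_4", "amputee", 2.9, 2.4, 4.1, 3.3),
]

# Integer percent-asymmetry values as published alongside the reference
# cohort; kept for cross-checking the rounding convention, not used in any
# computation (the pipeline always recomputes asymmetry from left/right).
EXAMPLE_REPORTED_ASYM = {
    "myelinated_thickness": {
        "control": (25, 2, 19, 22),
        "amputee": (22, 12, 15, 21),
    },
    "cortical_thickness": {
        "control": (10, 8, 15, 0),
        "amputee": (7, 18, 12, 22),
    },
}


def example_cohort() -> pd.DataFrame:
    """The bundled reference cohort as a tidy table (asymmetry recomputed)."""
    records = []
    for sid, group, ml, mr, tl, tr in _EXAMPLE_ROWS:
        records.append(
            {"subject_id": sid, "group": group, "metric": "myelinated_thickness",
             "left": ml, "right": mr}
        )
        records.append(
            {"subject_id": sid, "group": group, "metric": "cortical_thickness",
             "left": tl, "right": tr}
        )
    return cohort_table(records)


def summarize_group(table: pd.DataFrame, group: str, metric: str, column: str):
    """Arithmetic mean and sample SD (n-1) of one column for one group/metric."""
    sel = table[(table["group"] == group) & (table["metric"] == metric)][column]
    if len(sel) < 2:
        raise ValueError(
            f"need >= 2 rows for group={group!r}, metric={metric!r}; got {len(sel)}"
        )
    vals = sel.to_numpy(dtype=float)
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# Kruskal-Wallis


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _h_from_rank_sums(rank_sums, sizes, n_total, tie_term):
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        rs**2 / n for rs, n in zip(rank_sums, sizes)
    ) - 3.0 * (n_total + 1)
    if tie_term > 0:
        denom = 1.0 - tie_term / (n_total**3 - n_total)
        if denom <= 0:  # all values identical
            return 0.0
        h /= denom
    return h


def _rank_setup(samples):
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    ranks = sps.rankdata(pooled)  # midranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return pooled, ranks, tie_term


def h_statistic(*samples) -> float:
    """Kruskal-Wallis H with midrank ties and the tie correction factor."""
    sizes = [len(s) for s in samples]
    pooled, ranks, tie_term = _rank_setup(samples)
    n_total = len(pooled)
    idx = np.cumsum([0] + sizes)
    rank_sums = [ranks[idx[i]: idx[i + 1]].sum() for i in range(len(samples))]
    return _h_from_rank_sums(rank_sums, sizes, n_total, tie_term)


def kruskal_wallis(a, b, method: str = "auto", alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Two-group Kruskal-Wallis test.

    ``method='chi_square_approx'`` refers H to chi-square with 1 df;
    ``'exact_permutation'`` enumerates all C(N, n_a) assignments of the
    pooled values to the groups and reports the proportion with H at least
    as large as observed.  ``'auto'`` selects the exact test for pooled
    N <= 12.  Identical pooled values give H = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must have size >= 2")
    n_total = len(a) + len(b)
    if method == "auto":
        method = "exact_permutation" if n_total <= EXACT_N_MAX else "chi_square_approx"
    if method not in ("chi_square_approx", "exact_permutation"):
        raise ValueError(f"unknown method {method!r}")

    pooled, ranks, tie_term = _rank_setup([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, method, alpha)
    rank_sum_a = float(ranks[: len(a)].sum())
    total_ranks = float(ranks.sum())
    sizes = (len(a), len(b))

    def h_of(rs_a):
        return _h_from_rank_sums((rs_a, total_ranks - rs_a), sizes, n_total, tie_term)

    h_obs = h_of(rank_sum_a)

    if method == "chi_square_approx":
        p = float(sps.chi2.sf(h_obs, df=1))
        return TestResult(h_obs, min(p, 1.0), method, alpha)

    count = 0
    total = 0
    for idx in combinations(range(n_total), len(a)):
        rs = float(ranks[list(idx)].sum())
        if h_of(rs) >= h_obs - 1e-12:
            count += 1
        total += 1
    return TestResult(h_obs, count / total, method, alpha)


def compare_asymmetry(table: pd.DataFrame, metric: str, groups=("control", "amputee"),
                      method: str = "auto") -> TestResult:
    """Kruskal-Wallis comparison of percent asymmetry between two groups."""
    samples = [
        table[(table["group"] == g) & (table["metric"] == metric)]["asym_percent"]
        .to_numpy(dtype=float)
        for g in groups
    ]
    return kruskal_wallis(*samples, method=method)


# ---------------------------------------------------------------------------
# Power / sample-size analysis (two-sample t-test model)


def power_two_sample_t(delta: float, sd: float, n_per_group: int,
                       alpha: float = ALPHA_DEFAULT) -> float:
    """Power of the two-sided two-sample t-test for a mean difference delta."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(
        tt_ind_solve_power(effect_size=delta / sd, nobs1=n_per_group, alpha=alpha,
                           power=None, ratio=1.0, alternative="two-sided")
    )


def detectable_difference(n_per_group: int, sd: float, alpha: float = ALPHA_DEFAULT,
                          power: float = 0.8) -> float:
    """Smallest mean difference detectable at the given power and alpha.

    Solves the noncentral-t power equation of the two-sided two-sample
    t-test for the effect size and rescales by ``sd``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    es = tt_ind_solve_power(effect_size=None, nobs1=n_per_group, alpha=alpha,
                            power=power, ratio=1.0, alternative="two-sided")
    return float(es) * sd


def required_sample_size(delta: float, sd: float, alpha: float = ALPHA_DEFAULT,
                         power: float = 0.8) -> int:
    """Per-group n needed to detect a mean difference delta (rounded up)."""
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    n = tt_ind_solve_power(effect_size=delta / sd, nobs1=None, alpha=alpha,
                           power=power, ratio=1.0, alternative="two-sided")
    return int(math.ceil(float(n)))
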