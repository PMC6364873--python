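"""Paired cohort comparison: percent differences, Wilcoxon signed-rank
tests and mean +/- SD aggregation.

The exact signed-rank test enumerates the full null distribution of the
positive-rank sum over all 2^n sign assignments (computed by dynamic
programming over doubled mid-ranks, so ties are handled exactly); the
approximate mode uses the tie-corrected normal approximation.  Zero
differences are dropped before ranking, the usual signed-rank convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def percent_diff(reference: float, comparison: float) -> float | None:
    """(reference - comparison) / reference * 100.

    Positive means the comparison value is smaller — an improvement for
    dose-bath style metrics.  Undefined (None) when the reference is zero.
    """
    if reference == 0:
        return None
    return (reference - comparison) / reference * 100.0


def aggregate_mean_sd(values, round_to_int: bool = False
                      ) -> tuple[float, float | None]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("no values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    if round_to_int:
        mean = float(np.rint(mean))
        sd = None if sd is None else float(np.rint(sd))
    return mean, sd


def _exact_wplus_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of the positive-rank sum over all 2^n sign assignments.

    Ranks are doubled so mid-ranks from ties become integers; index k of
    the returned array counts assignments with doubled W+ equal to k.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided",
                         mode: str = "auto") -> tuple[float, float]:
    """Signed-rank test on paired data (or on differences if y is None).

    Returns (W+, p) where W+ is the sum of the ranks of the positive
    differences.  ``mode``: ``exact`` enumerates the 2^n null distribution
    (ties handled via mid-ranks), ``approx`` is the tie-corrected normal
    approximation, ``auto`` picks exact for n <= 20 after zero removal.
    """
    d = np.asarray(x, float) - (0 if y is None else np.asarray(y, float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    wplus = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= 20 else "approx"
    if mode == "approx":
        res = stats.wilcoxon(d, alternative=alternative, method="approx",
                             correction=True)
        return wplus, float(res.pvalue)
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    doubled = np.rint(2 * ranks).astype(int)
    counts = _exact_wplus_distribution(doubled)
    total = 2.0 ** n
    w2 = int(round(2 * wplus))
    cdf = counts[:w2 + 1].sum() / total
    sf = counts[w2:].sum() / total
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(cdf, sf))
    elif alternative == "greater":
        p = sf
    elif alternative == "less":
        p = cdf
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return wplus, float(p)


# --------------------------------------------------------------- cohorts

@dataclass
class PairedCohort:
    """Per-patient metric tables for two planning conditions.

    ``table_a`` and ``table_b`` are patients x metrics DataFrames with
    identical indexes and columns (build them with
    ``PlanMetrics.to_series``).
    """

    name_a: str
    name_b: str
    table_a: pd.DataFrame
    table_b: pd.DataFrame

    def __post_init__(self):
        if not self.table_a.index.equals(self.table_b.index):
            raise ValueError("patient lists differ between conditions")
        if list(self.table_a.columns) != list(self.table_b.columns):
            raise ValueError("metric registries differ between conditions")
        if len(self.table_a) < 2:
            raise ValueError("need at least 2 patients for paired testing")


def from_metrics(name_a: str, metrics_a: list, name_b: str, metrics_b: list
                 ) -> PairedCohort:
    ta = pd.DataFrame([m.to_series() for m in metrics_a])
    tb = pd.DataFrame([m.to_series() for m in metrics_b])
    ta.index = tb.index = range(len(metrics_a))
    return PairedCohort(name_a, name_b, ta, tb)


def cohort_table(cohort: PairedCohort, alpha: float = 0.05,
                 mode: str = "auto") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-metric comparison table and per-patient percent differences.

    The comparison table lists mean +/- SD per condition, the two-sided
    signed-rank p value and a significance flag at ``alpha``; patients
    with a missing value for a metric are excluded pairwise (the count
    used is reported).  The percent-difference matrix uses condition B as
    the reference, (B - A)/B * 100, with a population-mean row appended.
    """
    rows = []
    pct = pd.DataFrame(index=cohort.table_a.index,
                       columns=cohort.table_a.columns, dtype=float)
    for col in cohort.table_a.columns:
        a = pd.to_numeric(cohort.table_a[col], errors="coerce")
        b = pd.to_numeric(cohort.table_b[col], errors="coerce")
        ok = a.notna() & b.notna()
        n = int(ok.sum())
        for i in cohort.table_a.index[ok]:
            pd_val = percent_diff(b[i], a[i])
            pct.loc[i, col] = np.nan if pd_val is None else pd_val
        if n < 2:
            rows.append({"metric": col, "n": n})
            continue
        mean_a, sd_a = aggregate_mean_sd(a[ok])
        mean_b, sd_b = aggregate_mean_sd(b[ok])
        if np.allclose(a[ok], b[ok]):
            p = 1.0
        else:
            _, p = wilcoxon_signed_rank(a[ok], b[ok], mode=mode)
        rows.append({"metric": col, "n": n,
                     f"mean_{cohort.name_a}": mean_a,
                     f"sd_{cohort.name_a}": sd_a,
                     f"mean_{cohort.name_b}": mean_b,
                     f"sd_{cohort.name_b}": sd_b,
                     "p": p, "significant": bool(p < alpha)})
    table = pd.DataFrame(rows).set_index("metric")
    pct.loc["population mean"] = pct.mean(axis=0, skipna=True)
    return table, pct
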