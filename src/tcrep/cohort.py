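"""Group-level comparison of diversity statistics across cohort arms.

Comparisons use the unpaired two-tailed two-sample t-test.  The default is
the pooled-variance (Student) form; Welch's unequal-variance form is
available via a flag — note that plain ``t.test`` in R defaults to Welch, so
analyses citing "the R t-test" without detail are ambiguous between the two.
No multiple-testing correction is applied across comparisons; all raw
p-values are reported together so users can correct as they see fit.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["group_summary", "ttest_unpaired", "compare_groups"]


def group_summary(values, labels, groups=None) -> pd.DataFrame:
    """Per-group median (midpoint convention for even n) and (min, max) range.

    ``groups`` optionally fixes the admissible label set; an observation with
    a label outside it raises ``ValueError``.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    if groups is not None:
        unknown = set(labels) - set(groups)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        order = list(groups)
    else:
        order = list(dict.fromkeys(labels))
    rows = []
    for g in order:
        v = values[[lab == g for lab in labels]]
        if len(v) == 0:
            continue
        rows.append(
            {
                "group": g,
                "n": len(v),
                "median": float(np.median(v)),
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)


def ttest_unpaired(a, b, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed two-sample t-test; returns ``(t, p)``.

    Pooled-variance (Student) by default, Welch when requested.  When both
    groups are degenerate (zero variance): equal means give ``(0.0, 1.0)`` by
    convention, unequal means are an error (the statistic is infinite).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_groups(
    diversity_table: pd.DataFrame,
    statistics=("entropy", "hec_count", "hec_ratio"),
    welch: bool = False,
) -> pd.DataFrame:
    """All pairwise group comparisons of the given statistics, per cell subset.

    ``diversity_table`` is the per-sample cohort table (columns sample_id,
    group, subset, n_clones, entropy, hec_count, hec_ratio).  Output rows
    carry group medians/ranges alongside the t statistic and raw two-tailed
    p-value.
    """
    rows = []
    for subset in sorted(diversity_table["subset"].unique()):
        sub = diversity_table[diversity_table["subset"] == subset]
        groups = sorted(sub["group"].unique())
        for stat in statistics:
            for ga, gb in combinations(groups, 2):
                va = sub.loc[sub["group"] == ga, stat].to_numpy(dtype=float)
                vb = sub.loc[sub["group"] == gb, stat].to_numpy(dtype=float)
                if len(va) < 2 or len(vb) < 2:
                    continue
                t, p = ttest_unpaired(va, vb, welch=welch)
                rows.append(
                    {
                        "statistic": stat,
                        "subset": subset,
                        "group_a": ga,
                        "group_b": gb,
                        "n_a": len(va),
                        "n_b": len(vb),
                        "median_a": float(np.median(va)),
                        "min_a": float(va.min()),
                        "max_a": float(va.max()),
                        "median_b": float(np.median(vb)),
                        "min_b": float(vb.min()),
                        "max_b": float(vb.max()),
                        "t": t,
                        "p": p,
                    }
                )
    return pd.DataFrame(rows)
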