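"""Clonal-expansion and diversity statistics: HEC calling and normalized
Shannon entropy.

A highly-expanded clone (HEC) is a clonotype whose within-sample frequency is
at least 1% of reads (inclusive threshold); everything else is a
lowly-expanded clone (LEC).  Repertoire diversity is summarized by the
normalized Shannon entropy

    H(X) = - sum_i p(x_i) log p(x_i) / log n,

where p(x_i) is the clone frequency and n the number of observed clonotypes.
H lies in [0, 1]: 1 for a perfectly even repertoire, 0 for a single clone
(the n = 1 case is defined as 0 by convention, since log 1 = 0).  The log
base cancels; natural log is used internally.  Entropy is computed on the
nucleotide-level clonotype frequencies (the finest observed partition) by
default; amino-acid-level entropy is available for sensitivity analysis.
No richness extrapolation is applied — n is the observed clone count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clonotype import RepertoireSample, aggregate_by_aa

__all__ = [
    "HEC_THRESHOLD",
    "DiversityReport",
    "call_hecs",
    "shannon_entropy",
    "shannon_entropy_normalized",
    "diversity_report",
    "cohort_diversity_table",
]

HEC_THRESHOLD = 0.01


@dataclass
class DiversityReport:
    sample_id: str
    group: str
    subset: str
    n_clones: int
    entropy: float
    hec_count: int
    hec_ratio: float
    hec_ids: list[str] = field(repr=False, default_factory=list)


def call_hecs(
    sample: RepertoireSample, threshold: float = HEC_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a sample's clonotypes into HECs (frequency >= threshold,
    inclusive) and LECs.  The partition is exhaustive and disjoint."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    is_hec = sample.clonotypes["frequency"] >= threshold
    return sample.clonotypes[is_hec], sample.clonotypes[~is_hec]


def shannon_entropy(frequencies) -> float:
    """Unnormalized Shannon entropy -sum p ln p of a frequency vector."""
    p = _validated(frequencies)
    return float(-(p * np.log(p)).sum())


def shannon_entropy_normalized(frequencies) -> float:
    """Normalized Shannon entropy in [0, 1]; n = 1 returns 0 by convention."""
    p = _validated(frequencies)
    n = len(p)
    if n == 1:
        return 0.0
    return float(stats.entropy(p) / np.log(n))


def _validated(frequencies) -> np.ndarray:
    p = np.asarray(frequencies, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("frequencies must be a non-empty 1-d vector")
    if (p <= 0).any():
        raise ValueError("all frequencies must be positive")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {total}, expected 1 within 1e-6")
    return p / total


def diversity_report(
    sample: RepertoireSample,
    threshold: float = HEC_THRESHOLD,
    level: str = "nt",
) -> DiversityReport:
    """Bundle clone count, normalized entropy, HEC count and HEC ratio
    (sum of HEC frequencies) for one sample.

    ``level="aa"`` computes entropy on amino-acid-aggregated clonotypes.
    """
    if sample.n_clones == 0:
        raise ValueError(f"{sample.sample_id}: empty sample")
    if level == "nt":
        freqs = sample.frequencies
    elif level == "aa":
        freqs = aggregate_by_aa(sample)["frequency"].to_numpy()
    else:
        raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")
    hecs, _ = call_hecs(sample, threshold)
    return DiversityReport(
        sample_id=sample.sample_id,
        group=sample.group,
        subset=sample.subset,
        n_clones=len(freqs),
        entropy=shannon_entropy_normalized(freqs),
        hec_count=len(hecs),
        hec_ratio=float(hecs["frequency"].sum()),
        hec_ids=list(hecs["cdr3_nt"]),
    )


def cohort_diversity_table(
    samples, threshold: float = HEC_THRESHOLD, level: str = "nt"
) -> pd.DataFrame:
    """Per-sample diversity report table for a cohort."""
    rows = []
    for s in samples:
        r = diversity_report(s, threshold, level)
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "subset": r.subset,
                "n_clones": r.n_clones,
                "entropy": r.entropy,
                "hec_count": r.hec_count,
                "hec_ratio": r.hec_ratio,
            }
        )
    return pd.DataFrame(rows)
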