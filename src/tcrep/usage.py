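"""V/J gene-family usage, usage correlations, VJ-combination matrices and
CDR3-length spectratypes.

All usage structures are read-weighted (clone counts weighted by read count):
the canonical displays size features by read number, so reads are the natural
weight.  A clone-weighted variant is available for sensitivity analysis.
Family vectors are zero-filled over the GermlineDB's ordered family lists so
profiles are comparable cohort-wide; VJ-matrix marginals equal the usage
vectors exactly.  CDR3 length is measured in amino acids of the
anchor-excluded CDR3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonotype import RepertoireSample
from .germline import GermlineDB

__all__ = [
    "UsageProfile",
    "usage_profile",
    "usage_correlation",
    "vj_matrix",
    "spectratype",
]


@dataclass
class UsageProfile:
    """Per-sample V and J family usage vectors over fixed family orderings."""

    sample_id: str
    v_usage: pd.Series = field(repr=False)
    j_usage: pd.Series = field(repr=False)

    def __post_init__(self):
        for vec in (self.v_usage, self.j_usage):
            if len(vec) and abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError("usage vector must sum to 1")


def _weights(sample: RepertoireSample, weight: str) -> pd.Series:
    if weight == "reads":
        return sample.clonotypes["count"].astype(float)
    if weight == "clones":
        return pd.Series(1.0, index=sample.clonotypes.index)
    raise ValueError(f"weight must be 'reads' or 'clones', got {weight!r}")


def usage_profile(
    sample: RepertoireSample, db: GermlineDB, weight: str = "reads"
) -> UsageProfile:
    """Family usage frequencies of one sample, zero-filled over the
    reference's ordered V/J family lists."""
    w = _weights(sample, weight)
    total = w.sum()
    v = (
        w.groupby(sample.clonotypes["v_family"]).sum().reindex(db.v_families, fill_value=0.0)
        / total
    )
    j = (
        w.groupby(sample.clonotypes["j_family"]).sum().reindex(db.j_families, fill_value=0.0)
        / total
    )
    return UsageProfile(sample.sample_id, v, j)


def usage_correlation(profiles, chain: str = "v") -> pd.DataFrame:
    """Pairwise Pearson correlation of usage vectors across samples.

    Returns a symmetric matrix (DataFrame indexed by sample id) with unit
    diagonal.  A zero-variance usage vector has no defined correlation; its
    off-diagonal entries are reported as missing (NaN), never as 0.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    attr = {"v": "v_usage", "j": "j_usage"}[chain]
    ids = [p.sample_id for p in profiles]
    mat = np.vstack([getattr(p, attr).to_numpy() for p in profiles])
    if mat.shape != (len(ids), len(getattr(profiles[0], attr))):
        raise ValueError("profiles must share one family ordering")
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ids, columns=ids)


def vj_matrix(
    sample: RepertoireSample, db: GermlineDB, weight: str = "reads"
) -> pd.DataFrame:
    """Read-fraction per (V family x J family) combination; unobserved
    combinations are 0, not missing.  Row/column sums equal the V/J usage
    vectors exactly."""
    w = _weights(sample, weight)
    total = w.sum()
    cells = (
        w.groupby([sample.clonotypes["v_family"], sample.clonotypes["j_family"]])
        .sum()
        .unstack(fill_value=0.0)
    )
    mat = cells.reindex(index=db.v_families, columns=db.j_families, fill_value=0.0)
    return mat / total


def dominant_vj(matrix: pd.DataFrame) -> tuple[str, str, float]:
    """The (V family, J family) cell holding the largest read fraction."""
    j = matrix.to_numpy().argmax()
    vi, ji = np.unravel_index(j, matrix.shape)
    return matrix.index[vi], matrix.columns[ji], float(matrix.iat[vi, ji])


def spectratype(sample: RepertoireSample, weight: str = "reads") -> pd.Series:
    """Read-weighted histogram of CDR3 amino-acid lengths (fractions sum to 1)."""
    w = _weights(sample, weight)
    lengths = sample.clonotypes["cdr3_aa"].str.len()
    hist = w.groupby(lengths).sum()
    hist = hist / hist.sum()
    hist.index = hist.index.astype(int)
    hist.index.name = "cdr3_aa_length"
    return hist.sort_index()
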