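"""Collapse annotated reads into per-sample clonotype frequency tables.

A clonotype is keyed by (CDR3 nucleotide sequence, V family, J family).
Frequencies are computed over productive, filter-passing reads only — the
"total number of CDR3 sequences" a clone frequency is expressed against is
necessarily a count of reads that have a CDR3.  No error-correction or
clustering of near-identical CDR3s is applied, so substitution sequencing
error inflates singleton clonotypes; recovery checks run at error rate 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Clonotype",
    "RepertoireSample",
    "EmptySampleError",
    "build_clonotypes",
    "aggregate_by_aa",
    "sample_from_truth",
    "write_clonotype_table",
    "read_clonotype_table",
]

GROUPS = ("T1D", "T2D", "control")
SUBSETS = ("CD4", "CD8")

CLONOTYPE_COLUMNS = ["cdr3_nt", "cdr3_aa", "v_family", "j_family", "count", "frequency"]


class EmptySampleError(ValueError):
    """No productive, filter-passing reads to build clonotypes from."""


@dataclass(frozen=True)
class Clonotype:
    cdr3_nt: str
    cdr3_aa: str
    v_family: str
    j_family: str
    count: int
    frequency: float


@dataclass
class RepertoireSample:
    """A named sample holding its clonotype table.

    ``clonotypes`` columns: cdr3_nt, cdr3_aa, v_family, j_family, count,
    frequency — sorted by descending count with lexicographic cdr3_nt
    tie-break; frequencies sum to 1.
    """

    sample_id: str
    group: str
    subset: str
    clonotypes: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = set(CLONOTYPE_COLUMNS) - set(self.clonotypes.columns)
        if missing:
            raise ValueError(f"clonotype table missing columns {sorted(missing)}")
        total = self.clonotypes["frequency"].sum()
        if len(self.clonotypes) and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")

    @property
    def n_clones(self) -> int:
        return len(self.clonotypes)

    @property
    def frequencies(self) -> np.ndarray:
        return self.clonotypes["frequency"].to_numpy()


def _sort_clonotypes(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["count", "cdr3_nt"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def build_clonotypes(
    reads, sample_id: str, group: str, subset: str
) -> RepertoireSample:
    """Aggregate annotated reads into a clonotype table.

    Only reads with ``productive and pass_filter`` enter; counts are
    aggregated on (cdr3_nt, v_family, j_family) and frequencies normalized
    over the included reads.  Raises :class:`EmptySampleError` when nothing
    qualifies.
    """
    rows = [
        {
            "cdr3_nt": r.cdr3_nt,
            "cdr3_aa": r.cdr3_aa,
            "v_family": r.v_family,
            "j_family": r.j_family,
        }
        for r in reads
        if r.productive and r.pass_filter
    ]
    if not rows:
        raise EmptySampleError(f"{sample_id}: no productive, filter-passing reads")
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["cdr3_nt", "v_family", "j_family"], sort=False)
        .agg(cdr3_aa=("cdr3_aa", "first"), count=("cdr3_aa", "size"))
        .reset_index()
    )
    agg["frequency"] = agg["count"] / agg["count"].sum()
    agg = _sort_clonotypes(agg[CLONOTYPE_COLUMNS])
    return RepertoireSample(sample_id, group, subset, agg)


def aggregate_by_aa(sample: RepertoireSample) -> pd.DataFrame:
    """Sum counts and frequencies over nucleotide clonotypes sharing a CDR3
    amino-acid sequence.  Returns a table keyed by ``cdr3_aa``."""
    if sample.n_clones == 0:
        return pd.DataFrame(columns=["cdr3_aa", "count", "frequency"])
    agg = (
        sample.clonotypes.groupby("cdr3_aa", sort=False)[["count", "frequency"]]
        .sum()
        .reset_index()
        .sort_values(["count", "cdr3_aa"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return agg


def sample_from_truth(
    truth: pd.DataFrame,
    sample_id: str,
    group: str,
    subset: str,
    n_reads: int,
    rng: np.random.Generator,
) -> RepertoireSample:
    """Build a clonotype table directly from a simulated truth table by
    multinomial read sampling (bypassing read generation and annotation).

    Useful for statistics-level experiments and for substituting externally
    annotated data; clones drawn zero times are absent from the sample.
    """
    counts = rng.multinomial(n_reads, truth["frequency"].to_numpy())
    keep = counts > 0
    df = truth.loc[keep, ["cdr3_nt", "cdr3_aa", "v_family", "j_family"]].copy()
    df["count"] = counts[keep]
    df["frequency"] = df["count"] / df["count"].sum()
    df = _sort_clonotypes(df[CLONOTYPE_COLUMNS])
    return RepertoireSample(sample_id, group, subset, df)


def write_clonotype_table(sample: RepertoireSample, path) -> None:
    out = sample.clonotypes.copy()
    out.insert(0, "sample_id", sample.sample_id)
    out.insert(1, "group", sample.group)
    out.insert(2, "subset", sample.subset)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_clonotype_table(path) -> RepertoireSample:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if len(df) == 0:
        raise EmptySampleError(f"{path}: empty clonotype table")
    sample_id = str(df["sample_id"].iloc[0])
    group = str(df["group"].iloc[0])
    subset = str(df["subset"].iloc[0])
    table = df[CLONOTYPE_COLUMNS].copy()
    table["frequency"] = table["count"] / table["count"].sum()
    return RepertoireSample(sample_id, group, subset, _sort_clonotypes(table))
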