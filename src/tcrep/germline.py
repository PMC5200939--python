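"""Germline TRBV/TRBD/TRBJ reference segments and the anchors needed for CDR3 extraction.

A rearranged TCR-beta chain is assembled from a variable (TRBV), diversity
(TRBD) and joining (TRBJ) germline segment.  The CDR3 loop is delimited by two
conserved residues: the cysteine near the 3' end of the V segment and the
phenylalanine of the J segment's F-G-X-G motif (tryptophan occurs in a few J
genes and can be allowed explicitly).  Rather than rediscovering these anchors
by motif scanning, they are carried as explicit per-segment metadata — the
positions are fixed by the reference numbering and precomputed once.

Allele-level entries (``TRBV15*01``) collapse to the gene family
(``TRBV15``) for every usage statistic; clonotype identity is family-level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GermlineSegment",
    "GermlineDB",
    "ReferenceIntegrityError",
    "SegmentValidationError",
    "family_of",
    "locus_sort_key",
    "load_germline",
    "write_germline",
    "builtin_toy_reference",
]

_VALID_BASES = frozenset("ACGTN")


class ReferenceIntegrityError(ValueError):
    """A V or J segment is missing required anchor metadata."""


class SegmentValidationError(ValueError):
    """A segment's content contradicts its declared anchors."""


def family_of(segment_id: str) -> str:
    """Gene family of a segment id: the part before the allele separator.

    ``family_of("TRBV15*01") == "TRBV15"``; idempotent on family names.
    """
    fam = segment_id.split("*")[0]
    if not fam:
        raise SegmentValidationError(f"empty family in segment id {segment_id!r}")
    return fam


_FAMILY_RE = re.compile(r"^TRB(?P<type>[VDJ])(?P<major>\d+)(?:-(?P<minor>\d+))?$")


def locus_sort_key(family: str):
    """Sort key reproducing locus nomenclature order (TRBV1..TRBV30, TRBJ1-1..TRBJ2-7)."""
    m = _FAMILY_RE.match(family)
    if m:
        return (0, int(m.group("major")), int(m.group("minor") or 0), family)
    return (1, 0, 0, family)


@dataclass(frozen=True)
class GermlineSegment:
    """One germline reference segment.

    Parameters
    ----------
    segment_id
        Allele-level identifier, e.g. ``"TRBV15*01"``.
    gene_type
        ``"V"``, ``"D"`` or ``"J"``.
    sequence
        Nucleotide sequence (A/C/G/T/N).
    anchor_pos
        0-based offset of the first base of the conserved anchor codon
        (Cys for V, Phe/Trp for J); ``None`` for D segments.
    """

    segment_id: str
    gene_type: str
    sequence: str
    anchor_pos: int | None = None

    def __post_init__(self):
        if self.gene_type not in ("V", "D", "J"):
            raise SegmentValidationError(
                f"{self.segment_id}: gene_type must be V, D or J, got {self.gene_type!r}"
            )
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise SegmentValidationError(
                f"{self.segment_id}: invalid bases {bad} in sequence"
            )
        if self.anchor_pos is not None:
            if not 0 <= self.anchor_pos <= len(self.sequence) - 3:
                raise SegmentValidationError(
                    f"{self.segment_id}: anchor_pos {self.anchor_pos} outside sequence"
                )

    @property
    def family(self) -> str:
        return family_of(self.segment_id)

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_pos is None:
            return None
        return self.sequence[self.anchor_pos : self.anchor_pos + 3]

    @property
    def anchor_residue(self) -> str | None:
        codon = self.anchor_codon
        if codon is None:
            return None
        return str(Seq(codon).translate())


class GermlineDB:
    """A validated collection of germline segments with ordered family lists.

    Validation enforced at construction:

    * every ``segment_id`` is unique;
    * every V and J segment carries an anchor;
    * the V anchor codon translates to C, the J anchor codon to F
      (W allowed when ``j_anchor_residues`` includes it).

    ``v_families`` / ``j_families`` are sorted by locus nomenclature order so
    usage vectors align across samples.
    """

    def __init__(self, segments, j_anchor_residues: tuple[str, ...] = ("F",)):
        segments = list(segments)
        seen: set[str] = set()
        for seg in segments:
            if seg.segment_id in seen:
                raise ReferenceIntegrityError(f"duplicate segment id {seg.segment_id}")
            seen.add(seg.segment_id)
            if seg.gene_type in ("V", "J") and seg.anchor_pos is None:
                raise ReferenceIntegrityError(
                    f"{seg.segment_id}: {seg.gene_type} segment lacks an anchor position"
                )
            if seg.gene_type == "V" and seg.anchor_residue != "C":
                raise SegmentValidationError(
                    f"{seg.segment_id}: V anchor codon {seg.anchor_codon} translates to "
                    f"{seg.anchor_residue}, expected C"
                )
            if seg.gene_type == "J" and seg.anchor_residue not in j_anchor_residues:
                raise SegmentValidationError(
                    f"{seg.segment_id}: J anchor codon {seg.anchor_codon} translates to "
                    f"{seg.anchor_residue}, expected one of {j_anchor_residues}"
                )
        self.segments: list[GermlineSegment] = segments
        self.j_anchor_residues = tuple(j_anchor_residues)
        self._by_id = {seg.segment_id: seg for seg in segments}
        self.v_families = sorted(
            {s.family for s in segments if s.gene_type == "V"}, key=locus_sort_key
        )
        self.j_families = sorted(
            {s.family for s in segments if s.gene_type == "J"}, key=locus_sort_key
        )

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GermlineDB):
            return NotImplemented
        return sorted(self.segments, key=lambda s: s.segment_id) == sorted(
            other.segments, key=lambda s: s.segment_id
        )

    def get(self, segment_id: str) -> GermlineSegment:
        return self._by_id[segment_id]

    def _of_type(self, gene_type: str) -> list[GermlineSegment]:
        return sorted(
            (s for s in self.segments if s.gene_type == gene_type),
            key=lambda s: s.segment_id,
        )

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return self._of_type("V")

    @property
    def d_segments(self) -> list[GermlineSegment]:
        return self._of_type("D")

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return self._of_type("J")


def load_germline(
    fasta_path, anchor_table, j_anchor_residues: tuple[str, ...] = ("F",)
) -> GermlineDB:
    """Load a germline reference from a FASTA file plus a sidecar anchor table.

    The anchor table is tab-separated with columns ``segment_id``,
    ``gene_type`` and ``anchor_pos`` (0-based; empty for D segments).
    Segments present in the FASTA but absent from the table — or V/J segments
    without an anchor — raise :class:`ReferenceIntegrityError`.
    """
    anchors = pd.read_csv(anchor_table, sep="\t", dtype={"segment_id": str})
    required = {"segment_id", "gene_type", "anchor_pos"}
    if not required <= set(anchors.columns):
        raise ReferenceIntegrityError(
            f"anchor table must have columns {sorted(required)}"
        )
    meta = anchors.set_index("segment_id")
    segments = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in meta.index:
            raise ReferenceIntegrityError(
                f"{record.id}: present in FASTA but missing from anchor table"
            )
        row = meta.loc[record.id]
        anchor = row["anchor_pos"]
        anchor = None if pd.isna(anchor) else int(anchor)
        segments.append(
            GermlineSegment(
                segment_id=record.id,
                gene_type=str(row["gene_type"]),
                sequence=str(record.seq).upper(),
                anchor_pos=anchor,
            )
        )
    return GermlineDB(segments, j_anchor_residues=j_anchor_residues)


def write_germline(db: GermlineDB, fasta_path, anchor_table) -> None:
    """Write a GermlineDB back to FASTA + anchor table (inverse of :func:`load_germline`)."""
    records = [
        SeqRecord(Seq(seg.sequence), id=seg.segment_id, description="")
        for seg in db.segments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "segment_id": seg.segment_id,
            "gene_type": seg.gene_type,
            "anchor_pos": "" if seg.anchor_pos is None else seg.anchor_pos,
        }
        for seg in db.segments
    ]
    pd.DataFrame(rows).to_csv(anchor_table, sep="\t", index=False)


# --- packaged toy reference -------------------------------------------------

_TOY_V_FAMILIES = [
    "TRBV2",
    "TRBV5",
    "TRBV7",
    "TRBV9",
    "TRBV12",
    "TRBV15",
    "TRBV19",
    "TRBV28",
]

# V segments end in TGT GCC AGC AGC -> C A S S; the Cys codon is the anchor.
_V_TAIL = "TGTGCCAGCAGC"

# J heads (4 codons feeding the CDR3) + Phe anchor + 3' tail.
_TOY_J_HEADS = {
    "TRBJ1-1": "AACACTGAAGCT",  # N T E A
    "TRBJ1-2": "AACTATGGCTAC",  # N Y G Y
    "TRBJ2-1": "AATGAGCAGCTC",  # N E Q L
    "TRBJ2-3": "ACAGATACGCAG",  # T D T Q
    "TRBJ2-5": "GAAACCCAGTAC",  # E T Q Y  -> ...E-T-Q-Y-F... with the anchor
    "TRBJ2-7": "TCCTACGAGCAG",  # S Y E Q
}
_TOY_J25_TAIL = "GGCCCAGGCACCCGGCTGACAGTGCTC"  # G P G T R L T V L


def builtin_toy_reference() -> GermlineDB:
    """A small packaged synthetic germline reference (no download required).

    Eight V families (including TRBV15, with two alleles to exercise
    allele-to-family collapsing), two D segments, and six J families
    (including TRBJ2-5, whose sequence encodes ...E-T-Q-Y-F... with the
    conserved Phe as anchor).  Framework regions are synthetic: generated
    deterministically from a fixed seed, so repeated calls return identical
    content.  They are not IMGT sequences — they only need to be mutually
    distinguishable under alignment and to carry correct anchors.
    """
    rng = np.random.default_rng(190333)
    bases = np.array(list("ACGT"))

    def random_nt(n: int) -> str:
        return "".join(bases[rng.integers(0, 4, n)])

    segments: list[GermlineSegment] = []
    for fam in _TOY_V_FAMILIES:
        framework = random_nt(45)
        segments.append(
            GermlineSegment(f"{fam}*01", "V", framework + _V_TAIL, anchor_pos=45)
        )
        if fam == "TRBV15":
            # second allele: two substitutions inside the framework
            fw = list(framework)
            fw[10] = "A" if fw[10] != "A" else "G"
            fw[30] = "C" if fw[30] != "C" else "T"
            segments.append(
                GermlineSegment(f"{fam}*02", "V", "".join(fw) + _V_TAIL, anchor_pos=45)
            )

    segments.append(GermlineSegment("TRBD1*01", "D", "GGGACAGGGGGC"))
    segments.append(GermlineSegment("TRBD2*01", "D", "GGGACTGGGGGGAGG"))

    for fam, head in _TOY_J_HEADS.items():
        tail = _TOY_J25_TAIL if fam == "TRBJ2-5" else random_nt(27)
        segments.append(
            GermlineSegment(f"{fam}*01", "J", head + "TTC" + tail, anchor_pos=12)
        )
    return GermlineDB(segments)
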