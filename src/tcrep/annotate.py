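"""Read annotation: pair merging, germline V/J alignment, identity filtering,
CDR3 extraction and productivity calling.

Alignment model
---------------
Each read is aligned against every V segment (then, on the read suffix 3' of
the V match, every J segment) by dynamic programming with match +1,
mismatch -1, linear gap -2.  The alignment is *overlap* (glocal): the
germline segment must be spanned end-to-end while read overhangs are free.
Identity is matches / aligned columns (x100) over the segment-spanning
region.  Spanning the whole segment is what gives the identity threshold its
teeth: a purely local alignment of an unrelated read always contains some
short near-perfect core, whereas a spanning alignment of an unrelated read
settles near the random match rate, well below 70%.

Reads with ``min(v_identity, j_identity) < 70`` (the default threshold,
inclusive at the boundary: exactly 70 is kept) are flagged as failing.

CDR3 convention
---------------
The CDR3 is reported as the bases strictly between the conserved-Cys codon of
the V segment and the conserved-Phe codon of the J segment — anchors
excluded, so printed clones carry no leading C and no trailing F.  A read is
productive when the anchor-to-anchor span preserves the reading frame (CDR3
length divisible by 3) and the translation contains no stop.  Coordinates are
0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
from Bio import SeqIO
from Bio.Seq import Seq

from .germline import GermlineDB, GermlineSegment
import pandas as pd

__all__ = [
    "AlignParams",
    "AnnotatedRead",
    "MergeReport",
    "FilterReport",
    "merge_pairs",
    "align_to_germline",
    "annotate_read",
    "annotate_reads",
    "filter_by_identity",
    "extract_cdr3",
    "write_rearrangements",
    "read_rearrangements",
]

DEFAULT_IDENTITY_THRESHOLD = 70.0

#: reads shorter than this cannot anchor both a V and a J seed
MIN_ALIGNABLE_LENGTH = 20

#: an aligned region shorter than this is treated as no alignment at all
#: (identity 0): free terminal gaps admit short corner overlaps whose
#: identity would otherwise be meaninglessly high
MIN_ALIGNED_COLUMNS = 15


@dataclass(frozen=True)
class AlignParams:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


_ALPHABET = bseq.NucleotideSequence.alphabet_unamb


def _matrix(params: AlignParams) -> balign.SubstitutionMatrix:
    m = np.full((4, 4), params.mismatch, dtype=np.int32)
    np.fill_diagonal(m, params.match)
    return balign.SubstitutionMatrix(_ALPHABET, _ALPHABET, m)


_DEFAULT_MATRIX = _matrix(AlignParams())


@dataclass
class SegmentAlignment:
    """One read-vs-segment overlap alignment with identity and coordinate maps."""

    segment_id: str
    score: int
    identity: float           # percent over the aligned region
    read_start: int           # read span covered by the aligned region
    read_end: int
    seg_to_read: dict         # segment position -> read position (aligned cols)


def _align_segment(
    read_code: np.ndarray,
    read_ns: bseq.NucleotideSequence,
    seg: GermlineSegment,
    seg_ns: bseq.NucleotideSequence,
    matrix: balign.SubstitutionMatrix,
    gap: int,
    read_offset: int = 0,
) -> SegmentAlignment:
    aln = balign.align_optimal(
        read_ns,
        seg_ns,
        matrix,
        gap_penalty=gap,
        local=False,
        terminal_penalty=False,
        max_number=1,
    )[0]
    trace = aln.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    idx = np.nonzero(both)[0]
    if len(idx) == 0:
        return SegmentAlignment(seg.segment_id, aln.score, 0.0, 0, 0, {})
    region = trace[idx[0] : idx[-1] + 1]
    if len(region) < MIN_ALIGNED_COLUMNS:
        return SegmentAlignment(seg.segment_id, aln.score, 0.0, 0, 0, {})
    pair = (region[:, 0] >= 0) & (region[:, 1] >= 0)
    seg_code = seg_ns.code
    matches = int(
        np.sum(read_code[region[pair, 0]] == seg_code[region[pair, 1]])
    )
    identity = 100.0 * matches / len(region)
    seg_to_read = {
        int(s): int(r) + read_offset for r, s in region[pair]
    }
    return SegmentAlignment(
        segment_id=seg.segment_id,
        score=int(aln.score),
        identity=identity,
        read_start=int(region[pair, 0].min()) + read_offset,
        read_end=int(region[pair, 0].max()) + 1 + read_offset,
        seg_to_read=seg_to_read,
    )


def _best_alignment(
    read: str,
    segments: list[GermlineSegment],
    params: AlignParams,
    matrix: balign.SubstitutionMatrix,
    read_offset: int = 0,
) -> SegmentAlignment | None:
    """Highest-scoring segment alignment; ties broken by lexicographically
    smallest segment_id (segments arrive sorted)."""
    if len(read) == 0:
        return None
    read_ns = bseq.NucleotideSequence(read)
    read_code = read_ns.code
    best: SegmentAlignment | None = None
    for seg in segments:
        seg_ns = bseq.NucleotideSequence(seg.sequence)
        cand = _align_segment(
            read_code, read_ns, seg, seg_ns, matrix, params.gap, read_offset
        )
        if best is None or cand.score > best.score:
            best = cand
    return best


def align_to_germline(
    read: str, db: GermlineDB, params: AlignParams = AlignParams()
):
    """Best V and J calls for a read with their identities.

    Returns ``(v_alignment, j_alignment)`` (either may be ``None`` for an
    unalignable read).  The J search runs on the read suffix 3' of the V
    match.  D segments are not called.
    """
    read = read.upper().replace("N", "A")  # N has no score row; treat as mismatch-prone
    if len(read) < MIN_ALIGNABLE_LENGTH:
        return None, None
    matrix = _matrix(params) if params != AlignParams() else _DEFAULT_MATRIX
    v_aln = _best_alignment(read, db.v_segments, params, matrix)
    j_aln = None
    if v_aln is not None:
        suffix_start = v_aln.read_end
        j_aln = _best_alignment(
            read[suffix_start:], db.j_segments, params, matrix, read_offset=suffix_start
        )
    return v_aln, j_aln


@dataclass
class AnnotatedRead:
    """A read with V/J calls, identities, CDR3 and productivity flags."""

    read_id: str
    sequence: str
    v_call: str | None = None
    j_call: str | None = None
    v_family: str | None = None
    j_family: str | None = None
    v_identity: float = 0.0
    j_identity: float = 0.0
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    productive: bool = False
    pass_filter: bool = False


def _cdr3_from_alignments(
    read: str,
    v_seg: GermlineSegment,
    j_seg: GermlineSegment,
    v_aln: SegmentAlignment,
    j_aln: SegmentAlignment,
):
    """(cdr3_nt, cdr3_aa, productive) from anchor positions projected onto the
    read; (None, None, False) when an anchor codon is not covered."""
    v_anchor = v_aln.seg_to_read.get(v_seg.anchor_pos)
    j_anchor = j_aln.seg_to_read.get(j_seg.anchor_pos)
    if v_anchor is None or j_anchor is None:
        return None, None, False
    start = v_anchor + 3
    if not (0 <= start <= j_anchor <= len(read) - 3):
        return None, None, False
    cdr3_nt = read[start:j_anchor]
    if len(cdr3_nt) % 3 != 0:
        return cdr3_nt, None, False
    cdr3_aa = str(Seq(cdr3_nt).translate())
    productive = len(cdr3_aa) > 0 and "*" not in cdr3_aa
    return cdr3_nt, cdr3_aa, productive


def extract_cdr3(
    read: str,
    v_call: str,
    j_call: str,
    db: GermlineDB,
    params: AlignParams = AlignParams(),
):
    """CDR3 (nt + aa) and productivity of a read given its V/J calls.

    Anchors are located on the read through fresh alignments to the named
    segments; a read not covering an anchor codon yields
    ``(None, None, False)``.
    """
    v_seg, j_seg = db.get(v_call), db.get(j_call)
    matrix = _matrix(params)
    read_u = read.upper()
    read_ns = bseq.NucleotideSequence(read_u.replace("N", "A"))
    read_code = read_ns.code
    v_aln = _align_segment(
        read_code, read_ns, v_seg, bseq.NucleotideSequence(v_seg.sequence), matrix, params.gap
    )
    j_aln = _align_segment(
        read_code, read_ns, j_seg, bseq.NucleotideSequence(j_seg.sequence), matrix, params.gap
    )
    return _cdr3_from_alignments(read_u, v_seg, j_seg, v_aln, j_aln)


def annotate_read(
    read_id: str,
    sequence: str,
    db: GermlineDB,
    params: AlignParams = AlignParams(),
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> AnnotatedRead:
    """Annotate one read: V/J calls, identities, CDR3, productivity, filter flag.

    ``pass_filter`` requires both identities at or above the threshold
    (inclusive) *and* a defined CDR3; reads whose anchors cannot be located
    are marked as failing.
    """
    out = AnnotatedRead(read_id=read_id, sequence=sequence)
    v_aln, j_aln = align_to_germline(sequence, db, params)
    if v_aln is None or j_aln is None:
        return out
    v_seg, j_seg = db.get(v_aln.segment_id), db.get(j_aln.segment_id)
    out.v_call, out.j_call = v_seg.segment_id, j_seg.segment_id
    out.v_family, out.j_family = v_seg.family, j_seg.family
    out.v_identity, out.j_identity = v_aln.identity, j_aln.identity
    cdr3_nt, cdr3_aa, productive = _cdr3_from_alignments(
        sequence.upper(), v_seg, j_seg, v_aln, j_aln
    )
    out.cdr3_nt, out.cdr3_aa, out.productive = cdr3_nt, cdr3_aa, productive
    out.pass_filter = (
        min(out.v_identity, out.j_identity) >= identity_threshold
        and cdr3_nt is not None
    )
    return out


def annotate_reads(
    reads,
    db: GermlineDB,
    params: AlignParams = AlignParams(),
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[AnnotatedRead]:
    """Annotate an iterable of ``(read_id, sequence)`` pairs.

    Identical sequences are annotated once and the result reused — on
    deep-sequenced repertoires most reads are exact duplicates of a clone's
    junction, so this dominates throughput.
    """
    cache: dict[str, AnnotatedRead] = {}
    out = []
    for read_id, sequence in reads:
        hit = cache.get(sequence)
        if hit is None:
            hit = annotate_read(read_id, sequence, db, params, identity_threshold)
            cache[sequence] = hit
        out.append(replace(hit, read_id=read_id))
    return out


@dataclass
class FilterReport:
    kept: int = 0
    excluded: int = 0


def filter_by_identity(
    reads, threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> tuple[list[AnnotatedRead], FilterReport]:
    """Keep reads with ``min(v_identity, j_identity) >= threshold`` (inclusive).

    Raising the threshold never adds reads.  Returns the passing reads (with
    ``pass_filter`` restamped at this threshold) and a kept/excluded report.
    """
    report = FilterReport()
    kept = []
    for r in reads:
        if min(r.v_identity, r.j_identity) >= threshold:
            kept.append(replace(r, pass_filter=r.cdr3_nt is not None))
            report.kept += 1
        else:
            report.excluded += 1
    return kept, report


# --- paired-end merging -----------------------------------------------------

@dataclass
class MergeReport:
    merged: int = 0
    dropped: int = 0


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    quality: list[int] = field(repr=False, default_factory=list)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _merge_one(
    seq1: str,
    qual1: list[int],
    seq2rc: str,
    qual2rc: list[int],
    min_overlap: int,
    max_mismatch_rate: float,
):
    """Best-scoring overlap merge of mate 1 with the reverse-complemented
    mate 2, or None when no admissible overlap exists."""
    a1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(seq2rc.encode(), dtype=np.uint8)
    l1, l2 = len(a1), len(a2)
    best = None  # (score, overlap)
    for o in range(min_overlap, min(l1, l2) + 1):
        matches = int(np.sum(a1[l1 - o :] == a2[:o]))
        mismatches = o - matches
        if mismatches / o > max_mismatch_rate:
            continue
        score = matches - mismatches
        if best is None or score > best[0]:
            best = (score, o)
    if best is None:
        return None
    _, o = best
    head_seq, head_q = seq1[: l1 - o], qual1[: l1 - o]
    tail_seq, tail_q = seq2rc[o:], qual2rc[o:]
    ov_seq = []
    ov_q = []
    for i in range(o):
        b1, q1 = seq1[l1 - o + i], qual1[l1 - o + i]
        b2, q2 = seq2rc[i], qual2rc[i]
        if b1 == b2:
            ov_seq.append(b1)
            ov_q.append(max(q1, q2))
        elif q1 >= q2:  # higher quality wins; tie goes to mate 1
            ov_seq.append(b1)
            ov_q.append(q1)
        else:
            ov_seq.append(b2)
            ov_q.append(q2)
    return (
        head_seq + "".join(ov_seq) + tail_seq,
        list(head_q) + ov_q + list(tail_q),
    )


def merge_pairs(
    fastq1,
    fastq2,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.25,
) -> tuple[list[MergedRead], MergeReport]:
    """Merge overlapping paired-end FASTQ mates into single reads.

    Mates are merged at the highest-scoring overlap of length >=
    ``min_overlap`` whose mismatch rate is <= ``max_mismatch_rate``; at a
    mismatching overlap position the base with higher quality wins.
    Unmergeable pairs are counted and dropped.  Files must be paired and in
    order; a length mismatch raises ``ValueError``.
    """
    reads1 = list(SeqIO.parse(str(fastq1), "fastq"))
    reads2 = list(SeqIO.parse(str(fastq2), "fastq"))
    if len(reads1) != len(reads2):
        raise ValueError(
            f"pairing error: {len(reads1)} reads in mate-1 file, "
            f"{len(reads2)} in mate-2 file"
        )
    merged: list[MergedRead] = []
    report = MergeReport()
    for r1, r2 in zip(reads1, reads2):
        seq2rc = str(r2.seq).upper().translate(_COMPLEMENT)[::-1]
        qual2rc = r2.letter_annotations["phred_quality"][::-1]
        result = _merge_one(
            str(r1.seq).upper(),
            r1.letter_annotations["phred_quality"],
            seq2rc,
            qual2rc,
            min_overlap,
            max_mismatch_rate,
        )
        if result is None:
            report.dropped += 1
            continue
        seq, qual = result
        merged.append(MergedRead(read_id=r1.id, sequence=seq, quality=qual))
        report.merged += 1
    return merged, report


# --- tabular output ---------------------------------------------------------

_REARRANGEMENT_COLUMNS = [
    "read_id",
    "v_call",
    "j_call",
    "v_identity",
    "j_identity",
    "cdr3",
    "cdr3_aa",
    "productive",
    "pass_filter",
]


def write_rearrangements(reads: list[AnnotatedRead], path) -> None:
    """Write annotated reads as a rearrangement table (AIRR-style TSV)."""
    rows = [
        {
            "read_id": r.read_id,
            "v_call": r.v_call or "",
            "j_call": r.j_call or "",
            "v_identity": round(r.v_identity, 3),
            "j_identity": round(r.j_identity, 3),
            "cdr3": r.cdr3_nt or "",
            "cdr3_aa": r.cdr3_aa or "",
            "productive": r.productive,
            "pass_filter": r.pass_filter,
        }
        for r in reads
    ]
    pd.DataFrame(rows, columns=_REARRANGEMENT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_rearrangements(path) -> list[AnnotatedRead]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        from .germline import family_of

        out.append(
            AnnotatedRead(
                read_id=str(row.read_id),
                sequence="",
                v_call=row.v_call or None,
                j_call=row.j_call or None,
                v_family=family_of(row.v_call) if row.v_call else None,
                j_family=family_of(row.j_call) if row.j_call else None,
                v_identity=float(row.v_identity),
                j_identity=float(row.j_identity),
                cdr3_nt=row.cdr3 or None,
                cdr3_aa=row.cdr3_aa or None,
                productive=bool(row.productive),
                pass_filter=bool(row.pass_filter),
            )
        )
    return out
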