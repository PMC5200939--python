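"""Cross-sample shared-HEC analysis.

For every CDR3 amino-acid sequence that is a HEC (frequency >= 1%) in at
least one case-group sample, a record gives its per-sample status — HEC, LEC
(present below 1%) or absent — and a two-way classification:

* **type 1**: a HEC in >= 1 case sample that is also *present* (as HEC or
  LEC) in at least one non-case sample;
* **type 2**: a HEC in >= 1 case sample that is absent from every non-case
  sample (case-unique).

Sharing is at the amino-acid level only: a clone expanded in two patients is
the same public clone if its CDR3 protein sequence matches, regardless of
the nucleotide rearrangement or V/J context encoding it.
"""

from __future__ import annotations

import pandas as pd

from .clonotype import RepertoireSample, aggregate_by_aa
from .diversity import HEC_THRESHOLD

__all__ = ["share_matrix", "sharing_summary"]

STATUS_HEC = "HEC"
STATUS_LEC = "LEC"
STATUS_ABSENT = "absent"


def _status_by_aa(sample: RepertoireSample, threshold: float) -> pd.Series:
    aa = aggregate_by_aa(sample)
    status = pd.Series(STATUS_LEC, index=aa["cdr3_aa"].to_numpy(), dtype=object)
    status[aa.set_index("cdr3_aa")["frequency"] >= threshold] = STATUS_HEC
    return status


def share_matrix(
    cohort,
    case_group: str,
    threshold: float = HEC_THRESHOLD,
) -> pd.DataFrame:
    """Shared-clone table over a cohort of :class:`RepertoireSample`.

    One row per CDR3 amino-acid sequence that is a HEC in >= 1 sample of
    ``case_group``; columns are per-sample statuses (case samples first),
    ``n_case_hec`` (number of case samples where it is a HEC) and
    ``hec_type`` ("type1"/"type2").  Rows are ranked by descending
    ``n_case_hec`` with lexicographic tie-break on the sequence.  The result
    does not depend on sample ordering within groups.
    """
    cohort = list(cohort)
    ids = [s.sample_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in cohort")
    case = sorted(
        (s for s in cohort if s.group == case_group), key=lambda s: s.sample_id
    )
    other = sorted(
        (s for s in cohort if s.group != case_group), key=lambda s: s.sample_id
    )
    if not case:
        raise ValueError(f"no samples in case group {case_group!r}")

    status = {s.sample_id: _status_by_aa(s, threshold) for s in cohort}
    case_hec = set()
    for s in case:
        st = status[s.sample_id]
        case_hec.update(st.index[st == STATUS_HEC])

    ordered_samples = [s.sample_id for s in case] + [s.sample_id for s in other]
    rows = []
    for aa_seq in case_hec:
        row = {"cdr3_aa": aa_seq}
        n_case_hec = 0
        present_other = False
        for s in case:
            st = status[s.sample_id].get(aa_seq, STATUS_ABSENT)
            row[s.sample_id] = st
            n_case_hec += st == STATUS_HEC
        for s in other:
            st = status[s.sample_id].get(aa_seq, STATUS_ABSENT)
            row[s.sample_id] = st
            present_other |= st != STATUS_ABSENT
        row["n_case_hec"] = n_case_hec
        row["hec_type"] = "type1" if present_other else "type2"
        rows.append(row)
    out = pd.DataFrame(rows, columns=["cdr3_aa", *ordered_samples, "n_case_hec", "hec_type"])
    out = out.sort_values(
        ["n_case_hec", "cdr3_aa"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def sharing_summary(records: pd.DataFrame, n_case_samples: int) -> dict:
    """Headline counts over a share matrix.

    ``hec_in_over_half`` counts clones that are HECs in strictly more than
    half of the case samples; type fractions partition the records.
    """
    total = len(records)
    if total == 0:
        return {
            "total_case_hecs": 0,
            "type1_count": 0,
            "type2_count": 0,
            "type1_fraction": float("nan"),
            "type2_fraction": float("nan"),
            "hec_in_all_case": 0,
            "hec_in_over_half": 0,
        }
    t1 = int((records["hec_type"] == "type1").sum())
    return {
        "total_case_hecs": total,
        "type1_count": t1,
        "type2_count": total - t1,
        "type1_fraction": t1 / total,
        "type2_fraction": (total - t1) / total,
        "hec_in_all_case": int((records["n_case_hec"] == n_case_samples).sum()),
        "hec_in_over_half": int((records["n_case_hec"] > n_case_samples / 2).sum()),
    }
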