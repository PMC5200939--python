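"""End-to-end orchestration: configuration, staged execution, manifests.

A run executes simulate -> annotate -> clonotype -> diversity -> usage ->
sharing -> cohort comparison (-> PCR-bias estimation when a cycle series is
configured), writing each stage's artifact as a tab-separated table (JSON
for summaries) into the output directory together with a manifest recording
the tool version, config hash and seed.  Given the same config and seed a
run is deterministic, so the manifest allows exact re-runs.  Stage failures
abort with the stage name attached.

Every stage is also usable standalone through the library (or the CLI
subcommands), reading and writing the same schemas — real annotated data can
be substituted for the simulator at any point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_reads, merge_pairs
from .clonotype import build_clonotypes, write_clonotype_table
from .cohort import compare_groups
from .diversity import cohort_diversity_table
from .germline import builtin_toy_reference, load_germline
from .pcr_bias import estimate_bias, vgene_usage_stability
from .sharing import share_matrix, sharing_summary
from .simulate import (
    PcrModel,
    RepertoireModel,
    SequencingModel,
    simulate_cycle_series,
    simulate_reads,
    simulate_repertoire,
    write_truth_table,
)
from .usage import spectratype, usage_correlation, usage_profile, vj_matrix
from Bio import SeqIO

__all__ = ["GroupConfig", "RunConfig", "PipelineError", "run_pipeline", "demo_config"]

logger = logging.getLogger("tcrep")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class GroupConfig:
    """One cohort arm: how many samples and which abundance regime."""

    name: str
    n_samples: int
    subset: str = "CD4"
    n_clones: int = 100
    abundance_mode: str = "even_lognormal"
    n_expanded: int = 22
    expanded_mass: float = 0.77
    lognormal_sigma: float = 1.0

    def repertoire_model(self) -> RepertoireModel:
        return RepertoireModel(
            n_clones=self.n_clones,
            abundance_mode=self.abundance_mode,
            n_expanded=self.n_expanded,
            expanded_mass=self.expanded_mass,
            lognormal_sigma=self.lognormal_sigma,
        )


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through YAML unchanged."""

    seed: int = 0
    reference_fasta: str | None = None     # None -> packaged toy reference
    reference_anchors: str | None = None
    identity_threshold: float = 70.0
    hec_threshold: float = 0.01
    case_group: str = "T1D"
    groups: list[GroupConfig] = field(default_factory=list)
    n_reads: int = 1500
    read_length: int = 150
    error_rate: float = 0.001
    paired: bool = False
    overlap: int = 30
    pcr_cycles: int = 25
    pcr_bias_sigma: float = 0.076
    cycle_series_cycles: list[int] = field(default_factory=list)
    cycle_series_reads: list[int] = field(default_factory=list)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in [0, 100]")
        if not 0 < self.hec_threshold < 1:
            raise ValueError("hec_threshold must be in (0, 1)")
        if (self.reference_fasta is None) != (self.reference_anchors is None):
            raise ValueError("reference_fasta and reference_anchors go together")
        if not self.groups:
            raise ValueError("at least one group is required")
        for g in self.groups:
            g.repertoire_model().validate()
        SequencingModel(
            n_reads=self.n_reads,
            read_length=self.read_length,
            error_rate=self.error_rate,
            paired=self.paired,
            overlap=self.overlap,
        ).validate()
        PcrModel(self.pcr_bias_sigma, self.pcr_cycles).validate()
        if len(self.cycle_series_cycles) != len(self.cycle_series_reads):
            raise ValueError("cycle_series_cycles and cycle_series_reads must pair up")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["groups"] = [GroupConfig(**g) for g in d.get("groups", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def demo_config(seed: int = 0) -> RunConfig:
    """The demo cohort: 9 T1D-like, 4 T2D-like and 6 control-like CD4 samples
    at desk scale (small clone counts and depths so a run finishes in
    seconds)."""
    return RunConfig(
        seed=seed,
        groups=[
            GroupConfig(
                name="T1D",
                n_samples=9,
                n_clones=300,
                abundance_mode="hec_dominated",
                n_expanded=12,
                expanded_mass=0.70,
            ),
            GroupConfig(name="T2D", n_samples=4, n_clones=600, lognormal_sigma=0.8),
            GroupConfig(name="control", n_samples=6, n_clones=600, lognormal_sigma=0.8),
        ],
        n_reads=1000,
        error_rate=0.001,
    )


def _load_reference(config: RunConfig):
    if config.reference_fasta is None:
        return builtin_toy_reference()
    return load_germline(config.reference_fasta, config.reference_anchors)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages of a configured run; returns the output directory.

    Artifacts: per-sample truth tables, FASTQ, clonotype tables; cohort
    diversity table; usage matrices and correlations; VJ matrices;
    spectratypes; share matrix + summary per subset; group comparisons;
    optional PCR-bias report; ``manifest.json``.
    """
    try:
        config.validate()
    except ValueError as e:
        raise PipelineError("config", str(e)) from e

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))

    db = _load_reference(config)
    seq_model = SequencingModel(
        n_reads=config.n_reads,
        read_length=config.read_length,
        error_rate=config.error_rate,
        paired=config.paired,
        overlap=config.overlap,
    )
    pcr_model = PcrModel(config.pcr_bias_sigma, config.pcr_cycles)

    samples = []
    counters = []
    (out / "samples").mkdir(exist_ok=True)
    for gi, group in enumerate(config.groups):
        for si in range(group.n_samples):
            sample_id = f"{group.name}_{group.subset}_{si + 1:02d}"
            rng = np.random.default_rng([config.seed, gi, si])
            try:
                truth = simulate_repertoire(group.repertoire_model(), db, rng)
                write_truth_table(truth, out / "samples" / f"{sample_id}.truth.tsv")
                fq1 = out / "samples" / f"{sample_id}_R1.fastq"
                fq2 = out / "samples" / f"{sample_id}_R2.fastq"
                simulate_reads(
                    truth, seq_model, pcr_model, rng,
                    fq1, fq2 if config.paired else None,
                )
            except Exception as e:
                raise PipelineError("simulate", f"{sample_id}: {e}") from e
            try:
                if config.paired:
                    merged, merge_report = merge_pairs(fq1, fq2)
                    reads = [(m.read_id, m.sequence) for m in merged]
                    n_merged = merge_report.merged
                else:
                    reads = [
                        (rec.id, str(rec.seq))
                        for rec in SeqIO.parse(str(fq1), "fastq")
                    ]
                    n_merged = len(reads)
                annotated = annotate_reads(
                    reads, db, identity_threshold=config.identity_threshold
                )
            except Exception as e:
                raise PipelineError("annotate", f"{sample_id}: {e}") from e
            n_pass = sum(r.pass_filter for r in annotated)
            n_prod = sum(r.pass_filter and r.productive for r in annotated)
            logger.info(
                "%s: merged=%d identity>=%.0f%%=%d productive=%d",
                sample_id, n_merged, config.identity_threshold, n_pass, n_prod,
            )
            counters.append(
                {
                    "sample_id": sample_id,
                    "group": group.name,
                    "subset": group.subset,
                    "reads": len(reads),
                    "merged": n_merged,
                    "pass_identity": n_pass,
                    "productive_passing": n_prod,
                }
            )
            try:
                sample = build_clonotypes(
                    annotated, sample_id, group.name, group.subset
                )
            except Exception as e:
                raise PipelineError("clonotype", f"{sample_id}: {e}") from e
            write_clonotype_table(
                sample, out / "samples" / f"{sample_id}.clonotypes.tsv"
            )
            samples.append(sample)
    pd.DataFrame(counters).to_csv(out / "read_accounting.tsv", sep="\t", index=False)

    try:
        div = cohort_diversity_table(samples, threshold=config.hec_threshold)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.10g")
    except Exception as e:
        raise PipelineError("diversity", str(e)) from e

    try:
        profiles = [usage_profile(s, db) for s in samples]
        v_usage = pd.DataFrame(
            {p.sample_id: p.v_usage for p in profiles}
        ).T.rename_axis("sample_id")
        j_usage = pd.DataFrame(
            {p.sample_id: p.j_usage for p in profiles}
        ).T.rename_axis("sample_id")
        v_usage.to_csv(out / "usage_v.tsv", sep="\t", float_format="%.10g")
        j_usage.to_csv(out / "usage_j.tsv", sep="\t", float_format="%.10g")
        usage_correlation(profiles, "v").to_csv(
            out / "usage_corr_v.tsv", sep="\t", float_format="%.10g"
        )
        usage_correlation(profiles, "j").to_csv(
            out / "usage_corr_j.tsv", sep="\t", float_format="%.10g"
        )
        (out / "vj").mkdir(exist_ok=True)
        for s in samples:
            vj_matrix(s, db).to_csv(
                out / "vj" / f"{s.sample_id}.tsv", sep="\t", float_format="%.10g"
            )
        spectra = pd.DataFrame(
            {s.sample_id: spectratype(s) for s in samples}
        ).fillna(0.0).T.rename_axis("sample_id")
        spectra.to_csv(out / "spectratype.tsv", sep="\t", float_format="%.10g")
    except Exception as e:
        raise PipelineError("usage", str(e)) from e

    try:
        for subset in sorted({s.subset for s in samples}):
            members = [s for s in samples if s.subset == subset]
            if not any(s.group == config.case_group for s in members):
                continue
            records = share_matrix(
                members, config.case_group, threshold=config.hec_threshold
            )
            records.to_csv(
                out / f"sharing_{subset}.tsv", sep="\t", index=False
            )
            n_case = sum(s.group == config.case_group for s in members)
            summary = sharing_summary(records, n_case)
            (out / f"sharing_{subset}.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True)
            )
    except Exception as e:
        raise PipelineError("sharing", str(e)) from e

    try:
        comparisons = compare_groups(div)
        comparisons.to_csv(
            out / "comparisons.tsv", sep="\t", index=False, float_format="%.10g"
        )
    except Exception as e:
        raise PipelineError("cohort_stats", str(e)) from e

    if config.cycle_series_cycles:
        try:
            rng = np.random.default_rng([config.seed, 10_000])
            truth = simulate_repertoire(
                config.groups[0].repertoire_model(), db, rng
            )
            series = simulate_cycle_series(
                truth,
                tuple(config.cycle_series_cycles),
                tuple(config.cycle_series_reads),
                config.pcr_bias_sigma,
                rng,
            )
            c1, c2 = min(series.cycles), max(series.cycles)
            est = estimate_bias(series, c1, c2)
            report = {
                "c1": est.c1,
                "c2": est.c2,
                "k": est.k,
                "per_cycle_bias": est.per_cycle_bias,
                "n_clones": est.n_clones,
                "slope": est.slope,
                "intercept": est.intercept,
                "residual_sd": est.residual_sd,
                "v_usage_deviation": vgene_usage_stability(series, c1, c2),
            }
            (out / "pcr_bias.json").write_text(
                json.dumps(report, indent=2, sort_keys=True)
            )
        except Exception as e:
            raise PipelineError("pcr_bias", str(e)) from e

    manifest = {
        "tool": "tcrep",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "n_samples": len(samples),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
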