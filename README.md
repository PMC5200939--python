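# tcrep

Analysis of TCR-β immune repertoires sequenced over the CDR3 region, for
immunologists comparing clonal expansion and diversity across cohorts
(e.g. type-1 diabetes patients versus type-2 diabetes patients and
nondiabetic controls).  The package covers the full path from reads to
cohort statistics:

* a ground-truthed **synthetic repertoire generator** (clone-abundance
  skew, V(D)J junctional structure, PCR amplification bias, sequencing
  error) standing in for unreleased study data;
* **annotation**: paired-end merging, V/J germline alignment with a 70 %
  identity filter, IMGT-convention CDR3 extraction and productivity
  calling;
* **clonotype tables** keyed by (CDR3 nt, V family, J family);
* **expansion/diversity statistics**: highly-expanded clones (HECs,
  frequency ≥ 1 %), HEC count and ratio, and the normalized Shannon
  entropy

      H = − Σᵢ p(xᵢ) log p(xᵢ) / log n  ∈ [0, 1],

  where p(xᵢ) is the frequency of clone xᵢ and n the number of observed
  clones (1 = maximally diverse, 0 = monoclonal);
* **V/J usage structure**: family usage vectors, pairwise Pearson
  correlations, VJ-combination matrices, CDR3-length spectratypes;
* **shared-clone analysis** across samples at the CDR3 amino-acid level,
  classifying case-expanded clones as present-elsewhere (type 1) or
  case-unique (type 2);
* **cohort comparison** by unpaired two-tailed t-tests;
* **multiplex-PCR bias estimation** from repeated amplification of one
  template at different cycle numbers, recovering the accumulated bias k
  and the per-cycle bias k^(1/Δcycles).

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Run the demo cohort — 9 T1D-like samples (expanded-clone dominated), 4
T2D-like and 6 control-like samples (near-even), simulated, annotated and
analyzed end to end:

```python
import pandas as pd
from tcrep.pipeline import demo_config, run_pipeline

out = run_pipeline(demo_config(seed=1), "demo_run")
div = pd.read_csv(out / "diversity.tsv", sep="\t")
print(div.groupby("group")[["entropy", "hec_count", "hec_ratio"]].median())
comp = pd.read_csv(out / "comparisons.tsv", sep="\t")
print(comp[comp.statistic == "entropy"][["group_a", "group_b", "t", "p"]])
```

which prints

```
         entropy  hec_count  hec_ratio
group
T1D        0.729       14.0      0.670
T2D        0.952        4.0      0.064
control    0.950        7.0      0.102

group_a group_b          t            p
    T1D     T2D -17.205724 2.668004e-09
    T1D control -20.916242 2.156801e-11
    T2D control   1.225497 2.552399e-01
```

The case arm is dominated by a handful of expanded clones: two thirds of
its reads sit in HECs, its normalized entropy drops from ~0.95 to ~0.73,
and the entropy difference against either comparison arm is significant
while the two near-even arms do not differ.  The output directory also
holds per-sample clonotype tables, usage matrices and correlations
(`usage_*.tsv`), spectratypes, the shared-HEC matrix with its type-1/type-2
classification (`sharing_CD4.tsv`/`.json`), and a manifest (tool version,
config hash, seed) that makes the run exactly repeatable.

The same stages are available as CLI subcommands operating on
tab-separated tables, so real annotated data can replace the simulator at
any point:

```bash
tcrep simulate --n-clones 200 --n-reads 5000 --seed 3 --out sim
tcrep annotate sim.fastq --out rearr.tsv
tcrep clones rearr.tsv --sample-id S1 --group control --out clones.tsv
tcrep diversity clones.tsv --out diversity.tsv
tcrep run-all --config config.yaml --out results/
```

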