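# methyledit

Specificity analysis for CRISPR-guided DNA methylation editing.

Epigenome editors built from catalytically dead Cas9 (dCas9) and a
DNMT3A-DNMT3L effector can methylate a chosen CpG island (CGI) and silence
its gene — but the effector also binds accessible DNA on its own, so
treated cells accumulate off-target methylation genome-wide. Quantifying
that trade-off requires two assays and their analysis: targeted
bisulfite-amplicon sequencing at the target and at a sensitive off-target
promoter, and MBD-seq (methyl-CpG-binding-domain pulldown) for the
genome-wide picture. `methyledit` implements that analysis stack, a
matching synthetic-data generator so every stage is testable without any
external download, and an sgRNA off-target scanner.

**Who it is for:** people developing or benchmarking epigenome-editing
constructs (effector mutants, SunTag variants) who need reproducible
specificity numbers from amplicon bis-seq and MBD-seq-style data, and
people who want a fully seeded simulation of such experiments.

## The quantities at the core

For a construct with on-target methylation `on` and off-target methylation
`off` (percent, averaged over the analyzed CpGs):

* **specificity factor** = `on / off` (one decimal, ties away from zero);
* **residual activity** = `100 · on_mutant / on_reference` (integer percent);
* **off-target reduction** = `100 · (1 − off_mutant / off_reference)`.

For MBD-seq, coverage is binned (10 bp), RPKM-normalized, and then
**re-calibrated**: each sample is scaled so that its mean signal over the
K = 1000 CGIs most methylated in the *untreated* sample matches the
untreated mean there. Those CGIs are already fully methylated and cannot
legitimately gain signal; when treatment creates thousands of new
methylated regions, RPKM alone depresses unchanged regions and this
re-calibration removes exactly that distortion. Off-target severity between
constructs is summarized as the fold-reduction of background-subtracted
gain over originally unmethylated CGIs.

The simulator's treatment model gives each unmethylated off-target CGI a
methylation gain `theta · a_r · p_max`, where `theta` is the effector's
relative untargeted DNA-binding affinity and `a_r` the CGI's accessibility
— so engineered low-affinity mutants (small `theta`) reduce off-target
methylation proportionally while the dCas9-recruited on-target activity is
set independently. See `docs/methods.md` for the full model.

## Worked example

Published-style average methylation levels for a wild-type effector and
four DNA-binding mutants (on-target channel: CpGs 1–15 of the targeted
promoter amplicon; off-target channel: a sensitive untargeted promoter):

```python
import pandas as pd
from methyledit import metrics

summ = pd.DataFrame([
    {"sample": "WT",    "on_target_pct": 84.0, "off_target_pct": 53.0},
    {"sample": "K766E", "on_target_pct": 65.0, "off_target_pct": 53.0 * (1 - 0.55)},
    {"sample": "K844E", "on_target_pct": 58.0, "off_target_pct": 53.0 * (1 - 0.78)},
    {"sample": "R831E", "on_target_pct": 48.0, "off_target_pct": 53.0 * (1 - 0.90)},
    {"sample": "R887E", "on_target_pct": 64.0, "off_target_pct": 53.0 * (1 - 0.88)},
])
print(metrics.build_report(summ, reference="WT").to_string(index=False))
```

prints (columns abridged):

```
sample  on_target_pct  off_target_pct  specificity_factor  residual_activity_pct  off_target_reduction_pct
    WT           84.0           53.00                 1.6                  100.0                       0.0
 K766E           65.0           23.85                 2.7                   77.0                      55.0
 K844E           58.0           11.66                 5.0                   69.0                      78.0
 R831E           48.0            5.30                 9.1                   57.0                      90.0
 R887E           64.0            6.36                10.1                   76.0                      88.0
```

Reading: the wild-type effector methylates the target well (84%) but the
off-target promoter almost as much (53%) — a specificity factor of only
1.6. The R887E DNA-binding mutant keeps 76% of the on-target activity while
cutting off-target methylation by 88%, lifting the specificity factor to
10.1.

An end-to-end simulated experiment (reads → calling → report, plus the
genome-wide MBD workflow) runs from the command line:

```bash
methyledit run --workflow full --seed 3 --outdir out/
# out/specificity_report.tsv, out/mbd_results.json, out/scale_factors.json,
# per-sample FASTQ/BED/bedGraph artifacts and a checksummed manifest.json
```

Other subcommands (`bisseq-call`, `mbd-quantify`, `scan-offtargets`,
`metrics`, `simulate`) are thin shells over single library functions; see
`methyledit --help`.

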