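# Methods

`methyledit` models and analyzes the specificity of targeted DNA methylation
delivered by a dCas9-SunTag scaffold recruiting DNMT3A-DNMT3L effector
modules. This note documents the underlying models, the parameters that
matter, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## The specificity problem and its model

A programmable methyltransferase deposits CpG methylation through two
routes: recruitment by the dCas9-sgRNA complex to the target CpG island
(on-target), and binding of the freely diffusing effector to accessible DNA
anywhere in the genome (off-target). The package's generative model keeps
exactly these two routes:

* **On-target.** CpGs of the target CGI that are not shielded by the
  dCas9-sgRNA footprint are driven to a methylation probability `p_on`
  (default 0.84, a typical deep-editing level for an efficient construct).
  CpGs under the footprint stay at the untreated baseline — the bound
  ribonucleoprotein sterically excludes the methyltransferase, which is why
  such sites are excluded from on-target averages (`blocked_indices` in the
  amplicon specification; the default geometry blocks sites 16–19 of a
  19-CpG amplicon and averages sites 1–15).
* **Off-target.** Every unmethylated off-target CGI *r* gains methylation
  probability `theta * a_r * p_max`, added to its baseline and clipped to
  [0, 1]. `theta` in (0, 1] is the relative untargeted DNA-binding affinity
  of the effector (1 for wild type; DNA-binding mutants have smaller
  values), `a_r` in [0, 1] is the chromatin accessibility of the CGI, and
  `p_max` (default 0.6) is the gain at full affinity and accessibility.
  The model makes the off-target gain exactly proportional to `theta`, so a
  mutant with affinity `theta` shows a `1/theta`-fold off-target reduction
  by construction — the property the genome-wide pipeline is tested to
  recover.

Intrinsically methylated CGIs do not change under treatment. This is not
a simplification of convenience: it is the biological anchor that the
internal re-calibration normalization (below) depends on.

### Baseline distributions

Untreated per-CpG methylation probabilities are drawn per CGI class:
Beta(20, 2) for the methylated class (mean ≈ 0.91, tight), Beta(1, 30) for
the unmethylated class and non-CGI CpGs (mean ≈ 0.03). Accessibility is
Beta(2, 2) (symmetric, mean 0.5). These choices produce a clearly bimodal
untreated CGI signal and a strong wild-type off-target gain, i.e. the
qualitative regime the analysis is designed for; all three are
config-exposed. The accessibility distribution of real off-target CGIs is
not characterized by any measurement we model — Beta(2, 2) is a declared
stand-in, and any conclusion that depends on the *shape* of the
accessibility distribution (rather than its mean) should not lean on the
simulator.

## Bisulfite amplicon simulation and analysis

Reads are simulated from the top strand only (single-strand amplicon
designs are the norm for targeted bis-seq; no CpG destranding is needed
downstream). For each fragment — always the full amplicon — each CpG
cytosine is methylated by a Bernoulli draw from its site probability;
unmethylated cytosines (CpG or not) convert to T with `conversion_rate`
(default 0.998), methylated ones with `inappropriate_conversion` (default
0.002); uniform substitution errors (default 1e-3 per base) are applied to
the emitted reads last. Qualities are constant Q37; an optional
low-quality-tail injector exists solely to exercise the 3' trimming path.
No PCR duplicates and no adapters are simulated, so adapter trimming
reduces to quality trimming.

The analysis pipeline mirrors the standard amplicon workflow: 3' quality
trimming at Q20, overlap merging (minimum overlap 20, mismatch fraction cap
0.1, highest-match overlap wins, ties to the longest overlap, disagreements
to the higher-quality base), alignment, per-CpG calling (C = methylated,
T = unmethylated, anything else or below Q20 ignored), conversion QC as
T/(C+T) over non-CpG cytosines, and an unweighted per-site mean over the
analysis CpGs ("site-averaged" rather than read-weighted; with amplicon
data at uniform coverage the two coincide up to edge effects).

**Alignment.** Reads are placed by ungapped scoring in a C→T-collapsed
alphabet (best match count, leftmost on ties, reject below 90% reduced-
alphabet identity). This replaces a full bisulfite aligner deliberately:
amplicon reads are indel-free by construction and the only quantity
extracted is the C/T state over reference CpGs, which the reduced-alphabet
placement preserves exactly. This is the package's one intentional
methodological substitution and it is exercised end-to-end by
simulation-backed recovery tests. It is not suitable for genome-scale
bisulfite mapping.

**Coverage floor.** Region means require ≥ 100 merged reads by default
(config-exposed); real amplicon libraries run thousands of reads per
amplicon, desk-scale simulations may lower the floor.

**Pair handling.** Pairs that fail to merge are dropped, not analyzed
single-end: amplicon designs guarantee overlap, so a failed merge indicates
a defective read pair.

## MBD-seq model and the internal re-calibration

**Capture model.** A pulldown fragment is retained with probability
`1 − prod_i(1 − q · p_i)` over the CpGs it covers, where `q`
(`mbd_capture_q`, default 0.05) is the per-methylated-CpG capture
probability. This closed form is the exact marginal of the two-stage
process "draw each CpG's methylation state, then capture each methylated
CpG with probability q, keep the fragment if any site captured"; because
fragments are independent, collapsing the two stages changes no
distribution. The test suite nevertheless cross-checks it against a literal
two-stage Monte-Carlo. Retention is linear in methylation only while
`q · sum(p_i)` is small; at the default q a fully methylated 150 bp
fragment (~17 CpGs here) is already in the saturating regime. Analyses that
must read *ratios* of methylation gains off coverage ratios (fold-reduction
recovery) therefore use q = 0.015, where the response is linear to ~5%.

**Coverage and normalization.** Fragment sets are binned at 10 bp (a bin
counts the fragments overlapping it), scaled to RPKM
(`signal × 1e9 / (total_fragments × bin_size)`), and then re-calibrated:
the K = 1000 CGIs with the highest per-CGI mean signal in the untreated
sample form the reference set R; each sample i is multiplied by
`f_i = mean_R(untreated) / mean_R(sample_i)` (per-CGI means averaged, not
pooled bins), and the untreated sample keeps `f = 1` exactly, so RPKM units
and the reference sample are preserved. Ties in the top-K selection are
broken by genomic order. The rationale: reference CGIs are fully methylated
before treatment, so their pulldown signal cannot legitimately rise;
treatments that create thousands of new methylated regions inflate the
library's captured mass, and RPKM then *depresses* unchanged regions —
a spurious global decrease that the re-calibration removes. The acceptance
suite demonstrates this quantitatively: with ~9000 newly methylated CGIs
the RPKM-only stable-CGI ratio is distorted by > 30 %, and ≤ 5 % after
re-calibration (exact when the stable set coincides with R).

**CGI classification.** Two-class split by one-dimensional two-means on
log1p per-CGI mean signal, deterministically initialized at the 25th/75th
percentiles, class boundary at the midpoint of the final centers. All-equal
signals are a declared degenerate input.

**Peak calling.** No specific published algorithm is being reproduced; the
caller is the simplest one whose behavior is provable on planted truth.
A bin is peak-eligible when the treated signal strictly exceeds a
background threshold (99th percentile of untreated non-CGI bins) *and* the
treated − untreated differential strictly exceeds `min_differential`
(default 0). Eligible runs are fused across gaps ≤ 50 bp and runs narrower
than 100 bp are dropped; the peak score is the mean differential. Strict
inequalities make a flat background yield zero peaks. Known limitation: on
deep-coverage regions Poisson noise alone can satisfy `differential > 0`
over fused runs, so differential peak lists on noisy data need
`min_differential` set to a few noise standard deviations; the planted-gain
and flat-background properties are what the defaults are proven against.

**Fold reduction.** Over the unmethylated CGI set,
`(mean_WT − mean_untreated) / (mean_mutant − mean_untreated)` on
re-calibrated signals; a non-positive mutant gain is reported censored at a
fold ceiling rather than as a number.

**CGI matrices.** Rows cover CGI ± flank (default 1 kb): flanks in real
genomic bins, the CGI body linearly resampled to a fixed column count;
out-of-chromosome bins are NaN.

## Off-target scanner

SpCas9 convention: 20-mer protospacer immediately 5' of the PAM on the hit
strand, PAM pattern NGG with the N position unconstrained, mismatches
counted over the 20-mer only, both strands scanned, reverse-strand hits in
forward coordinates, genome Ns never matching a guide base. Bulges are not
modeled, and hits are reported per position without deduplicating
overlapping hits. The scanner is vectorized per guide position and verified
against an exhaustive per-position Hamming oracle.

## Specificity metrics and rounding

Specificity factor = on/off ratio at one decimal; residual activity =
100 × mutant-on / reference-on at integer precision; off-target reduction =
100 × (1 − mutant-off / reference-off) at integer precision (negative
values pass through as increases). Rounding is half-away-from-zero
throughout — with banker's rounding 10.06 would print as 10.1 but 10.05 as
10.0, which does not match how such ratios are conventionally reported.
An off-target level of exactly zero yields an infinite factor with an
explicit flag. The off-target channel of the amplicon workflow is the mean
over all 12 CpGs of the untargeted sensitive-promoter amplicon (no blocked
sites there).

## Determinism and seeds

One global seed is expanded into independent per-stage child seeds by
SHA-256 of `"{seed}:{stage}"`, so each stage is independently reproducible
and adding a stage never shifts another stage's stream. Baseline methylome
and accessibility draws use streams independent of `theta`, which makes
off-target gains exactly proportional to `theta` across runs with a shared
seed. Identical config + seed reproduce byte-identical FASTQ/BED/bedGraph
artifacts (checksummed in the run manifest).

## Statistical testing design

Per-CpG calling is calibration-tested against the exact readout
probability: the methylation truth propagated through the conversion,
inappropriate-conversion and sequencing-error channels,
`p_obs = P(C-call | C-or-T-call)`. Site-level agreement is asserted with
exact (Clopper–Pearson) intervals held *simultaneously* over all sites and
truth vectors via a Šidák correction at 99% family confidence, plus a cap
of 3% on the miss rate of unadjusted per-site 99% intervals. Uncorrected
per-site assertions over hundreds of sites would be failed with near
certainty by a perfectly calibrated caller (~1% of sites fall outside a 99%
interval by construction); the simultaneous band is the coherent version of
"every site is calibrated" and the miss-rate cap bounds dispersed
miscalibration the family-wise band could miss.

## Problem sizes in the shipped tests

Chosen to make every property measurable at desk scale: amplicon recovery
uses 20 random 15-CpG truth vectors at 10,000 read pairs; conversion QC
5,000 pairs; the re-calibration demonstration a 10,000-CGI genome (1000
stably methylated) with 200,000 fragments per sample; fold-reduction
recovery an 800-CGI genome with 150,000 fragments per sample at q = 0.015;
scanner equivalence 100 random 50 kb genomes with planted near-matches.

## Known limitations

* The generator emulates neither transfection/sorting heterogeneity, PCR
  duplicates, adapter read-through, indels, nor chromatin-state covariance
  between neighboring CGIs; passing tests certify the analysis logic on the
  stated statistical structure, not performance on any real library.
* Real MBD pulldown efficiency depends on CpG density and salt conditions
  in ways the single-q capture model flattens.
* The amplicon aligner is ungapped by design (see above) and must not be
  reused for genome-scale mapping.
* Genome-wide peak *counts* are a function of the (unspecified) peak-caller
  parameters and sequencing depth; the package treats them as descriptive
  output, not as reproducible quantities.
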