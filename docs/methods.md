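# Methods

This note documents the models and procedures implemented in `holopipe`,
the defaults and why they were chosen, what the synthetic data emulate,
and the numerical decisions taken where the design was genuinely open.

## Coverage-scan trimming

Per-base alignment depth along each assembled transcript is scanned with a
rolling window (default 10 bp, 1-bp stride). The threshold is
`frac × max(window means)` with `frac = 0.33`; a window passes when its
mean is **≥** the threshold (a tie at exactly the threshold passes, reading
"less than 33%" strictly). The retained interval runs from the first
passing window's start to the last passing window's end — only the two
ends are trimmed; interior dips are never removed. Transcripts whose
retained interval is shorter than `min_len = 300` bp are dropped
(`below_min_len`), and profiles shorter than one window are dropped
(`no_window_passes`).

Open choices, resolved as follows and configurable: the threshold maximum
is taken over window means (the scan is defined over windows, and a
per-base maximum would make the threshold sensitive to single-base depth
spikes), and windows slide by 1 bp rather than tiling by 10 (tiling would
quantize trim points to window boundaries for no benefit). `scan_trim` is
O(L) via a cumulative sum; the test suite checks exact agreement with an
independent O(L·W) re-summation on 1,000 random block profiles.
Idempotence holds by construction: re-scanning a retained interval keeps
all of it, because its end windows already pass a threshold that can only
stay equal or drop after trimming.

## Species assignment from dual-enrichment gDNA

For each transcript and each of the two gDNA libraries (host-enriched,
symbiont-enriched) we record properly-paired mapped read counts, depth
= reads/length, and breadth = covered fraction. Classification happens in
log10 depth space after adding a 0.5-read pseudocount before length
normalization (so zero-count transcripts remain plottable and rankable).

Auto gates: a transcript is called **host** when
log10(depth_host/depth_symb) ≥ `min_log10_ratio` (default 1.0, i.e. 10×)
**and** its host-enriched depth clears an absolute floor (default 0.1× the
median depth of that sample, so gates rescale with sequencing effort);
symmetric for **symbiont**; everything else — including boundary ties —
is **ambiguous**. Manual gates (two rectangles in the depth plane) can
reproduce any hand-drawn gate. Breadth and GC are diagnostic: the
GC-separation report gives per-label GC mean/sd and a Mann–Whitney
common-language effect size between the host and symbiont labels.

Chloroplast flagging is a conjunction: label ambiguous **and**
symbiont-enriched depth at/above the 90th percentile **and** an annotated
chloroplast cellular-component GO term (GO:0009507 or GO:0009535). The
flag can never sit on a host- or symbiont-labelled transcript.

## Differential expression

Counts are modelled as K_ij ~ NB(mean s_j·q_i, dispersion α_i) per species.

- **Size factors**: median-of-ratios against the per-gene geometric mean,
  restricted to genes expressed in every sample, rescaled to geometric
  mean 1. Each species is normalized independently.
- **Dispersions**: gene-wise Cox–Reid adjusted profile likelihood,
  maximized over a log-spaced grid (1e-4 … 10) with group means profiled
  out in closed form; the Cox–Reid term (half the log of the summed NB
  weights per group) removes most of the small-sample downward bias. A
  trend α(μ) = a₀ + a₁/μ is fitted across genes by trimmed least squares
  and the final dispersion is a log-scale blend with weight **0.1** on the
  gene-wise value. The weight is small because at 3-replicate designs the
  gene-wise estimate carries ~4 residual degrees of freedom against a
  trend pooled over thousands of genes; heavier gene-wise weight
  measurably inflates the Wald type-I error. Dispersions (and the
  normalization) are always estimated from the **full** sample set, not
  just the two contrasted groups.
- **Wald test**: group means q̂ = ΣK/Σs (the closed-form NB mean estimate
  at fixed dispersion); log2FC = log2((q̂_A+ε)/(q̂_B+ε)) with ε = 0.5
  normalized counts in the fold change only (never in the likelihood);
  SE from the observed Fisher information of log q̂ evaluated at the
  pseudocounted means; p from the normal reference; BH correction within
  one species × contrast family. Genes with zero counts in both groups
  get p = NaN and are excluded from the family. Contrast orientation:
  the later timepoint (or the knockdown's comparator as documented per
  call) is the numerator.
- **DEG thresholds** are inclusive: |log2FC| ≥ 0.8 and adjusted p ≤ 0.05.

Known limitation: with 3 replicates the normal-reference Wald test has
slightly heavy extreme tails (empirically ~1.3–1.8× the nominal
probability below p ≈ 0.002 even with the true dispersion); at the 0.05
level the empirical type-I error is 0.050–0.057 in the calibration
simulations. Multi-factor designs, independent filtering and outlier
replacement are out of scope.

## Driver-dependence selection

Spearman ρ of every gene against the driver is computed on size-factor
normalized counts with average-rank ties, pooled over all samples of the
knockdown experiment (both conditions and timepoints — the scatter the
analysis is based on pools them); constant genes get NaN and can never be
selected by the correlation route. A gene is selected when **either** it
is significantly downregulated in the knockdown at the early timepoint
(adjusted p ≤ 0.1 and log2FC ≥ 0.8 with control in the numerator) **or**
ρ ≥ 0.8; thresholds inclusive; the route (by_de / by_rho / both) is
recorded.

The DE route is directional by default: both routes target genes
*activated* by the driver's program, and admitting genes upregulated in
the knockdown roughly doubles the null false-positive rate of the
selector for no biological gain. The sign-agnostic |log2FC| reading is
available as `absolute_lfc=True`.

## PAM photophysiology

F_o is the mean fluorescence over the last 10 s of darkness before the
first saturating flash; F_m (and F_m′ per actinic step) is the mean over
the central 50% of the flash, skipping the rise/fall edges. F (steady
state) is the mean over the last 10 s before each in-step flash, and only
flashes at least 2 min into a step count (light acclimation). Yields:
F_v/F_m = (F_m−F_o)/F_m and Y(II) = (F_m′−F)/F_m′. Values outside [0,1]
(or F_m ≤ F_o) are flagged invalid, never clipped. The variant arithmetic
(F_m′−F_o)/F_m that circulates in some protocol write-ups is implemented
behind `yii_formula="printed"` for auditability; the operating-yield form
is the default. Light curves sort steps by PAR, average duplicate levels
(with a note), and report whether Y(II) is non-increasing.

## Synthetic data

The generators emulate the statistical structure the analyses assume;
all are deterministic under their seed and emit planted truth tables.

- **Transcriptomes**: per-base GC-probability sequences, defaults 0.40
  (host) vs 0.58 (symbiont) — a realistic metazoan/chlorophyte contrast —
  lengths uniform on 300–4,000 bp; shared/organelle-like transcripts at
  the midpoint GC.
- **Enrichment reads**: expected reads scale with length at `base_depth`
  (default 300 reads/kb, a deeply sequenced gDNA run) in the enriched
  sample and 1/`enrichment_factor` (default 50×) in the depleted one;
  shared transcripts are 10× base depth on both sides (high-copy
  organelle model). Counts follow a negative binomial with size 20. The
  size parameter was set so that the planted clusters are well separated:
  the log10-ratio noise floor is √(2·ψ′(size))/ln 10 regardless of depth
  (~0.29 at size 5, ~0.14 at size 20), and the assignment analysis
  presumes clusters separated well beyond the 10×-ratio gate. Breadth
  follows the Lander–Waterman expectation 1−exp(−depth·150).
- **Counts**: NB with global dispersion 0.1 and lognormal baselines
  (ln-mean 5.5, ln-sd 1.0 → median ≈ 245 counts); planted genes floored
  at mean 200 so effects are recoverable at 3 replicates. Early-wave
  effects act at 3 and 6 hpa, late at 2 dpa, overlap at both, default
  |log2FC| = 2 with alternating signs. The driver is induced ×4 at 3 hpa
  and multiplied by `knockdown_factor` = 0.2 in all RNAi samples (reduced
  but never eliminated); wave effects are attenuated by the same factor
  under RNAi when `waves_runt_dependent` is set. Dependent genes follow
  log-mean = α + slope·log(driver mean of the sample), slope 1. Library
  size factors are lognormal (sd 0.1). Design: 3 replicates per
  timepoint × condition.
- **Traces**: 20-min dark adaptation, 600-ms saturating flashes, 100-Hz
  sampling, 150-s actinic steps, with plateaus set by
  F_m = F_o/(1−F_v/F_m true) and F_m′ = F/(1−Y(II) true) and
  multiplicative Gaussian noise (default 1%). Flashes are modelled as
  instantaneous plateaus — only plateau values enter the yield
  arithmetic, so induction kinetics are deliberately not simulated.
  The bundled injury scenario plants F_v/F_m 0.65 → 0.55 → 0.55 and a
  Y(II) ladder falling further at 24 hpa, the qualitative post-amputation
  pattern.

What passing tests do *not* show about real data: the simulators contain
no mapping ambiguity or multi-mapping reads, no GC- or length-dependent
coverage bias, no per-gene dispersion heterogeneity beyond the fitted
trend, no batch effects, and no instrument drift or induction kinetics in
the traces. Results on real libraries depend on those factors; the
planted-truth benchmarks validate the estimators, not the upstream
measurement process.

## Benchmark problem sizes

The standard scenarios (shared by the tests and `scripts/acceptance.py`)
use 1,000 random profiles for the trim oracle; 2,000 transcripts at 50×
(and 1×) enrichment for assignment; 5,000 null genes (mean 100,
dispersion 0.1, 3 vs 3) for type-I calibration and 500 balanced planted
2-fold genes for log2FC recovery; 2,000 genes with 60+60+10 planted wave
genes for the two-wave scenario; 2,000 genes with 30 planted dependent
genes for the selector; and single traces at 1% noise for yield recovery.
These sizes give stable metrics (median/mean sampling error well inside
the asserted bounds) while keeping a full run in tens of seconds.

## Pipeline determinism

One global seed is fanned out per stage as
`(seed·1000003 + crc32(stage)) mod 2³¹`, so adding a stage never perturbs
the others. All outputs are plain text with fixed float formatting; the
manifest records SHA-256 digests per stage, and two runs at the same seed
are byte-identical (checked in the tests and the reproduction script).
The report re-verifies digests and recomputes every summary number from
the stage outputs, failing loudly on tampering.
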