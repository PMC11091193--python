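# holopipe

Analysis pipeline for dual-species transcriptomics and photophysiology in a
regenerating photosymbiotic animal — an acoel host carrying extracellular
*Tetraselmis*-like green algal endosymbionts. When such a holobiont is
injured, both partners respond: the host launches a wound/regeneration
program driven by an injury-induced *runt* transcription factor, and the
algae show transcriptional waves and a drop in photosynthetic efficiency.
Studying this requires a set of computations that no single existing tool
covers, and `holopipe` implements them as a tested, reusable library:

1. **Coverage-scan transcript trimming** — de novo assembled transcripts are
   trimmed at both ends where a 10-bp rolling window of per-base alignment
   depth falls below 33% of the maximum window mean; transcripts shorter
   than 300 bp after trimming are dropped. This removes chimeric joints and
   poorly supported ends.
2. **Species-of-origin assignment** — each transcript is scored by its depth
   (mapped reads / length) in two enrichment gDNA libraries (symbiont-cleared
   host vs flow-sorted algae). Gates in the log10 depth plane label
   transcripts host / symbiont / ambiguous; GC content supports the split,
   and high-copy ambiguous transcripts carrying chloroplast GO terms
   (GO:0009507 / GO:0009535) are flagged as putative chloroplast genes.
3. **Dual-species differential expression** — the mixed count matrix is
   split by species and each species normalized independently
   (median-of-ratios size factors). A self-contained negative-binomial Wald
   test (Cox–Reid gene-wise dispersions shrunk toward a mean–dispersion
   trend) with Benjamini–Hochberg correction calls DEGs at
   |log2FC| ≥ 0.8, adjusted p ≤ 0.05.
4. **Driver-dependence selection** — genes belonging to the *runt*-dependent
   program are selected if they are downregulated in the knockdown at 3 hpa
   (adjusted p ≤ 0.1, log2FC ≥ 0.8) **or** strongly positively Spearman-correlated
   with driver expression (ρ ≥ 0.8) across the knockdown experiment.
5. **PAM photophysiology** — F_o, F_m, F and F_m′ are extracted from
   annotated pulse-amplitude-modulation fluorescence traces;
   F_v/F_m = (F_m − F_o)/F_m and Y(II) = (F_m′ − F)/F_m′ quantify maximum
   and operating PSII quantum yields, with light curves over stepped
   actinic intensities.

A first-class **synthetic-data module** generates every input with planted
ground truth — mixed transcriptomes with contrasting GC, enrichment read
counts, coverage profiles, NB count matrices with two temporally distinct
DE waves plus an injury-induced driver and driver-coupled dependent genes,
and PAM traces with planted yields — so every stage is testable end to end.

## Worked example

```python
from holopipe.simulate import HolobiontSimConfig, gen_enrichment_profiles, gen_transcriptomes
from holopipe.species import classify, fit_auto_gates

cfg = HolobiontSimConfig(n_host=600, n_symbiont=400, n_shared=20, seed=7)
ts, truth = gen_transcriptomes(cfg)
profiles = gen_enrichment_profiles(ts, truth, cfg)
calls = classify(profiles, fit_auto_gates(profiles))
print(calls["label"].value_counts())
```

prints

```
host         599
symbiont     400
ambiguous     21
```

i.e. of 1,020 simulated transcripts (600 host, 400 symbiont, 20 high-copy
shared), the auto-derived gates recover 99.9% of the single-genome
transcripts and park all 20 organelle-like transcripts in the ambiguous
bucket — exactly the behavior wanted from "conservative" gates: no
transcript is assigned to a species without clear enrichment evidence.

The other capabilities have matching narrative scripts under `examples/`
(one per stage, each printing the numbers it computes and what they mean),
and `holopipe run --seed 7 --out-dir demo` runs all six stages from one
config, writing plain-text tables plus a SHA-256 digest manifest;
`holopipe report demo` recomputes every summary number from those files.

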