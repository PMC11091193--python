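"""Species-of-origin assignment from dual-enrichment gDNA sequencing.

Simulates a mixed host/symbiont transcriptome with contrasting GC content
plus a minority of organelle-like (high copy in both samples)
transcripts, derives conservative gates from the depth plane, and labels
every transcript host / symbiont / ambiguous.
"""

from holopipe.simulate import HolobiontSimConfig, gen_enrichment_profiles, gen_transcriptomes
from holopipe.species import classify, fit_auto_gates, gc_separation_report

cfg = HolobiontSimConfig(n_host=600, n_symbiont=400, n_shared=20, seed=7)
ts, truth = gen_transcriptomes(cfg)
profiles = gen_enrichment_profiles(ts, truth, cfg)

gates = fit_auto_gates(profiles)
calls = classify(profiles, gates)
merged = truth.merge(calls, on="transcript_id")

print(calls["label"].value_counts().to_string())
non_shared = merged[merged["species"] != "shared"]
acc = (non_shared["label"] == non_shared["species"]).mean()
print(f"accuracy on non-shared transcripts: {acc:.4f}")
shared = merged[merged["species"] == "shared"]
print(f"shared/organelle-like transcripts labelled ambiguous: "
      f"{(shared['label'] == 'ambiguous').mean():.2f}")
# At 50x enrichment the two species separate cleanly in the depth plane;
# the high-copy shared transcripts sit near the diagonal and stay ambiguous.

report = gc_separation_report(profiles, calls)
for label, stats in report["groups"].items():
    print(f"GC {label}: mean {stats['gc_mean']:.3f} sd {stats['gc_sd']:.3f} (n={stats['n']})")
# The contrasting GC content of the two genomes independently supports the split.
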