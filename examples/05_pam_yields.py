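"""PAM fluorometry: F_v/F_m and the Y(II) light curve from one trace.

Simulates a dark-adapted trace with a saturating flash followed by four
stepped actinic light levels (one flash per step after 2 min of
acclimation), then recovers the planted quantum yields.
"""

from holopipe.pam import analyze_trace, light_curve
from holopipe.simulate import TraceSimConfig, gen_trace

cfg = TraceSimConfig(
    true_fvfm=0.65,
    true_yii=(0.60, 0.45, 0.30, 0.15),
    par_levels=(25, 50, 100, 200),
    noise_sd=0.01,
    seed=3,
)
trace = gen_trace(cfg)
result = analyze_trace(trace)

print(f"Fo = {result.Fo:.1f}, Fm = {result.Fm:.1f}")
print(f"Fv/Fm = {result.FvFm:.3f} (planted {cfg.true_fvfm})")
for row in result.steps.itertuples():
    print(f"  PAR {row.par:>5.0f}: F = {row.F_steady:6.1f}  Fm' = {row.Fm_prime:6.1f}"
          f"  Y(II) = {row.YII:.3f}")
# Each Y(II) lands within ~0.01 of its planted value at 1% noise.

curve, mono = light_curve(result.steps)
print(f"Y(II) non-increasing with PAR: {mono['non_increasing']}")
# Higher actinic light closes more PSII centers, so the operating yield
# falls monotonically along the light curve.
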