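"""Coverage-scan trimming of assembled transcripts.

Builds a coverage profile with poorly supported ends (as left by chimeric
joints and assembly overhangs), trims both ends below 33% of the maximum
10-bp window mean, and drops anything shorter than 300 bp.
"""

import numpy as np

from holopipe.trim import TrimParams, scan_trim, trim_set

# a 700-bp transcript: 100 bp of thin support, a 500-bp well-covered core,
# then 100 bp of thin support again
depth = np.concatenate([np.full(100, 3), np.full(500, 90), np.full(100, 2)])
result = scan_trim("tx_chimeric_ends", depth, TrimParams())
print(f"kept={result.kept} retained=[{result.start}, {result.end}) "
      f"({result.retained_length} bp of {depth.size})")
# The retained interval hugs the high-coverage core: the thin flanks are
# removed, the transcript survives the 300-bp length filter.

# a transcript whose well-supported core is too short to keep
short = np.concatenate([np.full(250, 2), np.full(200, 80), np.full(250, 2)])
result2 = scan_trim("tx_short_core", short, TrimParams())
print(f"kept={result2.kept} reason={result2.reason}")

_, summary = trim_set({"a": depth, "b": short}, TrimParams())
print(f"summary: {summary}")
# n_kept + n_dropped always equals n_input; bases_trimmed counts the
# flanks removed from kept transcripts.
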