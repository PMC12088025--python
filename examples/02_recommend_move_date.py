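"""Recommend the least burdensome MWH move date meeting a risk target.

Candidates run from 'no stay at all' to 'move four weeks early'; the
rule returns the first that reaches the requested P(SBA), so women are
not asked to leave home earlier than the target requires.
"""

import math

import sbarisk as sk

F = sk.onset_distribution("khambalia")
G = sk.latent_distribution("multiparous")

t = sk.parse_access_time("10h15")
for threshold in (0.80, 0.90, 0.95, 0.99):
    rec = sk.recommend_move_date("multiparous", t, threshold, F, G)
    where = "no MWH stay" if math.isinf(rec.move_date_d) else f"{-rec.move_date_d:.0f} d before EDD"
    met = "" if rec.met else "  (threshold unreachable; best available)"
    print(f"target P(SBA) >= {threshold:.2f}: {where:>18}  achieves {rec.p_sba:.4f}{met}")
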