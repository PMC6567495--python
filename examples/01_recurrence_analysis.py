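"""Recurrence quantification of a single coded interaction sequence.

Builds a short who-with-whom sequence for a 3-member group by hand, then
prints the recurrence plot measures.  RR is the percentage of time-point
pairs at which the same interaction state recurs; DET the share of those
recurrences that sit on diagonal lines (repeated sub-sequences) of length
at least two; ENT the Shannon entropy (bits) of the line-length
distribution.
"""

from teamdyn.rqa import rqa_measures
from teamdyn.sequences import InteractionEvent, TEAM, encode_sequence

events = [
    InteractionEvent(time_s=t, source=s, target=tgt, ipa_category=ipa)
    for t, s, tgt, ipa in [
        (1, 1, 2, 5), (3, 2, 1, 6), (5, 1, 2, 5), (8, 2, 3, 4),
        (11, 3, 2, 4), (13, 1, TEAM, 10), (15, 2, 3, 6), (18, 3, 2, 7),
        (20, 1, 2, 5), (23, 2, 1, 6), (25, 1, 2, 5), (27, 1, TEAM, 11),
    ]
]

seq = encode_sequence(events, n_members=3, group_id="demo")
print(f"sequence ({len(seq)} events): {' '.join(seq.symbols)}")

m = rqa_measures(seq)
print(f"recurrence rate : {m.rr:.2f} %   (how often any state recurs)")
print(f"determinism     : {m.det:.2f} %   (recurrences on lines >= 2)")
print(f"entropy         : {m.ent:.3f} bits (diversity of line lengths)")
print(f"line histogram  : {dict(sorted(m.line_histogram.items()))}")
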