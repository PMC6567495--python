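"""Inter-rater and internal-consistency reliability.

Two coders count behaviours for the same sessions; their agreement is the
two-way random-effects, single-measures, absolute-agreement intraclass
correlation ICC(2,1).  A multi-item Likert subscale's internal consistency
is Cronbach's alpha.
"""

import numpy as np

from teamdyn.association import cronbach_alpha
from teamdyn.sequences import icc_two_way_random

# behaviour counts per session (rows) from two independent coders (columns)
ratings = [[42, 45], [31, 30], [56, 58], [24, 27], [39, 38], [47, 47]]
res = icc_two_way_random(ratings)
print(f"ICC(2,1) over {res.n_subjects} sessions, {res.n_raters} coders: {res.icc:.3f}")
print(f"model: {res.model_label}")

# five 7-point Likert items answered by 30 participants, driven by one latent trait
rng = np.random.default_rng(0)
latent = rng.normal(5, 1, size=(30, 1))
items = np.clip(np.round(latent + rng.normal(0, 0.8, size=(30, 5))), 1, 7)
print(f"Cronbach's alpha over {items.shape[1]} items: {cronbach_alpha(items):.3f}")
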