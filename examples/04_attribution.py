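"""Attribute latent-embedding variance to metadata tags (R^2).

Part 1 plants a lone numeric effect with closed-form R^2 = 0.30 and checks
recovery; part 2 adds a dominant 3-class structure and checks the
label-first ranking (class signal >> metadata tags).
"""

import numpy as np

import ngtlife as ng
from ngtlife.attribute import encode_tag

# part 1: effect (a, a) with unit noise gives R^2 = a^2 / (a^2 + 1) = 0.30
a = np.sqrt(3.0 / 7.0)
lone = ng.synth_embeddings([2000, 0, 0], np.zeros((3, 2)),
                           tag_effects={"planted": np.array([a, a])},
                           noise_sd=1.0, seed=1)
rec = ng.tag_r2(lone.X, encode_tag("planted", lone.tags["planted"], kind="numeric"))
print(f"planted R^2 0.30 -> recovered {rec.r2:.3f} at n = {rec.n}")

# part 2: strong class structure plus weak metadata effects
es = ng.synth_embeddings(
    [1200, 700, 100],
    centers=np.array([[4.0, 0.0], [-4.0, 2.0], [0.0, -5.0]]),
    tag_effects={"age_like": np.array([a, a]),
                 "manufacturer": np.array([[0, 0], [0.4, 0.1], [0.1, 0.4]])},
    noise_sd=1.0, seed=3,
)

tags = [
    encode_tag("label", es.labels),
    encode_tag("age_like", es.tags["age_like"], kind="numeric"),
    encode_tag("manufacturer", es.tags["manufacturer"].astype(str)),
]
for r in ng.rank_tags(es.X, tags):
    print(f"rank {r.rank}: {r.tag:13s} R^2 = {r.r2:.3f}")

joint = ng.cumulative_r2(es.X, tags[1:])
print(f"metadata tags jointly: R^2 = {joint.r2:.3f}")
# The class label explains most variance; metadata tags explain a small
# fraction - the signature of a classifier that learned its task rather
# than its scanners.
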