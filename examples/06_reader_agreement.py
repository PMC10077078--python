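"""Reader-study agreement analytics: Cohen kappa, pairwise matrices, and the
unaided-vs-aided paired t test on a synthetic two-phase feed/do-not-feed study.
"""

import numpy as np

import ngtlife as ng

ratings = ng.synth_reader_ratings(n_images=335, n_readers=5, seed=0)

per_phase = {}
for phase in ("unaided", "aided"):
    sub = ratings[ratings["phase"] == phase]
    wide = sub.pivot(index="record_id", columns="reader", values="decision")
    matrix, inter_mean, inter_sd = ng.kappa_matrix(wide)
    truth = sub.drop_duplicates("record_id").set_index("record_id")["consensus"]
    vs = [ng.cohen_kappa(wide[c], truth.loc[wide.index]).kappa for c in wide.columns]
    per_phase[phase] = vs
    print(f"{phase:8s} inter-reader kappa {inter_mean:.2f} +/- {inter_sd:.2f};  "
          f"vs consensus {np.mean(vs):.2f} +/- {np.std(vs, ddof=1):.2f}")

t, p, df = ng.paired_kappa_test(per_phase["unaided"], per_phase["aided"])
print(f"paired two-tailed t test: t = {t:.2f}, df = {df}, P = {p:.4f}")
# Decision support raises both inter-reader agreement and agreement with the
# expert consensus; the paired t test quantifies the per-reader improvement.
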