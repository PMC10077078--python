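"""Curate a cohort: QC filters, keyword retention, consensus, 90/5/5 split.

Each exclusion is logged with its first failing rule; the split keeps
patients whole and preserves label/sex/view frequencies.
"""

import pandas as pd

import ngtlife as ng

manifest = ng.generate_manifest(ng.SynthConfig(n_images=800, seed=11))

kept, exclusions = ng.qc_filter(manifest)
print(f"QC: kept {len(kept)}/{len(manifest)}; "
      f"exclusion rules: {pd.Series([e['rule'] for e in exclusions]).value_counts().to_dict() if exclusions else {}}")

kept = ng.keyword_filter(kept)
print(f"keyword retention: {len(kept)} records mention tube keywords")

consensus = ng.consensus_labels(kept)
print(f"consensus: {consensus.notna().sum()} with majority, "
      f"{consensus.isna().sum()} three-way ties")

split = ng.grouped_stratified_split(kept, seed=11)
print("realized fractions:", {k: round(v, 3) for k, v in split.fractions.items()})
print("patient-disjoint:", len(split.multi_strata_patients), "patients spanned strata")
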