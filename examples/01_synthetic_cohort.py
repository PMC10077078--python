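"""Generate a synthetic chest-radiograph cohort and render one image.

Builds a 500-record manifest with the default class mix (satisfactory :
malpositioned : bronchial = 4100 : 2500 : 481), renders one radiograph
stand-in per class, and reports where the planted tube tip landed.
"""

import ngtlife as ng

cfg = ng.SynthConfig(n_images=500, seed=7)
manifest = ng.generate_manifest(cfg)

print("cohort size:", len(manifest))
print("class counts:", manifest["label"].value_counts().to_dict())
print("patients:", manifest["patient_id"].nunique())
print("manufacturers:", manifest["manufacturer"].value_counts().to_dict())

for label in ng.CLASSES:
    rec = manifest[manifest["label"] == label].iloc[0]
    img = ng.render_image(rec, cfg)
    r0, r1, c0, c1 = ng.tip_region(label, cfg.image_size)
    print(f"{label:14s} tip at {img.tip_xy} inside rows [{r0},{r1}) cols [{c0},{c1})"
          f"  pixel range [{img.pixels.min()}, {img.pixels.max()}]")

# The tip region encodes the class: lower 'stomach' box for satisfactory,
# mid-esophagus band for malpositioned, lateral branch for bronchial.
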