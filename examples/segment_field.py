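"""Segment one synthetic crop-field scene and inspect the threshold report.

Builds a 30%-canopy scene (soil hue ~40 deg, vegetation hue ~110 deg),
runs the hue-histogram threshold detection and prints every candidate
threshold with the final combined value and pixel accuracy.
"""

from hueseg import FieldSpec, generate, pixel_accuracy, segment_image

scene = generate(FieldSpec(height=256, width=256, veg_fraction=0.3, seed=42))
mask, report = segment_image(scene.image)

print(f"image case: {report.case.value} "
      f"(dominant {report.dominant.dominant_class}, "
      f"search {report.dominant.direction.value})")
for name, value in report.candidates.items():
    print(f"  {name}: {'absent' if value is None else f'{value:.1f} deg'}")
print(f"final threshold: {report.final_threshold:.1f} deg "
      "(mean of the detected candidates)")
print(f"pixel accuracy vs exact ground truth: "
      f"{pixel_accuracy(mask, scene.truth):.2f} %")
# The final threshold sits between the soil mode (40 deg) and the
# vegetation mode (110 deg): every hue above it is labelled vegetation.
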