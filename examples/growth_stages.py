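"""How the image case and candidate set change with canopy cover.

Sparse early growth leaves soil dominant (cases 1/3, search toward
higher hue); a closed canopy makes vegetation dominant (cases 2/4,
search toward lower hue). Single-class scenes fall back to the
one-peak cases where only the confidence-interval candidate exists.
"""

from hueseg import FieldSpec, generate, segment_image

for frac in (0.0, 0.1, 0.5, 0.9, 1.0):
    scene = generate(FieldSpec(height=256, width=256, veg_fraction=frac, seed=7))
    mask, report = segment_image(scene.image)
    present = [k for k, v in report.candidates.items() if v is not None]
    print(f"cover {frac:.0%}: {report.case.value}, "
          f"search {report.dominant.direction.value}, "
          f"candidates {present}, final {report.final_threshold:.1f} deg")
# case1/2 = one hue peak, case3/4 = two; odd cases mean soil dominates.
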