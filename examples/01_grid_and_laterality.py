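"""Assign retinal points to the modified ETDRS grid of one fundus frame.

Builds a 1440x960, 45-degree macula-centered frame, infers eye laterality
from the optic-disc position, and labels a handful of points.  The printed
labels show the temporal/nasal flip between a right and a left eye.
"""

from drquad import FundusFrame, assign_region

right = FundusFrame("right-eye", 1440, 960, 720, 480, 1220, 450)
left = FundusFrame("left-eye", 1440, 960, 720, 480, 220, 450)
print(f"scale: {right.um_per_px:.1f} um/px; laterality: {right.laterality.value} / {left.laterality.value}")

points = {
    "fovea": (720, 480),
    "2000 um above fovea": (720, 480 - 2000 / 9),
    "2000 um left of fovea": (720 - 2000 / 9, 480),
    "image corner": (5, 5),
}
for name, (x, y) in points.items():
    print(
        f"{name:>22}: right eye -> {assign_region(x, y, right).value:13s}"
        f" left eye -> {assign_region(x, y, left).value}"
    )
print("The same image-left point is temporal in a right eye but nasal in a left eye;")
print("points within 750 um of the fovea fall in the central ring, never a quadrant.")
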