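"""Rule-based DR grading from whole-image lesion counts.

Prints the grade for the boundary count combinations of the MESSIDOR scale:
muA microaneurysms, H hemorrhages, and the neovascularization flag NV.
"""

from drquad import grade_from_counts

cases = [(0, 0, 0), (5, 0, 0), (6, 0, 0), (2, 3, 0), (15, 0, 0), (0, 5, 0), (1, 0, 1)]
print(" muA   H  NV  -> level label")
for mu_a, h, nv in cases:
    g = grade_from_counts(mu_a, h, nv)
    print(f"{mu_a:4d} {h:3d} {nv:3d}  -> {g.level:5d} {g.label}")
print("Severity is monotone in both counts; NV=1 alone forces Severe (level 3).")
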