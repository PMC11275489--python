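"""Audit a published quadrant-comparison t table from its summary statistics.

Severe-DR per-quadrant lesion counts are reported as mean +/- SD over n=261
images per quadrant group.  A two-sample t-test needs nothing more, so the
printed t-values can be recomputed (and checked) directly from the table.
"""

from drquad import SummaryStats, t_from_summary

N = 261
severe = {
    "MA": {"temporal": (5.50, 6.52), "nasal": (1.86, 2.22), "superior": (2.47, 2.80), "inferior": (3.10, 3.23)},
    "HEM": {"temporal": (4.98, 6.55), "nasal": (1.96, 2.66), "superior": (2.08, 3.44), "inferior": (2.18, 3.22)},
}

print("severe-DR stratum, temporal quadrant vs the rest (Welch t, n=261/group):")
for lesion, table in severe.items():
    ref = SummaryStats(N, *table["temporal"])
    for other in ("nasal", "superior", "inferior"):
        res = t_from_summary(ref, SummaryStats(N, *table[other]))
        print(f"  {lesion:3s} temporal vs {other:8s}: t = {res.t:5.2f}  (df = {res.df:5.1f}, p = {res.p:.2e})")
print("Every comparison exceeds |t| ~ 5: the temporal quadrant carries a clear excess")
print("of both lesion types in severe disease.")
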