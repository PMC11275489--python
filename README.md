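# drquad

Quadrant-wise analysis of diabetic-retinopathy (DR) lesions on fundus
photographs: assignment of microaneurysms (MA) and hemorrhages (HEM) to the
quadrants of a **modified ETDRS grid**, rule-based **MESSIDOR severity
grading**, and the **cohort statistics** (per-grade per-quadrant summaries,
ANOVA, pairwise t-tests) that quantify where in the retina the lesions
concentrate.

The package is aimed at retinal-image-analysis researchers who need a
tested, fully reproducible implementation of this spatial-counting pipeline
without access to proprietary image cohorts or trained segmentation
weights: a calibrated synthetic cohort generator and a classical stand-in
lesion detector make every stage exercisable end to end.

## The model

**Grid.** The ETDRS macular grid is reduced to its central ring (1500 µm
diameter, centered on the fovea) and its four diagonal quadrants, extended
to the periphery of the 45° field. A point at angle θ from the fovea
(measuring counter-clockwise from the horizontal, "up" positive) falls in
the superior wedge for θ ∈ [45°, 135°), inferior for θ ∈ [225°, 315°), and
in the two horizontal wedges otherwise — labeled *temporal*/*nasal* by eye
laterality, which is inferred from the optic-disc side (the disc is nasal
to the fovea). Scale: 1° of field ≈ 288 µm of retina, so a 1440 px / 45°
image has 9 µm/px.

**Grading.** With μA = whole-image microaneurysm count, H = hemorrhage
count, NV ∈ {0,1} the neovascularization flag:

| level | label | rule |
|---|---|---|
| 0 | NoDR | μA = 0 and H = 0 |
| 1 | Mild | 0 < μA ≤ 5 and H = 0 |
| 2 | Moderate | (5 < μA < 15 or 0 < H < 5) and NV = 0 |
| 3 | Severe | μA ≥ 15 or H ≥ 5 or NV = 1 |

evaluated most-severe first (the clauses overlap at boundaries).

**Statistics.** Per (lesion, grade, quadrant) cell: n, mean, SD, SEM.
Quadrant count groups are compared as independent samples with the
two-sample t (Welch by default; with equal n the t value equals the pooled
one) — computable from raw counts *or* from printed summary statistics,
t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂) — and with one-way ANOVA,
F = MS_between/MS_within, across quadrants or grades.

**Synthetic cohorts.** Per-image quadrant counts are drawn from a negative
binomial moment-matched to a cell's (mean, SD) when SD² > mean (every
severe-DR cell is overdispersed), else Poisson(mean). Lesions are placed
uniformly in their target wedge, outside the central ring, inside the
field, clear of the disc. Two presets mirror screening-cohort structure
(`messidor`: 182/162/261 mild/moderate/severe images; `miradataset`:
300/grade).

## Worked example

Auditing a published-style severe-DR t table from its summary statistics
alone (`python examples/03_published_table_audit.py`):

```
severe-DR stratum, temporal quadrant vs the rest (Welch t, n=261/group):
  MA  temporal vs nasal   : t =  8.54  (df = 319.5, p = 5.63e-16)
  MA  temporal vs superior: t =  6.90  (df = 352.7, p = 2.44e-11)
  MA  temporal vs inferior: t =  5.33  (df = 380.4, p = 1.70e-07)
  ...
```

Simulating a calibrated severe stratum and recovering its quadrant
structure through the full pipeline
(`python examples/04_simulated_cohort_report.py`):

```
simulated severe stratum, n = 261 images; microaneurysm counts:
  superior : 2.43 +/- 2.61  (SEM 0.161)
  temporal : 5.31 +/- 5.57  (SEM 0.345)
  nasal    : 1.82 +/- 2.19  (SEM 0.136)
  inferior : 3.35 +/- 3.50  (SEM 0.217)
ANOVA across quadrants: F = 44.4, p = 5.61e-27
```

The temporal mean 5.31 recovers the generating value 5.50 within sampling
error (3·SEM ≈ 1.2), and the across-quadrant ANOVA is significant far below
p = 0.001 — the temporal quadrant carries the lesion excess. The other
examples cover grid assignment and laterality (`01`), the grading rules
(`02`), and the render→detect round trip (`05`).

A thin CLI mirrors the stages:

```bash
drquad simulate --preset messidor --strata Severe --seed 7 --out out/
drquad count --frames out/frames.json --marks out/marks.csv --out out/counts.csv
drquad grade --counts out/counts.csv --out out/grades.csv
drquad stats --counts out/counts.csv --grades out/grades.csv --out out/report
```

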