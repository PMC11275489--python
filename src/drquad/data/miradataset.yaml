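# MIRADATASET cohort preset: 300 images randomly sampled per graded stratum,
# with per-quadrant lesion-count calibration (mean, sd) per lesion type.
name: miradataset
strata:
  Mild:
    level: 1
    n: 300
    rates:
      MA:  {superior: [1.65, 1.10], temporal: [1.18, 1.51], nasal: [1.86, 1.16], inferior: [1.01, 1.25]}
      HEM: {superior: [1.34, 0.76], temporal: [1.39, 0.80], nasal: [1.24, 0.56], inferior: [1.29, 0.64]}
  Moderate:
    level: 2
    n: 300
    rates:
      MA:  {superior: [1.04, 1.33], temporal: [2.23, 2.85], nasal: [1.47, 1.72], inferior: [1.76, 2.05]}
      HEM: {superior: [1.52, 0.85], temporal: [1.76, 1.25], nasal: [1.55, 0.88], inferior: [1.45, 0.85]}
  Severe:
    level: 3
    n: 300
    rates:
      MA:  {superior: [4.72, 4.19], temporal: [7.51, 7.72], nasal: [5.16, 4.78], inferior: [7.46, 7.67]}
      HEM: {superior: [2.28, 3.25], temporal: [3.13, 4.81], nasal: [2.47, 3.79], inferior: [3.19, 5.30]}
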