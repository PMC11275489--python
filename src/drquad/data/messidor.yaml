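# MESSIDOR cohort preset: per-grade image counts and per-quadrant lesion-count
# calibration (mean, sd) for microaneurysms (MA) and hemorrhages (HEM).
# Graded strata only; lesion-free (level 0) images carry no count signal.
name: messidor
strata:
  Mild:
    level: 1
    n: 182
    rates:
      MA:  {superior: [1.25, 0.71], temporal: [1.01, 1.08], nasal: [0.38, 0.62], inferior: [0.86, 0.92]}
      HEM: {superior: [1.07, 0.27], temporal: [1.53, 0.77], nasal: [1.12, 0.48], inferior: [1.17, 0.64]}
  Moderate:
    level: 2
    n: 162
    rates:
      MA:  {superior: [1.64, 0.92], temporal: [1.50, 2.07], nasal: [0.65, 1.13], inferior: [1.01, 1.27]}
      HEM: {superior: [1.26, 0.50], temporal: [1.69, 0.98], nasal: [1.29, 0.55], inferior: [1.31, 0.58]}
  Severe:
    level: 3
    n: 261
    rates:
      MA:  {superior: [2.47, 2.80], temporal: [5.50, 6.52], nasal: [1.86, 2.22], inferior: [3.10, 3.23]}
      HEM: {superior: [2.08, 3.44], temporal: [4.98, 6.55], nasal: [1.96, 2.66], inferior: [2.18, 3.22]}
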