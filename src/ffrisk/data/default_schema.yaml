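# Default cohort feature schema: one entry per model feature with its kind
# and the closed numeric range observed in the study cohort (soft bounds for
# validation). Lesion features hold a stenosis percentage after translation.
features:
  - {name: Smoker, kind: binary, min: 0, max: 1}
  - {name: Gender, kind: binary, min: 0, max: 1}
  - {name: Age, kind: numeric, min: 36, max: 73}
  - {name: CK, kind: numeric, min: 61, max: 3353}
  - {name: CKMB, kind: numeric, min: 11, max: 324}
  - {name: AST, kind: numeric, min: 12, max: 348}
  - {name: LDH, kind: numeric, min: 210, max: 2557}
  - {name: Troponin, kind: numeric, min: 0.0124, max: 58.96}
  - {name: pBNP, kind: numeric, min: 48.1, max: 32700.0}
  - {name: CRP, kind: numeric, min: 3.3, max: 122.6}
  - {name: Leukocyte, kind: numeric, min: 7.1, max: 18.61}
  - {name: Glucose, kind: numeric, min: 4.7, max: 16.3}
  - {name: Urea, kind: numeric, min: 5.0, max: 23.2}
  - {name: Creatinine, kind: numeric, min: 59.0, max: 1447.0}
  - {name: Ac. uricum, kind: numeric, min: 204.0, max: 532.0}
  - {name: Cholesterol, kind: numeric, min: 3.33, max: 7.4}
  - {name: Trig, kind: numeric, min: 0.88, max: 8.3}
  - {name: HDL, kind: numeric, min: 0.7, max: 2.07}
  - {name: LDL, kind: numeric, min: 2.57, max: 5.88}
  - {name: Atherosclerosis index, kind: numeric, min: 3.23, max: 6.17}
  - {name: Cholesterol/HDL, kind: numeric, min: 3.28, max: 9.43}
  - {name: LAD, kind: descriptive_lesion, min: 0, max: 100}
  - {name: LCx, kind: descriptive_lesion, min: 0, max: 100}
  - {name: RCA, kind: descriptive_lesion, min: 0, max: 100}
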