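# Default generator parameters: the four sex-by-status groups of the study
# cohort.  Analyte entries are [mean, sem] in rotor units; per-group SD is
# reconstructed in code as SEM * sqrt(n).  GLOB is never drawn — it is
# derived per fish as TP - ALB (the analyzer's own rule) and its printed
# group values (1.8/1.5/1.8/1.3 g/dL) follow from the TP and ALB entries.
# BA is not printed in the source table (it was excluded from
# interpretation); its entries here are a synthetic choice inside the
# 35-200 umol/L rotor range, documented in docs/methods.md.  UA is absent:
# it was never detected in this species.
# Morphometric means: ages and the healthy/diseased average lengths and
# weights are printed; the per-sex length split is chosen to satisfy every
# printed anchor (males longer, diseased males +10% / females +6%).
# Morphometric SDs default to 10% of the mean (set in code).
groups:
  male_healthy:
    sex: male
    status: healthy
    n: 9
    analytes:
      AST: [75, 22]
      CK: [1258, 500]
      GLU: [43, 7]
      Ca: [14.5, 0.2]
      PHOS: [8.0, 0.4]
      TP: [3.9, 0.1]
      ALB: [2.1, 0.1]
      K: [4.3, 0.2]
      Na: [172, 2]
      BA: [60, 6.7]
    morpho:
      age: 5.5
      total_length: 41.0
      weight: 1.5
  male_diseased:
    sex: male
    status: diseased
    n: 10
    analytes:
      AST: [64, 18]
      CK: [2123, 450]
      GLU: [32, 2]
      Ca: [12.2, 0.3]
      PHOS: [5.1, 0.3]
      TP: [3.1, 0.1]
      ALB: [1.6, 0.1]
      K: [4.1, 0.2]
      Na: [162, 3]
      BA: [60, 6.3]
    morpho:
      age: 7.5
      total_length: 45.1
      weight: 2.0
  female_healthy:
    sex: female
    status: healthy
    n: 9
    analytes:
      AST: [115, 47]
      CK: [2203, 680]
      GLU: [34, 2]
      Ca: [15.9, 0.6]
      PHOS: [7.6, 0.5]
      TP: [4.0, 0.2]
      ALB: [2.2, 0.1]
      K: [4.4, 0.3]
      Na: [170, 2]
      BA: [60, 6.7]
    morpho:
      age: 6.4
      total_length: 37.8
      weight: 1.3
  female_diseased:
    sex: female
    status: diseased
    n: 11
    analytes:
      AST: [61, 15]
      CK: [2079, 420]
      GLU: [36, 4]
      Ca: [14.8, 0.7]
      PHOS: [6.4, 0.4]
      TP: [3.3, 0.1]
      ALB: [2.0, 0.1]
      K: [4.1, 0.1]
      Na: [166, 3]
      BA: [60, 6.0]
    morpho:
      age: 9.6
      total_length: 40.1
      weight: 1.5
correlation:
  - [TP, ALB, 0.3]
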