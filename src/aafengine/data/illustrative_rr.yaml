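# ILLUSTRATIVE relative-risk registry — NOT a published meta-analysis.
#
# Coefficients are on the log-RR scale: constant -> RR = exp(b0);
# log-linear -> RR(x) = exp(b1*x); log-quadratic -> RR(x) = exp(b1*x + b2*x^2),
# with x in grams of pure alcohol per day.  Magnitudes are chosen to be
# plausible for the comparative-risk literature (steep monotone risk for
# liver cirrhosis, a J-shaped curve for ischemic disease among non-heavy
# drinkers that vanishes under heavy episodic drinking, steeper injury risk
# under heavy episodic drinking) so the pipeline runs out of the box.
# Substitute published coefficient tables before any substantive use; the
# schema is documented in the README.
causes:
  alcohol_use_disorders:
    icd10: [F10, X45, T51]
    attribution: fully_attributable
    hed_stratified: false
    functions: []
  liver_cirrhosis:
    icd10: [K70, K74]
    attribution: partially_attributable
    hed_stratified: false
    functions:
      - {sex: all, age_group: all, group: former, form: constant,
         beta: [0.262364], cov: [[0.0036]], max_dose: 150.0}
      - {sex: male, age_group: all, group: current, form: log-linear,
         beta: [0.0195], cov: [[4.0e-06]], max_dose: 150.0}
      - {sex: female, age_group: all, group: current, form: log-linear,
         beta: [0.0220], cov: [[6.25e-06]], max_dose: 150.0}
  ischemic_heart_disease:
    icd10: [I20-I25]
    attribution: partially_attributable
    hed_stratified: true
    functions:
      - {sex: all, age_group: all, group: former, form: constant,
         beta: [0.139762], cov: [[0.0025]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_non_hed, form: log-quadratic,
         beta: [-0.0075, 9.0e-05],
         cov: [[2.25e-06, -2.1e-08], [-2.1e-08, 4.0e-10]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_hed, form: log-linear,
         beta: [0.0035], cov: [[1.0e-06]], max_dose: 150.0}
  ischemic_stroke:
    icd10: [I63]
    attribution: partially_attributable
    hed_stratified: true
    functions:
      - {sex: all, age_group: all, group: former, form: constant,
         beta: [0.095310], cov: [[0.0025]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_non_hed, form: log-quadratic,
         beta: [-0.0040, 6.0e-05],
         cov: [[1.0e-06, -1.0e-08], [-1.0e-08, 2.5e-10]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_hed, form: log-linear,
         beta: [0.0040], cov: [[1.0e-06]], max_dose: 150.0}
  motor_vehicle_accidents:
    icd10: [V01-V89]
    attribution: partially_attributable
    hed_stratified: true
    functions:
      - {sex: all, age_group: all, group: former, form: constant,
         beta: [0.0], cov: [[0.0025]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_non_hed, form: log-linear,
         beta: [0.0060], cov: [[1.44e-06]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_hed, form: log-linear,
         beta: [0.0120], cov: [[4.0e-06]], max_dose: 150.0}
  other_injuries:
    icd10: [W00-W19, X60-X84]
    attribution: partially_attributable
    hed_stratified: true
    functions:
      - {sex: all, age_group: all, group: former, form: constant,
         beta: [0.0], cov: [[0.0025]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_non_hed, form: log-linear,
         beta: [0.0070], cov: [[1.96e-06]], max_dose: 150.0}
      - {sex: all, age_group: all, group: current_hed, form: log-linear,
         beta: [0.0130], cov: [[4.84e-06]], max_dose: 150.0}
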