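{
  "case_id": "toy_mi",
  "correct_diagnosis": "MI",
  "appropriate_diagnoses": ["MI", "unstable angina", "PE", "GERD"],
  "dxj_labels": [
    {"datum_id": "hx_pain", "diagnosis": "MI", "label": "required_increase"},
    {"datum_id": "hx_risk", "diagnosis": "MI", "label": "required_increase"},
    {"datum_id": "px_distress", "diagnosis": "MI", "label": "required_increase"},
    {"datum_id": "troponin", "diagnosis": "MI", "label": "required_increase"},
    {"datum_id": "ecg", "diagnosis": "MI", "label": "required_increase"},
    {"datum_id": "hx_pain", "diagnosis": "unstable angina", "label": "required_increase"},
    {"datum_id": "troponin", "diagnosis": "unstable angina", "label": "required_decrease"},
    {"datum_id": "px_legs", "diagnosis": "PE", "label": "required_decrease"},
    {"datum_id": "ddimer", "diagnosis": "PE", "label": "required_decrease"},
    {"datum_id": "hx_no_reflux", "diagnosis": "GERD", "label": "required_decrease"},
    {"datum_id": "hx_pain", "diagnosis": "GERD", "label": "wrong"},
    {"datum_id": "px_no_tender", "diagnosis": "MI", "label": "neutral"},
    {"datum_id": "hx_diaphoresis", "diagnosis": "MI", "label": "required_increase"},
    {"datum_id": "px_vitals", "diagnosis": "PE", "label": "required_increase"}
  ],
  "test_labels": {
    "ecg": "required",
    "troponin": "required",
    "ddimer": "required",
    "cxr": "neutral",
    "ct_head": "inappropriate",
    "abd_us": "inappropriate"
  },
  "second_choice_credit": 0.5,
  "wrong_assignment_deduction": 0.5,
  "max_tests_threshold": "auto",
  "max_rounds_threshold": "auto",
  "penalty_weights": {
    "excess_tests": 1.0,
    "excess_rounds": 1.0,
    "unused_result": 0.5,
    "inappropriate_test": 0.5
  }
}
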