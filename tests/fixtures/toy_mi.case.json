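{
  "case_id": "toy_mi",
  "intro": "A 58-year-old man presents to the emergency department with chest pain.",
  "findings": [
    {"finding_id": "hx_pain", "stage": "history", "text": "Crushing retrosternal chest pain radiating to the left arm for 40 minutes"},
    {"finding_id": "hx_diaphoresis", "stage": "history", "text": "Associated diaphoresis and nausea"},
    {"finding_id": "hx_risk", "stage": "history", "text": "Smoker with hypertension and hyperlipidemia"},
    {"finding_id": "hx_no_reflux", "stage": "history", "text": "No relation of pain to meals or position; no acid brash"},
    {"finding_id": "px_distress", "stage": "physical", "text": "Pale, diaphoretic, clutching chest"},
    {"finding_id": "px_vitals", "stage": "physical", "text": "BP 148/92, HR 104, SpO2 97% on room air"},
    {"finding_id": "px_no_tender", "stage": "physical", "text": "Chest wall non-tender to palpation"},
    {"finding_id": "px_legs", "stage": "physical", "text": "No calf swelling or tenderness"}
  ],
  "tests": [
    {"test_id": "ecg", "name": "Electrocardiogram", "synonyms": ["ECG", "EKG", "12-lead"], "result": "ST elevation in leads II, III, aVF"},
    {"test_id": "troponin", "name": "Troponin I", "synonyms": ["troponin", "cardiac enzymes"], "result": "Elevated at 2.3 ng/mL"},
    {"test_id": "ddimer", "name": "D-dimer", "synonyms": ["d dimer"], "result": "Within normal limits"},
    {"test_id": "cxr", "name": "Chest X-ray", "synonyms": ["CXR", "chest radiograph"], "result": "Clear lung fields, normal cardiac silhouette"},
    {"test_id": "ct_head", "name": "CT head", "synonyms": ["head CT"], "result": "No acute intracranial abnormality"},
    {"test_id": "abd_us", "name": "Abdominal ultrasound", "synonyms": ["abdo ultrasound"], "result": "Unremarkable"}
  ],
  "correct_diagnosis": "MI",
  "diagnosis_lexicon": {
    "MI": ["myocardial infarction", "heart attack", "STEMI"],
    "unstable angina": ["UA", "acute coronary syndrome"],
    "PE": ["pulmonary embolism", "pulmonary embolus"],
    "GERD": ["reflux", "gastroesophageal reflux disease"],
    "costochondritis": ["chest wall pain", "musculoskeletal chest pain"]
  }
}
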