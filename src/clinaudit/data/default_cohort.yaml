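# Default synthetic-cohort configuration emulating the pulmonary-screening
# case-study composition: 303 patients (171 male / 132 female), seven disease
# subgroups, ~55% male smokers and no female smokers, and an SES-smoking
# gradient (high-SES mostly non-smokers, low-SES roughly half smokers).
n_male: 171
n_female: 132
disease_counts:
  AR: 26
  Asthma: 48
  Asthma+AR: 54
  COPD: 36
  COPD+AR: 11
  Healthy: 87
  Other: 41
smoking_rate_by_gender:
  male: 0.55
  female: 0.0
ses_split: 0.5          # fraction of the cohort assigned low SES
smoking_rate_by_ses:    # qualitative targets, reconciled with gender quotas
  low: 0.5
  high: 0.1
smoking_copd_weight: 3.0   # log-odds increment for COPD assignment per smoker
peak_flow_cuts: [0.8, 0.5]
peak_flow_params:          # fraction-of-predicted-normal, per disease category
  AR:        {mean: 0.88, sd: 0.10}
  Asthma:    {mean: 0.72, sd: 0.14}
  Asthma+AR: {mean: 0.70, sd: 0.14}
  COPD:      {mean: 0.58, sd: 0.15}
  COPD+AR:   {mean: 0.56, sd: 0.15}
  Healthy:   {mean: 0.90, sd: 0.12}
  Other:     {mean: 0.80, sd: 0.15}
# Per-category Bernoulli emission probabilities for the 10-item symptom panel.
# Chosen so baseline models are learnable but imperfect: obstructive symptoms
# load on Asthma/COPD, upper-airway symptoms on AR, comorbid categories carry
# both, healthy controls have low background rates.
symptom_emission:
  AR:
    wheeze: 0.15
    chronic_cough: 0.20
    dyspnea: 0.15
    sputum: 0.10
    chest_tightness: 0.10
    nasal_congestion: 0.85
    sneezing: 0.80
    itchy_eyes: 0.70
    nocturnal_symptoms: 0.20
    fever: 0.05
  Asthma:
    wheeze: 0.75
    chronic_cough: 0.45
    dyspnea: 0.65
    sputum: 0.35
    chest_tightness: 0.60
    nasal_congestion: 0.20
    sneezing: 0.15
    itchy_eyes: 0.10
    nocturnal_symptoms: 0.55
    fever: 0.05
  Asthma+AR:
    wheeze: 0.80
    chronic_cough: 0.50
    dyspnea: 0.65
    sputum: 0.35
    chest_tightness: 0.60
    nasal_congestion: 0.80
    sneezing: 0.75
    itchy_eyes: 0.60
    nocturnal_symptoms: 0.55
    fever: 0.05
  COPD:
    wheeze: 0.60
    chronic_cough: 0.80
    dyspnea: 0.75
    sputum: 0.70
    chest_tightness: 0.45
    nasal_congestion: 0.10
    sneezing: 0.10
    itchy_eyes: 0.05
    nocturnal_symptoms: 0.35
    fever: 0.10
  COPD+AR:
    wheeze: 0.65
    chronic_cough: 0.80
    dyspnea: 0.75
    sputum: 0.70
    chest_tightness: 0.45
    nasal_congestion: 0.55
    sneezing: 0.50
    itchy_eyes: 0.40
    nocturnal_symptoms: 0.35
    fever: 0.10
  Healthy:
    wheeze: 0.05
    chronic_cough: 0.05
    dyspnea: 0.08
    sputum: 0.05
    chest_tightness: 0.05
    nasal_congestion: 0.10
    sneezing: 0.10
    itchy_eyes: 0.08
    nocturnal_symptoms: 0.05
    fever: 0.03
  Other:
    wheeze: 0.30
    chronic_cough: 0.35
    dyspnea: 0.40
    sputum: 0.30
    chest_tightness: 0.25
    nasal_congestion: 0.20
    sneezing: 0.15
    itchy_eyes: 0.10
    nocturnal_symptoms: 0.20
    fever: 0.30
seed: 20210415
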