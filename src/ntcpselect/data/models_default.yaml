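# Default 16-model NTCP registry for nasopharyngeal-carcinoma plan comparison.
#
# Structural content (organs, endpoints, CTS weights, MBS membership and
# thresholds, evidence levels, reference keys) is fixed.  Weights sum to
# unity; the seven MBS members carry standard and young per-endpoint
# thresholds in percentage points of delta-NTCP (photon minus proton).
#
# The dose-response PARAMETER VALUES below are representative defaults chosen
# to give clinically plausible complication probabilities at typical
# head-and-neck organ-at-risk dose levels.  For clinical use, transcribe the
# published parameter values from the publication named in each entry's
# `reference` key.
#
# Forms:
#   lkb_probit             NTCP = Phi((S - td50) / (m * td50))
#   logistic_linear        NTCP = 1 / (1 + exp(-(intercept + sum coef_i * x_i)))
#   loglogistic_d50_gamma  NTCP = 1 / (1 + (d50 / S)^(4 * gamma50))
# where S is the dose summary (mean_dose, geud with volume-effect parameter a,
# or d1 = dose to the hottest 1% of the volume, used as near-maximum dose).

models:
  - id: brain_necrosis_niyazi2020
    reference: Niyazi2020
    organ: brain
    endpoint: "Brain necrosis > grade II (2 years)"
    form: lkb_probit
    dose_summary: {metric: d1}
    parameters: {td50: 66.0, m: 0.18}
    evidence_level: 3
    mbs_member: true
    threshold_standard: 10.0
    threshold_young: 5.0
    cts_weight: 0.1

  - id: temporal_lobe_infarction_kong2016
    reference: Kong2016
    organ: temporal_lobe
    endpoint: "Temporal lobe infarction (>3 months)"
    form: lkb_probit
    dose_summary: {metric: d1}
    parameters: {td50: 95.0, m: 0.10}
    evidence_level: 4
    cts_weight: 0.1

  - id: rion_palorini2019
    reference: Palorini2019
    organ: optic_pathways
    endpoint: "Radiation-induced ocular toxicity, RION (>3 months)"
    form: lkb_probit
    dose_summary: {metric: d1}
    parameters: {td50: 70.0, m: 0.08}
    evidence_level: 3
    mbs_member: true
    threshold_standard: 5.0
    threshold_young: 3.0
    cts_weight: 0.07

  - id: visual_loss_palorini2019
    reference: Palorini2019
    organ: optic_pathways
    endpoint: "Grade IV visual acuity loss (>3 months)"
    form: lkb_probit
    dose_summary: {metric: d1}
    parameters: {td50: 75.0, m: 0.08}
    evidence_level: 3
    mbs_member: true
    threshold_standard: 5.0
    threshold_young: 3.0
    cts_weight: 0.07

  - id: glottic_edema_rancati2009
    reference: Rancati2009
    organ: glottic_larynx
    endpoint: "Laryngeal edema grade II (15 months)"
    form: lkb_probit
    dose_summary: {metric: geud, a: 2.22}
    parameters: {td50: 46.3, m: 0.73}
    evidence_level: 4
    cts_weight: 0.005

  - id: aspiration_glottic_eisbruch2011
    reference: Eisbruch2011
    organ: glottic_larynx
    endpoint: "Aspiration (12 months)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -4.6
      terms:
        - {feature: mean_dose, coef: 0.060}
    evidence_level: 4
    cts_weight: 0.005

  - id: mucositis_bhide2012
    reference: Bhide2012
    organ: oral_cavity
    endpoint: "Acute mucositis (8 weeks)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -4.9
      terms:
        - {feature: mean_dose, coef: 0.090}
        - {feature: covariate, name: chemo, coef: 0.80}
    evidence_level: 4
    mbs_member: true
    threshold_standard: 10.0
    threshold_young: 10.0
    cts_weight: 0.05

  - id: aspiration_pcm_eisbruch2011
    reference: Eisbruch2011
    organ: pcm_superior
    endpoint: "Aspiration (12 months)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -5.0
      terms:
        - {feature: mean_dose, coef: 0.070}
    evidence_level: 4
    cts_weight: 0.005

  - id: dysphagia_loizeau2021
    reference: Loizeau2021
    organ: pcm_superior
    endpoint: "Grade II-IV dysphagia (6 months)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -4.2
      terms:
        - {feature: mean_dose, coef: 0.063}
    evidence_level: 3
    mbs_member: true
    threshold_standard: 5.0
    threshold_young: 3.0
    cts_weight: 0.2

  - id: swallow_solids_christianen2012
    reference: Christianen2012
    organ: pcm_superior
    endpoint: "Problems swallowing solids (6 months)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -6.7
      terms:
        - {feature: mean_dose, coef: 0.105}
    evidence_level: 3
    cts_weight: 0.005

  - id: swallow_liquids_christianen2012
    reference: Christianen2012
    organ: pcm_superior
    endpoint: "Problems swallowing liquids (6 months)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -7.2
      terms:
        - {feature: mean_dose, coef: 0.100}
    evidence_level: 3
    cts_weight: 0.005

  - id: xerostomia_loizeau2021
    reference: Loizeau2021
    organ: parotid
    endpoint: "Moderate-to-severe xerostomia (6 months)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -3.0
      terms:
        - {feature: mean_dose, coef: 0.100}
    evidence_level: 3
    mbs_member: true
    threshold_standard: 15.0
    threshold_young: 15.0
    cts_weight: 0.2

  - id: parotid_flow_roesink2001
    reference: Roesink2001
    organ: parotid
    endpoint: "Parotid flow ratio < 25% (1 year)"
    form: lkb_probit
    dose_summary: {metric: mean_dose}
    parameters: {td50: 39.0, m: 0.45}
    evidence_level: 4
    cts_weight: 0.005

  - id: tinnitus_lee2015
    reference: Lee2015
    organ: cochlea
    endpoint: "Tinnitus (2 years)"
    form: lkb_probit
    dose_summary: {metric: mean_dose}
    parameters: {td50: 46.0, m: 0.25}
    evidence_level: 4
    cts_weight: 0.01

  - id: trismus_lindblom2014
    reference: Lindblom2014
    organ: tmj
    endpoint: "Trismus, jaw opening < 35 mm (>3 months)"
    form: loglogistic_d50_gamma
    dose_summary: {metric: mean_dose}
    parameters: {d50: 55.0, gamma50: 1.2}
    evidence_level: 3
    mbs_member: true
    threshold_standard: 10.0
    threshold_young: 7.5
    cts_weight: 0.15

  - id: hypothyroidism_vogelius2011
    reference: Vogelius2011
    organ: thyroid
    endpoint: "Hypothyroidism (2 years)"
    form: logistic_linear
    dose_summary: {metric: mean_dose}
    parameters:
      intercept: -3.9
      terms:
        - {feature: mean_dose, coef: 0.075}
    evidence_level: 4
    cts_weight: 0.02
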