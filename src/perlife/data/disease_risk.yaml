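# Default disease-risk parameters (synthetic illustrative values).
#
# Prevalence curves mirror the synthetic cohort generator's logistic-in-age
# shapes; PARFs and relative-risk tables are plausible round numbers for the
# lifestyle exposures, supplied here as configuration: substitute
# literature-derived values for a real-data analysis.
#
# RR bin convention: `breaks` are left edges, last bin open-ended;
# exposure factors: bmi (kg/m^2), pa_met_min (MET-min/week),
# smoking_exposure (decayed, thousands of packs), diet_score (points).
diseases:
  diabetes:
    parf: 0.45
    prevalence:
      male:   {type: logistic, pmax: 0.25, age50: 62.0, scale: 12.0}
      female: {type: logistic, pmax: 0.25, age50: 62.0, scale: 12.0}
    rr:
      - {factor: bmi, breaks: [0.0, 25.0, 30.0, 35.0], rr: [1.0, 1.5, 3.0, 6.0]}
      - {factor: pa_met_min, breaks: [0.0, 1.0, 600.0], rr: [1.3, 1.1, 1.0]}
  irregular_pulse:
    parf: 0.15
    prevalence:
      male:   {type: logistic, pmax: 0.10, age50: 70.0, scale: 12.0}
      female: {type: logistic, pmax: 0.10, age50: 70.0, scale: 12.0}
    rr:
      - {factor: bmi, breaks: [0.0, 30.0], rr: [1.0, 1.4]}
  chd:
    parf: 0.40
    prevalence:
      male:   {type: logistic, pmax: 0.22, age50: 72.0, scale: 10.0}
      female: {type: logistic, pmax: 0.18, age50: 72.0, scale: 10.0}
    rr:
      - {factor: smoking_exposure, breaks: [0.0, 0.001, 5.0], rr: [1.0, 1.6, 2.2]}
      - {factor: bmi, breaks: [0.0, 25.0, 30.0], rr: [1.0, 1.3, 1.8]}
      - {factor: pa_met_min, breaks: [0.0, 1.0, 600.0], rr: [1.4, 1.2, 1.0]}
      - {factor: diet_score, breaks: [-100.0, 0.0, 10.0], rr: [1.3, 1.1, 1.0]}
  stroke:
    parf: 0.35
    prevalence:
      male:   {type: logistic, pmax: 0.12, age50: 72.0, scale: 10.0}
      female: {type: logistic, pmax: 0.12, age50: 72.0, scale: 10.0}
    rr:
      - {factor: smoking_exposure, breaks: [0.0, 0.001, 5.0], rr: [1.0, 1.5, 2.0]}
      - {factor: bmi, breaks: [0.0, 25.0, 30.0], rr: [1.0, 1.2, 1.5]}
  cancer:
    parf: 0.30
    prevalence:
      male:   {type: logistic, pmax: 0.12, age50: 75.0, scale: 9.0}
      female: {type: logistic, pmax: 0.12, age50: 75.0, scale: 9.0}
    rr:
      - {factor: smoking_exposure, breaks: [0.0, 0.001, 5.0, 15.0], rr: [1.0, 2.0, 4.0, 8.0]}
      - {factor: diet_score, breaks: [-100.0, 0.0], rr: [1.2, 1.0]}
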