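# Small end-to-end demo scenario (runs in a few seconds).
generator:
  per_year_counts: {2016: 400, 2017: 300, 2018: 300}
  symptom_prevalence:
    tremor: {2016: 0.556, 2017: 0.519, 2018: 0.527}
    stiffness: {2016: 0.253, 2017: 0.246, 2018: 0.295}
    difficulty_walking: {2016: 0.207, 2017: 0.192, 2018: 0.245}
    pain: {2016: 0.244, 2017: 0.252, 2018: 0.258}
    insomnia: {2016: 0.062, 2017: 0.063, 2018: 0.089}
    depression: {2016: 0.061, 2017: 0.070, 2018: 0.114}
    constipation: {2016: 0.079, 2017: 0.084, 2018: 0.121}
    dyskinesia: {2016: 0.020, 2017: 0.040, 2018: 0.060}
  typo_rate: 0.02
  double_negation_rate: 0.01
  demographic_rate: 0.19
  seed: 0
out_dir: results/demo
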