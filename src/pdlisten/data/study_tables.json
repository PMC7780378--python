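{
  "years": [2016, 2017, 2018],
  "included_dialogues": {"2016": 7524, "2017": 5198, "2018": 2397},
  "demographics": {
    "age_mean": 63.0,
    "age_sd": 13.4,
    "n_with_age": 2895,
    "bin_edges": [50, 60, 70],
    "bin_counts": {"<50": 405, "50-60": 586, "60-70": 957, ">70": 947}
  },
  "category_sov_pct": {
    "motor": {"2016": 79, "2017": 76, "2018": 79},
    "non_motor": {"2016": 62, "2017": 66, "2018": 69},
    "motor_complication": {"2016": 3, "2017": 6, "2018": 9}
  },
  "nocturnal_any_sov_pct": {"2016": 39, "2017": 41, "2018": 45},
  "nocturnal_any_cagr_pct": 6.0,
  "symptom_sov_pct": {
    "tremor": {"2016": 55.6, "2017": 51.9, "2018": 52.7, "cagr": -2.6},
    "stiffness": {"2016": 25.3, "2017": 24.6, "2018": 29.5, "cagr": 8.0},
    "turning_over": {"2016": 10.5, "2017": 11.6, "2018": 13.9, "cagr": 15.0},
    "difficulty_walking": {"2016": 20.7, "2017": 19.2, "2018": 24.5, "cagr": 8.9},
    "reduced_facial_expression": {"2016": 4.5, "2017": 3.0, "2018": 3.0, "cagr": -18.2},
    "unclear_enunciation": {"2016": 3.0, "2017": 2.2, "2018": 2.8, "cagr": -2.0},
    "speech_disorder": {"2016": 0.8, "2017": 0.7, "2018": 1.0, "cagr": 14.4},
    "falling": {"2016": 7.3, "2017": 7.8, "2018": 9.9, "cagr": 16.6},
    "gait_instability": {"2016": 1.6, "2017": 2.7, "2018": 5.1, "cagr": 79.3},
    "pain": {"2016": 24.4, "2017": 25.2, "2018": 25.8, "cagr": 2.9},
    "frequent_urination": {"2016": 7.5, "2017": 8.6, "2018": 11.8, "cagr": 25.8},
    "insomnia": {"2016": 6.2, "2017": 6.3, "2018": 8.9, "cagr": 20.0},
    "rbd": {"2016": 3.9, "2017": 5.1, "2018": 7.4, "cagr": 37.3},
    "poor_sleep_quality": {"2016": 5.4, "2017": 5.6, "2018": 5.7, "cagr": 2.4},
    "daytime_sleepiness": {"2016": 3.8, "2017": 4.1, "2018": 5.6, "cagr": 20.9},
    "numbness": {"2016": 4.9, "2017": 4.2, "2018": 5.0, "cagr": 1.4},
    "spasm": {"2016": 3.7, "2017": 3.8, "2018": 3.6, "cagr": -1.6},
    "olfactory_disorder": {"2016": 0.9, "2017": 1.0, "2018": 2.5, "cagr": 64.5},
    "depression": {"2016": 6.1, "2017": 7.0, "2018": 11.4, "cagr": 36.2},
    "hallucinations": {"2016": 7.2, "2017": 9.1, "2018": 10.0, "cagr": 18.1},
    "dementia": {"2016": 5.7, "2017": 6.3, "2018": 9.1, "cagr": 26.6},
    "anxiety": {"2016": 2.4, "2017": 3.3, "2018": 6.9, "cagr": 70.6},
    "slow_reaction": {"2016": 2.0, "2017": 2.0, "2018": 3.4, "cagr": 31.4},
    "psychiatric_other": {"2016": 1.2, "2017": 1.1, "2018": 1.3, "cagr": 4.7},
    "constipation": {"2016": 7.9, "2017": 8.4, "2018": 12.1, "cagr": 23.9},
    "gastrointestinal": {"2016": 6.8, "2017": 8.3, "2018": 8.1, "cagr": 9.5},
    "drooling": {"2016": 4.9, "2017": 4.8, "2018": 5.9, "cagr": 9.6}
  },
  "nocturnal_symptom_sov_pct": {
    "rigidity_turning_over": {"2016": 11.9, "2017": 12.8, "2018": 16.0, "cagr": 16.0},
    "insomnia": {"2016": 6.2, "2017": 6.3, "2018": 8.9, "cagr": 20.0},
    "night_tremor": {"2016": 7.0, "2017": 6.8, "2018": 8.7, "cagr": 11.2},
    "rbd": {"2016": 3.9, "2017": 5.1, "2018": 7.4, "cagr": 37.3},
    "nocturnal_pain": {"2016": 5.3, "2017": 5.9, "2018": 7.3, "cagr": 17.3},
    "poor_sleep_quality": {"2016": 5.4, "2017": 5.6, "2018": 5.7, "cagr": 2.4},
    "daytime_sleepiness": {"2016": 3.8, "2017": 4.1, "2018": 5.6, "cagr": 20.9},
    "frequent_nocturia": {"2016": 2.9, "2017": 3.6, "2018": 5.3, "cagr": 35.6},
    "hallucinations": {"2016": 1.6, "2017": 2.1, "2018": 2.5, "cagr": 26.9},
    "morning_pain": {"2016": 0.6, "2017": 1.0, "2018": 1.4, "cagr": 51.0},
    "nocturnal_spasm": {"2016": 1.1, "2017": 1.0, "2018": 1.2, "cagr": 8.2},
    "difficulty_breathing": {"2016": 0.3, "2017": 0.5, "2018": 0.8, "cagr": 52.2}
  },
  "sentiment_scores_any_time": {
    "depression": 8.5, "anxiety": 7.4, "apathy": 5.0, "olfactory_disorder": 3.9,
    "restless_legs": 3.6, "pain": 3.5, "difficulty_breathing": 3.4, "immobility": 2.8,
    "hallucinations": 2.7, "daytime_sleepiness": 2.7, "turning_over": 2.6,
    "frequent_urination": 2.6, "spasm": 2.6, "falling": 2.3, "stiffness": 2.2,
    "tremor": 1.6
  },
  "sentiment_scores_nocturnal": {
    "morning_pain": 5.3, "fragmented_sleep": 4.8, "restless_legs": 4.4,
    "nocturnal_pain": 4.4, "difficulty_breathing": 4.4, "insomnia": 3.5,
    "poor_sleep_quality": 3.5, "hallucinations": 3.5, "nocturnal_spasm": 3.4,
    "frequent_nocturia": 3.2, "rbd": 3.1, "night_tremor": 2.8,
    "nocturnal_immobility_stiffness": 2.8, "daytime_sleepiness": 2.7
  }
}
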