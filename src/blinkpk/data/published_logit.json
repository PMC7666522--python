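{
  "version": 1,
  "description": "Published fitted binary logit for the probability of unresponsiveness (aRASS = -5) as a function of propofol Ce and the selected T1/T2 EMG features. Units are passed through as published.",
  "response": "log-odds of aRASS = -5",
  "intercept": -339.206,
  "coefficients": {
    "ce_ug_ml": 2.476,
    "v_mean_T1": -0.281,
    "f_mean_T1": -5.422,
    "f_median_T1": 3.234,
    "p_bandwidth_T1": 0.116,
    "spectral_entropy_T1": 1441.537,
    "f_mean_T2": 0.074,
    "spectral_entropy_T2": -38.100
  }
}
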