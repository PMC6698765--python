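{
  "breast_tumor": {
    "model": "poisson_lq_tcp",
    "d50": 30.89,
    "gamma": 1.3,
    "alpha_beta": 4.0,
    "a": -7.2,
    "citation": "Okunieff et al. radiation dose-response of human tumors; Niemierko EUD exponent for breast tumour"
  },
  "heart": {
    "model": "lkb_ntcp",
    "d50": 48.0,
    "m": 0.1,
    "n": 0.35,
    "alpha_beta": 3.0,
    "citation": "Gagliardi et al. cardiac mortality LKB fit; QUANTEC heart"
  },
  "lung_ipsilateral": {
    "model": "lkb_ntcp",
    "d50": 37.6,
    "m": 0.35,
    "n": 0.87,
    "alpha_beta": 3.0,
    "citation": "Burman/Emami LKB pneumonitis parameters"
  },
  "skin": {
    "model": "lkb_ntcp",
    "d50": 39.0,
    "m": 0.14,
    "n": 0.38,
    "alpha_beta": 3.0,
    "citation": "Pastore et al. acute skin toxicity LKB fit for breast radiotherapy"
  }
}
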