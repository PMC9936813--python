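[
 {"set": 0, "min_f": 3.1, "max_f": 4.6,
  "ge0": 0.00321429, "gi0": 0.01085714, "De": 0.00068571, "Di": 0.00214286},
 {"set": 1, "min_f": 4.6, "max_f": 6.8,
  "ge0": 0.00342857, "gi0": 0.01028571, "De": 0.00057143, "Di": 0.00214286},
 {"set": 2, "min_f": 6.5, "max_f": 9.3,
  "ge0": 0.00342857, "gi0": 0.01114286, "De": 0.0, "Di": 0.00428571},
 {"set": 3, "min_f": 8.3, "max_f": 10.9,
  "ge0": 0.00385714, "gi0": 0.01171429, "De": 0.0, "Di": 0.00428571},
 {"set": 4, "min_f": 10.4, "max_f": 13.0,
  "ge0": 0.00428571, "gi0": 0.01171429, "De": 0.00045714, "Di": 0.00357143},
 {"set": 5, "min_f": 11.8, "max_f": 15.2,
  "ge0": 0.00385714, "gi0": 0.01142857, "De": 0.00011429, "Di": 0.00571429},
 {"set": 6, "min_f": 13.3, "max_f": 16.8,
  "ge0": 0.00428571, "gi0": 0.01114286, "De": 0.0, "Di": 0.00428571},
 {"set": 7, "min_f": 15.2, "max_f": 18.6,
  "ge0": 0.00407143, "gi0": 0.01, "De": 0.0, "Di": 0.00428571},
 {"set": 8, "min_f": 16.7, "max_f": 19.9,
  "ge0": 0.00364286, "gi0": 0.00828571, "De": 0.0, "Di": 0.00428571},
 {"set": 9, "min_f": 18.5, "max_f": 22.6,
  "ge0": 0.0045, "gi0": 0.01085714, "De": 0.00011429, "Di": 0.00571429}
]
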