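{
  "kyte_doolittle": {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
  },
  "grantham_polarity": {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9
  },
  "zimmerman_bulkiness": {
    "A": 11.5, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46,
    "Q": 14.45, "E": 13.57, "G": 3.4, "H": 13.69, "I": 21.4,
    "L": 21.4, "K": 15.71, "M": 16.25, "F": 19.8, "P": 17.43,
    "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57
  },
  "emboss_pk": {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1
  },
  "aromatic": ["F", "W", "H", "Y"],
  "acidic": ["D", "E"],
  "basic": ["R", "H", "K"],
  "positive_side_chains": ["R", "K", "H"],
  "negative_side_chains": ["C", "D", "E", "Y"],
  "aliphatic_weights": {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}
}
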