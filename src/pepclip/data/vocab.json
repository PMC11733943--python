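{
  "[PAD]": 0,
  "[UNK]": 1,
  "[CLS]": 2,
  "[SEP]": 3,
  "A": 4,
  "C": 5,
  "D": 6,
  "E": 7,
  "F": 8,
  "G": 9,
  "H": 10,
  "I": 11,
  "K": 12,
  "L": 13,
  "M": 14,
  "N": 15,
  "P": 16,
  "Q": 17,
  "R": 18,
  "S": 19,
  "T": 20,
  "V": 21,
  "W": 22,
  "Y": 23
}
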