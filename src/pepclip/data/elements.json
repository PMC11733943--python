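{
  "_comment": "Atomic number, standard atomic weight (u), covalent radius (angstrom); single bundled snapshot of standard reference values for elements occurring in peptide structures and common hetero atoms.",
  "H":  {"number": 1,  "mass": 1.008,   "covalent_radius": 0.31},
  "C":  {"number": 6,  "mass": 12.011,  "covalent_radius": 0.76},
  "N":  {"number": 7,  "mass": 14.007,  "covalent_radius": 0.71},
  "O":  {"number": 8,  "mass": 15.999,  "covalent_radius": 0.66},
  "F":  {"number": 9,  "mass": 18.998,  "covalent_radius": 0.57},
  "NA": {"number": 11, "mass": 22.990,  "covalent_radius": 1.66},
  "MG": {"number": 12, "mass": 24.305,  "covalent_radius": 1.41},
  "P":  {"number": 15, "mass": 30.974,  "covalent_radius": 1.07},
  "S":  {"number": 16, "mass": 32.06,   "covalent_radius": 1.05},
  "CL": {"number": 17, "mass": 35.45,   "covalent_radius": 1.02},
  "K":  {"number": 19, "mass": 39.098,  "covalent_radius": 2.03},
  "CA": {"number": 20, "mass": 40.078,  "covalent_radius": 1.76},
  "FE": {"number": 26, "mass": 55.845,  "covalent_radius": 1.32},
  "ZN": {"number": 30, "mass": 65.38,   "covalent_radius": 1.22},
  "SE": {"number": 34, "mass": 78.971,  "covalent_radius": 1.20},
  "BR": {"number": 35, "mass": 79.904,  "covalent_radius": 1.20},
  "I":  {"number": 53, "mass": 126.904, "covalent_radius": 1.39}
}
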