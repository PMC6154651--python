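{
  "version": "CODATA-2018 / IUPAC-2021, pinned",
  "comment": "monoisotopic: most-abundant-isotope masses (u); average: standard atomic weights (u). Pinned so every mass in the pipeline is bit-stable.",
  "electron_mass": 0.000548579909,
  "proton_mass": 1.007276466,
  "monoisotopic": {
    "H": 1.007825032,
    "B": 11.009305167,
    "C": 12.0,
    "N": 14.003074004,
    "O": 15.994914620,
    "F": 18.998403163,
    "Na": 22.989769282,
    "Si": 27.976926535,
    "P": 30.973761998,
    "S": 31.972071174,
    "Cl": 34.968852682,
    "K": 38.963706487,
    "Se": 79.916521762,
    "Br": 78.918337601,
    "I": 126.904471853
  },
  "average": {
    "H": 1.008,
    "B": 10.811,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403,
    "Na": 22.989769,
    "Si": 28.085,
    "P": 30.973762,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.90447
  }
}
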