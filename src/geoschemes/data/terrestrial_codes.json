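{
  "_comment": "Sample of the terrestrial WGSRPD code list used for collision checks: level-1 digits, level-2 two-digit codes, and representative three-letter level-3 codes. The full list is configuration supplied by the user.",
  "codes": ["1", "2", "3", "4", "5", "6", "7", "8", "9",
            "10", "11", "12", "13", "14", "20", "21", "22", "30", "40",
            "50", "51", "60", "70", "80", "90", "91",
            "ABT", "AGE", "ALA", "AUT", "BEL", "BRA", "CAL", "CHN", "EGY",
            "FRA", "GER", "GRB", "IND", "ITA", "JAP", "MDG", "MXC", "NET",
            "NOR", "NZN", "POR", "RUC", "SPA", "SWE", "TUR", "USA", "VEN"]
}
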