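{
 "version": "1.0",
 "units": "kcal/mol at 37C",
 "description": "Nearest-neighbor duplex parameters. Watson-Crick stacks follow the Turner 2004 table; stacks involving G:U wobbles are approximated as the corresponding A:U-type stack plus 0.4 kcal/mol per wobble pair (symmetric by construction). Loop penalties are smooth Turner-like size tables.",
 "stack": {
  "AA/UU": -0.93,
  "AU/UA": -1.1,
  "AC/UG": -2.24,
  "AG/UC": -2.08,
  "AG/UU": -0.53,
  "AU/UG": -0.7,
  "UA/AU": -1.33,
  "UU/AA": -0.93,
  "UC/AG": -2.35,
  "UG/AC": -2.11,
  "UG/AU": -0.93,
  "UU/AG": -0.53,
  "CA/GU": -2.11,
  "CU/GA": -2.08,
  "CC/GG": -3.26,
  "CG/GC": -2.36,
  "CG/GU": -1.71,
  "CU/GG": -1.68,
  "GA/CU": -2.35,
  "GU/CA": -2.24,
  "GC/CG": -3.42,
  "GG/CC": -3.26,
  "GG/CU": -1.95,
  "GU/CG": -1.84,
  "GA/UU": -0.53,
  "GU/UA": -0.7,
  "GC/UG": -1.84,
  "GG/UC": -1.68,
  "GG/UU": -0.13,
  "GU/UG": -0.3,
  "UA/GU": -0.93,
  "UU/GA": -0.53,
  "UC/GG": -1.95,
  "UG/GC": -1.71,
  "UG/GU": -0.53,
  "UU/GG": -0.13
 },
 "duplex_initiation": 4.09,
 "terminal_au_gu_penalty": 0.45,
 "bulge": {
  "1": 3.8,
  "2": 2.8,
  "3": 3.2,
  "4": 3.6,
  "5": 4.0,
  "6": 4.4,
  "7": 4.59,
  "8": 4.7,
  "9": 4.8,
  "10": 4.89
 },
 "internal": {
  "2": 1.0,
  "3": 1.8,
  "4": 2.0,
  "5": 2.2,
  "6": 2.5,
  "7": 2.7,
  "8": 2.9,
  "9": 3.1,
  "10": 3.2
 },
 "max_loop": 10
}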