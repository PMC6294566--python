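{
  "name": "santalucia-unified-dna",
  "version": "1998-unified/hairpin-loops-2004, monotone-smoothed loops",
  "comment": "Unified nearest-neighbor parameters for DNA/DNA Watson-Crick stacks at 1 M NaCl. dH in kcal/mol, dS in cal/(mol K). Stack keys are the 5'->3' dinucleotide of the top strand; both orientations of each symmetric step are listed explicitly. Hairpin-loop increments are free energies at 37 C (kcal/mol), smoothed to be non-decreasing in loop length.",
  "stack_dH": {
    "AA": -7.9, "TT": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8,
    "GA": -8.2, "TC": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0, "CC": -8.0
  },
  "stack_dS": {
    "AA": -22.2, "TT": -22.2,
    "AT": -20.4,
    "TA": -21.3,
    "CA": -22.7, "TG": -22.7,
    "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0,
    "GA": -22.2, "TC": -22.2,
    "CG": -27.2,
    "GC": -24.4,
    "GG": -19.9, "CC": -19.9
  },
  "terminal_dH": {"GC": 0.1, "AT": 2.3},
  "terminal_dS": {"GC": -2.8, "AT": 4.1},
  "at_closing_dG37": 0.5,
  "loop_dG37": {
    "3": 3.5, "4": 3.5, "5": 3.5, "6": 4.0, "7": 4.2, "8": 4.3,
    "9": 4.5, "10": 4.6, "11": 4.8, "12": 5.0, "13": 5.05, "14": 5.1,
    "15": 5.2, "16": 5.3, "17": 5.4, "18": 5.5, "19": 5.6, "20": 5.7,
    "21": 5.78, "22": 5.86, "23": 5.94, "24": 6.02, "25": 6.1,
    "26": 6.14, "27": 6.18, "28": 6.22, "29": 6.26, "30": 6.3
  },
  "loop_ref_temperature_K": 310.15,
  "loop_extrapolation_coeff": 1.75,
  "salt": {"na_molar": 0.0, "mg_molar": 0.010},
  "salt_entropy_coeff": 0.368,
  "ref_temperature_K": 298.15
}
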