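{
  "builtin": [
    {
      "name": "enzyme",
      "kind": "categorical",
      "default": "trypsin",
      "candidates": ["trypsin", "lys-c", "chymotrypsin"],
      "depends_on": []
    },
    {
      "name": "specificity",
      "kind": "categorical",
      "default": "specific",
      "candidates": ["specific", "semi"],
      "depends_on": ["enzyme"]
    },
    {
      "name": "max_missed_cleavages",
      "kind": "numeric",
      "default": 2,
      "candidates": [0, 1, 2],
      "depends_on": ["enzyme"]
    },
    {
      "name": "precursor_tolerance",
      "kind": "numeric",
      "default": [10, "ppm"],
      "candidates": [[5, "ppm"], [10, "ppm"], [50, "ppm"]],
      "depends_on": []
    },
    {
      "name": "fragment_tolerance",
      "kind": "numeric",
      "default": [0.02, "Da"],
      "candidates": [[0.02, "Da"], [0.05, "Da"], [0.5, "Da"]],
      "depends_on": []
    },
    {
      "name": "fixed_mods",
      "kind": "categorical",
      "default": [],
      "candidates": [[], ["carbamidomethyl_c"]],
      "depends_on": []
    },
    {
      "name": "variable_mods",
      "kind": "categorical",
      "default": [],
      "candidates": [[], ["oxidation_m"], ["oxidation_m", "deamidation_n"]],
      "depends_on": []
    },
    {
      "name": "max_variable_mods",
      "kind": "numeric",
      "default": 2,
      "candidates": [1, 2, 3],
      "depends_on": ["variable_mods"]
    }
  ]
}
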