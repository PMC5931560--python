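# JSON model dialect

The JSON dialect mirrors the content of the SBML L3+FBC v2 serialisation so
that tests and analysis scripts can avoid XML.  One document per model:

```json
{
  "id": "toy_endothelial",
  "objective": "BIOMASS",
  "genes": ["g_glyc1", "g_glyc2"],
  "metabolites": [
    {"id": "glc_e", "name": "glc", "compartment": "e", "n_carbons": 6}
  ],
  "reactions": [
    {
      "id": "GLYC",
      "stoichiometry": {"glc_c": -1.0, "pyr_c": 2.0},
      "lower_bound": 0.0,
      "upper_bound": 1000.0,
      "gpr": "(g_glyc1 and g_glyc2) or g_glyc3",
      "subsystem": "Glycolysis",
      "super_subsystem": "Carbohydrate",
      "is_exchange": false
    }
  ]
}
```

Field notes:

- `objective` — reaction id of the biomass objective; must appear in
  `reactions`.
- `n_carbons` — carbon count of the metabolite; `0` means unknown.  Stored in
  SBML as the FBC chemical formula (`C6`).
- `gpr` — infix boolean rule over gene ids, case-insensitive `and`/`or`,
  parentheses allowed, no negation.  The empty string means the reaction is
  not gene-linked and is always available.
- `is_exchange` — exchange reactions consume exactly one metabolite with
  coefficient −1.  **Positive flux is secretion, negative flux is uptake.**
  In SBML this flag is carried as SBO:0000627.
- `subsystem` / `super_subsystem` — free-text pathway labels (stored in SBML
  reaction notes).
- Every metabolite referenced by a stoichiometry and every gene used in a GPR
  must be declared; loaders reject violations with a validation error naming
  the offending element.

Serialisation is canonical (sorted keys, fixed indentation), so
`write(load(text)) == text` byte-for-byte.
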