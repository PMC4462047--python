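# JSON model dialect (schema_version 1)

A minimal, deterministic JSON serialization of a constraint-based
metabolic model, written so that `write(read(file))` is byte-stable on
canonicalized input (2-space indent, fixed key order, trailing newline).

```json
{
  "schema_version": 1,
  "id": "toy_core_network",
  "default_objective": "EX_aa",
  "genes": ["gG6PD", "gPGD"],
  "metabolites": [
    {"id": "g6p_c", "name": "glucose 6-phosphate", "compartment": "c", "formula": null}
  ],
  "reactions": [
    {
      "id": "G6PD",
      "name": "glucose-6-phosphate dehydrogenase",
      "stoichiometry": {"g6p_c": -1.0, "nadp_c": -1.0, "nadph_c": 1.0, "p6g_c": 1.0},
      "lower_bound": 0.0,
      "upper_bound": 100.0,
      "gpr": "gG6PD",
      "is_exchange": false
    }
  ]
}
```

Field semantics:

| field | meaning |
|---|---|
| `stoichiometry` | metabolite id → signed coefficient (negative = consumed); only nonzero entries, keys sorted |
| `lower_bound`, `upper_bound` | flux bounds in mmol·gDW⁻¹·h⁻¹; infinities serialized as the strings `"-inf"` / `"inf"` |
| `gpr` | boolean gene rule: identifiers, `and`, `or` (case-insensitive), parentheses; `null` if absent |
| `is_exchange` | boundary reaction written as export (`metabolite → ∅`); must touch exactly one metabolite |
| `genes` | sorted list; every gene referenced by a `gpr` must appear |
| `default_objective` | reaction id or `null` |

Validation on load: unique ids, stoichiometry keys resolve to declared
metabolites, GPR genes resolve to `genes`, `lower_bound ≤ upper_bound`.
The same model can be written as SBML Level 3 + FBC v2 (bounds as shared
constant parameters, GPRs as gene-product associations, objective in the
FBC objective list); the two formats load to field-identical models.
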