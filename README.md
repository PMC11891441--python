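# bofkit

Build structured, mass- and charge-balanced **biomass objective functions**
(BOFs) for genome-scale metabolic models (GEMs) from biomass composition
data, and insert them into — or remove them from — an existing model.

A BOF is the pseudo-reaction that consumes every precursor needed to make
1 g of cell dry weight (gDW); its flux is the growth rate maximized in flux
balance analysis. Turning measured compositions (mass fractions, molar
amounts, mole percentages, in whatever units the data come in) into correct
stoichiometric coefficients involves several normalization and conversion
steps that are easy to get wrong by hand. bofkit automates them:

* **Up to three levels** of pseudo-reactions: a top sheet (macromolecule
  content, final unit mmol·gDW⁻¹), pool sheets (e.g. DNA from dNTPs, final
  unit mol·mol⁻¹) and class sheets (e.g. individual lipids into a PC class).
* **Unit flexibility per sheet** (`g_per_gDW`, `mg_per_gDW`,
  `percent_DW_mass`, `mmol_per_gDW`, `umol_per_gDW`, `mol_per_mol`,
  `percent_mol`); rows within one sheet must share a unit.
* **Normalization to 1 gDW**: the total mass recovered from the data is
  rescaled to exactly 1 g of dry weight before conversion to
  model-compatible units; the scale factor is reported.
* **Maintenance / cofactor rows** (ATP costs, vitamins, byproducts) are
  applied *as given* — signed coefficients, negative = consumed, positive =
  produced, in `mmol_per_gDW` or `mol_per_mol_pool`; they are never
  converted or rescaled. Polymers are treated as one monomer long, so any
  condensation cost belongs in these rows.
* **Balanced by construction**: pseudo-metabolite formulas and charges are
  computed as the net of their producing reaction, so every generated
  reaction passes elemental and charge balance whenever constituent
  formulas/charges are known.
* **Tagged, reversible edits**: every generated ID gets a `_<tag>` suffix;
  several BOFs can coexist in one model and each can be removed cleanly by
  its tag.

Models are read and written as SBML (Level 3 + FBC) or COBRA-JSON via
[cobrapy]. Note that SBML/FBC stores metabolite charge as an integer:
non-integer pseudo-metabolite charges are rounded (with a warning) when
writing SBML, while COBRA-JSON preserves them exactly.

[cobrapy]: https://opencobra.github.io/cobrapy/

## Input format

One workbook (`.xlsx`) with one sheet per pseudo-reaction, or a directory
of TSV files (`<sheet>.tsv` + optional `<sheet>.maintenance.tsv`). Columns
are resolved by header name:

| composition table | maintenance table |
| --- | --- |
| `metabolite_id` (model ID, or the name of a deeper sheet) | `maintenance_metabolite_id` (model ID only) |
| `name` (optional) | `maintenance_name` (optional) |
| `value` (≥ 0; zero rows are dropped) | `maintenance_coefficient` (signed, ≠ 0) |
| `unit` (one per sheet) | `maintenance_unit` |

Sheet name = pool name = base ID of the generated pseudo-metabolite and
pseudo-reaction. The top sheet is the unique sheet referenced by no other
sheet; references must form a tree of depth ≤ 3. Generate a blank template
with documented headers:

```sh
bofkit template --levels 3 --out template.xlsx
```

## CLI

```sh
# build a BOF and insert it
bofkit build --model model.xml --data composition.xlsx \
             --tag myBOF --compartment c \
             --out-model updated.xml --report coefficients.xlsx

# balance-check (and optionally FBA-test) an existing tagged BOF
bofkit validate updated.xml myBOF --json --growth

# remove it again
bofkit remove updated.xml myBOF --out reverted.xml
```

`build` accepts `--formulas-available/--no-formulas-available` and
`--charges-available/--no-charges-available` to assert (or deny) that the
model carries formulas/charges for all consumed metabolites — asserting
availability turns a missing formula into a hard error. `--set-objective`
makes the new top reaction the model objective (off by default);
`--compartment-suffix` appends `_<compartment>` to pseudo-metabolite IDs
for BiGG-style models. Options can also come from a JSON/YAML file via
`--config` (explicit flags win). Exit codes distinguish config (2), schema
(3), validation-of-data (4), conversion (5), ID-collision (6), balance (7),
not-found (8) and model-I/O (9) failures.

## Python API

```python
from bofkit import load_model, load_workbook, build_spec, build_bof, \
                   balance_check, growth_check, save_model

model = load_model("model.xml")
spec = build_spec(load_workbook("composition.xlsx"), "myBOF", "c", model)
report = build_bof(model, spec)          # inserts the tagged BOF
print(balance_check(model, "myBOF").to_text())
print("growth:", growth_check(model, "myBOF"))
save_model(model, "updated.xml")
```

`bofkit.fixtures` generates deterministic toy models and composition
workbooks (seeded, no downloads) used throughout the test suite.

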