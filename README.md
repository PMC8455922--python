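# framen400

A computational model of the N400 ERP component built on stochastic frames.
Category concepts are attribute–value structures whose value spaces carry
probability distributions; combining the concept at an open argument position
with the category expressed by the critical word yields two components:

- **predictability** — base-10 entropy reduction over the extensions of the
  frame on its non-disconfirmed context-dependent chains, and
- **plausibility** — typicality of the critical word's category relative to
  the argument concept, a diagnosticity-weighted sum of min-rule value
  similarities (with cue-validity / diagnosticity computed against contrast
  classes, or stipulated by the scenario).

The two are combined into a predicted N400 index in [0, 1]
(`alpha * (1 − ΔH/H(t1)) + beta * (1 − typicality)`, weights configurable).
Categorization failure (a pre-activated attribute chain undefined for the
critical word) yields the maximal index with typicality uncomputed. A
thematic-role extension scores words against several role-prefixed argument
concepts at once.

## Scenarios

Scenarios are purpose-defined JSON files (`format_version: 1`) bundling
sorts, attribute chains with finite value spaces, per-category probability
tables, the argument concept (context-independent vs. context-dependent
chains, threshold `r`, stipulated diagnosticity weights or a contrast-class
declaration), optional prenominal updates, optional thematic roles, and the
declared critical words. Five scenarios ship with the package
(`src/framen400/data/`): `holiday_resort`, `birthday_party`,
`seaside_caution_HC`, `seaside_caution_LC`, `prescription`. Tables not fixed
by the reference values are marked `"provenance": "fixture-choice"`.

A seeded generator produces random valid scenarios for property testing:

```python
from framen400 import generate_random_scenario
spec = generate_random_scenario(seed=42)
```

## CLI

```bash
framen400 validate src/framen400/data/holiday_resort.json
framen400 evaluate src/framen400/data/holiday_resort.json --cw palms --format json
framen400 evaluate src/framen400/data/birthday_party.json --prenominal sweet --cw veggies
framen400 entropy  src/framen400/data/holiday_resort.json
framen400 typicality src/framen400/data/birthday_party.json --prenominal healthy
framen400 simulate --seed 7 --n 3 --out scratch/sims
framen400 report src/framen400/data/holiday_resort.json
```

Exit code 0 on success, 2 on validation failure or an unknown critical word.
Flags: `--alpha/--beta` (index weights), `--threshold-r`, `--log-base`,
`--variant raw|normalized`, `-v/-vv` for stderr logging.

## Python API

```python
import framen400 as fn

scenario = fn.fixture_holiday_resort()      # or fn.load_scenario(path)
report = fn.evaluate(scenario, "pines")
report.h_t1, report.h_t2, report.delta_h    # 0.4335, 0.1412, 0.2923
report.typicality_raw, report.n400_index
```

Lower-level pieces (`update_set`, `update_t`, `enumerate_extensions`,
`entropy`, `similarity`, `cue_validity`, `diagnosticity`, `typicality`,
`role_typicality`) are exported individually.

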