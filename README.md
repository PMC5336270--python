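# dietmix

Cost-effectiveness modelling of insect mass-rearing diets with constrained
mixture designs and Scheffé polynomial response surfaces.

Mass-rearing facilities that produce sterile insects for the sterile insect
technique (SIT) spend a large share of their budget on artificial diet, and
the protein source (torula yeast) is the costly ingredient.  `dietmix`
implements the complete statistical workflow for asking *how far can the
expensive ingredient be reduced without hurting insect production*: a
three-component constrained mixture experiment (yeast A, corn flour B,
corncob fractions C, jointly 30.3% of the diet by weight), Scheffé
polynomial response-surface models for the biological responses (pupation,
larval duration, pupal weight, adult emergence), a linear ingredient-cost
model, and a grid-based multi-response optimization that intersects all
acceptance criteria into an **area of operability** and reports the
maximum-savings blend.  The package is aimed at rearing scientists and
biostatisticians who design and analyse diet-formulation experiments.

## The model

Blends are coded onto the unit simplex with L-pseudocomponent coding
`z_i = (x_i − L_i)/(T − ΣL)`, where `L` are the component lower bounds and
`T` the mixture total, so the three extreme blends become pure components.
Responses are fitted with intercept-free Scheffé polynomials, e.g. the
special quartic

    E[y] = Σ βi·zi + Σ βij·zi·zj + β1123·z1²z2z3 + β1223·z1z2²z3 + β1233·z1z2z3²,

walked up the ladder mean → linear → quadratic → special cubic → cubic →
special quartic → quartic with Type I sequential F tests, lack-of-fit tests
against replicate pure error, the PRESS/R²-predicted family, adequate
precision, and hierarchical backward elimination at α = 0.05.  Influence
diagnostics (externally studentized residuals, Cook's distance, DFFITS,
DFBETAS, Box-Cox profiles) drive a capped outlier-exclusion workflow.
Ingredient cost is linear in the blend, so savings surfaces are planes on
the simplex; the optimization is an exhaustive lattice search (default step
0.01 percentage points) over all criteria simultaneously.

## Worked example

The package ships the reference study's published coefficient surfaces and
cost anchors, so the optimization stage runs without any raw data:

```bash
dietmix reproduce --step 0.01
```

prints (abridged):

```json
{
  "unit_prices": [4.20402, 0.443749, 0.956855],
  "criteria": {
    "pupation":        {"bound_type": "minimum", "limit": 0.70},
    "duration_days":   {"bound_type": "maximum", "limit": 9.46},
    "pupal_weight_mg": {"bound_type": "minimum", "limit": 16.39},
    "emergence":       {"bound_type": "minimum", "limit": 0.80}
  },
  "region": {
    "n_feasible": 1207, "n_grid": 45451,
    "component_ranges": {
      "yeast_pct":     [5.27, 6.0],
      "cornflour_pct": [5.3, 6.03],
      "corncob_pct":   [19.0, 19.71]
    },
    "binding_constraints": {"duration_days": true, "...": false},
    "most_restrictive": "duration_days"
  },
  "max_savings": {
    "blend": [5.27, 6.03, 19.0],
    "savings_percent": 5.99918,
    "savings_annual": 47496.5,
    "savings_per_ton": 27.4501
  }
}
```

Reading this: the per-kg ingredient prices recovered from the published cost
anchors are $4.20 (yeast), $0.44 (corn flour) and $0.96 (corncob fractions);
1,207 of the 45,451 candidate blends satisfy all four criteria; the larval
duration limit of 9.46 days is the constraint that actually bounds the
region; and the cheapest acceptable blend (5.27% yeast, 6.03% corn flour,
19% corncob) saves 6.0% of the standard mixture's annual ingredient cost —
about $47.5k per year, or $27.45 per ton of diet, at an annual production of
1,730.29 tons.

A data-driven analysis runs the same stages from a run-table CSV:

```bash
dietmix simulate --seed 2 --out runs.csv   # or your own 40-run table
dietmix fit runs.csv --out report/
```

and from Python:

```python
from dietmix import (PipelineConfig, reference_design, simulate_runs,
                     run_pipeline)

runs = simulate_runs(reference_design(seed=1), seed=42)
bundle = run_pipeline(PipelineConfig(), runs)
bundle["models"]["duration_days"]["model"]   # e.g. 'reduced:special_quartic'
bundle["region"]["component_ranges"]
```

## Layout

| module | contents |
|---|---|
| `dietmix.design` | mixture space, pseudo-component coding, the 19 tested blends, replicate plans, leverage |
| `dietmix.scheffe` | term sets, model ladder, fitting, sequential selection, LOF/PRESS/adequate precision, backward elimination |
| `dietmix.diagnostics` | influence statistics, Box-Cox profiles, exclusion workflow |
| `dietmix.cost` | cost model, anchor inversion, savings |
| `dietmix.optimize` | criteria, lattice evaluation, operability region, overlay export |
| `dietmix.synthetic` | seedable generator emulating the experiment, recovery harness, contamination |
| `dietmix.reference` | packaged published surfaces/anchors and the one-call reproduction |
| `dietmix.io` / `dietmix.cli` | CSV/config/JSON I/O, pipeline driver, `dietmix` CLI |

See `docs/methods.md` for the statistical details and design choices.
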