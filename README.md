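# seqdoe

Sequential design-of-experiments for combinatorial optimization of strain
genotype, media composition and process conditions.

Screening a microbial cell factory over many two-level factors — promoter
strengths for pathway genes, temperature, agitation, inoculum density,
nitrogen source, buffering, amino-acid supplementation — quickly outgrows a
full factorial: eleven two-level factors already demand ∏ Lᵢ = 2¹¹ = 2048
experiments. `seqdoe` implements the standard alternative: **regular
two-level fractional factorial designs** 2^(k−p) with guaranteed resolution,
fitted with the linear effect model

    y = β₀ + Σᵢ MEᵢ·Fᵢ + Σᵢ<ⱼ 2FIᵢ:ⱼ·Fᵢ·Fⱼ + ε ,   Fᵢ ∈ {−1, +1}

where y is the titre (mg/L), MEᵢ is the main effect of factor i and 2FIᵢ:ⱼ
the two-factor interaction. A resolution IV fraction estimates all MEs free
of 2FIs (which remain confounded among themselves); a resolution V fraction
leaves MEs and 2FIs unconfounded. The package is organized around a
two-round campaign:

1. **Screen** all factors in a resolution IV fraction; fit ME-only and
   ME+2FI models by OLS with coefficient t-tests and Bonferroni correction.
2. **Fix** the strongest significant main effects at their favorable level.
3. **Refine** the remaining factors in a resolution V fraction; **enumerate**
   every remaining candidate setting, predict the optimum, and probe it with
   leave-out refits, one-factor perturbations and interaction cell means.

The library includes the design algebra that backs this workflow — defining
contrast subgroups, minimum-aberration generator search, alias tables,
orthogonality and projection diagnostics, estimability reports after run
removal — plus a synthetic-data module that generates ground-truth response
models emulating a p-coumaric-acid production study in *S. cerevisiae*
(sparse effects, multiplicative log-normal replicate noise, titres spanning
two orders of magnitude, two unconstructable genotypes), so every stage can
be exercised and calibrated without wet-lab data.

## Worked example

```python
import seqdoe as sq

truth = sq.default_pca_truth()          # hidden coefficients of the simulator
result = sq.run_campaign(truth, seed=1) # screen -> fix -> refine -> predict
```

Inspecting the result prints:

```
round 1: 32 runs designed, 28 executed in triplicate
ME model    adj R2 = 0.64, MAE = 36.5 mg/L
ME+2FI model adj R2 = 0.87, MAE = 16.9 mg/L
significant MEs: PAL-C4H (+46.6), ARO4 (-26.5), pH (-24.0), OD (+17.9),
                 Phe (+15.6), rpm (+15.0), AROL (-14.5), N (-14.4), T (-14.2)
fixed after round 1: {'PAL-C4H': 1, 'ARO4': -1, 'pH': -1}
round 2: 64 runs, resolution 5
predicted optimum: 436.8 mg/L at
    {'PAL-C4H': 1, 'ARO4': -1, 'pH': -1, 'T': -1, 'rpm': 1, 'OD': 1,
     'N': -1, 'Phe': 1, 'Glu': 1, 'ARO7': 1, 'AROL': -1}
ground-truth optimum: 448.0 mg/L -> recovered: True
```

Reading the output: the 32-run resolution IV screen (16 strains × 2 process
conditions, 4 runs infeasible) identifies high PAL-C4H expression and
unbuffered media as dominant; adding confounded interaction representatives
lifts adj R² from 0.64 to 0.87, signalling real interactions. Three factors
are pinned at their favorable level, the remaining eight enter a 64-run
resolution V fraction, and enumerating all 2⁸ = 256 candidates predicts an
optimum of 436.8 mg/L — whose settings coincide with the simulator's true
argmax (448.0 mg/L noiseless). At this seed the screen ranked ARO4 above
Phe, so ARO4 was fixed instead; the campaign still recovers the optimum
because any strong factor pinned at its favorable sign remains at its
optimal level.

The same pipeline is scriptable from the shell:

```
seqdoe design --factors default --resolution IV --out design.csv
seqdoe alias --design design.csv
seqdoe simulate --design design.csv --replicates 3 --seed 7 --out titres.csv
seqdoe fit --design design.csv --response titres.csv --model 2fi --out report/
seqdoe campaign --seed 1 --out campaign/
```

## Layout

- `seqdoe.design` — designs, defining words, alias tables, projections,
  run-removal estimability reports
- `seqdoe.model` — model matrices, OLS fits, Bonferroni, metrics, prediction
- `seqdoe.workflow` — screening rounds, factor fixing, candidate
  enumeration, leave-out validation, perturbation and interaction analyses
- `seqdoe.synthetic` — ground truths, response simulation, parameter
  recovery and family-wise error studies
- `seqdoe.io` / `seqdoe.cli` — CSV/YAML readers and writers, `seqdoe` CLI

See `docs/methods.md` for the statistical methodology and the design
decisions behind the synthetic study generator.
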