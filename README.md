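# protmr

Proteome-wide drug-target Mendelian randomization in Python: two-sample
MR estimation with a full sensitivity battery, two-step mediation through
circulating proteins, reverse MR, and approximate-Bayes-factor
colocalization — plus a synthetic-data generator with known causal ground
truth so every stage can be validated end to end without access to the
original GWAS cohorts.

## Who this is for

Genetic epidemiologists asking whether a drug target's effect on a
disease runs through an intermediate molecular trait. The canonical
design: variants near a drug-target gene proxy pharmacological inhibition
(the *exposure*); a plasma-proteome panel of pQTL summary statistics
supplies candidate *mediators*; a large case/control GWAS supplies the
*outcome*. Everything works from published summary statistics — no
individual-level data.

## The statistics

With harmonized per-variant effects (β̂ₓᵢ, β̂ᵧᵢ) the per-instrument Wald
ratio is rᵢ = β̂ᵧᵢ/β̂ₓᵢ, and the headline estimator is inverse-variance
weighting, β̂_IVW = Σwᵢrᵢ/Σwᵢ with wᵢ the inverse Wald-ratio variance;
MR-Egger, weighted-median and mode estimators guard against pleiotropy,
with Cochran's Q/I², the Egger intercept, a simulation-based global
pleiotropy (residual-sum-of-squares) test, radial outlier contributions
and leave-one-out influence as diagnostics. Instrument strength uses

    R² = 2β²·EAF(1−EAF) / [2β²·EAF(1−EAF) + 2·SE²·n·EAF(1−EAF)],
    F  = (n−2)·R²/(1−R²),   F < 10 ⇒ weak, excluded.

Two-step mediation combines β₁ (exposure→protein) and β₂
(protein→outcome) by the product of coefficients: indirect effect β₁β₂
with delta-method SE √(β₁²se₂² + β₂²se₁²), and mediated proportion
β₁β₂/β₃ against the total effect β₃, with a three-term delta-method CI.
Colocalization enumerates the five single-causal-variant hypotheses
H0–H4 from per-variant Wakefield log approximate Bayes factors,
log ABF = ½[log(V/(V+W)) + z²W/(V+W)], with priors p1 = p2 = 1e-4,
p12 = 1e-5; PP.H4 > 0.70 calls a shared causal variant.

## Worked example

`examples/02_two_step_mediation.py` plants one mediator in a 200-protein
panel (β₁ = 0.96, β₂ = −0.21, direct path −0.62, so the true mediated
proportion is β₁β₂/β₃ ≈ 24.5%) and runs the whole pipeline:

```
planted mediator: P0001; true mediated proportion 0.245
[     ok] main_mr: 6 instruments
[     ok] screen1: 1/200 pass FDR
[     ok] screen2: 1/1 pass FDR
[     ok] mediation: 1 mediator(s)
[     ok] reverse_mr: 1 protein(s)
[     ok] coloc: 1 region(s)

mediator P0001:
  total effect beta3      = -0.875
  exposure->protein beta1 = +1.037
  protein->outcome beta2  = -0.210
  indirect beta1*beta2    = -0.218 [-0.285, -0.150], p=3.37e-10
  mediated proportion     = 24.9% [14.1%, 35.6%]
```

Only the planted protein survives the FDR-controlled two-step screen,
and the estimated proportion lands on the simulated truth. The other
examples cover a single MR pair with the full diagnostic battery
(`01_single_pair_mr.py`), shared- versus distinct-causal-variant
colocalization (`03_colocalization.py`), and the shell interface
(`04_cli_pipeline.sh`):

```bash
protmr simulate --seed 7 --panel-size 50 --out scenario/
protmr run --config scenario/config.yaml --out report/
```

## Layout

- `src/protmr/sumstats.py` — summary-statistic containers, TSV I/O, allele harmonization
- `src/protmr/instruments.py` — R²/F instrument strength, greedy LD/distance pruning, cis-pQTL windows
- `src/protmr/estimators.py` — Wald ratio, IVW, Egger, weighted median, modes, OR transforms
- `src/protmr/sensitivity.py` — Cochran Q/I², effects-model rule, global pleiotropy test, radial MR, leave-one-out
- `src/protmr/screening.py` — BH-FDR, two-step proteome screen, direction consistency, mediation, reverse MR
- `src/protmr/coloc.py` — Wakefield ABFs and five-hypothesis enumeration
- `src/protmr/simulate.py` — ground-truth scenario and LD-region generators
- `src/protmr/pipeline.py`, `src/protmr/cli.py` — six-stage orchestration and the `protmr` command

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
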