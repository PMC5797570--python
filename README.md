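# soilrisk

Ecological analysis of topsoil metal composition and cancer mortality for
**spatially misaligned** data: element concentrations are measured at soil
sampling points, deaths are aggregated by town, and the exposure a town
experiences must be interpolated between the two.  `soilrisk` implements
the full chain for that problem:

1. **Compositional transforms.**  Concentrations (mg/kg) are closed data;
   the package opens them with the standardised log transform
   `y = (log x − mean(log x)) / sd(log x)` or the centred logratio
   `y_i = log(x_i / g(x))`, `g` the per-sample geometric mean.
2. **Principal factor analysis.**  Iterated principal-axis factoring of
   the correlation matrix, factor count from a cumulative
   explained-variance rule (default 75%), varimax rotation, sign
   orientation, and regression factor scores at every sampling point —
   robust to the singular clr correlation matrix.
3. **Joint misalignment model.**  Per town *i*,
   `O_i ~ Poisson(E_i λ_i)` with
   `log λ_i = α + β·expos_i + Σ_j δ_j Soc_ij + u_i + v_i`
   (BYM: intrinsic-CAR `u` over town adjacency plus iid `v`); per soil
   sample *j*, `c_j ~ N(x(s_j), σ_x²)` where `x(·)` is a Matérn (ν = 1)
   Gaussian field represented on a triangulated mesh by its sparse SPDE
   precision.  `expos_i = x(s_i)` is the same latent field at the town
   centroid, so fitting both layers **jointly** propagates the exposure
   interpolation error into the posterior of β.  The effect is reported
   as a relative risk `RR = exp(β)` with a 95% credibility interval and a
   flag for intervals excluding 1.  A two-stage "naïve" comparator
   (krige, then plug in) is included to quantify what ignoring the
   kriging error costs.
4. **Synthetic scenarios.**  A generator produces coherent misaligned
   datasets — planted factor structure on smooth spatial fields, a town
   lattice with queen adjacency, confounders, Poisson deaths from known
   coefficients — so every stage is testable with known ground truth.

Inference is a nested Laplace scheme on the sparse precision (no sampling;
deterministic given the seed); see `docs/methods.md` for the estimation
details, priors and design choices.

Intended users: spatial epidemiologists and environmental-geochemistry
groups relating point-sampled environmental surfaces to small-area health
outcomes.

## Worked example

```python
import numpy as np
from soilrisk import (ScenarioConfig, generate_scenario,
                      standardised_log_transform, PrincipalFactorAnalysis,
                      JointMisalignmentModel)

cfg = ScenarioConfig(seed=7)            # 20x20 towns, 600 soil samples
soil, towns, graph, truth = generate_scenario(cfg, seed=7)

fa = PrincipalFactorAnalysis(standardised_log_transform(soil),
                             variance_threshold=0.75).fit()
print(fa.labels())                      # ['Al, Mn, Fe', 'Zn, Pb, Cd']

scores = truth.exposure_scores(factor=0, seed=7)
model = JointMisalignmentModel(scores, towns, graph, adjusted=True)
result = model.fit(seed=7)
print(f"beta = {result.beta:.3f} (sd {result.beta_sd:.3f})")
print(result.rr())
```

Output from this exact run:

```
['Al, Mn, Fe', 'Zn, Pb, Cd']
beta = 0.193 (sd 0.030)
RRSummary(rr=1.213407944103485, ci_low=1.1438697953852939, ci_high=1.2871734569383453, excludes_one=True)
```

The factor analysis recovers the two planted element associations; the
joint fit estimates β̂ = 0.193 against a simulated truth of 0.2, i.e. a
relative risk of about 1.21 per unit of factor score, with an interval
that (correctly) excludes 1.

The same pipeline runs from the shell on CSV inputs (the synthetic
scenario carries six elements, so the log pipeline is shown — clr opening
removes one rank and leaves less common variance for the 75% rule):

```sh
soilrisk simulate --seed 7 --out scenario/
cd scenario
printf 'transform: log\n' > config.yaml
soilrisk run --config config.yaml          # transform -> factors -> fits -> report
```

which writes `output/rr_report.csv` (one row per model variant, endpoint,
sex and factor, with RR, its 95% interval and the `excludes_one` flag),
`output/factor_labels.txt` and a `manifest.json` recording per-stage
status, input digests and the seed.

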