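# sarmap

Small-area disease mapping of hospital-admission risk: indirect
standardization, Bayesian CAR smoothing, and spatial cluster detection for
census-tract admission counts.

## The problem

Urgent admission counts aggregated to census tracts (the smallest
administrative population unit, often ~1,000–1,500 inhabitants) are too
noisy to map directly: a tract with 2 expected and 4 observed admissions
doubles its rate by chance. The standard chain for such data — used
throughout spatial epidemiology for outcomes like ischemic-heart-disease
admissions — is:

1. **Indirect standardization.** Area-wide age-specific rates
   r<sub>g,s</sub> = Σ<sub>i</sub> O<sub>igs</sub> / Σ<sub>i</sub> n<sub>igs</sub>
   give expected counts E<sub>is</sub> = Σ<sub>g</sub> n<sub>igs</sub> r<sub>gs</sub>
   and the standardized admission ratio **SAR = 100·O/E** per tract and sex.
2. **Bayesian smoothing.** O<sub>i</sub> ~ Poisson(E<sub>i</sub>θ<sub>i</sub>)
   with log θ<sub>i</sub> = α + u<sub>i</sub> + v<sub>i</sub>, where u is an
   intrinsic CAR (ICAR) field over the tract contiguity graph and v is iid
   noise (the BYM model; iCAR-only, Leroux and no-spatial variants are
   available and compared by DIC/WAIC). The posterior mean of 100·θ is the
   **smoothed relative risk (SRR)** and **PP = P(θ > 1 | data)** is the
   exceedance probability, with PP ≥ 0.8 flagging a significant excess.
3. **Joint male/female model.** A shared-component model
   log θ<sub>i,m</sub> = α<sub>m</sub> + κδ<sub>i</sub> + v<sub>i,m</sub>,
   log θ<sub>i,f</sub> = α<sub>f</sub> + δ<sub>i</sub>/κ + v<sub>i,f</sub>
   pools the common risk geography across sexes.
4. **Cluster detection.** Global Moran's I and Anselin's local Moran
   (LISA) on the SRR surface, with permutation inference, classify tracts
   into high-high/low-low clusters and high-low/low-high spatial outliers.

Inference is Metropolis-within-Gibbs MCMC (colour-blocked adaptive
random-walk updates for the fields, conjugate gamma updates for
precisions), deterministic for a fixed seed. Real admission registries are
not redistributable, so the package ships a synthetic generator whose
`asturias-like` preset emulates an urban-industrial Spanish study area:
558 tracts averaging 1265 inhabitants, ~3,218 admissions over 3 years
split 64.42/35.58 male/female, and ~1% geocoding failure. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import sarmap as sm

study = sm.asturias_like(seed=7)                     # synthetic 558-tract study
std = sm.standardize(study.counts, study.population) # O, E, SAR per tract x sex

male = std[std.sex == "male"]
print(f"male SAR > 100 in {sm.threshold_summary(male['SAR'], 100, 'above'):.2f}% of tracts")

model = sm.CARModel.from_dataframe(std, study.graph, sex="male", model="bym")
res = model.fit(n_iter=2000, burnin=1000, chains=2, seed=7)
print(res.summary())

w = sm.make_weights(study.graph)
print(sm.morans_i_test(res.srr, w, n_perm=999, seed=7))
```

prints

```
male SAR > 100 in 43.91% of tracts
Spatial Poisson model (bym prior), 558 tracts
MCMC: 2 chains x 2000 iterations (burn-in 1000, thin 1, seed 7)
DIC = 2253.65 (p_D = 151.09); WAIC = 2264.76 (p_WAIC = 131.50)
Tracts with PP >= 0.8: 92

param    mean      sd    q2.5  median   q97.5
alpha -0.1238  0.0282 -0.1778 -0.1234 -0.0690
tau_u  2.5654  0.9671  1.3508  2.3411  4.9596
tau_v 37.2130 25.0697  9.7125 32.9803 94.2806
Moran's I = 0.7171 (E[I] = -0.0018), z = 32.52, p = 0.001 [permutation]
```

Reading this: about 44% of tracts sit above the area-wide admission level
before smoothing; after BYM smoothing 92 of 558 tracts (16%) keep a
significant excess (PP ≥ 0.8); the smoothed risk surface is strongly
spatially autocorrelated (I = 0.72 against a null expectation of ≈ 0),
so the excess admissions cluster geographically rather than scattering.
`res.to_frame()` gives the per-tract table (SRR, credible interval, PP),
`sm.lisa(res.srr, w)` the cluster classification, and
`sm.SharedComponentModel.from_dataframe(std, study.graph).fit()` the joint
male/female fit.

The same chain runs from the shell:

```bash
sarmap pipeline --preset asturias-like --seed 7 --out-dir out/
sarmap simulate --rows 15 --cols 15 --mean-pop 1265 --seed 1 --out-dir sim/
sarmap standardize --counts sim/counts.csv --population sim/population.csv --out sim/sar.csv
sarmap smooth --model bym --counts sim/sar.csv --adjacency sim/adjacency.gal --out-prefix sim/srr
sarmap cluster --values sim/srr_male.csv --adjacency sim/adjacency.gal --out-prefix sim/cl
```

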