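# gwnr — geographically weighted nonparametric regression and its fit test

`gwnr` is a small toolkit for spatial regression problems — poverty rates
across districts, infant mortality across municipalities — where the
relationship between predictors and the response is neither linear nor the
same everywhere. It combines two ideas:

1. **A mixed nonparametric basis.** Each predictor enters either as a
   truncated power spline (for smooth, possibly kinked trends) or as a
   Fourier cosine series (for oscillating patterns). For spline predictors
   of degree *M* with knots *t₁ < … < t_R* the component is
   `β₁x + … + β_M x^M + Σ_r β_{M+r}(x − t_r)₊^M`; for periodic predictors
   with *H* harmonics it is `½θ₀ + γz + Σ_h θ_h cos(hz)`. Stacking all
   components gives one design matrix **Q\*** of width
   `m = 2 + P(M+R) + Q(1+H)` shared by every model below.

2. **Geographical weighting.** The *global* model (MNR, mixed nonparametric
   regression) fits one coefficient vector η by least squares, with hat
   matrix **L**. The *local* model (GWNR) re-fits the entire coefficient
   vector at every location *(uᵢ, vᵢ)* by weighted least squares,
   `η̂(uᵢ,vᵢ) = (Q*ᵀW(uᵢ,vᵢ)Q*)⁻¹Q*ᵀW(uᵢ,vᵢ)y`, with kernel weights that
   decay with distance from location *i*. Row-stacking the local predictors
   gives the GWNR hat matrix **G**.

The question the package answers is: **is the spatially varying fit
significantly better than the global one?** The test statistic is

```
F₁* = { yᵀ[(I−L) − (I−G)ᵀ(I−G)]y / τ₁ } / { yᵀ(I−G)ᵀ(I−G)y / γ₁ }
```

with `γᵢ = tr(((I−G)ᵀ(I−G))ⁱ)` and `τᵢ = tr(((I−L) − (I−G)ᵀ(I−G))ⁱ)`.
Neither quadratic form is exactly chi-square, so each is approximated by a
Satterthwaite-matched scaled chi-square, giving the F reference distribution
with non-integer degrees of freedom `df₁ = τ₁²/τ₂` and `df₂ = γ₁²/γ₂`; H₀
(no spatial variation) is rejected when F₁* exceeds the upper-α F quantile.
The unbiased error-variance estimate is `σ̂² = SSE_GWNR/γ₁`.

Because no public dataset accompanies the method, the package ships a
first-class synthetic-data generator (`gwnr.simulate`) that draws spatial
units on the unit square, builds the mean from the same mixed basis with
constant (H₀) or smoothly varying (H₁) coefficient surfaces, and adds iid
Normal errors — so every stage is testable end to end.

## Worked example

Generate a dataset with strongly varying coefficient surfaces, then test
whether the geographically weighted model is warranted:

```bash
cat > scenario.yml <<'EOF'
n: 60
seed: 23
bandwidth: 0.5
coefficient_mode: varying
surface_amplitude: 3.0
EOF
gwnr simulate --scenario scenario.yml --out data.csv

cat > config.yml <<'EOF'
data: data.csv
response: y
spline: [x1, x2]
fourier: [z1, z2]
u: u
v: v
bandwidth: 0.5
alpha: 0.05
outdir: report
verbosity: WARNING
EOF
gwnr test --config config.yml
```

which prints:

```
SSE_MNR=715.232  SSE_GWNR=397.551
F1*=4.0393  F(0.05; 19.70; 48.01)=1.7973  p=3.986e-05
reject H0: GWNR fits significantly better
```

Reading: the global model leaves an error sum of squares of 715.2; letting
the coefficients vary over space cuts it to 397.6. Normalized by the trace
degrees of freedom (df₁ = 19.70 for the improvement, df₂ = 48.01 for the
local residual), that improvement is 4.04 times larger than expected under
H₀ — far above the 5% critical value 1.80 — so the spatial heterogeneity is
real. `gwnr fit --config config.yml` additionally writes one fitted
coefficient vector per location (`report/local_coefficients.csv`) and the
scalar summary `σ̂² = 9.34`. A null scenario shows the other side:

```
gwnr mc --scenario null.yml --reps 200
rejection rate = 0.0200 (binomial SE 0.0099), degenerate replicates = 0
```

Under constant coefficients the test rejects rarely — in fact somewhat
below the nominal 5% (see `docs/methods.md` for why the test is
conservative).

## Library use

```python
from gwnr import SimulationScenario, gen_dataset, fit_gwnr, fit_mnr, gof_test

scn = SimulationScenario(n=60, seed=23, coefficient_mode="varying", surface_amplitude=3.0)
data, truth = gen_dataset(scn)
gwnr_fit = fit_gwnr(data, scn.spec)
mnr_fit = fit_mnr(data.y, gwnr_fit.design)
result = gof_test(data.y, mnr_fit, gwnr_fit, alpha=0.05)
print(result.f_stat, result.df1, result.df2, result.p_value, result.reject_h0)
```

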