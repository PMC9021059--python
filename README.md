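# yonezawa

Modelling and quantification of the **Raper–Yonezawa (priming-dose) effect**,
a special case of the radiation adaptive response: a small *priming* dose
D₁ of ionizing radiation, delivered some hours before a large *challenging*
dose D₂, can reduce the DNA lesions or mutations the challenge produces.
The package is aimed at radiobiologists and biophysicists who want to
quantify two-dose (or multi-dose) fractionation experiments, fit the model
to chromosome-damage data, and predict the effect for planned dose schemes.

## The model

A short pulse of dose D received t hours ago triggers successful
adaptive-response repair at the hunchbacked probability rate

```
p_AR(D, t) = α₀ D² t² exp(−α₁ D − α₂ t)        [h⁻¹]
```

with three positive parameters: an amplitude α₀ [Gy⁻² h⁻³], a dose decay
α₁ [Gy⁻¹] (response maximal at D = 2/α₁) and a time decay α₂ [h⁻¹]
(response maximal at t = 2/α₂).  Lesions decay as dN = −N p_AR dt, which
integrates in closed form through

```
f(D, t) = (α₀/α₂³) D² e^(−α₁D − α₂t) [(α₂t)² + 2α₂t + 2],    f(D, ∞) = 0,
ξ_D = f(D, 0) = 2 (α₀/α₂³) D² e^(−α₁D)
```

so a single pulse leaves N(T) = N₀ e^(f(D,T) − ξ_D) unrepaired lesions —
never zero: N(∞) = N₀ e^(−ξ_D).  The effect size of a priming scheme is

```
δ = 1 − N₁₊₂ / N₂
```

the fractional reduction of damage relative to the challenge alone.  For
direct lesions observed at finite time T (with 0 < Δt < T),

```
δ = 1 − e^(f(D₁,T) − f(D₁,Δt)) − (D₁/D₂) e^(f(D₁,T) − ξ_D₁)
```

and for stable mutations (T → ∞)

```
δ = 1 − e^(−f(D₁,Δt)) − (D₁/D₂) e^(−ξ_D₁).
```

δ > 0 is the protective (Yonezawa) effect; for large Δt the effect
disappears and δ falls to its negative asymptote δ_min = −(D₁/D₂) e^(−ξ_D₁).
Closed forms for two priming doses, n identical priming doses ("radiation
training"), discrete pulse schedules and chronic constant-rate exposure are
included.

The α parameters are estimated from experiment records by least squares on
δ, with two interchangeable optimisers — bounded quasi-Newton (L-BFGS-B)
multistart and a simplified genetic algorithm — plus Poisson worst-case
uncertainty bounds.  The package bundles the published calibration records:
41 two-dose observations (chromatid breaks and chromosome aberrations in
human lymphocytes; chromosomal inversions in mouse prostate and spleen).

## Worked example

```python
import yonezawa as yz

# abstract-unit example: alpha = (1, 1, 0.7), D1 = 1, D2 = 5, interval 3
p = yz.AdaptiveResponseParams(1.0, 1.0, 0.7)
res = yz.delta_mutations(p, d1=1.0, d2=5.0, dt=3.0)
print(round(res.delta, 3), res.yonezawa_effect)   # 0.728 True

# fit the bundled lymphocyte lesion records (23 two-dose observations)
model = yz.AdaptiveResponseModel.from_bundled("shadley_lesions")
fit = model.fit(method="lbfgsb")
print(fit.summary())
```

```
Adaptive-response model fit
==============================================
endpoint:   lesions
records:    23  (source: shadley_lesions)
method:     lbfgsb
SSR:        0.207716
restarts:   125 kept / 0 discarded
----------------------------------------------
alpha0         22.947  [Gy^-2 h^-3]
alpha1         79.455  [Gy^-1]
alpha2       0.083237  [h^-1]
----------------------------------------------
response maximal at D = 0.02517 Gy, t = 24.03 h
```

The priming dose of a two-dose scheme protects a 1 Gy-order challenge most
strongly here at D₁ = 2/α₁ ≈ 25 mGy given 2/α₂ ≈ 24 h before it — a
δ ≈ 0.728 means the primed cells show ~73% fewer mutations than unprimed
ones.  The same interface works from the shell:

```sh
yonezawa delta --scheme mutations --alpha0 1 --alpha1 1 --alpha2 0.7 \
    --d1 1 --d2 5 --dt 3
# delta = 0.728384  (yonezawa_effect=True)
yonezawa fit shadley_lesions --method lbfgsb
yonezawa datasets --validate
```

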