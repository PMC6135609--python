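# parpflow

Kinetic modelling of how PARP1 — the nuclear first responder to DNA damage —
binds and, crucially, *releases* DNA. PARP1 associates with double-strand
breaks at an essentially diffusion-limited rate, which creates a paradox: a
protein that grabs DNA that fast and lets go that slowly could never scan a
nucleus full of DNA it also binds. The resolution is intersegment transfer
(the "monkey bar" mechanism): a second DNA molecule binds the protein–DNA
complex first, forming a transient ternary complex, and only then is the
original DNA released. `parpflow` implements the mass-action kinetics of this
system, simulates the stopped-flow fluorescence-anisotropy experiments used to
measure it, and fits and discriminates the candidate mechanisms.

The package is aimed at kineticists who want to reproduce, extend, or
stress-test this analysis: every published rate constant can be re-derived by
simulating the corresponding experiment at the published truth and re-fitting
it from scratch.

## Models

Three reaction schemes, in nM and seconds throughout (P = free PARP1,
D\* = labeled probe DNA, D = unlabeled competitor DNA):

1. **Association** — P + D\* ⇌ PD\* (k₁, k₋₁). Observed as an anisotropy rise
   over 25 ms; under protein excess k_obs = k₁[P] + k₋₁.
2. **Simple competition** — PD\* → P + D\* (k₋₁) with irreversible competitor
   capture P + D → PD (k₁′[D] ≫ k₋₁). Release is rate-limiting, so k_obs is
   independent of competitor concentration.
3. **Ternary complex** — PD\* + D ⇌ D\*·P·D (k₂, k₋₂); D\*·P·D ⇌ PD + D\*
   (k₃, k₋₃). Probe release requires prior competitor binding, so k_obs rises
   with competitor, approaching k₃ with half-saturation at
   K = (k₋₂ + k₃)/k₂.

The observable is anisotropy r(t) = r_free + (r_bound − r_free)·([PD\*] +
[T])/[D\*]_total: the ternary complex carries the bound (high) signal.
Wild-type PARP1 and the Zn-domain deletions follow scheme 3; deleting the WGR
domain (or the single point mutation W589A) removes the second DNA-binding
site and collapses release to scheme 2.

## Worked example

Simulate the wild-type dissociation experiment (37 nM PARP1 pre-bound to
25 nM labeled 18-mer, mixed with six competitor concentrations from 76 nM to
4 µM) and re-fit the ternary-complex constants:

```python
import parpflow as pf

wt = pf.get_preset("WT")
series = pf.simulate_preset_series("WT", "dissociation", seed=123)
fit = pf.global_fit(series, "ternary", fixed_params=wt, n_starts=6, seed=123)
print({k: round(v, 4) for k, v in fit.free_values().items()})
print(f"chi2 = {fit.chi2:.4f} over {fit.n_data} points")
```

```
{'k2': 0.045, 'k_m2': 107.3097, 'k3': 9.7248, 'k_m3': 0.013}
chi2 = 0.0506 over 3000 points
```

The generating truth was k₂ = 0.043 nM⁻¹s⁻¹, k₋₂ = 102 s⁻¹, k₃ = 9.7 s⁻¹,
k₋₃ = 0.013 nM⁻¹s⁻¹: a single noisy series recovers each constant to within
its published replicate spread, and the chi-square matches the injected noise
floor (3000 × 0.0041² ≈ 0.05). Mechanism discrimination on the same data:

```python
cmp = pf.compare_schemes(series, base_params=wt, seed=123)
print(cmp.verdict)
```

```
preferred mechanism: ternary; delta_AIC = 13381.7 (decisive); kobs increases
with competitor (slope p = 0.00065, significant)
```

The same pipeline is available from the shell:

```bash
parpflow simulate --preset WT --design dissociation --seed 123 --out runs/wt
parpflow fit runs/wt --scheme ternary --preset WT
parpflow compare runs/wt --preset WT
parpflow recover --preset W589A --n 10 --seed 7 --out runs/w589a
```

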