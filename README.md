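# oralbe

**Oral bioequivalence assessment: dissolution similarity, Caco-2
permeability, and mechanistic absorption/PBPK virtual trials.**

`oralbe` is a Python library for the in vitro → in silico workflow used to
compare oral drug formulations — in particular single-drug versus
fixed-dose-combination (FDC) immediate-release tablets, built around the
amlodipine (5 mg) + atorvastatin (10 mg) antihypertensive/statin
combination under fasted and fed conditions. It is aimed at
biopharmaceutics and pharmacometrics scientists who want a transparent,
fully scriptable alternative to closed simulator workflows.

Four capabilities, one per module group:

1. **Dissolution** (`oralbe.dissolution`) — sampling-withdrawal-corrected
   cumulative release, Weibull/first-order/tabulated release models, and
   the regulatory difference/similarity factors

       f1 = 100 · Σ|R_t − T_t| / ΣR_t
       f2 = 50 · log10(100 / √(1 + (1/n) Σ(R_t − T_t)²))

   with the f1 < 15 / f2 > 50 similarity rule and the >85%-in-15-min
   biowaiver condition.

2. **Caco-2 transport** (`oralbe.caco2`) — TEER, sampling-corrected
   cumulative mass transfer, apparent permeability
   Papp = (dQ/dt)/(C₀·A), efflux ratio Papp(B→A)/Papp(A→B), mass balance.

3. **Gut absorption** (`oralbe.gut_absorption`) — a compartmental
   absorption-and-transit model (stomach, 7 small-intestine segments,
   colon) driven by the measured dissolution kinetics, with
   permeability-limited uptake (ka = 2·Peff/r), enterocyte CYP3A4
   metabolism on an aborally decreasing abundance gradient, saturable
   P-gp efflux on an increasing gradient, and full mass accounting:
   fa, fg and their regional decompositions.

4. **Virtual trials** (`oralbe.trial_engine`) — a minimal PBPK disposition
   model (well-stirred liver + central compartment, F_oral = fa·fg·fh by
   construction), log-normal virtual populations, bioequivalence-style PK
   summaries (geometric-mean Cmax, median AUC/tmax), Welch t-tests and
   GMR diagnostics, and bounded multi-start parameter estimation.

`oralbe.synthetic_data` generates every input with known ground truth
(dissolution replicates at the observed plateaus, monolayer flux runs with
sampling/replacement, plasma profiles, populations), and `oralbe.studies`
packages the end-to-end verification workflows. Compound files for
amlodipine and atorvastatin ship as YAML presets.

## Worked example

```python
from oralbe.compound import load_compound
from oralbe.synthetic_data import dose_event_for
from oralbe.gut_absorption import build_physiology, simulate_gut

atorvastatin = load_compound("atorvastatin")
dose = dose_event_for(atorvastatin, "single")     # 10 mg, preset release curves

for state in ("fasted", "fed"):
    r = simulate_gut(atorvastatin, dose, build_physiology(state))
    print(f"{state}: fa={r.fa:.3f} fg={r.fg:.3f} "
          f"gut-metabolized={r.fraction_metabolized:.3f}")
```

prints

```
fasted: fa=1.000 fg=0.224 gut-metabolized=0.776
fed: fa=0.973 fg=0.355 gut-metabolized=0.627
```

Fasted, atorvastatin dissolves fast and is absorbed proximally, where
enterocyte CYP3A4 density is highest: 78% of the absorbed dose is lost in
the gut wall (fg 0.22, close to the literature assumption fg ≈ 0.24). Fed,
slower gastric emptying and much slower dissolution push absorption
distally, where CYP3A4 density is lower — fg rises to 0.36, which is the
mechanism behind the higher fed-state exposure of atorvastatin despite a
nominally "worse" fed dissolution profile. Narrative scripts for each
capability live in `examples/` (dissolution comparison, permeability,
food-effect mechanism, virtual trial, parameter fitting).

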