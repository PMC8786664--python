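# chloroflux

Analysis of transient ¹³C-labelling experiments in photosynthetic
micro-organisms: mass-isotopomer processing, enrichment kinetics, carbon-flux
estimators and desk-scale isotopically non-stationary metabolic flux analysis
(INST-MFA).

## The problem

Green microalgae such as *Chlorella ohadii* fix CO₂ at extreme rates, and the
question of where that carbon goes — starch, sucrose, protein, lipid, the TCA
cycle via PEP carboxylase — can be answered by switching a culture to
¹³C-labelled inorganic carbon and following the mass-isotopomer distributions
(MIDs) of central metabolites over seconds to hours.  At metabolic steady
state the labelling dynamics of a metabolite pool of size `P` fed by fluxes
`v_r` obey

    P · dX/dt = Σ_r v_r (source_r − X)

where `X` is the pool's MID and `source_r` the MID delivered by reaction `r`
through its carbon atom map.  `chloroflux` implements this forward model twice
— exhaustively over all positional isotopomers (the oracle) and via
elementary-metabolite-unit (EMU) decomposition (the engine) — and builds the
surrounding analysis: natural-abundance correction of measured MIDs,
enrichment (Σᵢ i·mᵢ/n) kinetics with gap-statistic clustering and classical
MDS, the standard flux estimators (minimum ¹³C assimilation, minimum PEPC
flux, end-product synthesis rates from enrichment × pool slopes, starch
¹²C/¹³C turnover, protein synthesis from bound vs free amino-acid labelling),
and multi-start least-squares flux fitting with χ² goodness of fit and
confidence intervals.

It is written for researchers in photosynthetic carbon metabolism who want a
tested, scriptable pipeline from delimited MID tables to flux estimates, with
a synthetic-data generator that stands in for the instrument.

## Worked example

Fit the toy Calvin–Benson network to a simulated noisy short-pulse experiment
(the `analysis/` scripts run the full narrative; here is the core):

```python
import numpy as np, pandas as pd
from chloroflux import builtin_network, simulate_labeling, add_noise, fit
from chloroflux.simulate import mid_table
from chloroflux.mfa import MeasuredMIDs

net = builtin_network("cbc_toy")            # balanced, atom-mapped, 50% 13C input
times = [5.0, 10.0, 20.0, 40.0]
sim = simulate_labeling(net, times)         # EMU forward model
tables = [mid_table(add_noise(sim, 0.005, seed=s), replicate=s)
          for s in (1, 2, 3)]
meas = MeasuredMIDs.from_table(pd.concat(tables), min_sd=0.001)

rng = np.random.default_rng(1)
anchors = {r: (net.fluxes[r], 0.05 * net.fluxes[r]) for r in ("sts", "sps")}
pools = {m: (p, 0.10 * p) for m, p in net.pools.items()}
res = fit(net, meas, restarts=10, seed=1,
          rate_measurements=anchors, pool_measurements=pools)
print(res.fluxes["rbc"], res.flux_ci["rbc"])
```

Running `analysis/05_inst_mfa.py` on the seeded synthetic experiment prints:

```
reaction   flux  ci_lo  ci_hi   true  covered
     rbc 0.2996 0.2808 0.3184 0.3000     True
     pgk 0.5606 0.5278 0.5933 0.5600     True
     ...
SSR 70.9 on 226 d.f. -> chi-square verdict: reject
(rejection is on the low side: the conservative max-over-channels replicate
errors overstate the noise)
true fluxes inside 95% CI: 14/14
```

i.e. the carboxylation flux (`rbc`, truth 0.30 µmol g⁻¹ DW s⁻¹) is recovered
to ~0.1% with a CI that covers the truth, as do all 14 net fluxes; the χ²
verdict flags that the replicate-based error model is conservative for this
synthetic noise.  `analysis/04_flux_estimates.py` likewise recomputes the
published derived starch columns — e.g. net starch accumulation
59 nmol C g⁻¹ DW s⁻¹ and 6.28% ¹²C supply from starch for *C. ohadii* in low
light — exactly from the primary synthesis/degradation/assimilation columns.

The analysis sequence (`analysis/01…05`) generates the synthetic experiment,
corrects and extracts enrichments, runs the kinetics/clustering/MDS stage,
computes the flux estimators and fits the network; each script writes its
tables under `results/`.

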