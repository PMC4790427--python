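# cumoflux

Bonded-cumomer ¹³C metabolic flux analysis of brain energy metabolism.

`cumoflux` is for researchers doing dynamic in vivo ¹³C MRS of the brain who
want to turn labeling time courses of glutamate and glutamine — including
their multiplet fine structure — into quantitative metabolic fluxes. It
implements a two-compartment neuronal–glial network model of
[1,6-¹³C₂]glucose infusion, forward-simulates the ¹³C labeling of every
NMR-observable multiplet, and estimates the seven free fluxes from measured
(or synthetic) curves with Monte-Carlo uncertainty, flux-correlation and
sensitivity analysis.

## The model in brief

A cumomer fraction π_M{i} is the fraction of molecules of pool M labeled at
least at carbon set {i}. *Bonded* cumomers of order ≤ 3 (adjacent carbons
only) carry exactly the information of one-bond ¹³C–¹³C couplings, so the
observable multiplets are linear images of them, e.g. for GluC4:

    Q   = π{3,4,5}              D43 = π{3,4} − π{3,4,5}
    D45 = π{4,5} − π{3,4,5}     S   = π{4} − π{3,4} − π{4,5} + π{3,4,5}

Each cumomer obeys a mass-action balance P·dπ/dt = Σ V·(product of source
cumomer fractions) − (Σ V_out)·π over the atom-mapped reaction network
(glycolysis, both TCA cycles with fumarate scrambling, pyruvate carboxylase
with CO₂ refixation, the glutamate/glutamine neurotransmission cycle, and
dilution fluxes). For the canonical network this yields a 133-equation ODE
system; its exact order-1 reduction is the classical positional
(total-enrichment) model. Free fluxes (µmol/g/min): neuronal TCA `vpdh_n`,
glial TCA `vg`, pyruvate carboxylase `vpc`, amino-acid/TCA exchange `vx`,
neurotransmission `vnt`, glial acetyl-CoA dilution `vdil`, lactate outflow
`vout`; derived: VTCA_g = vg + vpc, Vsyn = vnt + vpc,
CMRglc_ox = (vpdh_n + vg + vpc)/2.

Every simulation can be cross-checked against a brute-force full-isotopomer
oracle (every 2ⁿ labeling state integrated explicitly) that shares no code
with the compiled cumomer engine; the two agree to better than 10⁻⁶.

## Worked example

Fit the bonded-cumomer model to a noiseless synthetic 17-curve dataset
(`python examples/02_fit_fluxes.py`):

```
dataset: 17 curves x 17 time points
converged: True   weighted SSE: 3.75e-13

flux        estimate     truth   µmol/g/min
vpdh_n        0.4000    0.4000
vg            0.1000    0.1000
vpc           0.0600    0.0600
vx            0.4500    0.4500
vnt           0.1000    0.1000
vdil          0.3000    0.3000
vout          0.3000    0.3000

derived: VTCA_g = 0.1600   Vsyn = 0.1600   CMRglc_ox = 0.2800
```

The estimator is an exact fixed point of the forward model: every flux
returns to its generating value, and the derived oxidative glucose
consumption CMRglc_ox = (0.40 + 0.10 + 0.06)/2 = 0.28 µmol/g/min.

Adding the study's noise model (5% relative SD on totals, 15% on
multiplets) and running 25 Monte-Carlo replicates per model variant
(`python examples/03_monte_carlo.py`):

```
flux         SD bonded  SD positional
vx              0.0630         0.1086
vnt             0.0059         0.0078
vdil            0.0589         0.0979
...
bonded: corr(vnt, vdil) = +0.48
positional: corr(vnt, vdil) = +0.55
```

Including the multiplet curves narrows the spread of the glial dilution
flux `vdil` and weakens its correlation with the neurotransmission flux
`vnt` — the methodological payoff of the bonded-cumomer model: the GlnC4
singlet and doublet respond in opposite directions to `vnt`
(`python examples/04_sensitivity_scan.py`), separating effects that total
enrichment averages away.

The same pipeline is available from the shell:

```sh
cumoflux simulate --variant bonded --out ds.csv
cumoflux fit ds.csv --out fit.json
cumoflux mc ds.csv --n-mc 500 --out mc.json
cumoflux report mc.json
```

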