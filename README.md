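# epstitrate

Potentiometric titration analysis of the proton-binding sites of microbial
exopolymeric substances (EPS).

Microbial-mat EPS carry acidic functional groups — carboxyl, phosphoryl,
amine, hydroxyl — whose density governs how the organic matrix binds
cations and, in dolomite-forming mats, provides nucleation sites for
carbonate precipitation. Those site densities are measured by acid–base
titration: a small mass of purified EPS in dilute KCl is dosed stepwise
with HCl or NaOH while pH is recorded, and the curve is inverted into the
concentrations of discrete monoprotic ligands. `epstitrate` implements
that inversion end to end, together with a charge-balance simulator that
generates ground-truthed synthetic titrations so every stage can be
verified quantitatively.

## Model

At each titrant addition *j* the net titratable charge of the EPS (the
**charge excess**) follows from the proton balance and is modelled as a
sum of *n* independent monoprotic ligands on a pKa grid plus a constant
offset:

```
Cb_j − Ca_j + [H+]_j − [OH−]_j = Σ_{i=1..n}  Ka_i · L_Ti / (Ka_i + [H+]_j)  +  S
```

* `Ca_j`, `Cb_j` — dilution-corrected acid and base concentrations,
* `[H+]_j = 10^(−pH_j)` (optionally Davies-corrected), `[OH−]_j = Kw/[H+]_j`,
* `Ka_i = 10^(−pKa_i)` and `L_Ti ≥ 0` — acidity constant and total
  concentration of ligand class *i* (mol per gram EPS after normalising
  the left side by `V_total/m`),
* `S` — the constant acid-neutralization capacity of the surface.

The spectrum `{L_Ti}, S` is recovered by the classical **linear
programming method (LPM)**: minimise the sum of absolute residuals
subject to `L_Ti ≥ 0` over a fixed pKa grid (4–10 in 0.2-unit steps, 31
candidate sites), linearised with per-point slack variables and solved by
HiGHS. Fitted sites are binned into functional-group classes — carboxyl
(pKa 3–5.8), phosphoryl (6–8), amine (8–9), hydroxyl (9–10) — and
replicate runs are aggregated to `mean ± sd` in mMol per gram EPS.

## Worked example

`examples/simulate_and_fit.py` titrates the carboxyl-rich "october-like"
ground truth in silico without noise and inverts the curve:

```
titration points: 81, pH span 3.50-10.50
solver: optimal, sum|residual| = 1.52e-13 mol/g

recovered sites (pKa, L_T mmol/g):
   4.4  0.200
   5.2  0.261
   6.8  0.260
   8.4  0.721
  S = 0.0100 mmol/g

class          truth   fitted   (mmol/g)
Carboxyl       0.461    0.461
Phosphoryl     0.260    0.260
Amine          0.721    0.721
Hydroxyl       0.000    0.000
unassigned     0.000    0.000
```

With clean data the LPM inversion recovers every site and the intercept
exactly (residuals at solver precision). `examples/functional_group_report.py`
runs the same pipeline on noisy triplicates of two seasonal compositions
and prints the replicate-aggregated table:

```
Functional Group  pKa Range  march-like                october-like
                             Average L_T (mMol/g EPS)  Average L_T (mMol/g EPS)
----------------  ---------  ------------------------  ------------------------
Carboxyl          3–5.8      0.118 ± 0.006             0.496 ± 0.030
Phosphoryl        6–8        0.175 ± 0.038             0.256 ± 0.012
Amine             8–9        0.816 ± 0.038             0.710 ± 0.019
Hydroxyl          9–10       0.002 ± 0.006             0.007 ± 0.013
```

The `± sd` columns show how electrode noise (sd 0.02 pH) and 0.5% dosing
noise propagate into class totals; the means sit within a few percent of
the simulated truths (carboxyl 0.113 and 0.461 mmol/g).
`examples/qc_agreement.py` prints the forward-vs-reverse and
measured-vs-modelled QC metrics.

## Command line

The same pipeline is available as a thin CLI:

```bash
epstitrate simulate --preset october-like --seed 1 --out sim/
epstitrate fit sim/curves.csv --config config.yaml --out fit/
epstitrate qc  sim/curves.csv --config config.yaml --out qc.json
epstitrate summarize fit/ --out summary
```

`config.yaml` needs at least `vessel: {eps_mass: 0.050}`; `grid`,
`scheme`, `fit` and `qc` keys override the defaults documented in
`docs/methods.md`. Curves travel as CSV
(`sample_id,replicate_id,direction,acid_volume_L,base_volume_L,pH`),
spectra as TSV, diagnostics and QC as JSON; identical seeds give
byte-identical outputs.

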