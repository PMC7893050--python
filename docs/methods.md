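# Methods

## The charge-excess model

A potentiometric titration dispenses strong acid (HCl) or strong base
(NaOH) into a vessel containing a known dry mass *m* of purified EPS in
dilute KCl, recording pH after each addition. Because every species in
the vessel other than the EPS is fully speciated, the proton balance
isolates the charge held by the EPS. At point *j*:

```
Q_j = (Cb_j − Ca_j + [H+]_j − [OH−]_j) · V_j / m        [mol g⁻¹]
```

`Ca_j = C_HCl·Va_j/V_j` and `Cb_j = C_NaOH·Vb_j/V_j` are the titrant
concentrations corrected for dilution by the cumulative added volume
(`V_j = V0 + Va_j + Vb_j`); this correction is not optional at these
volumes — 0.1 M acid dosed into 5 mL changes the total volume by tens of
percent over a run. `[H+]_j` is `10^(−pH_j)` under the default ideal
model; a Davies single-ion activity correction at the electrolyte ionic
strength (0.01 M KCl, γ ≈ 0.902, A = 0.509 at 25 °C) is available via
`VesselConfig(activity_model="davies")` for users who regard the meter
reading as an activity. `[OH−]_j = Kw/[H+]_j` with pKw = 14.0 by default
(configurable within [13, 15]). Whether the original laboratory analyses
applied either correction is generally unreported, so both are explicit
options with the parsimonious ideal/14.0 defaults.

Multiplying by `V_j/m` expresses Q per gram of EPS so that fitted ligand
concentrations are directly comparable across samples of different mass
and match the conventional reporting unit (mMol/g).

Assumptions: equilibrium at every point (no kinetic hysteresis),
carbonate-free solution (samples are degassed under N₂; no carbonate
terms), inert counter-ions, monoprotic non-interacting sites, no
electrostatic double-layer correction.

## The binding model and its LPM inversion

The EPS side of the balance is a discrete affinity spectrum:

```
Q(pH) = Σ_i Ka_i·L_Ti/(Ka_i + [H+]) + S,   Ka_i = 10^(−pKa_i),  L_Ti ≥ 0
```

Each term is the deprotonated fraction of site class *i* times its total
concentration; `S` is a constant acid-neutralization capacity, free in
sign since blank handling can offset the balance either way. Candidate
sites sit on a fixed grid, pKa 4–10 in 0.2-unit steps (31 sites). The
same 4–10/0.2 range is interpreted as both the candidate-site grid and
the default pH evaluation grid — an interpretation, since a single range
is conventionally quoted for both roles.

The fit minimises `Σ_j |Q_obs,j − Q_pred,j|` (the L1 norm — the classical
"linear programming method"; the norm itself is rarely stated alongside
the name). With slack variables `t_j` and `S = S⁺ − S⁻` this is a linear
program solved by HiGHS (deterministic, feasibility/optimality tolerance
1e-9). Fitted sites below a reporting threshold (default 1e-6 mol/g) are
zeroed to suppress LP vertex noise; the intercept is never thresholded.

Two evaluation modes exist (`fit_lpm(..., resample=...)`):

* **resampled** (default): Q is linearly interpolated onto the grid pH
  values inside the measured span (never extrapolated; duplicate pH
  readings are collapsed to their mean first). This is the conventional
  presentation but carries interpolation error of order `h²·Q″/8` for
  point spacing `h`, and gives 31 equations for 32 unknowns.
* **raw** (`resample=False`): the fit uses the measured points directly,
  truncated to the grid span. With dense noise-free data this mode is
  exact — the verification harness uses it for exact-recovery checks,
  where recovered class totals agree with truth to better than 1e-6
  mmol/g — and it is the right choice whenever the measured points
  already sample the window densely.

Degeneracy: when two near-identical pKa columns can trade mass at equal
objective the solver returns an arbitrary optimal vertex; no canonical
tie-break is attempted. All downstream reporting uses pKa-range class
sums, which are invariant to such trades — the class total, not the
per-site value, is the guaranteed quantity.

## Functional-group classes

Fitted sites are binned into carboxyl (pKa 3–5.8), phosphoryl (6–8),
amine (8–9) and hydroxyl (9–10). Intervals are half-open `[lo, hi)`, with
the upper bound included only when no following class starts there: 5.8
is carboxyl (a gap follows), 8.0 is amine and 9.0 hydroxyl (shared
boundaries go up), 10.0 is hydroxyl (last class closed). Sites in no
class (the 5.8–6 gap, or outside 3–10) are totalled under "unassigned",
so classes + unassigned always partition the spectrum total exactly. The
carboxyl class nominally starts at pKa 3, below the default fit grid;
sites there simply never arise under the default grid, and the printed
range keeps 3 for fidelity to convention.

Replicate aggregation reports the mean and sample standard deviation
(n−1 denominator; the convention behind published ± values is usually
unstated) per class in mMol/g; a single replicate reports sd as NA. Each
fitted curve (replicate × direction) counts as one replicate measurement.

## The synthetic-data generator

Ground-truthed curves are produced by inverting the same balance for pH.
At each cumulative addition the simulator solves

```
f(pH) = (Cb − Ca + [H+] − Kw/[H+]) − (Σ_i Ka_i·ℓ_i/(Ka_i+[H+]) + s) = 0
```

with `ℓ_i = L_Ti·m/V` and `s = S·m/V` the solution-phase equivalents of
the per-gram spectrum at the current volume. `f` is strictly decreasing
in pH, so the root is unique; Brent bracketing on (0, 14) plus one
analytic Newton polish drives |f| to ~1e-15 M, far below the 1e-12 M
closure the test-suite asserts. By construction, charge excess computed
from a noiseless simulated curve reproduces the forward model at the same
pH values — the two sides of the balance agree to < 1e-10 mol/g — so any
pipeline failure is attributable to the inversion, not the fixture.

**Vessel and schedules.** The default configuration mirrors standard
practice: 5 mL of 0.01 M KCl, 0.1 M HCl and 0.01 M NaOH titrants,
20–80 mg EPS (presets use 50 mg), triplicate runs in both directions. A
*forward* run adds base stepwise from the sample's natural (usually
acidic) pH; a *reverse* run first receives a constant base pre-dose and
then adds acid, sweeping back down — this keeps exactly one cumulative
titrant volume varying per curve while letting the acid leg cover the
full window. `design_schedule` chooses dose volumes by root-finding the
titrant amounts that reach pH ≈ 10.5 (base end) and ≈ 3.5 (acid end), so
simulated curves always span the 4–10 analysis window regardless of the
truth spectrum; 80 equal steps per run by default (~0.08 pH per point on
average).

**Noise model.** Additive Gaussian noise on the pH reading (default
sd 0.02, typical glass-electrode repeatability) and multiplicative
Gaussian noise on each dispensed volume (default 0.5%, autoburette
accuracy). The *dispensed* volumes are perturbed while the *nominal*
cumulative volume is recorded — as a real burette log would — so volume
noise genuinely corrupts the analysis rather than cancelling out. Error
models are never published for such runs; these defaults are
instrument-plausible and fully configurable. Randomness comes from one
`numpy` generator seeded by `(seed, replicate index)`, so replicate *k*
is identical regardless of how many replicates are requested and a fixed
seed gives byte-identical CSV output.

**Presets.** Three named scenarios: `minimal` (one pKa-6.0 site at
0.10 mmol/g, no noise — the smallest end-to-end fixture), `march-like`
(carboxyl-poor: 0.113 carboxyl / 0.149 phosphoryl / 0.845 amine mmol/g)
and `october-like` (carboxyl-rich: 0.461 carboxyl split over two sites /
0.260 phosphoryl / 0.721 amine mmol/g). The loads mirror the magnitudes
measured on hypersaline-mat EPS across seasons; they parameterise the
simulation and are not recoverable field values.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: electrode calibration error and junction
potentials, CO₂ ingress, kinetic (non-equilibrium) hysteresis,
multi-protic or electrostatically coupled sites, temperature drift, and
off-grid true pKa values (real sites are continuous; the discrete-grid
model absorbs them into neighbouring grid sites). Exact recovery on
synthetic data shows the inversion is faithful to the stated model, not
that the model is complete.

## QC diagnostics

Published quality control for such titrations is typically a visual
overlay ("good agreement"); this package quantifies it as RMSE and
maximum absolute difference of Q over the shared 0.2-unit pH grid
(forward vs reverse, replicate vs replicate) or at the measured points
(measured vs modelled), with a pass threshold defaulting to 5% of the
observed Q range. Reverse-run pH ordering is sorted ascending before
resampling. Because the shared grid is linearly interpolated, the
hysteresis metric has a discretisation floor set by point spacing —
tests asserting the ≤1e-9 mol/g no-hysteresis bound use densely dosed
(800-step) runs so that floor is negligible.

## Problem sizes and numerical choices

Verification runs use 20 random ground-truth spectra (1–5 on-grid sites,
loads 0.01–0.5 mmol/g, |S| ≤ 0.05 mmol/g) for exact recovery, 10
five-point/three-site instances against an exhaustive 51³×21
lattice-search oracle for LP optimality, and 100 noisy replicates of the
october-like preset for statistical recovery (median carboxyl-class
error, observed ≈ 4%, asserted < 10%). Exact-recovery fits run on raw
points of 100-step acid-direction runs: an acid leg from a base pre-dose
always traverses the full window, whereas a base leg starting from an
alkaline natural pH (possible when S < 0) would leave low-pKa sites
unidentifiable. Equilibrium roots are bracketed in pH ∈ (0.001, 13.999);
configurations whose balance has no root there (e.g. titrant
concentrations beyond the bracket) raise a configuration error rather
than returning a clamped value. All serialized numbers carry 6
significant digits, making repeated seeded runs byte-identical.

## Known limitations

* Monoprotic, non-interacting sites only; no NICA-Donnan or continuous
  regularised spectra.
* No electrode calibration, junction-potential or CO₂ corrections.
* The L1/LP estimator returns a vertex solution; per-site values near
  degenerate grid neighbours are reported as-is and only class sums are
  stable.
* The Davies correction uses the fixed electrolyte ionic strength; ionic
  strength drift from the titrants themselves is neglected (< 10% here).
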