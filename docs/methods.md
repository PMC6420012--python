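# Methods

## The assay

Cells at steady state carry an NAD+ pool that is continuously synthesized
from nicotinamide (Nam) through the salvage pathway (Nampt, then NMNAT) and
continuously consumed by NAD+-degrading enzymes (PARPs, sirtuins, CD38),
which release Nam back.  Replacing the medium Nam with the same
concentration of ring-deuterated d4-Nam starts a labeling clock: salvage
synthesis now produces M+3-labeled NAD+ (one ring deuterium is lost during
redox cycling of the nicotinamide moiety, so d4-Nam yields d3-NAD+, and no
d4-NAD+ species exists), while the pre-existing d0-NAD+ pool decays.

Over a labeling window `t` (hours), with `a` the d3-NAD+ appeared and `b`
the d0-NAD+ lost (both pmol per 10^6 cells):

    R_S = a / t          synthesis rate
    R_B = b / t          breakdown rate

Per-cell amounts convert to absolute intracellular concentrations through
the mean single-cell volume `V` (pL, from a Coulter-type counter):
pmol per 10^6 cells divided by pL is exactly uM, because 10^6 cells x 1 pL
= 1 uL and pmol/uL = uM.  No unit constants enter anywhere.

### Half-life

Breakdown is modeled as first-order in the pool (`j_B = k_B * C`), the
natural model when many consumers each draw proportionally on a shared
substrate pool.  Then

    t_1/2 = ln(2) * C / R_B.

With typical resting values (C = 500 uM, R_B = 30 uM/h) this gives 11.55 h.
The linear-depletion alternative `C / (2 R_B)` (8.3 h for the same inputs)
is not used.  `half_life` returns `None` when R_B = 0: with no observed
breakdown the pool never halves.

### Validity gates

Three descriptive (not inferential) checks guard the estimates:

* **Recycling** — breakdown-derived d3-/d0-Nam in the medium must stay a
  small fraction of the d4-Nam tracer, or re-incorporation biases both
  rates downward.  Default gate: combined non-precursor fraction <= 0.10.
  The reference 3-h run sits at ~6.5%, comfortably inside; no numeric
  cutoff is published, so 10% is this package's documented, configurable
  choice.
* **Linearity** — d3-NAD+ vs time, OLS through the origin (the label is
  structurally zero at the switch), scored with the conventional R^2 about
  the mean so saturating series are penalized.  Default gate R^2 >= 0.98.
* **Equivalence** — precursor isotopomers (d0/d3/d4-Nam) must give similar
  NAD+ readouts; statistic is the largest relative deviation of a group
  mean from the grand mean, default tolerance 0.15 (duplicate-level
  agreement).  Formal equivalence testing (TOST) is deliberately out of
  scope.

A negative observed `b` (d0-NAD+ apparently rising, possible under noise)
is clamped to zero with a warning and flags the sample invalid rather than
raising — a noisy replicate must not halt a batch.  A negative `a` raises:
labels cannot vanish.

## Calibration and quantification

Detector response per analyte is linear, `area = slope * amount +
intercept`, fitted by unweighted OLS with a free intercept (inverse-amount
weighting is available behind a switch for wide-range curves; blanks are
excluded from weighted fits).  Curves with R^2 < 0.99 are refused unless
explicitly overridden — linear response is an instrument expectation here,
not a statistical finding.  Unknowns are inverted through the line, floored
at zero, and flagged against the limit of quantification (default 0.4 pmol,
the conservative end of the instrument's 0.1-0.4 pmol range; per-analyte
values come from configuration) and against the calibrated amount range.
Flags are always carried; values are never silently dropped or clipped.
SRM transition settings are provenance metadata only.  No natural-abundance
cross-talk correction is applied between M+0 and M+3 channels: the mass
separation of three Daltons makes the channels effectively resolved, and
none is described for the reference instrument setup.

## The kinetic simulator

State (five pools, stored as pmol per 10^6 cells): medium d4-, d3-, d0-Nam
and cellular d0-, d3-NAD+.  With `C` the total cellular NAD+ concentration
and `S_i` the medium concentration of Nam isotopomer `i`:

    K_m(C)  = K_m0 * (1 + C / K_i)                      feedback inflation
    j_S     = Vmax * S_tot / (K_m(C) + S_tot)           total synthesis
    j_S,i   = j_S * S_i / S_tot                         channel apportioning
    j_B,i   = k_B * C_i                                 first-order breakdown

d4-Nam consumption produces d3-NAD+; recycled d3-Nam also produces d3-NAD+
(positions 2,5,6 retain deuterium) and d0-Nam produces d0-NAD+.  Breakdown
of each NAD+ isotopologue releases Nam of matching label into the medium.
The d4 channel carries an optional kinetic isotope-effect multiplier,
default 1 (the labeled and unlabeled precursors are bioequivalent within
measurement tolerance).  With `recycling` off, released d3-/d0-Nam still
accumulates in the medium but is excluded from the synthesis substrate.

The feedback is competitive-style, linear in C, and calibrated to two
anchors: K_m = 1 uM at zero NAD+ and 25 uM at 500 uM NAD+, giving
`K_i = 500/24 ~ 20.83 uM`.  Only the anchors are published; the linear form
is this package's parsimonious interpolation.

Breakdown is lumped into a single first-order constant for all consumers,
matching the aggregate nature of R_B.  A single well-mixed Nam pool is
assumed accessible to Nampt (transport fast; intracellular Nam not
resolved).  The `clamp_medium_nam` switch freezes the medium composition
(large-reservoir / perfusion limit) for steady-state scenarios; closed-
medium runs conserve the total Nam moiety exactly (breakdown returns the
nicotinamide moiety to the medium; the ADP-ribose leaving group is outside
the balance).

### Default parameters

| parameter | default | unit | origin |
|---|---|---|---|
| `vmax` | 645.17 | uM/h | calibrated (below) |
| `km0` | 1.0 | uM | published anchor |
| `ki_feedback` | 500/24 | uM | fits both K_m anchors |
| `k_b` | 0.06597 | 1/h | back-computed (below) |
| `nad0` | 574.8 | uM | 1437 pmol/1e6 cells / 2.5 pL |
| `nam_medium0` | 2.0 | uM | standard assay design |
| `nam_d0_residual` | 0.0 | uM | medium d0-Nam is explained by export |
| `cell_count` | 4.04e5 | cells | reference run |
| `cell_volume` | 2.5 | pL | gives a resting C in the 400-700 uM band |
| `medium_volume` | 1.0 | mL | makes the 2 uM medium hold ~4950 pmol/1e6 cells |
| `noise_cv` | 0.05 | — | typical LC-MS peak-area repeatability |
| `seed` | 0 | — | all stochastic routines require one |

`k_b` is back-computed from the reference run rather than taken as
R_B/C: because d0-NAD+ decays exponentially, the constant that loses 258
of 1437 pmol/1e6 cells in 3 h is `k_b = -ln(1 - 258/1437)/3 = 0.0660/h`
(the naive R_B/total = 0.0591/h would under-produce the printed decrease by
~10%).  `vmax` was then calibrated once, by root-finding on the noiseless
default simulation, so that d3-NAD+ formed at 3 h equals 276 pmol/1e6
cells; the value 645.17 uM/h is frozen as the default.  The resulting
model reproduces the reference 3-h state: 276 formed, 250 lost (printed:
258, within 3%), medium composition 93.5/5.1/0.6% (d4/d0/d3), and implies a
pool half-life of 10.5 h, inside the published 3.9-11.5 h range.

### Integration and numerics

LSODA with rtol 1e-8 / atol 1e-10; output pools are clipped at zero with a
1e-6 pmol tolerance and anything more negative is an integrator error.  The
state vector also carries running integrals of the gross synthesis and
breakdown fluxes, so time-averaged "true" fluxes used by the bias scan are
integrator-exact rather than quadrature approximations.  The steady state
under clamped medium solves the flux balance `k_B C = Vmax S / (K_m(C)+S)`
in closed form (a quadratic in C with one positive root); the ODE fixed
point agrees to integrator tolerance.

### Noise model and dataset generation

Measurement noise is multiplicative log-normal per observation,
mean-preserving: an amount `m > 0` becomes `m * exp(N(-s^2/2, s))` with
`s^2 = ln(1 + CV^2)`.  CV-type variability is the standard behavior of
LC-MS peak areas; exact zeros (pre-switch d3 pools) stay zero.  Generated
peak-area/metadata table pairs are byte-identical for a fixed seed.

What the generator does **not** emulate: chromatographic drift and batch
effects, detector saturation, carry-over, natural-abundance cross-talk,
extraction losses, or biological replicate-to-replicate variation beyond
the observation noise.  Passing recovery tests therefore demonstrates
estimator correctness under the stated noise model, not robustness to real
instrument pathology.

### Estimator bias, by construction

`a/t` and `b/t` measure *net* label movements, so against the gross
time-averaged fluxes they are biased low even with recycling off: freshly
made d3-NAD+ is itself degraded (at 3 h with the default `k_b` this loses
~9% of the gross synthesis — visibly, the d3-Nam that accumulates in the
medium), and the d3 share of the pool is missing from the d0-based
breakdown estimate.  Recycling adds a second, growing underestimation by
routing synthesis through unlabeled Nam.  The bias scan reports both
estimators against the gross averages; the package's accuracy claims for
the pipeline itself are stated against the realized net fluxes, which the
two-point estimator recovers exactly on noiseless data.  The practical
consequence matches the assay design rule: keep the labeling window short
enough that breakdown products stay below ~10% of the medium pool.

### Recovery-harness design

The recovery harness uses the standard two-point design (one observation at
the switch, one at 3 h), 50 datasets by default.  R_S inherits the
observation CV directly (d3 starts at exactly zero).  R_B is a small
difference (~250) of two large noisy pools (~1400), so its per-dataset CV
is structurally ~7x the observation CV (~0.35 at CV 0.05); at 50 datasets
the standard error of its mean (~4.6%) is of the same order as typical
accuracy targets.  Real designs that care about R_B should replicate both
timepoints.  Problem sizes used by the test suite and acceptance script
(50 datasets, 3-h design, <=24 h scan grids) are the package's standard
demonstration sizes.

## Reporting conventions

Cross-sample relationships use OLS with a free intercept and squared
Pearson R^2, on condition means by default.  The dose-response saturating
concentration is the smallest tested concentration whose rate reaches 95%
of the maximum observed — an operational rule, since "no further increase"
is otherwise verbal; if only the highest tested concentration qualifies the
series is flagged unsaturated.  Induction tables divide every condition row
by the designated baseline row.  Lysate Nampt activity is product amount /
time / cells x 10^6, then / cell volume for uM/h; no substrate-depletion
correction is applied to the 1-h assay (50 uM Nam, excess PRPP assumed
non-limiting).

## Known limitations

* Whole-cell concentrations only; no subcellular compartmentation.
* The NA/NAPRT route and NMN/NR precursors are outside the model.
* The feedback law is a two-anchor linear interpolation; the true
  inhibition curve may bend.
* `nam_d0_residual` lumps carry-over and any export mechanism; the data do
  not distinguish them.
* Two-point estimates inherit the biases quantified by the bias scan when
  labeling windows stretch beyond the validity gate.
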