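# Methods

`fetopulm` analyses fetal pulmonary vascular reactivity from Doppler
velocity envelopes recorded at three sites — main pulmonary artery (MPA),
an intrapulmonary artery (IPA) and the ductus arteriosus (DA) — before and
after maternal hyperoxygenation (MHOx: the mother breathes 100% O₂ for
10 min and the fetal Doppler is re-acquired).  The package has four
scientific layers: a synthetic cohort generator, Doppler index extraction, a
personalised 0-D model of the fetal pulmonary circulation, and an
unsupervised multiple-kernel-learning (MKL) analysis of waveform change.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data can and cannot establish.

## Doppler indices

For one beat of an envelope trace `v(t)`:

* `PI = (Vmax − Vmin) / Vmean`, `Vmean` the time average over the full
  cycle (TAmean).  On an envelope trace TAmean and TAmax coincide, so no
  separate switch is offered.
* `VTI` integrates forward (positive) velocity only, as in clinical
  envelope tracing; `PSV` is the cycle maximum.
* Systolic onset is the upstroke crossing of 5% of the peak above baseline
  (configurable), refined on the raw samples by linear back-projection to
  the baseline; the ejection end is the mirrored crossing after the peak.
  The baseline is zero whenever retrograde flow is present, else the cycle
  minimum (relevant for the DA, which never reaches zero).  `AT`/`ET` are
  onset-to-peak and onset-to-ejection-end in ms.
* `PEDRF` (IPA only) is the most negative velocity in the window
  `(ET, ET + 0.25·cycle]`, 0 when no reversal exists.  The window fraction
  is configurable; no definition is standardised in the field.
* Extremes and crossing neighbourhoods are read from a lightly smoothed
  copy (5-sample centred circular moving average); integrals and sub-sample
  crossing refinements use the raw samples.  The beat is internally rolled
  so the cycle minimum sits at index 0, which makes every index invariant
  to how the cycle was phased (up to one sample of onset re-detection).

## Synthetic cohort generator

The generator is the package's stand-in for the non-deposited clinical
recordings.  Its defaults are the study conditions: 111 controls and 97
growth-restricted (FGR) fetuses at 24–37 weeks, per-group/per-condition
index targets equal to the published cross-sectional means ± SD, fetal
heart rate 140 ± 10 bpm, pulmonary valve diameter 5.66 ± 1.16 mm (scaled
allometrically with estimated fetal weight, `d ∝ EFW^{1/3}`), and
group-conditional perinatal outcome rates equal to the published ones.

**Waveform families.**  All three sites are built from elementary pieces
with closed-form integrals, so every requested index is realised exactly:

* *MPA*: half-sine rise over AT, a short locally symmetric peak cap, a
  linear deceleration onto a post-peak shoulder plateau, and a terminal
  half-cosine fall at ET; zero diastolic flow.  The published (PSV, VTI,
  ET) triples imply a "fat" systole (`VTI/(PSV·ET) ≈ 0.71`), which this
  shape realises while keeping a sharp peak whose timing survives smoothing
  and measurement noise (a plain `sin^p` pulse with the same integral has a
  curvature-kinked, flat top whose apparent timing is biased by several
  per cent).
* *IPA*: systolic lobe (`sin^q`, exponent solved per beat), a negative
  early-diastolic half-lobe of depth PEDRF, and a forward late-diastolic
  plateau whose level is solved so the forward integral matches VTI and the
  cycle mean matches PI exactly.
* *DA*: diastolic floor plus the same shouldered ejection shape as the MPA
  drive.  The DA mean velocity is **derived from per-beat flow
  conservation** — valve inflow minus pulmonary branch flow, divided by the
  nominal ductal cross-section shared with the circuit model — clamped to a
  physiologic 8–60 cm/s envelope.  Without this constraint the three sites
  are mutually inconsistent and no circuit can fit them coherently.

**Cycle lengths.**  With zero diastolic flow, `PI = PSV·T/VTI` pins the MPA
cycle at ≈0.31 s (~195 bpm) for the published index combinations, which is
incompatible with a 140-bpm heart.  Each MPA trace therefore carries the
cycle its own indices imply (separate spectral acquisitions have different
instantaneous heart rates), while IPA and DA use the subject's drawn heart
rate; for personalisation the MPA ejection is mapped onto the DA/IPA cycle
in absolute time (ejection *duration*, not its cycle fraction, is the
conserved quantity).

**Index draws.**  Strictly positive quantities (PI, PSV, mean velocities,
reversal depth) are drawn with moment-matched lognormal margins coupled by
a Gaussian copula (e.g. deeper reversal with higher IPA pulsatility); AT/ET
are correlated normals.  MPA VTI is drawn through the systolic shape ratio
`r = VTI/(PSV·ET)` (narrow dispersion, so VTI inherits realistic dispersion
from PSV and ET), IPA VTI through the cycle-mean velocity.  Draws outside
the morphologically representable band are rejected; because such
truncation would bias the accepted means, every draw path is
**self-calibrated**: a cached internal Monte Carlo (private fixed seed)
measures the accepted-mean shift and recentres the proposal means so the
accepted draws hit the configured targets.  Residual index dispersion uses
the smaller of the two conditions' published SDs — cross-sectional tables
mix within-subject and between-acquisition variance, and only the
persistent part can carry over a paired comparison.

**Latent reactivity.**  Each subject carries a reactive/non-reactive class
(67% of FGR, 33% of controls reactive) and a latent baseline-severity score
`a` on the control(0)→FGR(1) axis; index means shift linearly along the
control→FGR difference vector with `a`.  Reactive subjects sit at a more
severe baseline phenotype (component means 0.75/1.75 for controls/FGR,
component SD 0.25), mirroring the clinical observation that non-reactive
FGR are the mild (plus a few severe, decompensated) cases; the non-reactive
component mean is solved so each group's marginal means equal the published
targets, and the mixture variance is subtracted from the residual SDs so
marginal SDs are preserved.  Under MHOx, non-reactors keep their baseline
indices up to a 2% multiplicative jitter; reactors draw around the
reactive-class MHOx mean — solved from the group marginal given that
non-reactors do not move — correlated 0.6 with their own baseline.  The DA
is re-derived from flow conservation in both classes.

**What the generator does not emulate:** speckle/spectral-envelope physics,
insonation angle, beat-to-beat variability (one representative cycle per
acquisition), longitudinal growth, within-subject outcome correlations, and
any dependence of outcomes on the waveforms beyond group membership.
Passing tests on this cohort therefore show that the *pipeline* recovers
structure of the stated form when present at the published effect sizes —
not that the clinical findings themselves are reproduced.

## 0-D circulation model

One flow input (right-ventricular output, `Q = V_MPA · π(D/2)²`), three
arterial L-section segments (series R–L, shunt C at the distal node), and
two three-element Windkessel beds (pulmonary, via the IPA segment; systemic,
via the DA segment).  The DA resistor supports a sign-preserving quadratic
term `ΔP = R·q + k_DA·q|q|` (default `k_DA = 0`).  The distal reference
pressure is 0.  Units: mmHg, mL/s, s, cm/s.

Nominal element values scale allometrically,
`X = X_ref (EFW/3000 g)^α` with α = −1 for R and L, +1 for C, +2/3 for
areas.  The reference constants are calibrated stand-ins (the provenance
values for a fetal circulation are not published alongside the study):
they put a term fetus at resting output at ~45 mmHg mean MPA pressure with
~20% of right-ventricular output perfusing the lungs, the accepted prenatal
distribution, and site areas (`A_DA = 0.22 cm²`, `A_IPA = 0.11 cm²` at
3 kg) that map branch flows onto the measured velocity scales.

Two solvers share one parameterisation:

* `simulate` — fixed-step RK4 (default 0.2 ms) on the 7-component state,
  cycle by cycle from the DC solution (or a caller-supplied state) until the
  relative cycle-to-cycle L2 change falls below `periodicity_tol` (default
  1e-4; the oracle-equivalence tests use 1e-11).
* `harmonic_steady_state` — for the linear circuit the periodic steady
  state is computed exactly per rFFT harmonic by a ladder impedance
  reduction.  This is the fast path inside personalisation (~10⁴× faster
  than transient integration) and is asserted against `simulate` in tests.

`dc_solve` (inductors short, capacitors open; scalar quadratic for the
ductus) is the independent steady-state oracle.

## Personalisation

Per subject and condition, four multiplicative factors — pulmonary and
systemic bed resistance (scaling Rc and Rp jointly, preserving their
nominal ratio) and the two bed compliances — are fitted by minimising
`J = NRMSE_DA + NRMSE_IPA`, each NRMSE being the RMS error over a common
100-point beat grid divided by the measured range.  Beats are aligned at
systolic onset (zero baseline when retrograde flow is present) and
time-normalised.  The optimiser is bounded Powell in log-factor space,
bounds [0.1, 10], with seeded Latin-hypercube multistart; failed
simulations score J = 10.

Two stabilisers address the shallow directions of this ill-posed inverse
problem (visible as decade-wide basins in `J(f_Rpulm)`): cohort fits add a
quadratic anchor `0.02·Σ(ln f)²` to the *optimised* objective only (the
reported J stays the plain NRMSE sum; recovery benchmarks run with the
anchor off), and the MHOx fit warm-starts from the subject's baseline
optimum so the within-subject ratio is not polluted by hops between
near-degenerate optima.  The headline read-out is the MHOx/baseline ratio
of the fitted resistances (1 = no change, <1 = vasodilation under oxygen).

Noiseless self-generated targets are recovered within 5% (J < 0.01); with
5% velocity noise the resistance factors are recovered within 15% in the
median.  Fits to the synthetic envelopes bottom out at J ≈ 0.3–0.6 — the
parametric envelope families are deliberately not circuit output — which is
sufficient for the ratio analysis but means absolute fitted values carry
substantial per-subject uncertainty.

## MKL embedding, boundary and DTN

MPA and IPA beats (100 samples, both conditions pooled: 2N observations)
each yield a Gaussian kernel with median-heuristic bandwidth; the pipeline
z-scores each source first, because between-subject amplitude variance
otherwise swamps waveform shape in the distances.  The combined kernel
`K = Σ β_m K_m` drives a kernelised graph embedding: a symmetrised 5-NN
affinity graph (weights from the kernel) with a tiny uniform "teleport"
affinity (1e-3 of the mean edge weight) so the graph is never disconnected,
then the generalized eigenproblem `K W K a = λ K D K a` (ridge 1e-8 on the
constraint side).  The stationary constant mode is strictly the top
eigenpair of the regularised graph and is deflated deterministically;
the next `d` eigenvectors (default d = 2), sign-fixed
(largest-|entry| positive) and scaled by `λ²` (two-step diffusion scaling,
so weakly separated directions shrink), are the coordinates `y = K a`.
Kernel weights are optimised in alternation with the projection by
maximising the same Rayleigh quotient over the source simplex (closed 2×2
generalized eigenproblem), with the affinity graph held fixed at its
uniform-combination version — rebuilding the graph each iteration makes the
alternation limit-cycle — and a weight step is accepted only if the
objective does not deteriorate, so the iteration is monotone.

A ridge-regularised logistic regression (ridge 1e-3) on the *baseline*
coordinates models P(control vs FGR); its boundary, oriented so the mean
control score is positive, splits the population into cluster A (controls'
region; ties to A) and cluster B.  Displacement towards normality is the
projection of each subject's baseline→MHOx displacement onto the boundary's
unit normal; clusters are compared by a two-sided Wilcoxon rank-sum
(mid-rank ties, no continuity correction), reported with medians and IQRs.

## Statistics module

Continuous variables: Student's t by default, rank-sum selectable;
categorical: chi-square with Yates continuity correction, with automatic
Fisher fallback when any expected cell is below 1; covariate adjustment via
OLS with the group-coefficient p reported; all tests two-sided at α = 0.05.
Percentages always recompute from stored counts.  The two-sample size
formula is the normal approximation
`n = ⌈(z_{1−α/2}+z_{1−β})² σ² (1+1/r) / δ²⌉` with `δ = mean·pct/100`.

## Problem sizes and determinism

The default analysis runs the full cohort (111/97), all 2N = 416
observations in one joint embedding, and 208×2 circuit fits with
multistart 2 (~1.5 min on one core thanks to the harmonic solver); the
recovery benchmarks use 20 seeded replicates.  Every stochastic component
consumes a `numpy.random.Generator` seeded from a single integer, so
cohorts, fits and embeddings are bit-reproducible.

## Known limitations

* The generator's envelope families are stylised; absolute J values and
  fitted absolute resistances are not comparable to clinical ones.
* Reference circuit constants are calibrated, not measured; only ratios
  and directions should be interpreted.
* The latent reactivity mechanism is a two-class mixture with a single
  severity axis — a deliberate minimal stand-in for whatever physiology
  separates the clinical clusters.
* With `k_DA > 0` personalisation would need the RK4 path (slow); the
  default analysis keeps the ductus linear.
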