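# Methods

## The model

`braincsp` encodes a kinetic model of human brain energy metabolism with
four compartments — neurons (`_n`), astrocytes (`_g`), extracellular
space (`_e`) and capillaries (`_c`) — and 29 state variables
(concentrations in mM; the venous volume fraction `Vv` is
dimensionless).  Each cell type carries glycolysis (lumped
hexokinase–phosphofructokinase, phosphoglycerate kinase, pyruvate
kinase), lactate dehydrogenase, mitochondrial oxidative metabolism (a
lumped TCA input and an electron transport chain step), cytosolic ↔
mitochondrial NADH shuttles, the creatine kinase / phosphocreatine
buffer, the Na,K-ATPase pump with a passive sodium leak, and
glucose/lactate/oxygen exchange with the extracellular space and the
capillary bed.  The vasculature contributes capillary inflow terms
proportional to cerebral blood flow (CBF), a venous "balloon"
(`Vv`, `dHb`), and the derived BOLD observable
`BOLD = Vv0 [(k1+k2)(1 − dHb/dHb0) − (k2+k3)(1 − Vv/Vv0)]`.

The dynamics is written as `dy/dt = S R(y)` with a constant 29×67
stoichiometric matrix `S` over unidirectional rates: every reversible
reaction is split into non-negative forward/backward parts, because the
participation diagnostics (below) attribute behaviour to individual
directions.  Reaction numbering follows the published model; numbers
42–53 belong to its electrophysiological part, which is not active in
the human-activation scenario, leaving 53 numbered reactions → 67
unidirectional labels (`"5f"`, `"27b"`, `"63"`, …).

Two closures keep the state low-dimensional:

* **Adenine pool.**  ADP and AMP are slaved to ATP through pool
  conservation `A = ATP + ADP + AMP` and adenylate-kinase equilibrium
  (`ADP² = q_AK · ATP · AMP`), giving the closed form
  `ADP = ATP/2 (−q + √(q² + 4q(A/ATP − 1)))`.  Because AMP moves when
  ATP moves, every ATP-producing/consuming flux is multiplied by
  `S(ATP) = (1 − dAMP/dATP)⁻¹` (reactions 34–36, 54–65), which keeps the
  stoichiometric matrix state-independent — a prerequisite for the
  per-reaction decomposition of the Jacobian.
* **Venous balloon.**  The outflow law
  `Fout = F0 [v^{1/α} + (τ_v/Vv0) v^{−1/2} dVv/dt]`, `v = Vv/Vv0`, is
  implicit through `dVv/dt = F(t) − Fout`; substituting gives a linear
  scalar equation solved in closed form
  (`braincsp.protocol.venous_outflow`).  The prefactor `F0` is the
  baseline flow (so a sustained 40 % flow increase settles at
  `v = 1.4^α ≈ 1.183`), while the volume balance uses the instantaneous
  `F(t)`.

All rate laws and their gradients with respect to the state are built
symbolically (sympy) by `scripts/generate_kinetics.py` and committed as
plain Python (`braincsp/_kinetics.py`); the analytic Jacobian
`J = S · dR/dy` is the default everywhere, with a Richardson-extrapolated
finite-difference Jacobian as the independent test oracle.  Eigenvalue
analysis is far more sensitive to Jacobian noise than integration is,
which is why the analytic route is the default.

### Transcription choices

Three details of the source tables required a decision (full reasoning
in the package history):

* The total NAD pool is `N = 0.212 mM` (the printed "212 mM" is a units
  slip — only the sub-mM value is consistent with resting NADH levels of
  0.006–0.12 mM).
* The capillary-lactate balance uses `+r2 (R19f − R19b)`: reaction 19 is
  glia→capillary transport, so the mass-conserving sign is positive.
* The deoxyhemoglobin inflow carries the same factor 2 as the capillary
  oxygen inflow, `R38 = 2 F(t) (O2a − O2c)`; without it the printed
  resting `dHb` is irreconcilable with stationarity.
* The unlisted glucose carrier affinity for capillary→extracellular
  transport is taken as 8 mM, the value shared by every other glucose
  carrier.

### The resting state

The published resting values are rounded to about two significant
digits, and the glycolytic intermediates GAP/PEP are printed as a single
shared value for both cell types; they are not an exact fixed point of
the equations.  The package therefore defines its baseline as the Newton
root of `g(y) = 0` under baseline flow (`braincsp.steady_state`), seeded
from the printed values after a 200 s pre-relaxation.  The refined fixed
point agrees with the printed table to ≲1 % for the slow observables
(sodium, glucose, lactate, ATP, PCr, oxygen), to a few percent for the
NADH pools, and differs appreciably only for the fast placeholders
(GAP_g, PEP_g) and the derived dHb baseline.  Scenario simulations start
from the refined state; starting from the literal printed values only
adds a seconds-long artificial transient.

## The activation scenario

The in-vivo activation protocol stimulates for 900 s: constant sodium
source terms `R40 = 0.15290`, `R41 = 0.059823 mM/s` inside the window,
zero outside; CBF rises linearly from `F0 = 0.012 s⁻¹` to `1.4 F0`
over 30 s after a 2 s onset lag, and returns after a 10 s offset lag.
The fall ramp duration is not specified in the source; the package
defaults to a symmetric 30 s fall (`ScenarioProtocol.fall_ramp`,
configurable).  All reported post-activation results are insensitive to
this choice (re-running with an instantaneous fall moves the pointer
diagnostics by < 0.01 and the late boundaries not at all).

Integration uses BDF with the analytic Jacobian at `rtol = 1e-8`,
`atol = 1e-10`, split into segments at the protocol breakpoints
(0, 2, 32, 900, 910, 940 s) with the piecewise-constant stimulation
frozen per segment, so the solver never steps across a discontinuity.
Dense output serves the analysis grid — 1 s spacing to 1000 s, 10 s
beyond, horizon 10000 s ("end of the process" for the final period is
open-ended in the source; 10000 s is comfortably past the last
transition at ~3600 s and the full run takes a few seconds).

## CSP decomposition

At each analysis time the Jacobian's right/left eigenvectors (the
leading-order CSP basis) are computed, sorted fastest-first by |λ| with
a stable tie-break (|λ|, then real part, then original index).  Left
vectors are the exact matrix inverse of the right basis, so
bi-orthonormality `b·a = δ` holds to machine precision; amplitudes
`fⁿ = bⁿ·g` are made non-negative by jointly flipping `(aₙ, bⁿ)`.
Complex conjugate pairs are represented by their real invariant
2-subspace (real and imaginary parts of one eigenvector), which keeps
every index real; the pair shares the timescale `1/|λ|`, and the
eigenvalue-sum identity for such a pair holds for the real part.

Diagnostics, all normalised:

* **API** (amplitude participation) `P_k = (b·S_k) R_k / Σ|…|` — the
  signed share of reaction k in a mode's amplitude cancellation; a
  reversible pair in partial equilibrium carries ≈ ±0.5.
* **TPI** (timescale participation) `J_k = c_k / Σ|c_i|`,
  `c_k = b ∇(S_k R_k) a`, with `Σ c_k = λ` — the signed share of
  reaction k in generating the mode's timescale; negative entries are
  dissipative, and a mode is classified dissipative when the signed TPI
  sum is negative.
* **Pointer** `D_i = a_i b_i`, summing to one — the association of each
  species with the mode; values near 1 flag quasi-steady-state species.

Because `∇(S_k R_k) = outer(S_k, ∇R_k)`, each TPI contribution
factorises as `(b·S_k)(∇R_k·a)` and the whole row costs two
matrix-vector products.

### Exhausted-mode criterion and its calibration

A mode is exhausted when freezing it (and all faster modes) perturbs the
state by less than the accuracy target on the timescale of the first
active mode:

    |τ_{M+1} Σ_{i≤M} a_i f^i|  <  e_rel |y| + e_abs   (componentwise).

`count_exhausted_modes` returns the largest M such that this holds for
every M' ≤ M.  The contiguity requirement is deliberate: the raw
inequality is not monotone in M (partial sums can cancel accidentally),
and demanding mode-by-mode validity makes the count stable over a wide
tolerance range.

The accuracy thresholds are not published.  The package ships a
calibration utility (`braincsp.tolerance_grid`) that tabulates M over a
(e_rel, e_abs) grid at chosen times; calibrating once against the known
per-period counts of the activation scenario shows a wide plateau —
every `e_rel` in ≈ 0.35–0.60 (with `e_abs` inert at 1e-6 mM) yields
counts 17/26/27 in the activation epoch and 22/26/27/28 in the
post-activation epoch at the standard representative times.  The
defaults are frozen at `e_rel = 0.45`, `e_abs = 1e-6 mM`.  The loose
leading-order threshold has a physical reading: during forced phases
(the CBF ramp, the sustained stimulation) the fast modes are slaved to a
*moving* manifold and retain small finite amplitudes proportional to the
forcing rate; the criterion must tolerate that quasi-static offset to
call them exhausted.

With a tolerance this size the pointwise count passes through
intermediate plateaus (21, 23, 25 …) that coarser procedures absorb into
the main periods; the segmentation reports them all (maximal
constant-count runs per epoch, with runs shorter than `min_dwell = 5 s`
debounced into the closer-count neighbour; the two epochs are segmented
independently at the 900 s forcing discontinuity).  Two published
boundaries are *not* reproduced by this pointwise criterion at any
single tolerance: the step to the 27-count activation period falls at
≈ 733 s (vs 620 s) and the final step to 28 at ≈ 3630 s (vs 5730 s) —
the latter would require an effective threshold ~0.04 for the neuronal
creatine-kinase mode while the activation-epoch counts require ≥ 0.35.
The window analysis in the calibration utility makes this tension
explicit; the package reports its own computed boundaries.

### Representative times

Dominant-mode tables are evaluated at the conventional representative
times 25, 500, 850, 950, 1000, 1300, 2000, 6500 s when a period contains
them, otherwise at the period midpoint.  Note two quirks inherited from
the source conventions: 950 s lies in the *second* post-activation
period under any consistent segmentation (the first post-activation
column corresponds to mode 18 at 950 s, which the package reproduces to
±0.01 in the pointer), and the sodium-recovery pointer at 1000 s is
extremely phase-sensitive — it sweeps from ≈ 0.57 to ≈ 0.96 across the
period, matching the published 0.881 near t ≈ 1095 s.

## Reporting conventions

Dominant-mode tables keep pointer entries ≥ 0.03 and |TPI| ≥ 3 %, sorted
by magnitude, with the filter thresholds recorded in the output.
Equilibria graphs aggregate over a period's exhausted modes at the
representative time (evaluation at that single time is configurable by
recomputing at any other time): a reaction is "strong" when its largest
|API| over exhausted modes exceeds 9 %, "weak" between 2 % and 9 %;
species are listed when any exhausted-mode pointer entry exceeds 0.45;
per-item provenance (the contributing mode) is retained so cumulative
per-period colourings can be reconstructed.  A mode whose projected
rates all vanish (the venous-volume mode at plateau) has an undefined
API and is skipped with its pointer still used.

## Toy benchmarks

The CSP engine is validated independently of the brain model on two
parametrised systems with known answers: a 2-D linear two-timescale
system (eigenvalues −1/ε and −1, configurable eigenvector angle) whose
basis vectors, pointer, TPI and exhaustion time are closed-form; and the
reversible enzyme system (substrate/complex) whose fast mode expresses
the binding/unbinding partial equilibrium (API → ±0.5), whose fast-mode
pointer concentrates on the complex as E0/S0 → 0, and whose trajectory
tracks the quasi-steady-state manifold `C = E0 S/(K_M + S)` to O(ε).
These toys are deterministic by construction; the synthetic step series
used in segmentation tests are likewise fixed.  What the toys do *not*
emulate is eigenvector mixing between near-degenerate modes — the one
feature of the full model that makes some pointer values phase-sensitive
(see the 1000 s note above), so toy-level agreement bounds algebraic
correctness, not the sensitivity of diagnostics at near-degeneracies.

## Numerical choices and limitations

* Integration tolerances `rtol 1e-8 / atol 1e-10`: halving them moves
  the trajectory by < 0.1 % per variable; the eigen-decomposition
  amplifies trajectory error, hence the tight default.
* Eigenbasis conditioning is monitored; a warning is emitted above
  condition 1e10 (never reached along the scenario).
* Each analysis time is decomposed independently; results are
  order-independent and trivially parallelisable.
* The reduced slow model (freezing the exhausted modes) is diagnosed,
  not integrated; no higher-order CSP basis refinement is applied.
* SBML import/export, the electrophysiological variables of the parent
  model, and non-human scenarios are out of scope.
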