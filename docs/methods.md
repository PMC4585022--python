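# Methods

## Scope and model

`lvsynapse` reduces deterministic Markov kinetic-state receptor models to
Volterra-series input–output (IO) models and assembles them into a complete
glutamatergic synapse. The IO model treats the synapse as a causal
functional of its presynaptic event train: the output (per-receptor
conductance for the fast AMPA-like pathway, open-state fraction for the
slow NMDA-like pathway) is

u(t) = c0 + Σ_q Σ_terms c·Π v,  v_j^n(t) = Σ_{τ≤M_k} b_j^n(τ)·x(t−τ),

with orders q = 1..4, input x the binned impulse train, and memory window
M_k = 2 s by default (events older than that contribute nothing
appreciable for the receptor time scales considered).

### Laguerre basis

b_j(t) = √(2p)·(−1)^j·L_j(2pt)·e^(−pt), with L_j the Laguerre polynomials
evaluated by the stable three-term recurrence. The (−1)^j factor matches
the conventional printed forms of the normalized family (b1 ∝ (2pt−1));
it has no effect on the fitted model since coefficients absorb signs. The
family is orthonormal on [0, ∞); the discrete kernels are evaluated at bin
centers (k+½)·dt so all convolutions are bit-reproducible. Two sets with
separate decay constants p are used: a fast set for the response waveform
and a slow set for desensitization-scale memory.

**Units of p.** Decay constants are bare numbers in this literature. The
package default interprets p per time-bin of the training discretization
(0.1 ms bins), and the basis constructor also accepts per-second units;
coefficient files record the convention, so either can be reproduced.

### Term structure

Product terms are multisets of (set, function) pairs. With
`cross_terms=False` every multiset draws from one set (self-kernels): a
3rd-order model with two sets of 4 functions has 8 + 2·C(5,2) + 2·C(6,3)
= 68 coefficients. With `cross_terms=True` multisets are drawn from the
pooled functions of both sets at every order: a 4th-order model with two
sets of 3 functions has C(6,1)+C(7,2)+C(8,3)+C(9,4) = 209. The constant
c0 is stored separately and excluded from these counts. The enumeration
order (by order, then lexicographic) is frozen and written into the
coefficient file, so fitted models are portable. The order cap is 4.

## Kinetic oracle

Receptor schemes are continuous-time Markov state models: dx/dt = A([glu])x
with A = A0 + [glu]·A1 (ligand exponent 0 or 1 per transition), occupancy
conserved by construction. Because the glutamate input is piecewise-
constant per bin (binned release transients), the master equation is
propagated **exactly**: each constant-ligand run is solved by
diagonalization of its generator, vectorized over the run. This replaces
fixed-step explicit integration — it is bit-reproducible, faster, and has
no truncation error; a classical fixed-substep RK4 integrator (default
substep 0.5 µs, with an explicit stability guard) is retained as an
independent cross-check and agrees to ~1e-9. Reported occupancies are
end-of-bin values (the ligand is held at the bin's value across the bin).

Glutamate transients are parametric stand-ins for cleft diffusion: a
square pulse (default 1 mM, 1 ms) or a peak-normalized double exponential.

### Packaged fixture schemes (version 1)

* `fast_ampa_like` — C⇌O→D→C with binding 400 (mM·s)⁻¹, deactivation
  300 s⁻¹, desensitization entry 200 s⁻¹, recovery 2.5 s⁻¹ (≈400 ms), open
  conductance 0.02 nS. Chosen for a moderate per-event peak open fraction
  (≈0.27 for the default transient), return to baseline well inside 30 ms,
  and strong rate-dependent depression: at a 2 Hz mean rate the response
  is mildly nonlinear (a first-order fit leaves ≈10% NRMSE), while at
  10 Hz desensitization accumulates and the nonlinearity is substantial.
  This is the regime the reduction method is designed for: higher-order
  kernels have real structure to capture at high rates.
* `slow_nmda_like` — the same topology with ≈330 ms deactivation and slow
  desensitization; its open-state fraction is the natural training target
  (conductance is applied afterwards through the magnesium block).
* `linear` — a two-state scheme with binding so weak that ground-state
  depletion is negligible; its response is linear in the input to ≈1e-7
  relative, giving tests a null model with no history dependence.

These are desk-scale synthetic stand-ins with the qualitative features of
published multi-state AMPA/NMDA receptor models; the published rate
constants themselves live in their original sources and can be transcribed
into the YAML scheme format if needed.

## Estimation

**Design and solver.** The design matrix has a constant column plus one
column per term (element-wise products of basis convolutions). Small
in-memory problems use `numpy.linalg.lstsq` (pseudoinverse, minimum-norm).
The full training pipeline streams the normal equations in chunks, scales
columns to unit RMS, and solves by eigendecomposition with a **spectral
truncation**: eigenvalues of the scaled Gram matrix below 1e-8 of the
largest are dropped (equivalent to discarding scaled design singular values
below 1e-4 of the largest). This truncation is not cosmetic. High-order
product columns are severely collinear (slow-set convolutions are nearly
constant at high rates), the exact least-squares solution lies partly along
noise-dominated directions and extrapolates catastrophically to novel
trains; the truncated solution generalizes. The cutoff is frozen,
configurable (`gram_cutoff`), and recorded with the model. For exactly
degenerate designs the solution reduces to the familiar minimum-norm
pseudoinverse answer.

**Decay optimization.** The two decay constants are optimized by a
deterministic log-space grid (default 4×4 within documented bounds,
p_fast > p_slow enforced) followed by coordinate-wise golden-section
refinement, minimizing the summed absolute training error with a full
coefficient refit at every candidate. A derivative-free search is used
because the objective is a refit-inside landscape — piecewise smooth at
best. To keep the end-to-end protocol at desk scale, the search runs on a
shorter train drawn from the same rate protocol (default 150 events per
rate segment, so hybrid protocols inform the search at every rate); the
final coefficient fit always uses the full training train.

**Training protocols.** Defaults follow the standard reduction recipe:
0.1 ms bins, 2 s memory window, 2 Hz Poisson random-interval training
trains with 1000 events for 3rd-order models, hybrid 2 + 10 Hz trains with
2000 events for 4th-order models (split evenly across rates), L = 4
functions per set for 3rd-order self-kernel models and L = 3 for
cross-kernel/4th-order models, and validation always on a freshly seeded
20 s train (never the training input). NRMSE = √(Σ(y−ŷ)²/Σy²) with the
baseline at 0. The event-windowed variant scores each event's response
segment separately, merging events closer than the segment window, so
paired responses are scored as one row.

**Estimator shape.** The core is `LaguerreVolterraRegressor`, a
scikit-learn-style estimator (get_params/set_params, fit/predict,
underscore-suffixed fitted attributes) over (binned input, target) series;
`fit_coefficients`, `optimize_decays` and `train_receptor_model` are the
functional surface over it.

## Synapse assembly

Release probability follows the facilitation/depression formulation driven
by decaying calcium-indicator variables: F = F1 + (1−F1)·CaX_F/(CaX_F+K_F);
D recovers between events at rate k(t) = k0 + (kmax−k0)·CaX_D/(CaX_D+K_D),
which has a closed-form inter-event integral, so the recursion is evaluated
exactly; release probability per event is F·D, with D depleted by F·D at
release. The default parameters (F1 = 0.24, τ_F = 100 ms, K_F = 2,
k0 = 2 s⁻¹, kmax = 30 s⁻¹, τ_D = 50 ms, K_D = 2) are documented
placeholders in the hippocampal range and are plain configuration.

Stochastic release draws one uniform number per event against its
probability (seeded, reproducible); a deterministic mode forces release on
every event for run-to-run comparisons.

NMDA magnesium block: g0 = g1 + (g2−g1)/(1+e^(αψm)) and
gmax = g0/(1+([Mg]0/K0)·e^(−δzFψm/RT)), with defaults g1 = 40 pS,
g2 = 247 pS, α = 0.01, ψm = 0.8 (fixed, dimensionless), [Mg]0 = 1 mM,
K0 = 3.57, F = 9.64867·10⁴ C/mol, R = 8.31434 J/(mol·K), T = 273.15 K.
δ = 0.8 and z = 2 do not appear as standalone values in the defining
equations' source and are taken from the magnesium-block literature; both
are configurable and flagged as such. ψm is a fixed parameter by default;
`nmda_gmax` accepts an override per call as the hook for users who want a
voltage-dependent block. With fixed ψm the NMDA current is affine in the
clamp potential (asserted in tests). The AMPA pathway never touches the
magnesium parameters.

Currents are I = nb·g·(V−V_rev) (nS·mV = pA) with nb_AMPA = 80 and
nb_NMDA = 20 by default; voltage coupling is feed-forward only (clamp
value or externally supplied trace) — no membrane model is solved.

## What the synthetic data does and does not show

The fixture schemes reproduce the *structure* of the reduction problem —
ligand-gated state kinetics, saturation, desensitization with slow
recovery, two well-separated time scales — at 2–3 states instead of 8–16,
with responses that are smooth, noise-free and perfectly stationary.
Passing tests therefore demonstrate that the estimation machinery
recovers models it should recover and reduces mechanistic kinetics with
single-digit-percent NRMSE under the standard protocol; they do not
demonstrate robustness to measurement noise, nonstationary receptor
properties, or the richer state topology of full published receptor
models. Problem sizes in tests and examples (e.g. 1000–2000 training
events, 20 s validations, one CPU) were chosen as representative
desk-scale runs of the published protocol.

## Numerical choices

* Bins are half-open `[k·dt, (k+1)·dt)`, 0-based, with a 1e-9-bin guard on
  edge round-off; impulses have unit amplitude (any physical scale is
  absorbed by the coefficients).
* Kernels are evaluated at bin centers; convolutions use FFT
  overlap–add, and the event-driven evaluation path (kernel scattering)
  agrees with it to 1e-9 relative — both paths are tested against a
  nested-loop evaluation of the series itself.
* Degenerate inputs: an event-free train predicts the constant c0; an
  all-zero NRMSE reference raises rather than returning NaN.
* Memory-window boundary: `active_events` is inclusive at age M_k; kernel
  support ends at the last bin inside the window.
* Generated trains end at their last event (duration configurable via a
  pad); RNG is `numpy.random.default_rng`, freshly seeded per call, no
  global state; all pipeline sub-seeds derive deterministically from the
  protocol seed.
* Coefficient JSON uses sorted keys and shortest-round-trip floats, so
  save → load → save is byte-identical.

## Known limitations

* The 4th-order cross-kernel fit is variance-limited: with fewer training
  events than ~2000 it can underperform the 3rd-order model it is meant to
  improve on. The spectral-truncation cutoff trades bias for variance; the
  default (1e-8) was fixed once and is not tuned per problem.
* Decay optimization is a local search over a 2-D landscape; pathological
  coefficient structures (a slow component that the fast set can mimic)
  can leave the slow decay weakly identified.
* The release model's parameter defaults are placeholders, not a
  calibration; the voltage-dependent magnesium block is available only
  through the ψm hook; metabotropic receptors, cleft diffusion PDEs and
  membrane dynamics are out of scope.
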