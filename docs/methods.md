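# Methods

## Model class and dynamics

Networks are collections of irreversible mass-action reactions over species
amounts in attomoles (amol); no volume/concentration conversion is attempted.
The balance equations are `dC/dt = ν·J(C)` with `J_B = k_B·Π_r C_r^s_rB`
over the reactants of reaction `B`. Catalytic steps are written with the
catalyst on both sides of the reaction, which keeps the rate law a pure
monomial and the catalyst's net stoichiometry zero. The sustained stimulus
is modeled by clamping the input species: its amount is set to the dose and
its derivative forced to zero. Transient-stimulus protocols, stochastic
simulation, delays and spatial effects are out of scope.

Candidate feedback loops are *injected terms*, not reactions: a positive
loop adds `+k_positive·[source]` and a negative loop adds
`−k_negative·[source]·[target]` to the target's balance equation. On export
these terms are materialized as equivalent reactions (catalytic production
`src → src + tgt`; bimolecular degradation `src + tgt → src`) so that
serialized models are self-contained.

## Numerics

* Integration: LSODA with analytic Jacobian, `rtol 1e-8`, `atol 1e-12` amol.
  Amounts that undershoot zero by less than ~10·atol are clipped to zero.
* Steady states: chunked integration (first chunk 300 s, doubling) until the
  relative derivative `max |dC/dt|/(1+|C|)` stays below `ss_tol = 1e-9` at two
  consecutive checkpoints, up to `t_max = 48 h`; non-convergence is flagged on
  the result, not raised. Once the relative derivative falls below `1e3·ss_tol`
  a Newton polish is attempted; the root is accepted only if it is
  componentwise close to the integrated state (same basin), non-negative, and
  linearly stable. Near a saddle-node ghost no root exists, so the slow
  transient is integrated through rather than short-circuited.
* Steady states are cached by (network content hash, dose, solver settings);
  a full sensitivity spectrum costs ~2·n_parameters critical-dose searches
  and reuses the base model's plateau estimates and bracket as the starting
  bracket for each perturbed search.

## Critical dose

All steady states start from the common resting initial condition; the
package deliberately does not perform a rising/falling hysteresis sweep,
because the construct of interest is the threshold seen by a resting cell.
A dose-response scan declares a switch when the largest single inter-dose
jump of the curve covers at least half of the curve's total range (an
all-or-none response concentrates its rise in the jump; a smooth
sub-threshold curve spreads it evenly) and the high plateau is at least
twice the low one. Plateaus are medians of the three lowest-dose points and
of the (up to three) highest-dose points beyond the jump. Fate
classification uses the midpoint of the plateaus, ties counting as
apoptosis. `Cd` is found by bisection to a default tolerance of
`dose_max/2000`, with `dose_max = 1e-2` amol, the in-vitro-equivalent
stimulus range; the returned `cd` is the upper end of the final bracket.

## Sensitivity protocol

One-at-a-time ±20% perturbations; only Cd *increases* are recorded
(`ΔCd = max(0, max(Cd₊, Cd₋) − Cd)`), since an increased apoptosis threshold
is the oncogenically relevant direction. `ΔCd ≥ 10%·Cd` marks a parameter
sensitive. A perturbation that abolishes apoptosis within `dose_max` is an
unbounded increase and therefore sensitive. When several parameters are
varied jointly, each moves in its own single-parameter Cd-increasing
direction (ties and no-effect default to the increase direction); duplicate
ids apply once. The 10% cutoff itself can be audited with `cutoff_roc`,
which sweeps the cutoff over the observed relative ΔCd values against an
external Boolean truth and reports TPR/FPR and Youden's J per cutoff, ties
broken toward the smaller cutoff. Global sensitivity methods (Sobol, Morris)
are deliberately out of scope; the protocol is strictly local.

## Mutation spectra and Hamming distance

Counts are binarized at ≥1 mutated sample per gene and mutation type.
Combined rules: *two types* — mutated if at least one of the pair is;
*three types* — mutated if at least two of the three are (the stricter
default), with the at-least-one variant available. Genes map onto parameter
order through an editable TSV; the map may be many-parameters-to-one-gene,
and one-parameter-to-many-genes is allowed behind a flag (OR of bits).
Production-process parameters are excluded from the map **and dropped from
both spectra** before comparison, keeping the two binary strings the same
length — the exclusion reflects that production rates correspond to gene
amplification/deletion rather than point mutations. Hamming distances are
only defined over identical id sequences; any reordering must be explicit,
and misaligned inputs raise instead of being silently reindexed.

## Feedback screening

The two loop types leave distinct fingerprints at a supra-critical probe
dose (default `1e-2` amol): negative loops shorten the **initial death
time**, positive loops lower the executioner's **steady level**. The death
time is defined operationally as the first crossing of 50% of the
executioner's own final steady level at that dose, located by the
integrator's event detection. Admissible strength ranges keep the relevant
metric within 20% of the unmodified model's value, evaluated as the maximal
contiguous prefix of a log-spaced grid (ranges are reported as single
intervals, matching how such calibrations are used). The HD-versus-strength
scan rebuilds the full sensitivity spectrum of the modified model at each
strength; the minimum-HD strength of a tied plateau is reported as the
plateau's middle grid point. Loops are only modeled onto the active-NFκB
role and only with the two term forms above.

## The synthetic module

`make_toy_network` builds a reduced network that preserves the architecture
the analysis needs, at desk scale: a conserved receptor pool cycling through
Complex-I and Complex-II analogs (half-saturating near the top of the
0–10⁻² amol dose range), an NFκB arm with slow dilution-like turnover
(synthesis plus equal-rate decay of both forms, pool ≈ 1 amol) driving an
inhibitor of both caspases, an initiator→executioner cascade, and
cooperative executioner self-amplification (`2·C3 + C3I → 3·C3`) as the
bistability source — the full-scale model achieves its all-or-none response
through its own structure; any switch-generating motif suffices to exercise
the protocol. The slow NFκB turnover is what lets injected negative
feedback act strongly on the *steady-state* survival arm (hence on Cd and
the sensitivity spectrum) at strengths that barely perturb the early
death-time transient, so planted loops are recoverable inside the
calibrated strength range.

Designed guarantees at the reference rates: survival at dose 0; a finite Cd
(~2.4×10⁻³ amol) inside the dose range; scaling the caspase-8 activation
rate `k_c8_act` by 0.8 raises Cd and by 0.6 abolishes apoptosis within
`dose_max`; one decoy parameter is fully decoupled from the fate readout;
the caspase-6 pair is a downstream readout with no influence on Cd; and
three basal-flux parameters are individually weak (relative ΔCd ≈ 1–6%) but
jointly significant, exercising the co-occurring-mutation accumulation
effect. The sensitive/insensitive label of every rate constant was
established with the dense-grid critical-dose oracle during generator
design and is re-verified by the test suite; the margins (insensitive
≤ ~6%, sensitive ≥ ~15% relative ΔCd) leave room for the per-instance
lognormal rate jitter (σ = 3%) used to generate independent instances.
Generator configurations that break the switch raise a validation error
rather than returning a silently monostable model.

`make_synthetic_mutations` emulates only the statistical structure the
comparison needs: one gene per non-excluded parameter, each mutation type's
bit matching the parameter's sensitivity bit with probability `p`
(independently across genes and types), counts cosmetic (0 versus a small
positive integer — binarization at ≥1 erases magnitudes). Consequently the
per-type projected HD is Binomial(n, 1−p) with mean `n(1−p)`, which is the
recovery target the tests check. The generator does not emulate mutational
signatures, gene lengths, hotspots, or cohort structure — so passing tests
validate the *pipeline*, not any biological claim about real cancer data.

## Problem sizes used in the checks

The bundled checks run the toy model (22 parameters): a 4000-point uniform
dose grid as the bisection oracle; five jittered instances for label
recovery; 120 seeds × 106 genes for the binomial HD means; 13-point strength
grids for phenotype calibration; and three instances × 9 strengths
(~0.3 decades apart) for planted-loop recovery, with the planted strength at
10⁻² amol⁻¹s⁻¹. The acceptance script uses a 2000-point grid and two planted
instances.

## Serialization

SBML import is restricted to the mass-action subset (monomial kinetic laws;
catalysts folded in; local parameters promoted with a reaction-scoped
prefix; unit compartments tolerated as factors). Anything else raises an
error naming the reaction. The declared substance units of an imported file
are recorded on the manifest, not converted. Because deposited models'
species naming cannot be assumed, the mapping of named roles
(stimulus, NFκB, caspases) to species ids is supplied by the caller.
Exports are deterministic (byte-identical per network) SBML L3V1 or TSV
tables.

## Known limitations

* The fate threshold (plateau midpoint) and the jump-dominance switch
  detector are heuristics; models whose response is steep but genuinely
  continuous may be classified as switching once the grid is coarse enough.
* `Cd` searches assume monotone fate in dose (survival below, apoptosis
  above); multi-threshold responses would need a different bracketing
  strategy.
* The caspase-6 role of the reduced model aliases the executioner readout;
  feedback sourced from it probes the same dynamics as caspase-3.
* Sensitivity caching keys on exact network content; changing solver
  tolerances invalidates nothing (they are part of the cache key) but mixing
  configs within one process grows the cache.
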