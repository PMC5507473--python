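# Methods

## Model

`scmfpep` predicts a peptide specificity profile by self-consistent
mean-field (SCMF) relaxation on a rotamer interaction graph. The state is
a ragged probability matrix **P** with one distribution per peptide
position over that position's rotamers (all amino acids' rotamers pooled,
so the converged marginals carry sequence information, not just
conformation). The mean-field energy of rotamer *r* at position *i* is its
one-body energy plus the **P**-weighted sum of its two-body energies with
all rotamers at all other positions; new probabilities are the per-position
Boltzmann distribution of those energies at temperature kT. The two maps
are iterated to a fixed point.

Assumptions inherited from mean-field theory: correlations between
positions are captured only through the averaged field, so strongly
coupled positions (e.g. a salt bridge whose two partners must co-occur)
are approximated — the per-position marginals can deviate substantially
from the exact Boltzmann marginals even when the iteration converges
tightly (the coupled-graph test suite prints these gaps next to the exact
enumeration oracle rather than asserting equality; observed max-marginal
gaps at moderate coupling are of order 0.1–0.5). What the method does
promise is self-consistency, determinism, and the exact answer in the
decoupled limit.

## From rotamers to amino acids, and across backbones

- **Amino-acid aggregation.** P_aa(bb,i) ∝ (Σ_{r∈aa} P(i,r)) / K_aa^γ,
  normalised over the amino acids actually present at the position; amino
  acids with no rotamers there get exactly 0 and are excluded from the
  denominator. γ interpolates between summing rotamer probabilities (γ=0,
  inflates amino acids with many library rotamers) and averaging them
  (γ=1, deflates them); the default 0.8 is a compromise that tracks
  background compositions well in calibration.
- **Energy tables.** E_bb(i,aa) = Σ_{r∈aa} E(i,r)·P(i,r) / K_aa^γ, with
  absent amino acids contributing 0 to downstream sums. Whether the
  backbone-weight energy sum should run over all 20 amino acids or only
  those present is ambiguous in principle; this package sums over those
  present (equivalently, absent amino acids contribute zero), which keeps
  the tables and the weights consistent.
- **Backbone weights.** W(bb,i) = softmax over backbones of
  −Σ_aa E_bb(i,aa)/kT, computed per position (W is (backbone, position)-
  indexed: each position weighs the M backbones independently, and each
  position's weights sum to 1 — the only reading under which the final
  weighted average is well defined). kT = ∞ gives exactly uniform 1/M.
- **Final profile.** P(i,aa) = Σ_bb P_aa(bb,i)·W(bb,i): a convex
  combination of distributions, so rows sum to 1 by construction.
- **Background enrichment.** Optionally each frequency is divided by a
  strictly positive background composition (single row broadcasts to all
  positions) and rows are renormalised — the output is a frequency
  profile, so the unnormalised quotients must be rescaled. Zero background
  entries are refused with a pointer to pseudo-count smoothing; no default
  background is applied.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| kT | 0.6 | energy | Boltzmann temperature (β = 1/kT); the most system-dependent knob — flatter profiles at high kT |
| λ (lam) | 0.5 | — | memory weight of the damped update; affects convergence path, not the fixed point |
| γ (gamma) | 0.8 | — | rotamer-count exponent in the amino-acid aggregation |
| threshold | 100 | energy | upper clamp applied to every one-body and two-body input energy |
| tol | 1e-7 | probability | convergence tolerance (see below) |
| max_iter | 1000 | — | sweep cap; exceeding it sets `converged=False`, never raises |

Defaults other than γ sit inside the standard calibration grid
(λ ∈ {0.25, 0.5, 0.75}, γ ∈ {0…1 step 0.2}, threshold ∈ {5, 10, 50, 100,
250, 500}, kT ∈ {0.2…1.0 step 0.2}; 540 combinations), which
`scmfpep.optimize.grid_search` ranks by 1 − cosine between the
position-averaged predicted composition and a target background
composition. All are overridable per run.

## Numerical choices

- **Truncation point.** The clamp is applied independently to each input
  energy (one-body and two-body entries), upper side only, before the
  probability-weighted sum — not to the summed E(i,r). This keeps the
  field linear in **P** and prevents one clash term from dominating while
  leaving favourable energies untouched.
- **Convergence criterion.** Each sweep computes the field of the current
  **P** and the resulting Boltzmann proposal; convergence is declared when
  the proposal would change no entry by more than `tol` (the undamped
  change). The returned state therefore satisfies
  `fixed_point_residual ≤ tol` by construction, and its energies are the
  field of the returned **P**. Measuring the change after damping instead
  would only bound the fixed-point gap up to the iteration map's Lipschitz
  constant, which is not observable; the undamped criterion makes the
  self-consistency contract unconditional. While unconverged, the damped
  update λ·P_prev + (1−λ)·P_new is applied.
- **Update order.** Jacobi-style: all energies are computed from the
  previous full **P**, then all positions update simultaneously (not
  position-by-position Gauss–Seidel).
- **Softmax stability.** The per-position minimum energy is subtracted
  before exponentiating, making the distribution exactly invariant to a
  constant shift of a position's energies and immune to underflow.
- **Degenerate inputs.** K_j = 1 positions are legal (probability 1); a
  single-backbone ensemble gets weight 1; non-convergence is reported in
  diagnostics (with a warning if *no* backbone converged) and the result
  is still returned for the caller to judge.
- **Determinism.** The predictor contains no randomness; identical inputs
  give bit-identical outputs. All stochastic components (fixture
  generation, sequence sampling, JSD p-values) take explicit seeds.

## Evaluation metrics

- Cosine similarity is computed between the two flattened N×20 frequency
  matrices (one number per profile). Frobenius distance likewise over all
  entries; two profiles disagreeing by disjoint point masses at every one
  of n positions score exactly √(2n).
- AAD is the mean of |pred − exp| over all N×20 entries. Under this
  definition the disjoint-point-mass extreme is 2/20 = 0.1.
- JSD uses base-2 logarithms so each position's divergence lies in [0, 1];
  the profile value is the mean over positions. Its empirical p-value
  counts random profiles (drawn uniformly from the 20-simplex, i.e.
  symmetric Dirichlet(1)) whose JSD against the experimental position is
  ≤ the observed one, with the add-one estimator
  (1 + count)/(n_random + 1), so 1/(n_random+1) is the attainable minimum
  and the estimate is never zero. Positions count as significant at
  p ≤ 0.05 (configurable).
- The positional AUC labels amino acids with experimental frequency ≥ 0.1
  (configurable) as tolerated and computes the tie-aware Mann–Whitney
  statistic of the predicted frequencies; positions lacking either class
  are skipped, and an all-skipped profile reports the AUC as missing with
  an explanation rather than a number. Note the tie handling means a pair
  of disjoint point masses does not reach AUC 0 (the 18 shared zeros tie);
  the worst score 0 is attained by tie-free inverted rankings.
- Sequence scoring is Σ_i log2(P(i, seq_i) + ε) with ε = 1e-6; any
  strictly monotone per-position score yields the same AUC ordering. SSAL
  is the experimental-profile ROC AUC minus the predicted-profile ROC AUC
  on recognised vs non-recognised sets, clamped at 0 (a prediction that
  discriminates better than the experimental profile is not penalised).
- Information content per position is log2(20) − H (bits), averaged over
  positions; the reported difference is predicted − experimental.
- Experimental profiles from sequence sets deduplicate exact duplicates
  for protease-style cleavage data and keep multiplicity for
  binding/PRD-style data (`dedupe` flag).

## Synthetic fixtures and what they do (not) show

The toy generator emulates the *structure* of rotamer interaction graphs:
per-rotamer Gaussian strain around per-(position, amino-acid) preference
offsets, Gaussian two-body blocks on a random subset of position pairs,
and deliberately unequal rotamer counts per amino acid (S/T/R-like amino
acids get up to 6 rotamers, G/A one) so the γ-correction is exercised.
It does not emulate real energetics: no physical energy function, no
backbone-dependent rotamer libraries, no correlated couplings. Passing
tests therefore demonstrate algorithmic correctness (fixed points,
closed-form limits, exact-enumeration agreement where exactness is
expected, parameter recovery under a known ground truth) — not predictive
accuracy on real receptor systems, which depends on the energy model that
produced the interaction graphs.

The brute-force oracle enumerates all Π K_j rotamer assignments (capped at
10^6), weights them by exp(−E_total/kT) using **untruncated** energies —
truncation is a mean-field device, not part of the physical distribution —
and marginalises exactly, also returning the log partition function. It is
the ground truth for all Boltzmann-limit tests.

Test problem sizes (positions, rotamer counts, backbone counts, seed
counts such as 50 decoupled / 20 coupled graphs, 100 recovery replicates,
and the reduced 540-point grid-search fixture) were chosen so the entire
suite runs in well under a minute while still covering every code path at
meaningful scale.

## Known limitations

- Mean-field marginals are approximate for coupled graphs; no error bound
  is provided, only the self-consistency residual and the optional
  enumeration oracle for small problems.
- kT is system-dependent; a value calibrated for one receptor family can
  flatten or sharpen profiles of another. Per-family recalibration via the
  grid search is expected.
- The background composition is user-supplied; none is bundled beyond the
  uniform constructor.
- Phosphorylated or otherwise modified residues are out of scope: the
  alphabet is the 20 canonical amino acids.
- Receptor-side rotamers are not modelled; graphs describe peptide
  positions against a fixed (per-backbone) receptor.
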