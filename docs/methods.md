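# Methods

This note records the model, the numerical choices and the design
decisions behind `playnet`, and what the synthetic-data experiments do
and do not demonstrate.

## Zone geometry

The game's published description fixes the zone *roles* — one food zone,
four snap-to-plate zones each strictly containing a plate zone extended
upward for stacked food, and seven other regions — but not their pixel
coordinates. The shipped default layout therefore only claims mutual
consistency between simulator and scorer: a bottom band (y ∈ [0.70, 1])
is the food zone, the snap-to-plate zones tile the mid-screen row
(y ∈ [0.35, 0.70]) with plate rectangles nested inside, four character
zones sit above them and three background strips tile the top. All
coordinates are normalised to [0,1]², origin top-left, y downward; raw
device-point logs are divided by the configured screen size on read.
Vertices are numbered so the plate set is ψ = {4, 5, 6, 7}. Any layout
satisfying the role invariants can be supplied as YAML/JSON; validation
names the violated invariant.

Point classification is total and deterministic: containment is
edge-inclusive, overlaps resolve by role precedence
(plate > snap-to-plate > food > other) and then by lower vertex index;
points covered by no zone fall back to a designated background vertex.
Ties on shared edges are therefore never ambiguous.

## Swipe assembly

A swipe runs from a `down` event to the first `up` event assigned to it.
When hardware touch ids are present they are trusted. Without ids, each
incoming `move`/`up` contact is assigned to the open swipe whose
predicted next location is nearest (Euclidean). The predictor fits the
unique cubic polynomial through the last four contacts, parameterised by
timestamp, and extrapolates to the incoming timestamp; this is the
not-a-knot cubic spline on four points, chosen over a natural spline
because it reproduces polynomial trajectories (a quadratic arc
extrapolates exactly), which is the behaviour a short-horizon motion
predictor needs. With fewer than four contacts the last two are
extrapolated linearly; a single contact predicts itself; degenerate
(repeated) timestamps fall back the same way.

Two robustness choices go beyond the minimal rule set: a configurable
maximum assignment distance (default 0.25 normalised units) keeps a log
with dropped `up` events from chaining distant contacts — a too-far
`move` starts a recovery swipe instead — and an orphan `up` with no open
swipe is dropped with a warning rather than inventing a swipe.

## Transition networks and rewiring

T counts between-zone swipes only (T_ii = 0): taps and within-zone
swipes carry no inter-zone information. One wording in the source
material could be read as giving within-zone swipes weight during
normalisation; the formal definition (diagonal zero) is followed.

Rewiring operates on the retained per-swipe endpoint list, not the
aggregated matrix, because the reconnection rule depends on each swipe's
true origin. Direct variant: f → s_k or f → ψ_k becomes f → ψ_k; any
other swipe ending in ψ_k is reconnected to s_k. Indirect variant:
origins in {f} ∪ ψ deliver to ψ_k, except a plate-to-own-snap-zone swipe
(kept as s_k — the food falls back onto the same plate); other swipes
into plates are reconnected as in the direct case, so plate in-edges
come only from {f} ∪ ψ. Both rewirings conserve the total swipe count.

The baseline C_ij = 0.01 is added on *all* entries including the
diagonal: the constant diagonal shift moves every eigenvalue equally and
leaves eigenvectors unchanged, while strict positivity of A guarantees a
simple positive Perron left eigenvector. Sessions with ΣT = 0 yield
A = C, are flagged degenerate, and score 0 by symmetry (the plate
entries tie the rest exactly at q = 0, dominate for q < 0 and are
dominated for q > 0).

## Sharing score

The leading left eigenpair is computed by dense eigendecomposition of
the transpose (16×16 is trivial) after shifting by c·I with
c = max(0, −min diag), which makes the matrix non-negative with strictly
positive off-diagonals — primitive, so the eigenvalue of largest real
part is the real simple Perron root with positive eigenvector, for every
perturbation in the bracket. Eigenvectors are unit-norm and oriented
positive; only rankings matter, so the normalisation convention has no
behavioural effect.

Plate dominance is *strict*: min over ψ must exceed max over V∖ψ. Ties
fail. This makes the degenerate score exactly 0 and the supremum
well-defined. The perturbation is uniform across ψ (a single scalar);
per-vertex perturbations are out of scope.

The score is sup{q : dominance holds}, located by bisection to
tol = 1e-4 on a default bracket (−1, 1) (operative values are of order
±0.1; the bracket doubles per side up to |q| = 16 if dominance does not
hold at the lower end or fails to fail at the upper end). Monotonicity
of the indicator in q is assumed — as the sup/bisection framing implies
— but verified per session on a 64-point grid; a non-step pattern (never
observed; the baseline coupling keeps the spectrum well behaved) diverts
to a dense-grid supremum and flags `monotone=False`.

An independent reference, `grid_scan_score`, locates the flip by
scanning a coarse 1e-2 grid and then the bracketing coarse cell at step
1e-5; under the verified step structure this equals a full 1e-5 scan of
the bracket at a fraction of the cost. Tests require
|bisection − grid| ≤ 2·tol across mixed-strategy sessions.

## Synthetic gameplay

Session lengths are expressed in cycles (default 12 ≈ a 5-minute game);
each cycle delivers four food pieces. A cycle is stacked with
probability `p_stack` (4× f → one plate, then 3 inter-plate
redistributions); otherwise each piece is delivered directly with
probability `p_direct` (default 1.0) or via a one-piece
drop-then-redistribute detour. Off-task swipes (between two distinct
"other" zones), taps and within-zone wiggles arrive as Poisson counts
per cycle (defaults 1.0, 0, 0); trajectories are quadratic Bézier
curves sampled at 60 Hz with optional interior jitter (endpoints stay
exact so endpoint classification is noise-free by construction), and
`multitouch_prob` pulls a swipe's start into the previous swipe's
interval to create genuine temporal overlap. Every swipe carries a
ground-truth label, and the pipeline's counts are required to match the
labels exactly on noise-free logs.

Cohorts draw integer ages uniformly per group (30–72 months) and map age
to strategy parameters through per-group linear slopes centred at 51
months, with probabilities clipped to [0, 1]. The preset recovery
conditions are: *direct vs stacker* — two groups of 100, matched on
everything (12 cycles, off-task rate 1.0, tap rate 0.5) except
p_stack = 0.05 vs 0.85; *age trend* — one group whose p_stack rises
0.012/month (≈0.1 at 30 months to ≈0.6 at 72), against a flat control at
0.35. Effect sizes are free parameters chosen once to make the recovery
experiments well powered at n = 100/group; they emulate the *structure*
of the group and age effects of interest, not the clinical cohort's
effect magnitudes. Sex is a label (ratio 0.5) and severity an optional
categorical with per-group probabilities, so stratified analyses are
exercisable without any claim of realism. What passing recovery tests
show is that the pipeline detects strategy and age structure it is
pointed at; they say nothing about effect sizes, kinematics or
heterogeneity in real children.

## Cohort statistics

Wilcoxon rank-sum contrasts are two-sided (the conventional choice; the
sidedness is not otherwise dictated), exact for ≤25 per side without
ties, normal approximation with tie and continuity correction otherwise;
two identical constant samples return p = 1. Spearman correlations use
average ranks; p-values come from the t approximation except n ≤ 9,
where the exact permutation distribution is enumerated. Zero variance
leaves r undefined (NaN, with a warning). No multiple-testing correction
is applied by default — raw pairwise p-values are the convention here —
but a Benjamini–Hochberg column is available opt-in. Notches are
median ± 1.57·IQR/√n (the McGill convention). Severity and sex
stratification relabel groups and reuse the same contrast machinery.
Quadratic fit lines with 68% prediction bands are plotting helpers only,
not part of the statistical contract.

## Problem sizes and limitations

Default experiment sizes — 100 sessions for the bisection/grid
equivalence, 50 seeds for ground-truth recovery and id-equivalence,
100 + 100 participants for the strategy contrast, 100 for the age trend
and 20 flat replicates of 50 — were chosen as the smallest cohorts at
which the recovery effects are decisively powered; all run in well under
two minutes each on one CPU.

Known limitations: the default geometry is a stand-in, not the game's
true layout; the predictor-based assignment is only validated on
trajectories separated by ≥0.1 normalised units (crossing fingers are
genuinely ambiguous without hardware ids); the simulator's smooth Bézier
kinematics carry no information about motor control, so kinematic
analyses are out of scope; and the flat-cohort false-positive check is a
single pre-registered draw of a stochastic event, not a guarantee.
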