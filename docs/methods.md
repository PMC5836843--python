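# Methods

## Model

The object of study is the Boltzmann ensemble of pseudoknot-free RNA
secondary structures: every non-crossing set of allowed base pairs
(Watson–Crick plus G·U wobble, at least `min_hairpin = 3` unpaired bases in
every hairpin), weighted by `exp(−E/RT)` under a nearest-neighbor loop
decomposition. Positions are 1-based; a structure is equivalently the
upper-triangular 0/1 matrix σ with σ_ij = 1 for each pair. The Hamming
distance between two structures is the size of the symmetric difference of
their pair sets.

Given a reference structure σ, the ensemble is classified by distance:
`Z(d, σ)` is the Boltzmann mass at distance exactly d, and `p(d) = Z(d)/Z`.
The pair-and-distance-resolved quantities are the inside partition function
`Z^b_ij(a)` (structures of `[i, j]` containing pair (i, j), distance measured
against the reference pairs lying inside `[i, j]`) and the outside partition
function `W^b_ij(t)` (everything outside the pair, distance against the
remaining reference pairs). Because inside and outside structures combine
freely, the joint mass at inside distance a and outside distance t is exactly
`Z^b(a) · W^b(t)`, and the BPP matrix restricted to a distance range is a
ratio of range sums (numerator `Σ_d Σ_t Z^b(d−t) W^b(t)`, denominator
`Σ_d Z(d)`).

## Distance-classified recursions

Both recursions are the SCFG inside/outside pair of McCaskill's algorithm
with five inside states (general `Z`, rightmost-outer-pair `Z1`, paired
`Z^b`, multiloop `Z^m`, single-branch multiloop `Z^m1`) and one outside state
`W^b`. Every transition multiplies its Boltzmann factor by `x^g`, where the
gain g counts the reference pairs the transition makes unsatisfiable, plus
`1 − 2σ_ij` when the transition closes pair (i, j) (+1 for a non-reference
pair, −1 for satisfying a reference pair). All gains reduce to two O(1)
prefix-sum primitives: the number of reference pairs inside an interval
(`gZ0`) and the number straddling a cut (`g0`). The derivation rule is
exhaustive and local: across any decomposition of a region into
sub-regions, each reference pair is charged exactly once — by the child
whose region contains it, or by the transition if no child region does.

The outside recursion runs from long spans to short. Its three structural
cases are: (i) exterior — (i, j) enclosed by nothing, flanked by free
subensembles `Z(1, i−1) · Z(j+1, L)`; (ii) a two-loop below an enclosing pair
(h, ℓ); (iii) a multiloop closed by (h, ℓ) with branches 5' of i, 3' of j, or
both. One subtlety is worth recording: the multiloop closure transition must
charge the affine penalty `a + b` of the enclosing pair *and* the branch
penalty `b` of (i, j) itself — inside, that b is charged when the closure
consumes `Z^m/Z^m1`; outside, nothing else charges it. The omission is
invisible on short oracle fixtures (≤ 16 nt ensembles barely reach
branch-in-multiloop outside contexts) and was caught by an expected-pair-count
identity (the derivative of log Z with respect to a uniform pair weight must
equal `Σ_ij Z^b W^b / Z`) and by a designed nested-multiloop sequence; both
are permanent tests.

The multiloop enclosing-pair scan is factorized through intermediates
`M(i, ℓ) = Σ_h W^b(h, ℓ) Z^m(h+1, i−1) x^{…}` and the mirror-image `N(j, h)`,
keeping one evaluation point at O(L³) despite the gains coupling h and ℓ.
The two-loop scans honor a configurable 30-base interior-loop cap (disabled
in oracle comparisons on short sequences).

## Spectral assembly

The coefficient arrays are recovered by evaluating the recursions at the
`Δ = d_max + 1` roots of unity `x_r = exp(2πi r/Δ)` and applying the inverse
DFT `Z(d) = (1/Δ) Σ_r x_r^{−d} Z̃(x_r)`. `d_max` defaults to L, a safe bound
on the distance support (predicted plus reference pairs never exceed L), so
no aliasing can occur at the default; the transform is always taken over
`[0, d_max]` and sliced, avoiding any spectrum-shift ambiguity. Coefficients
are real, so only `⌊Δ/2⌋ + 1` points are evaluated and the rest filled by
conjugate symmetry. Products of polynomials (the inside·outside numerator,
Eq. above) are pointwise complex products — no convolution is materialized.
Evaluation points are independent: any execution order (or worker count)
gives bit-identical output, and nothing in the core draws random numbers.

Numerical tolerances: recovered coefficients are exact up to FFT roundoff,
about 1e−15 of the total partition function. Values within `1e−13 · Z` of
zero are set to exactly zero (this keeps parity-forbidden distance cells
exactly empty); a coefficient below `−1e−8 · Z` raises an error instead of
being clamped, since genuine roundoff cannot reach that size — such a value
would indicate an undersized transform or a defect. A distance range whose
mass falls below `1e−13 · Z` is reported as empty rather than divided by;
range-restricted BPPs for ranges near that floor are precision-limited
(absolute coefficient error divided by range mass), which is why oracle
comparisons use ranges holding at least 1e−6 of the ensemble. BPP entries
within 1e−12 of 1 are snapped to 1. An optional per-base rescaling constant
guards against overflow at lengths beyond a few hundred bases (default 1;
results are invariant under rescaling, which is tested).

The two-reference variant attaches gains against each reference to its own
dummy variable and evaluates on a `Δ₁ × Δ₂` grid of root pairs; the 2-D
inverse FFT gives `p(d₁, d₂)`. Cost is `Δ₁Δ₂` inside evaluations, intended
for lengths up to roughly 120 at desk scale.

## Energy model

The default parameter table (`data/turner2004_min.txt`) is a deliberately
minimal Turner-2004-style set: the 6×6 stacking matrix (Watson–Crick values
from the standard optical-melting fits, representative wobble values),
loop-size initiation penalties for hairpins, bulges and internal loops with
`1.75 R T ln(n/n_max)` extrapolation, a linear asymmetry penalty (0.6/nt,
cap 3.0), an affine multiloop (a = 3.4, b = 0.4, c = 0 kcal/mol), and a
0.5 kcal/mol terminal penalty on non-GC closing pairs of hairpins and
two-loops. No dangling ends, coaxial stacking, special tetraloops, or
sequence-dependent loop terms: the decomposition method is parameter-agnostic,
and keeping the loop model small lets the recursions and the enumeration
oracle share an exactly identical energy function — which is what the tests
prove. Absolute probabilities on real sequences will differ from
full-featured parameter sets; distances, conservation laws and decompositions
do not depend on the parameter values.

Temperatures other than 37 °C rescale the table by splitting dG37 into
enthalpy and entropy with an assumed dH/dG37 ratio of 5 for stacks and purely
entropic loop initiations — a documented approximation good enough for
qualitative melting behaviour (used by the thermometer-style example), not a
fitted melting model. A second built-in "toy" model (−1 kcal/mol per stacked
pair, all loops free) keeps small oracle cases human-checkable.

## Decoding and peak ranges

The γ-centroid structure of a BPP matrix maximizes `Σ ((γ+1)P_ij − 1)` over
non-crossing pair sets via an interval DP; only pairs with `P_ij > 1/(γ+1)`
can contribute. Ties are broken deterministically: fewer pairs first, then
the earliest admissible pair at each choice point. Peak ranges on `p(d)`
follow a mask-then-split rule: distances with `p(d) ≤ exp(Q/RT)` (default
Q = −10 kcal/mol, θ ≈ 8.9e−8 at 310 K) are discarded first, then each
surviving run is split at every *strict* local minimum d′
(`p(d′−1) > p(d′) < p(d′+1)`); plateaus are not split points. Adjacent
ranges share the boundary bin, and the shared bin counts in both masses — so
per-range masses may sum to slightly more than the support mass. Whether a
sub-threshold gap inside a peak should split it was an open choice; masking
first means it does.

## Synthetic data and what the tests show

Test inputs are generated, not stored: random sequences with a configurable
GC content and random valid reference structures sampled by interval
recursion (seed-reproducible; seeds touch only fixture generation). The
ground-truth engine enumerates every structure of sequences up to ~20 nt,
scores them with the same loop decomposition, and reduces the table by
folds; a Nussinov-style counting DP independently checks completeness, and a
separate real-valued McCaskill implementation (no distance machinery) checks
the x = 1 collapse. Oracle equivalence on random instances (lengths 8–14,
both energy models) covers hairpins, stacks, bulges, internal loops,
multiloops and exterior multi-helix contexts; the designed 23-nt
nested-multiloop fixture covers the branch-in-multiloop geometry random
short fixtures miss. What passing tests do **not** show: agreement with
full-featured thermodynamic parameter sets on long natural sequences
(dangles, coaxial stacking and tetraloop bonuses are absent by design), and
behaviour at lengths where the O(Δ·L³) transform becomes the binding cost.
Verification problem sizes — enumeration to 14–23 nt, conservation and
full-range identities to 60 nt, 2-D to 10-mers — were chosen so every check
runs from a cold start in seconds while exercising all recursion cases.

## Known limitations

* Pseudoknots are out of scope (the distance is defined on nested structures).
* The interior-loop cap (30 unpaired bases) is the standard accuracy/cost
  trade-off; disable it for exact small-scale work.
* A peak in `p(d)` is a candidate cluster, not a guaranteed one: members of a
  range can be up to twice the range width apart. The 2-D projection onto two
  representatives is the cross-check.
* Ranges with mass near the 1e−13·Z floor are precision-limited; widen the
  range or work at smaller L if their BPPs matter.
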