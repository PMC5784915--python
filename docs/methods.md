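# Methods

## Model

The package analyzes directed networks through the stochastic matrix of a
random walk with uniform restart. From the 0/1 adjacency A (column = source,
row = target; duplicate edges collapsed, self-loops kept) the transition
matrix S divides each non-dangling column by its out-degree and replaces
dangling columns by the uniform vector 1/N. The Google matrix
G = αS + (1−α)/N·E (E all ones) is column-stochastic and, for α < 1,
irreducible, so its unit eigenvector — the PageRank — is unique and
positive. CheiRank is the PageRank of the edge-reversed network, with
dangling handling applied to the reversed network independently. The
damping factor defaults to α = 0.85, the standard choice for both web and
biological network studies; it is configurable everywhere.

Interaction signs (activation/inhibition) and layer labels
(signaling/transcription) are carried as edge metadata only; all matrices
are unsigned. Label matching between gene lists and networks is exact and
case-sensitive — no alias resolution is attempted, so callers should report
both raw and mapped set sizes.

## Reduced Google matrix

For a subset of N_r nodes, G is partitioned into blocks G_rr, G_rs, G_sr,
G_ss, where "s" indexes the complementary scattering network. Each block is
a slice of G itself (link part + teleportation + dangling correction),
implemented matrix-free as a sparse slice plus analytic rank-one terms, so
G_ss is never densified at production scale. The reduced matrix
G_R = G_rr + G_rs(1−G_ss)^{-1}G_sr is evaluated in two independent ways:

* **Projected series** (production path): the leading eigentriple
  (λ_c, ψ_R, ψ_L) of G_ss is found by power iteration on G_ss and its
  transpose (normalizations Σψ_R = 1, ψ_L·ψ_R = 1). The projector
  component is the rank-one outer product
  G_pr = (G_rs ψ_R)(ψ_L^T G_sr)/(1−λ_c). The hidden component is computed
  column-by-column: deflate the corresponding column of G_sr with
  Q_c = 1 − ψ_Rψ_L^T, iterate v ← Q_c G_ss v accumulating the Neumann
  series until the L1 increment drops below tolerance, and map back through
  G_rs. Deflation removes the λ_c pole, so increments decay with ratio
  roughly α and a few tens to a couple of hundred terms suffice.
* **Dense resolvent** (cross-check): an explicit solve of
  (1 − G_ss) X = G_sr, feasible up to a few thousand nodes. The test suite
  requires element-wise agreement of the two routes within 1e-8 across 100
  seeded fixtures; observed discrepancies are ~1e-12.

1 − λ_c is evaluated as ‖G_rs ψ_R‖₁ (the probability leaking from the
scattering network into the subset per step), which is exact by column
stochasticity and remains accurate when λ_c is close to 1; λ_c is
re-evaluated on the converged eigenvector so the two estimates agree to
machine precision. The identity 1 − λ_c ≈ Σ_P (the subset's global
PageRank mass) is reported as a diagnostic and asserted only within a
factor of two — it is an approximate relation, not an identity.

Entries of G_qr can be slightly negative because Q_c is not
positivity-preserving. They are retained verbatim; the summary metric
`negative_weight` records their total magnitude divided by N_r. On curated
pathway subsets of real networks this weight is reported to be of order
1e-3; on random subsets of random fixtures — which carry no coherent
PageRank mass — it can reach a few times 1e-2. This is a property of the
inputs, not a numerical artifact: the decomposition still matches the dense
resolvent element-wise.

Component weights W_rr, W_pr, W_qr (entry sums divided by N_r) sum to one
by construction; the suite asserts the sum to 1e-10. The degenerate case
subset = whole network is accepted and returns G_R = G with zero projector
and hidden parts — convenient as an identity case in tests.

## Hidden-interaction calling and two-condition comparison

Only the off-diagonal part G_qrnd scores interactions; the diagonal G_qrd
is the probability of leaving a node and returning to it and is never
reported as a link. A directed pair is called when G_qrnd exceeds the
threshold (default 0.01, the conventional cut); the reported count uses
ordered off-diagonal pairs. Across two conditions sharing the subset,
called pairs are classified common / emergent / disappearing; `top_k`
truncates each class by descending score with a deterministic (score,
source, target) tie-break.

Rank shifts between conditions use decimal log-ratios of the rank indexes
on the common node set; selections at ±1σ and ±2σ per axis and tail are
precomputed for enrichment-style exports. Local subnetwork PageRanks come
from the eigenvalue-1 eigenvector of G_R; by the fixed-point property they
reproduce the restricted global PageRank up to normalization, and the test
suite checks order agreement wherever probabilities are not numerically
tied (ties are broken by ascending node label, the package-wide rule).
Connectivity accounting uses weak (direction-blind) components. Path
explanations enumerate all shortest simple directed paths and all simple
paths exactly one edge longer.

## Spectrum

Leading eigenvalues of G are computed with implicitly restarted Arnoldi on
the matrix-free operator (dense fallback for small N or k close to N),
sorted by modulus, with each residual required below 1e-8 and eigenvector
phase fixed by making the largest-modulus component real-positive. Because
non-unit eigenvectors of the column-stochastic S are orthogonal to the
uniform left eigenvector, the teleportation term vanishes on them and every
non-leading eigenvalue of G is exactly α times an eigenvalue of S; the
suite verifies this as an eigenpair identity (G ψ = αλ ψ) rather than by
matching two independently computed spectra, which is ill-conditioned for
near-degenerate nonsymmetric eigenvalues.

Localization is measured by the inverse participation ratio
ξ = (Σ|ψ|²)²/Σ|ψ|⁴, the effective support size, ranging from 1 (single
site) to N (uniform). This is the standard estimator consistent with those
limits; a variant formula sometimes printed without the outer square is
dimensionally inconsistent with them and is not used.

## Synthetic study conditions

The fixture generator emulates a curated signaling network at SIGNOR scale:
defaults n = 2432 equivalent, mean out-degree 2.7 (≈ 6569 links per 2432
nodes), 10% dangling nodes, and fan-like hubs drawing ten times the mean
out-degree, with geometric (heavy-tailed) per-node out-degrees and uniform
target choice. Non-hub, non-dangling nodes draw at least one out-link so
the realized dangling fraction tracks the requested one. The planted-relay
generator adds a directed chain between two subset nodes through external
relay nodes (and removes any direct edge between them), giving a known
ground-truth hidden link. The two-condition generator keeps a signaling
layer bit-identical and rewires a controllable fraction of a
transcription-factor fan-out layer, resampling targets outside each
regulator's original fan so that full rewiring is observable.

What these fixtures do not emulate: reciprocal-edge enrichment, motif
statistics, degree–degree correlations, or the coherent modular structure
of real pathways. Passing tests therefore demonstrate the correctness of
the linear-algebraic machinery and the detectability of planted indirect
routes, not biological realism; reproduction of published real-network
counts requires the original third-party inputs (see README).

## Numerical choices

* Power iteration: L1 residual < 1e-12, max 10 000 iterations, uniform
  start. Rank indexes: descending probability, ties broken by ascending
  node label.
* Deflated series: L1 increment < 1e-12, max 10 000 terms (typically well
  under 200 at the sizes used); non-convergence raises with the last
  increment.
* 2DRank sweep order within each growing square: new right column
  top-to-bottom (increasing K*), then new bottom row left-to-right
  (increasing K). Other conventions exist; this one is fixed and matched by
  an exhaustive-enumeration oracle in the tests.
* Dense matrices are formed only for oracles and exports (N ≤ 2000); all
  production paths are matrix-free sparse.
* Problem sizes in the acceptance script — a 2432-node study-scale run, a
  20-instance decomposition-fidelity grid (n ≤ 100), 200-node relay
  fixtures — were chosen to mirror the scale of curated signaling networks
  while keeping a full rerun in the order of seconds.

## Known limitations

* No identifier mapping: gene lists must use the network's exact labels.
* Hidden-interaction counts depend on the documented ordered-off-diagonal
  convention; counts published under other conventions (unordered pairs,
  diagonal included) will differ.
* The Arnoldi path returns a *numerical* leading block of the spectrum;
  clustered eigenvalues near the α-disk boundary may be resolved in a
  different order between runs of different k.
* Networks beyond ~10⁶ nodes (where even N_s-length dense vectors per
  series term become costly) are out of scope.
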