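# Methods

## Structure model

An RNA secondary structure is a set of complementary (AU, GC, GU),
non-crossing base pairs with pairwise distinct ends over a sequence in
`{A, C, G, U}`; positions are 1-based. Pseudoknots are outside the model. A
pseudo base pair `a0 = (0, n+1)` closes the external loop, turning every
structure into a rooted loop tree in which the parent of a pair is its
minimal enclosing pair and `chi(a)` are the directly enclosed children:
hairpins have no children, stacks/bulges/interior loops one, multiloops at
least two. Hairpin loops must contain at least `min_hairpin` unpaired
positions (default 3, the standard steric constraint). Lonely pairs are
allowed; no canonical-helix restriction is imposed. The candidate-pair
universe — all complementary `(i, j)` with `j − i − 1 ≥ min_hairpin` — is
shared by the enumerator, the partition function and the aligner, so all
components quantify the same state space.

## Energy model

The package's energy model is deliberately simple but *strictly
loop-decomposable*: `E(S) = Σ_a E_loop(a, chi(a))`, summed over the loop
tree including the external loop. Reimplementing a full published
nearest-neighbor parameter set is out of scope; everything the package
establishes (the exact factorization below, the approximation bounds, DP
optimality) holds for any loop-decomposable model, so the defaults are
configuration, not science. Loop contributions (kcal/mol):

* **Stacks** (single child, zero unpaired): a 6×6 table over the
  complementary pair types derived from a per-pair-type strength
  (GC 2.1, AU 1.1, GU 0.7; energy `−(s_closing + s_inner)/1.3`), giving the
  canonical GC > AU > GU hierarchy with values in about [−3.2, −1.1].
* **Hairpins**: tabulated penalties for sizes 3–9 (5.0 … 6.0), extrapolated
  beyond the table by `1.75·RT·ln(size/size_max)` (Jacobson–Stockmayer
  form); sizes below the table floor clamp to the size-3 entry, which is
  only reachable when `min_hairpin < 3` is configured explicitly.
* **Bulge/interior loops** (single child, ≥1 unpaired): a size-only table
  for 1–6 total unpaired positions (3.6, 2.9, 3.2, 3.6, 4.0, 4.3) with the
  same logarithmic extrapolation; no asymmetry or mismatch terms.
* **Multiloops**: affine, `3.4 + 0.4·|chi(a)| + 0.0·unpaired`.
* **External loop**: a constant, default 0.
* `RT = 0.6163` kcal/mol (37 °C).

Parameters serialize to a flat `key = value` text config
(`stack.GC.AU`, `hairpin.4`, `multiloop.branch`, …), so alternative
parameterizations — including ones exported from an external
thermodynamics engine — can be dropped in without code changes. Dangling
ends, coaxial stacking and enthalpy/entropy temperature rescaling are
deliberately absent: none are needed for the loop-decomposition identities.

## Partition function and in-loop probabilities

`compute_ensemble` fills, per sequence, the inside partition functions
`Z_in[(i,j)]` over candidate pairs by loop type; multiloop contents use a
region table `Qm1[x][y]` (≥1 branch in `x..y`, branch weight
`e^{−b/RT}·Z_in`, unpaired weight `e^{−c/RT}`) with a unique first-branch
decomposition, so every structure is counted exactly once. External
prefix/suffix arrays give `Z` and the external-pair probabilities
`P_ext[a'] = Ze(i−1)·Z_in[a']·Ẑ(j+1)/Ze(n)`.

The outside pass visits candidates by decreasing span and distributes each
parent's probability over its possible direct children. Given parent
`a = (k, l)`, the in-loop mass of child `a' = (i, j)` splits by context:

* sole child: `exp(−E_loop(a, {a'})/RT) · Z_in[a']`,
* multiloop branch:
  `e^{−(a_ml+b)/RT} · Z_in[a'] · (Q_any(L)·Q_any(R) − Q_0(L)·Q_0(R))`,
  where `L`/`R` are the flanking loop regions, `Q_any = Q_0 + Qm1` and the
  subtracted term removes the configuration with no further branch (which
  would not be a multiloop).

Then `P(a' ‖ a) = mass/Z_in[a]` and `P_joint = P(a)·P(a' ‖ a)`; the two
context strata are retained separately for diagnostics, which makes the
overestimation property (`P(a' ‖ a) ≥` the exact single-child loop
conditional) directly inspectable — the multiloop stratum is exactly the
overcount. `P(a')` itself is accumulated as
`P_ext(a') + Σ_a P_joint(a, a')`, i.e. every occurrence of a pair has
exactly one parent; the independent correctness check of all these
quantities is exhaustive enumeration with Boltzmann weighting, at relative
tolerance 1e−10 (observed agreement ≈ 1e−14).

`structure_probability_exact` evaluates the factorization
`P(S) = ∏_a P(loop(a, chi(a)) | a)` with
`P(loop | a) = (∏_{a'} Z_in[a']) · e^{−E_loop/RT} / Z_in[a]`, and the test
suite verifies it equals `e^{−E(S)/RT}/Z` for every enumerated structure of
seeded cohorts.

Numerics: partition functions are computed in plain double precision, not
log space. Under the default parameters this is safe to roughly n ≈ 500
(Z overflows double range only when |E_min| approaches ~420 kcal/mol); the
package targets desk-scale analyses well below that, and the limit is the
main reason an alternative parameter set with much stronger stacks should
be rescaled rather than used as-is at long lengths.

## Scoring models

With `P_min` defaulting to `1/(2·sequence length)` and `β = 1.5`:

* `score_PMcomp(S) = Σ_{a∈S} log(P(a)/P_min)`; the induced probability
  `∏ P(a)` assumes independence between pairing events.
* `P_Pankov(S)` multiplies per-loop values: ML-prod (product of branch
  conditionals) or ML-min (minimum branch conditional; hairpins contribute
  1 by the empty-min convention). Children of `a0` condition through
  `P_ext`, the natural reading of the external in-loop probability.
* `score_Pankov(S) = Σ Φ(a', a) = log P_Pankov,ML-prod(S) + |S|·β`. The
  aligner uses ML-prod, matching the score definition; ML-min is kept as a
  separate model variant because its per-loop values dominate the exact
  conditionals, hence `P_Pankov,ML-min(S) ≥ P(S)` and its energy-scaled
  values never exceed the reference energies — a one-sided sanity bound the
  tests assert elementwise.
* `probability_to_energy(p) = −RT·log(p) + E_ens` inverts the Boltzmann
  relation, so the exact model maps back to `E(S)` to within float noise.

## Aligner

The DP follows the sparsified loop-closing recursion family: `D(a, b)` for
matching candidate pairs `a`, `b` (computed bottom-up by span, pseudo roots
last), `M^{ab}(i, k)` over the loop contents, and `I_A`/`I_B` for base-pair
deletion/insertion. Design choices that were genuinely open:

* In the pair-match case of `M` the similarity terms score the **child's**
  ends, `σ(a1^L, b1^L) + σ(a1^R, b1^R)` — scoring the closing pair's ends
  there would re-score them once per child.
* The `I_A` charge `(a1^L − a^L + 1)·γ` is read as: left flank
  (`a1^L − a^L − 1` positions) plus *both* endpoints of the deleted pair
  `a1`; with the right flank accumulated by the `I_A(i−1) + γ` case, the
  traceback's gap accounting is exactly consistent, which is what makes
  `rescore` (an independent definitional recomputation from edges and
  structures) reproduce the DP total bit-for-bit.
* The `D` recursion is applied uniformly at the pseudo-root level, so
  base-pair deletions are also available for external pairs; this requires
  mixed `D(a1, root)` entries, which the implementation computes.
* Domain indels (`l_d > 0`): two extra `M` cases delete a whole branch of
  span `< l_d` at cost `2γ + γ·(span − 1) + Φ`, i.e. gap cost only for the
  deleted region — a deleted branch contributes no alignment edges and no
  interior structure. `l_d = 0` is byte-identical to the base recursion.
* Both ends of every base pair are tracked exactly (no left-end
  relaxation), and traceback ties break in a fixed case order (residue
  match, gap in B, gap in A, pair match with smallest left end first), so
  output is deterministic.
* `σ` defaults to +2.0 match / −1.0 mismatch and `γ = −2.0`; both are
  injectable (`σ` accepts any symmetric residue-pair function, e.g. a
  RIBOSUM-style similarity).

Sparsification defaults are `θ = 0.001` and `θ' = 0.0001`. The optimality
oracle — an exhaustive search over (structure, structure, pair-matching)
triples realized recursively over the two loop trees — confirms exact DP
optimality at `θ = θ' = 0` on seeded short pairs.

## Suboptimal ensembles and model evaluation

Suboptimal structures within `e_window` (default 5.0 kcal/mol) of the
minimum free energy, truncated to `max_count` (default 500), are generated
by a best-first branch-and-bound over the same loop grammar as the
partition function: min-plus tables (`Vb`, multiloop region minima, an
external suffix array) give admissible, consistent bounds for every open
subproblem of a partial structure, so states pop from the priority queue
in non-decreasing bound order and completed structures emerge sorted by
energy. This makes generation exact at any length and lets truncation stop
at precisely the `max_count` lowest-energy structures; at small lengths the
output is verified to equal the exhaustively enumerated, energy-sorted
ensemble.

`evaluate_models` scores every suboptimal under five variants (PMcomp
probability and score, ML-min, ML-prod, the Φ score) plus optionally the
exact probability as an oracle, transforms values to the energy scale, and
reports Spearman correlations against the reference energies.
Probabilities are scaled by `−RT·log(p) + E_ens`; log-scale scores by the
monotone affine map `−RT·score + E_ens`. The affine map (rather than
undoing the score's normalization terms first) is deliberate: it preserves
each score's own ranking, so rank correlations are exactly
scaling-invariant, and `β = 0` — and only `β = 0` — makes the Φ-score
correlation coincide with the ML-prod correlation. Where reference
energies tie exactly between distinct structures, float noise (~1e−13) in
the factorized probabilities breaks the ties arbitrarily; tie-sensitive
assertions therefore compare ranks after rounding energies at 1e−8
kcal/mol.

## Synthetic data

The fixture generator emulates the shape of curated ncRNA inputs: seeded
random sequences (uniform or GC-biased composition), optionally with a
planted Watson-Crick hairpin stem (default six pairs, four-base loop) as a
stand-in for a conserved helix, and homolog pairs derived from a common
ancestor by per-site substitutions (compensated inside the planted stem so
complementarity survives) and indels, with the true alignment recorded.
Defaults — lengths 40–60, mutation rate 0.1, indel rate 0.02 — produce
pairs in the sequence-identity range where structure-aware alignment
matters. A calibration check confirms the planted pairs survive
sparsification at `θ = 0.001` in ≥90% of seeds.

What the generator does **not** emulate: covariation patterns of real
families beyond the single planted stem, biased loop compositions,
modified nucleotides, or realistic indel length distributions. Passing
tests therefore demonstrate the mathematical properties of the method and
its implementation — exactness, bounds, optimality, model ordering — on
the built-in energy model; they do not measure alignment accuracy on real
ncRNA families or under a full published parameter set.

## Problem sizes used in the shipped checks

Enumeration-based verification uses 50 sequences of length 10–18 (complete
ensembles are enumerable there); brute-force alignment verification uses
30 pairs of length 8–10 with thresholds at zero; the model-agreement
cohort uses 20 sequences of length 40–60 with the default evaluation
settings; aligner invariants run on homolog pairs of length 26–32. These
sizes were chosen so each property is checked against a fully independent
oracle.

## Known limitations

* The energy model is a stand-in parameterization: results on real RNAs
  will differ from engines with full published nearest-neighbor tables,
  and no claim is made about folding accuracy against experimental
  structures.
* Plain-double partition functions bound the usable sequence length (see
  above); no log-space fallback is provided.
* The aligner computes `D` for all candidate-pair combinations of the two
  sequences; with thresholds at zero this degrades to the dense quadratic
  pair space and is intended only for small verification instances.
* Pairwise alignment only; no progressive multiple alignment, local
  alignment or anchor constraints.
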