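# Methods

This note records the models as implemented, the numerical and design
choices made where the published description leaves freedom, and what the
synthetic tests do and do not establish.

## Model semantics (`modresc.core`)

A cross is compatible iff rescue covers modification. Under the goalkeeper
model the comparison is per factor: CI iff some summed paternal factor
strictly exceeds the summed maternal factor plus the host contribution.
Two conventions are fixed here:

* **Rescue is non-strict.** Equal mod and resc quantities are rescued
  (interpreting the timing factor: if the time available is at least the
  time needed, the male pronucleus participates). This also makes
  self-crosses structurally compatible for any strain set and host.
* **No cross-factor offsetting.** The quantitative level uses the
  componentwise clamp `max(0, mod − resc)` before taking the norm: surplus
  rescue in one factor cannot pay for a deficit in the other, matching the
  rectangular rescue region of the two-factor picture. The norm defaults
  to Euclidean (L1 selectable) and the proportionality constant to
  `c = 10`, chosen so single-strain differences on the default integer
  parameter grid (0–5 per factor, so differences up to 10) span 0–100 %.
  Both are configuration; the model only states proportionality.

Factor quantities may be ints, `Fraction`s or floats. Integer/rational
comparisons are exact (the fitting code works on integers); float
comparisons use an absolute tolerance of 1e-9.

Suicidal strains (keys not covering locks) are representable under
lock-key only, behind an explicit flag; the goalkeeper model structurally
guarantees self-rescue, so the constructor rejects a suicidal quantitative
strain. The packaged six-strain data keep wTei self-rescuing: the
anomalously high "compatible-cross" mortalities in the one discordant
study affect wRi and wMel equally and are treated as a data artifact, not
a property of wTei.

## Statement checking (`modresc.statements`)

The fifteen catalog statements quantify over at most three strain
variables and (for the quantitative families) one host background — two
for statement M, which compares the same strain across hosts. Formal
proofs are replaced by **bounded exhaustive verification**:

* goalkeeper/mistiming: all factor quantities and host contributions range
  over the integer grid 0..G (default G = 6). The CI conditions are order
  comparisons among sums of at most three strain quantities plus a host
  term, so small integer grids realize every order type these sums can
  take; a `true` universal verdict means "no counterexample below the
  bound". The suite checks that enlarging G to 10 (and the lock-key factor
  universe from 4 to 6) flips no verdict.
* lock-key: lock and key sets range over all subsets of K factor types
  (default K = 4) with keys ⊇ locks imposed on the whole domain
  (self-rescue footnote). Statements whose meaning involves the host
  background (M) have no lock-key interpretation and return
  `not_derivable` — a third verdict value, deliberately distinct from
  `false`.

The search is vectorized (numpy broadcasting over grid axes, bitmask
arrays for lock/key subsets) and chunked over the first variable, scanning
assignments in ascending lexicographic order so the returned
witness/counterexample is the canonical smallest. Every returned
assignment is re-verified through the scalar pure-Python predicates in
`modresc.core` — a code path disjoint from the vectorized search — before
a verdict is emitted.

Statement texts with placeholder strain variables were reconstructed from
the surrounding discussion (e.g. J: "if x rescues the double infection
{y, z}, the double infection {x, y} rescues the triple infection
{x, y, z}"); each reconstruction reproduces the published truth value in
both columns, which is the strongest consistency check available without
the supplementary proofs.

## Compatibility-matrix fitting (`modresc.fitting`)

Matrices are 3-valued (compatible / incompatible / unknown), rows
maternal, columns paternal; unknown entries are unconstrained throughout.

**Minimal lock-key factorization.** A factor type is fully described by
the pair (L, K) of strain sets carrying its lock resp. key; the cross
(female i, male j) is incompatible iff some factor has j ∈ L and i ∉ K.
For a fixed K the inclusion-maximal admissible L is forced by the
compatible entries (and by self-rescue: a non-suicidal strain may carry a
lock only with the matching key), so there are at most 2^n candidate
factors and the minimum factor count is an exact minimum set cover of the
incompatible entries by candidate factors — solved by branch-and-bound,
with factor-permutation symmetry eliminated because factors are canonical
candidates relabelled in sorted order. An independent brute-force
enumeration over per-strain (lock, key) subsets confirms minimality on
small matrices in the test suite.

By default every strain must carry at least one lock (`require_locks`):
the strains entering these matrices are CI inducers, and a lockless strain
would be mod−. Disable the flag to allow mod− strains (the round-trip
tests on random worlds do, since random lock sets may be empty).

**Goalkeeper feasibility.** Writing x for the per-factor quantities, a
compatible entry (i, j) demands x_j ≤ x_i + h in both factors and an
incompatible entry demands x_j ≥ x_i + h + 1 in at least one (strictness
realized as a unit margin, WLOG by scaling). The search branches over
which factor each incompatible entry violates (symmetric bidirectional
pairs are ordered adjacently and the first entry is pinned to factor 1 by
factor-swap symmetry) and checks each single-factor system by
negative-cycle detection on the difference-constraint graph. The free host
contribution is fixed to h = (n, n) without loss of generality: any
infeasibility certificate is a constraint cycle; cycles with at least as
many strict as non-strict edges are negative for *every* h ≥ 0, and all
other cycles are non-negative once h ≥ n − 1 (a simple cycle has at most
n − 1 strict edges). Hence feasibility at h = n is equivalent to
feasibility for some h ≥ 0. Witness quantities are the shortest-path
potentials — exact small integers — and are verified against the matrix
before being returned.

**The six-strain fixture.** The packaged matrix encodes: wTei rescues wRi
and wRi rescues wMel (each unidirectional), wMel↔wTei bidirectionally
incompatible, and wHa, wNo, wCer2 incompatible both ways with every tested
partner. One cross is encoded unknown: wTei female × wCer2 male. wCer2's
factor repertoire beyond its first lock/key pair is unreported in the
published witness, and every completion of that witness consistent with
the known entries confines wCer2's locks to {1, 3} — which wTei's keys
{1, 2, 3} always cover. The cross therefore cannot have been observed
incompatible, and encoding it unknown is forced, not optional. With this
encoding the minimal factor count is exactly five and the published
witness (wCer2 completed as locks = keys = {1, 3}, the unique consistent
completion) reproduces every known entry.

## CI-level predictions (`modresc.levels`)

The corrected CI level is the standard control-adjusted mortality
`100·(raw − control)/(100 − control)`, clipped to [0, 100]; the source
work cites the correction without printing it, so it is isolated behind
one function. Predictions over record pairs: type 1 (same father, nested
mother sets → level decreases), type 2 (same mother, nested father sets →
increases), type 3 (equal clamped difference vectors → levels within a
10-percentage-point margin, treated as absolute). Equivalence is judged on
model-derived difference vectors, not label multisets, so the host
contribution is honored; pairs that are equivalent are scored as type 3
even when also nested. Exact ties on directional predictions are draws
and are excluded from the binomial count (levels closer than 1e-9 are
tied, guarding against float round-trip noise); the margin question for
type 3 is resolved as binary correct/false. The binomial test is the exact
upper tail of Binomial(n, ½) computed by rational summation and converted
to float at the end.

## Population recursions (`modresc.popgen`)

Deterministic infinite-population recursions: random mating of cytotype
frequencies, zygote survival s(father cytotype, mother cytotype), maternal
transmission, renormalization. Choices:

* **Transmission** is independent per strain with probability t each, so a
  double infection is co-transmitted with probability t²; an explicit
  transmission matrix can be supplied instead.
* **Mortality acts on the zygote as a function of the parental cytotypes
  only** — modification happens in the father, rescue in the egg, so the
  offspring's own (maternally acquired) infection cannot influence its
  survival.
* **Survival from mechanism**: lock-key uses 1 − level/100 with the
  unmatched-lock fraction; goalkeeper uses independent per-factor linear
  death, survival = Π_f (1 − min(1, max(0, mod_f − resc_f))), with factor
  quantities on the [0, 1] scale and the linear slope fixed at 1
  (configurable through an explicit survival matrix).
* Defaults: tolerance 1e-12 on the max frequency change, 10 000
  generations, persistence threshold 1e-6. Non-convergence is flagged in
  the trajectory, not raised.

The packaged unidirectional fixtures use g_A = (0.5, 0), g_B = (0.5, 0.5),
h = 0 (goalkeeper) and locks/keys A:{1}/{1}, B:{2}/{1,2} (lock-key), with
t = 0.98 and the double infection started at 95 % — the scenario asks
whether an *established* double infection can persist. The published runs
print no parameter values, so these are asserted qualitatively only: under
goalkeeper the AB male can only be rescued by AB females and AB persists
(≈ 93 %); under lock-key the B mono-infection rescues everything AB
rescues and outgrows it by a factor 1/t per generation, driving AB
extinct. Invasion runs (no double infections) first equilibrate the
resident, then introduce the mutant at 1 %.

## Synthetic worlds (`modresc.synth`)

Goalkeeper worlds draw integer factor quantities and host contributions
uniformly on [0, 5]² (integer so all downstream fitting is exact);
lock-key worlds draw lock sets over 4 factor types with inclusion
probability ½ and add each missing key with probability ½. Crossing
datasets draw maternal/paternal infections of size 0–2, add Gaussian noise
(default sd 5 percentage points) to the model level on the percent scale,
clip to [0, 100] (a censoring caveat at the boundaries: clipped records
understate extreme levels), draw control mortality uniformly on [0, 5] %
and back-compute the raw mortality so the correction recovers the noisy
level. The generators emulate the *structure* of literature crossing data
— not laboratory replicate structure, binomial egg-count sampling, or
density reduction in multiple infections — so a green noiseless test
establishes that the predictions are theorems of the level function, not
that real data obey them; the published 45-correct/14-false tally from
literature data is deliberately not reproduced, only its binomial
computation is.

## Known limitations

* Statement verification is bounded, not symbolic; the bound-stability
  property is evidence, not proof.
* The minimal-factor search is exponential in the strain count (2^n
  candidate factors); it is exact and instant for the n ≤ 8 matrices this
  field produces, but is not a general Boolean matrix factorization tool.
* Density dependence of strains in multiple infections, stochastic drift
  (the published route by which suicidal strains spread), spatial
  structure and fecundity effects are out of scope.
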