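# modresc

Formal models of *Wolbachia*-induced cytoplasmic incompatibility (CI), for
evolutionary biologists studying the mod/resc system: sperm from an
infected male is *modified* (mod) and the resulting embryo dies unless the
egg *rescues* it (resc). `modresc` implements three candidate mechanisms
over one shared vocabulary of strains, infections and crosses, and the
analyses that discriminate among them.

## The models

For a cross between a male with infection $P$ and a female with infection
$M$ on host background $h$:

* **Goalkeeper** — every strain $s$ contributes fixed quantities
  $(g_{s,1}, g_{s,2})$ to two factors; the same quantities act as mod in
  males and resc in females, and the female host adds a net contribution
  $(h_1, h_2)$. CI occurs iff

  $$\exists f:\; \sum_{s \in P} g_{s,f} \;>\; \sum_{s \in M} g_{s,f} + h_f ,$$

  i.e. iff at least one summed mod factor strictly exceeds the matching
  resc factor (rescue is non-strict). The quantitative CI level is
  $c \cdot \lVert \max(0, \mathrm{mod} - \mathrm{resc}) \rVert$, clipped to
  $[0, 100]$ %.
* **Mistiming** — the one-factor special case (cell-cycle timing delay
  only).
* **Lock-key** — strains deposit qualitative lock types via sperm and key
  types via eggs; with multiple infections the unions are produced. CI
  occurs iff $\bigcup_{s \in P} \mathrm{locks}(s) \not\subseteq
  \bigcup_{s \in M} \mathrm{keys}(s)$; the quantitative extension sets the
  level to the unmatched-lock fraction (ten locks, six matched keys →
  40 %).

On top of the predicates the package provides:

* `modresc.statements` — a bounded checker for the quantified statements
  A–P about the models (bidirectional incompatibility is possible, added
  maternal strains cannot weaken rescue, intransitivity, …), returning
  verified witnesses/counterexamples and reproducing the published
  goalkeeper/lock-key truth table exactly;
* `modresc.fitting` — the exact minimal number of lock/key factor types
  explaining a compatibility matrix (set-cover search) and exact two-factor
  goalkeeper feasibility with or without host contribution
  (difference-constraint systems);
* `modresc.levels` — corrected CI levels, the three directional/similarity
  predictions for multiply infected crosses, and the one-tailed exact
  binomial test;
* `modresc.popgen` — deterministic cytotype-frequency recursions (panmixia,
  non-overlapping generations, maternal transmission with probability $t$
  per strain, CI as embryonic mortality) for double-infection persistence
  and mutant invasion;
* `modresc.synth` / `modresc.fixtures` — seeded ground-truth worlds, noisy
  crossing datasets and the packaged six-strain relationship
  (wTei, wRi, wHa, wNo, wMel, wCer2).

## Worked example

```sh
python examples/fit_compatibility.py
```

prints the six-strain matrix and then:

```
Minimal number of lock/key factor types: 5
...
Published assignment also explains the data: True

Goalkeeper (2 factors), free host contribution: feasible
  fitted factor quantities: {'wTei': (21, 15), 'wRi': (7, 21), 'wHa': (28, 7),
                             'wNo': (35, 0), 'wMel': (0, 22), 'wCer2': (14, 14)}
  host contribution: (6, 6)
Goalkeeper with host contribution forced to zero: infeasible
```

Five qualitative factor types are provably necessary and sufficient for
the lock-key model, while the goalkeeper model explains the same data with
its two quantitative factors — but only because the host aids rescue: the
fitted integer quantities place each strain in the factor plane and the
host vector (6, 6) enlarges every female's rescue region; with it removed
the chain wRi ≤ wTei, wMel ≤ wRi would force wTei females to rescue wMel
males, contradicting the data.

The other examples follow the same pattern: `check_statements.py`
(statement truth table plus witnesses), `predict_ci_levels.py` (prediction
scoring and the exact binomial test), `simulate_popgen.py` (the
double-infection persistence dichotomy and mutant invasion),
`generate_data.py` (file formats and round trips).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantitative result from scratch — the
CI level of the quantitative lock-key extension for a cross with ten
paternal lock types of which six are matched by maternal keys — and writes
it as JSON (`value` in percent, `n` the number of lock types used).
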