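"""Tests for compatibility-matrix fitting (lock-key factorization and
two-factor goalkeeper feasibility)."""

import itertools

import pytest

from modresc.fitting import (
    COMPATIBLE,
    INCOMPATIBLE,
    UNKNOWN,
    CompatibilityMatrix,
    GoalkeeperFit,
    LockKeyAssignment,
    goalkeeper_explains,
    goalkeeper_fit,
    lockkey_explains,
    matrix_from_levels,
    min_lockkey_factors,
)
from modresc.synth import induced_matrix, random_goalkeeper_world, \
    random_lockkey_world


# -- independent minimality oracle -----------------------------------------

def brute_force_min_factors(matrix, require_locks=True, k_max=4):
    """Exhaustive per-strain (locks, keys) enumeration; oracle for n <= 4."""
    n = len(matrix.strains)
    known = list(matrix.known_entries())
    for k in range(0, k_max + 1):
        # per strain: any (locks, keys) bitmask pair with keys >= locks
        options = [(l, l | e) for l in range(1 << k)
                   for e in range(1 << k) if l & e == 0]
        if require_locks:
            options = [o for o in options if o[0]]
        for combo in itertools.product(options, repeat=n):
            used = 0
            for l, _ in combo:
                used |= l
            if k and used != (1 << k) - 1:
                continue  # every factor type must carry a lock somewhere
            ok = True
            for i, j, cell in known:
                compat = combo[j][0] & ~combo[i][1] == 0
                if compat != (cell == COMPATIBLE):
                    ok = False
                    break
            if ok:
                return k
    return None


def M(strains, rows, suicidal=()):
    return CompatibilityMatrix(strains, rows, frozenset(suicidal))


# -- matrix basics ----------------------------------------------------------

def test_matrix_validation():
    with pytest.raises(ValueError):
        M(("a", "a"), (("C", "C"), ("C", "C")))
    with pytest.raises(ValueError):
        M(("a", "b"), (("C", "X"), ("C", "C")))
    with pytest.raises(ValueError):  # incompatible diagonal needs the flag
        M(("a",), (("I",),))
    assert M(("a",), (("I",),), suicidal=("a",)).entry("a", "a") == "I"


def test_matrix_from_levels_threshold():
    records = [("wTei", "wRi", 41.5), ("wRi", "wTei", 5.0)]
    m = matrix_from_levels(records, threshold=20.0)
    assert m.entry("wTei", "wRi") == INCOMPATIBLE  # 41.5% >= 20%
    assert m.entry("wRi", "wTei") == COMPATIBLE
    assert m.entry("wRi", "wRi") == COMPATIBLE     # diagonal default
    with pytest.raises(ValueError):
        matrix_from_levels([("a", "b", 120.0)])
    with pytest.raises(ValueError):
        matrix_from_levels([("a", "b", "high")])


# -- lock-key ---------------------------------------------------------------

def test_lockkey_explains(six_matrix, table2):
    assert lockkey_explains(six_matrix, table2)
    # empty assignment predicts universal compatibility
    empty = LockKeyAssignment({s: frozenset() for s in six_matrix.strains},
                              {s: frozenset() for s in six_matrix.strains})
    assert not lockkey_explains(six_matrix, empty)
    single = CompatibilityMatrix(("a",), (("C",),))
    assert lockkey_explains(single, LockKeyAssignment({"a": {"1"}},
                                                      {"a": {"1"}}))


@pytest.mark.parametrize("rows, expected_k", [
    # two mutually compatible strains: one shared lock/key pair suffices
    ((("C", "C"), ("C", "C")), 1),
    # bidirectional incompatibility needs two factor types
    ((("C", "I"), ("I", "C")), 2),
    # unidirectional (b rescues a): two with mandatory locks
    ((("C", "I"), ("C", "C")), 2),
])
def test_min_factors_small(rows, expected_k):
    m = M(("a", "b"), rows)
    k, assignment = min_lockkey_factors(m)
    assert k == expected_k
    assert lockkey_explains(m, assignment)
    assert brute_force_min_factors(m) == expected_k


def test_min_factors_matches_oracle_on_random_matrices():
    """Symmetry-reduced search agrees with exhaustive enumeration (n <= 4)."""
    import numpy as np
    rng = np.random.default_rng(7)
    for n in (3, 4):
        for _ in range(6):
            cells = [[None] * n for _ in range(n)]
            for i in range(n):
                for j in range(n):
                    cells[i][j] = ("C" if i == j else
                                   rng.choice(["C", "I", "?"], p=[.3, .5, .2]))
            m = M(tuple(f"s{i}" for i in range(n)),
                  tuple(map(tuple, cells)))
            k, assignment = min_lockkey_factors(m)
            assert lockkey_explains(m, assignment)
            assert brute_force_min_factors(m) == k


def test_min_factors_without_lock_requirement():
    # an all-compatible matrix needs no factors when strains may be lockless
    m = M(("a", "b"), (("C", "C"), ("C", "C")))
    k, assignment = min_lockkey_factors(m, require_locks=False)
    assert k == 0
    assert lockkey_explains(m, assignment)


def test_min_factors_monotone_in_unknowns(six_matrix):
    """Blanking entries to unknown never increases the minimal factor count."""
    k_full, _ = min_lockkey_factors(six_matrix)
    cells = [list(r) for r in six_matrix.cells]
    cells[0][2] = cells[2][0] = UNKNOWN  # drop the wTei/wHa pair
    k_less, _ = min_lockkey_factors(
        CompatibilityMatrix(six_matrix.strains, tuple(map(tuple, cells))))
    assert k_less <= k_full


def test_min_factors_suicidal_strain():
    # a suicidal strain may carry a lock without the matching key
    m = M(("a", "b"), (("I", "I"), ("C", "C")), suicidal=("a",))
    k, assignment = min_lockkey_factors(m)
    assert lockkey_explains(m, assignment)
    assert not assignment.keys["a"] >= assignment.locks["a"]


# -- goalkeeper fit ---------------------------------------------------------

def test_goalkeeper_explains_rejects_bad_fit(six_matrix):
    allzero = GoalkeeperFit(g={s: (0, 0) for s in six_matrix.strains},
                            h=(0, 0))
    assert not goalkeeper_explains(six_matrix, allzero)
    single = CompatibilityMatrix(("a",), (("C",),))
    assert goalkeeper_explains(single, GoalkeeperFit(g={"a": (3, 1)}))


def test_goalkeeper_fit_bidirectional_pair():
    m = M(("a", "b"), (("C", "I"), ("I", "C")))
    res = goalkeeper_fit(m, host_free=True)
    assert res.feasible
    assert goalkeeper_explains(m, res.fit)


def test_goalkeeper_fit_random_worlds_recover():
    """Fitting the induced matrix of a random goalkeeper world is always
    feasible and the fitted parameters reproduce every entry."""
    for seed in range(10):
        world = random_goalkeeper_world(5, seed=seed)
        m = induced_matrix(world)
        res = goalkeeper_fit(m)
        assert res.feasible
        assert goalkeeper_explains(m, res.fit)


def test_goalkeeper_fit_monotone_in_unknowns(six_matrix):
    """Blanking entries cannot make a feasible fit infeasible."""
    cells = [list(r) for r in six_matrix.cells]
    cells[1][4] = UNKNOWN
    m = CompatibilityMatrix(six_matrix.strains, tuple(map(tuple, cells)))
    assert goalkeeper_fit(m).feasible


def test_goalkeeper_fit_suicidal_infeasible():
    m = M(("a",), (("I",),), suicidal=("a",))
    assert not goalkeeper_fit(m).feasible


def test_lockkey_world_roundtrip():
    for seed in range(10):
        world = random_lockkey_world(5, 4, seed=seed)
        m = induced_matrix(world)
        k, assignment = min_lockkey_factors(m, require_locks=False)
        assert k <= 4  # the generating assignment bounds the search
        assert lockkey_explains(m, assignment)
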