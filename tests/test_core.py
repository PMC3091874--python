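"""Unit and property tests for the CI predicates and level functions."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from modresc.core import (
    CIOutcome,
    Cross,
    DimensionError,
    HostBackground,
    Infection,
    Strain,
    UNINFECTED,
    ci_goalkeeper,
    ci_level_goalkeeper,
    ci_level_lockkey,
    ci_lockkey,
    ci_mistiming,
    is_mod_minus,
    mod_vector,
    resc_vector,
    rescues,
)

# -- independent oracles ----------------------------------------------------

def naive_ci_goalkeeper(paternal, maternal, h):
    """Loop-over-factors re-implementation of the goalkeeper predicate."""
    F = len(h)
    for f in range(F):
        mod = sum(s.gk[f] for s in paternal)
        resc = sum(s.gk[f] for s in maternal) + h[f]
        if mod > resc:
            return True
    return False


def naive_ci_lockkey(paternal, maternal):
    """Explicit set-difference re-implementation of the lock-key predicate."""
    locks = set()
    for s in paternal:
        locks |= set(s.locks)
    keys = set()
    for s in maternal:
        keys |= set(s.keys)
    return len(locks - keys) > 0


def S(label, q1, q2):
    return Strain(id=label, gk=(q1, q2))


def L(label, locks, keys):
    return Strain(id=label, locks=frozenset(map(str, locks)),
                  keys=frozenset(map(str, keys)))


# -- vector sums ------------------------------------------------------------

@pytest.mark.parametrize("strains, expected", [
    ((), (0, 0)),
    ((S("a", 2, 1),), (2, 1)),
    ((S("a", 2, 1), S("b", 0, 3)), (2, 4)),
])
def test_mod_vector_sums(strains, expected):
    assert mod_vector(Infection.of(*strains)) == expected


@pytest.mark.parametrize("strains, h, expected", [
    ((), (1, 1), (1, 1)),
    ((S("a", 2, 1),), (0, 0), (2, 1)),
    ((S("a", 2, 1), S("b", 0, 3)), (1, 0), (3, 4)),
])
def test_resc_vector_sums(strains, h, expected):
    host = HostBackground(id="h", h=h)
    assert resc_vector(Infection.of(*strains), host) == expected


def test_mixed_dimensionality_rejected():
    bad = Infection.of(Strain(id="a", gk=(1,)), Strain(id="b", gk=(1, 2)))
    with pytest.raises(DimensionError):
        mod_vector(bad)


# -- goalkeeper predicate ---------------------------------------------------

def test_goalkeeper_uninfected_cross_compatible():
    out = ci_goalkeeper(Cross(host=HostBackground.zero(2)))
    assert out == CIOutcome(ci=False, level=0.0)


def test_goalkeeper_self_cross_equality_is_rescued():
    # rescue is non-strict: equal mod and resc quantities are compatible
    s = S("a", 2, 1)
    cross = Cross(paternal=Infection.of(s), maternal=Infection.of(s),
                  host=HostBackground.zero(2))
    assert not ci_goalkeeper(cross).ci


def test_goalkeeper_uninfected_female_ci():
    cross = Cross(paternal=Infection.of(S("a", 2, 1)),
                  host=HostBackground(id="h", h=(1, 1)))
    out = ci_goalkeeper(cross)
    assert out.ci and out.level > 0


# -- lock-key predicate -----------------------------------------------------

@pytest.mark.parametrize("paternal, maternal, expect_ci", [
    ([L("a", [1], [1])], [L("b", [], [1])], False),   # all locks matched
    ([L("a", [1], [1])], [L("b", [], [])], True),     # unmatched lock
    ([L("a", [1], [1]), L("b", [2], [2])], [L("c", [], [1])], True),  # union
])
def test_lockkey_predicate(paternal, maternal, expect_ci):
    cross = Cross(paternal=Infection.of(*paternal),
                  maternal=Infection.of(*maternal))
    assert ci_lockkey(cross).ci == expect_ci


def test_rescues_published_example():
    # wTei's keys 1-3 rescue wRi's locks 2-3
    wTei = L("wTei", [1, 2], [1, 2, 3])
    wRi = L("wRi", [2, 3], [2, 3, 4])
    assert rescues(Infection.of(wTei), Infection.of(wRi),
                   model_family="lockkey")
    assert not rescues(Infection.of(wRi), Infection.of(wTei),
                       model_family="lockkey")


def test_rescues_goalkeeper_componentwise():
    host = HostBackground.zero(2)
    assert rescues(Infection.of(S("b", 3, 3)), Infection.of(S("a", 2, 1)),
                   host=host)
    assert rescues(UNINFECTED, UNINFECTED, host=host)


@pytest.mark.parametrize("strain, host, family, expected", [
    (S("a", 0, 0), HostBackground.zero(2), "goalkeeper", True),
    (L("a", [], [1]), None, "lockkey", True),
    (S("a", 2, 0), HostBackground(id="h", h=(1, 1)), "goalkeeper", False),
])
def test_is_mod_minus(strain, host, family, expected):
    assert is_mod_minus(strain, host=host, model_family=family) == expected


# -- quantitative levels ----------------------------------------------------

def test_level_goalkeeper_compatible_is_zero():
    s = S("a", 1, 1)
    cross = Cross(paternal=Infection.of(s), maternal=Infection.of(s),
                  host=HostBackground.zero(2))
    assert ci_level_goalkeeper(cross) == 0.0


def test_level_goalkeeper_euclidean():
    cross = Cross(paternal=Infection.of(S("a", 3, 0)),
                  maternal=Infection.of(S("b", 1, 0)),
                  host=HostBackground.zero(2))
    assert ci_level_goalkeeper(cross, c=10.0) == pytest.approx(20.0)


def test_level_goalkeeper_no_cross_factor_offset():
    # surplus rescue in factor 2 must not offset the deficit in factor 1
    cross = Cross(paternal=Infection.of(S("a", 3, 0)),
                  maternal=Infection.of(S("b", 1, 9)),
                  host=HostBackground.zero(2))
    assert ci_level_goalkeeper(cross, c=10.0) == pytest.approx(20.0)


def test_level_goalkeeper_equivalent_crosses_equal():
    # equal mod-resc differences give equal levels
    a, b, m = S("a", 2, 1), S("b", 0, 1), S("m", 3, 2)
    host = HostBackground.zero(2)
    c1 = Cross(paternal=Infection.of(m, b), maternal=Infection.of(a, b),
               host=host)
    c2 = Cross(paternal=Infection.of(m), maternal=Infection.of(a), host=host)
    assert ci_level_goalkeeper(c1) == pytest.approx(ci_level_goalkeeper(c2))


@pytest.mark.parametrize("n_locks, n_matched, expected", [
    (10, 6, 40.0),
    (3, 3, 0.0),
    (3, 0, 100.0),
])
def test_level_lockkey_unmatched_fraction(n_locks, n_matched, expected):
    male = L("m", range(1, n_locks + 1), range(1, n_locks + 1))
    female = L("f", [], range(1, n_matched + 1))
    cross = Cross(paternal=Infection.of(male), maternal=Infection.of(female))
    assert ci_level_lockkey(cross) == pytest.approx(expected)


# -- invariants -------------------------------------------------------------

def test_suicidal_strain_not_representable_in_goalkeeper():
    with pytest.raises(ValueError):
        Strain(id="bad", gk=(1, 1), suicidal=True)
    with pytest.raises(ValueError):
        Strain(id="bad", locks=frozenset("1"), keys=frozenset())
    # but representable in lock-key behind the flag
    s = Strain(id="wTei", locks=frozenset("1"), keys=frozenset(),
               suicidal=True)
    assert ci_lockkey(Cross(paternal=Infection.of(s),
                            maternal=Infection.of(s))).ci


gk_vec = st.tuples(st.integers(0, 6), st.integers(0, 6))
strain_sets = st.lists(gk_vec, min_size=0, max_size=3)


@settings(derandomize=True, max_examples=200)
@given(strain_sets, gk_vec)
def test_self_compatibility_goalkeeper(vecs, h):
    """Any strain set crossed with itself is compatible for any host."""
    strains = [Strain(id=f"s{i}", gk=v) for i, v in enumerate(vecs)]
    inf = Infection.of(*strains)
    host = HostBackground(id="h", h=h)
    assert rescues(inf, inf, host=host)


@settings(derandomize=True, max_examples=200)
@given(strain_sets, strain_sets, gk_vec, gk_vec)
def test_monotonicity_goalkeeper(pat, mat, extra, h):
    """CI is preserved by adding paternal strains; compatibility by adding
    maternal strains."""
    pats = [Strain(id=f"p{i}", gk=v) for i, v in enumerate(pat)]
    mats = [Strain(id=f"m{i}", gk=v) for i, v in enumerate(mat)]
    x = Strain(id="x", gk=extra)
    host = HostBackground(id="h", h=h)
    before = rescues(Infection.of(*mats), Infection.of(*pats), host=host)
    if not before:  # male monotonicity
        assert not rescues(Infection.of(*mats), Infection.of(*pats, x),
                           host=host)
    else:  # female monotonicity
        assert rescues(Infection.of(*mats, x), Infection.of(*pats), host=host)


@settings(derandomize=True, max_examples=200)
@given(strain_sets, strain_sets, gk_vec)
def test_goalkeeper_matches_naive_oracle(pat, mat, h):
    pats = [Strain(id=f"p{i}", gk=v) for i, v in enumerate(pat)]
    mats = [Strain(id=f"m{i}", gk=v) for i, v in enumerate(mat)]
    host = HostBackground(id="h", h=h)
    got = ci_goalkeeper(Cross(paternal=Infection.of(*pats),
                              maternal=Infection.of(*mats), host=host)).ci
    assert got == naive_ci_goalkeeper(pats, mats, h)


subset = st.frozensets(st.sampled_from("1234"), max_size=4)
lockkey_strain = st.tuples(subset, subset)


@settings(derandomize=True, max_examples=200)
@given(st.lists(lockkey_strain, max_size=3), st.lists(lockkey_strain, max_size=3))
def test_lockkey_matches_naive_oracle(pat, mat):
    pats = [Strain(id=f"p{i}", locks=l, keys=l | k)
            for i, (l, k) in enumerate(pat)]
    mats = [Strain(id=f"m{i}", locks=l, keys=l | k)
            for i, (l, k) in enumerate(mat)]
    got = ci_lockkey(Cross(paternal=Infection.of(*pats),
                           maternal=Infection.of(*mats))).ci
    assert got == naive_ci_lockkey(pats, mats)


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(0, 6), min_size=0, max_size=3),
       st.lists(st.integers(0, 6), min_size=0, max_size=3),
       st.integers(0, 6))
def test_mistiming_is_one_factor_goalkeeper(pat, mat, h):
    """Mistiming outcomes are bit-identical to goalkeeper on 1-factor input."""
    pats = [Strain(id=f"p{i}", gk=(v,)) for i, v in enumerate(pat)]
    mats = [Strain(id=f"m{i}", gk=(v,)) for i, v in enumerate(mat)]
    host = HostBackground(id="h", h=(h,))
    cross = Cross(paternal=Infection.of(*pats), maternal=Infection.of(*mats),
                  host=host)
    assert ci_mistiming(cross).ci == ci_goalkeeper(cross).ci
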