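"""Bounded verification of quantified CI statements (the A-P catalog).

Each statement is a quantified proposition over strains (and, for the
quantitative families, host backgrounds) whose body is a boolean combination
of ``rescues`` and mod- atoms.  Statements are checked per model family by
exhaustive bounded search:

* goalkeeper / mistiming -- factor quantities and host contributions range
  over the integer grid ``0..G``.  CI conditions are order comparisons among
  sums of at most three strain vectors plus a host vector, so small integer
  grids realize every relevant order type.
* lock-key -- lock sets and key sets range over all subsets of ``K`` factor
  types, with keys covering locks (self-rescue) imposed on the whole domain.

Existential statements return ``true`` with a concrete witness, universal
statements return ``false`` with a concrete counterexample; every returned
assignment is re-verified through :mod:`modresc.core` (pure-Python
predicates), independently of the vectorized search path.  Statements whose
meaning involves the host background have no interpretation under lock-key
semantics and evaluate to ``not_derivable`` there.

This is bounded *verification*, not symbolic proof: a ``true`` universal
verdict means "no counterexample within the configured bounds".  Enlarging
the bounds does not change any verdict for the shipped catalog (a tested
property).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import core
from .core import HostBackground, Infection, Strain

__all__ = [
    "Statement",
    "Verdict",
    "SearchConfig",
    "statement_catalog",
    "evaluate",
    "reproduce_table1",
    "check_table1",
    "TABLE1",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SearchConfig:
    """Bounds for the exhaustive search domains.

    ``grid_bound`` is the top of the integer grid for factor quantities and
    host contributions (goalkeeper/mistiming); ``factor_types`` the size of
    the lock/key factor universe; ``max_strains`` the largest number of
    strain variables a statement may quantify over.
    """

    grid_bound: int = 6
    factor_types: int = 4
    max_strains: int = 3

    def __post_init__(self):
        if self.grid_bound < 2:
            raise ConfigError("grid_bound must be >= 2")
        if self.factor_types < 2:
            raise ConfigError("factor_types must be >= 2")


@dataclass(frozen=True)
class Statement:
    """A quantified proposition over strains and host backgrounds.

    ``body(ops, strains)`` evaluates the quantifier-free matrix; ``ops``
    provides the atoms (``rescues``, ``mod_minus``) for one model family and
    must be used for every comparison so the same body runs both vectorized
    (grid search) and on concrete objects (witness verification).
    """

    id: str
    text: str
    quantifier: str  # "exists" | "forall"
    n_strains: int
    body: Callable
    n_hosts: int = 1
    host_dependent: bool = False  # body meaning involves the host background

    def __post_init__(self):
        if self.quantifier not in ("exists", "forall"):
            raise ValueError(f"bad quantifier {self.quantifier!r}")


@dataclass(frozen=True)
class Verdict:
    """Three-valued outcome with the assignment that settles it.

    ``assignment`` maps variable names (``x``, ``y``, ``z``, ``host``,
    ``host2``) to concrete :class:`Strain` / :class:`HostBackground`
    objects.  It is a witness for a true existential and a counterexample
    for a false universal; ``None`` otherwise.
    """

    value: str  # "true" | "false" | "not_derivable"
    assignment: Optional[dict] = None


def _implies(p, q):
    return ~p | q


# ---------------------------------------------------------------------------
# statement catalog
# ---------------------------------------------------------------------------

def _catalog():
    S = Statement
    imp = _implies
    return [
        S("A", "Wolbachia only in the ovum but not in the sperm does not cause CI",
          "forall", 1,
          lambda o, s: o.rescues([s[0]], [])),
        S("B", "Bidirectional incompatibility is possible",
          "exists", 2,
          lambda o, s: ~o.rescues([s[0]], [s[1]]) & ~o.rescues([s[1]], [s[0]])),
        S("C", "Unidirectional incompatibility is possible",
          "exists", 2,
          lambda o, s: o.rescues([s[0]], [s[1]]) & ~o.rescues([s[1]], [s[0]])),
        S("D", "Additional strains in males cannot decrease mod strength",
          "forall", 3,
          lambda o, s: imp(~o.rescues([s[2]], [s[0]]),
                           ~o.rescues([s[2]], [s[0], s[1]]))),
        S("D'", "Even if x rescues y, it cannot rescue the double-infection "
                "x,y (except if y is mod-)",
          "forall", 2,
          lambda o, s: imp(o.rescues([s[0]], [s[1]]) & ~o.mod_minus(s[1]),
                           ~o.rescues([s[0]], [s[0], s[1]]))),
        S("D''", "If x rescues y, it also rescues the double-infection x,y",
          "forall", 2,
          lambda o, s: imp(o.rescues([s[0]], [s[1]]),
                           o.rescues([s[0]], [s[0], s[1]]))),
        S("E", "Additional strains in females cannot decrease resc strength",
          "forall", 3,
          lambda o, s: imp(o.rescues([s[2]], [s[0]]),
                           o.rescues([s[2], s[1]], [s[0]]))),
        S("E'", "The double-infection x,y rescues the mono-infection x",
          "forall", 2,
          lambda o, s: o.rescues([s[0], s[1]], [s[0]])),
        S("F", "The existence of mod- resc+ strains is possible",
          "exists", 2,
          lambda o, s: o.mod_minus(s[0]) & ~o.mod_minus(s[1])
                       & o.rescues([s[0]], [s[1]])),
        S("H", "There are strains x and y that cannot rescue z by themselves "
               "but can do so together",
          "exists", 3,
          lambda o, s: ~o.rescues([s[0]], [s[2]]) & ~o.rescues([s[1]], [s[2]])
                       & o.rescues([s[0], s[1]], [s[2]])),
        S("I", "Intransitivity: x rescues y which rescues z, but x cannot "
               "rescue z",
          "exists", 3,
          lambda o, s: o.rescues([s[0]], [s[1]]) & o.rescues([s[1]], [s[2]])
                       & ~o.rescues([s[0]], [s[2]])),
        S("J", "If x rescues the double-infection y,z then the double-"
               "infection x,y rescues the triple-infection x,y,z",
          "forall", 3,
          lambda o, s: imp(o.rescues([s[0]], [s[1], s[2]]),
                           o.rescues([s[0], s[1]], [s[0], s[1], s[2]]))),
        S("K", "Only if x rescues y does the double-infection x,z rescue the "
               "double-infection y,z",
          "forall", 3,
          lambda o, s: imp(o.rescues([s[0], s[2]], [s[1], s[2]]),
                           o.rescues([s[0]], [s[1]]))),
        S("M", "There are strains that are mod- in one host and mod+ in "
               "another",
          "exists", 1,
          lambda o, s: o.mod_minus(s[0], host=0) & ~o.mod_minus(s[0], host=1),
          n_hosts=2, host_dependent=True),
        S("P", "If x rescues y and x rescues z, it also rescues the double-"
               "infection y,z",
          "forall", 3,
          lambda o, s: imp(o.rescues([s[0]], [s[1]]) & o.rescues([s[0]], [s[2]]),
                           o.rescues([s[0]], [s[1], s[2]]))),
    ]


_CATALOG = _catalog()
_BY_ID = {s.id: s for s in _CATALOG}


def statement_catalog() -> list:
    """The 15 catalog statements, in published order (A ... P)."""
    return list(_CATALOG)


#: published truth values, per statement id: (goalkeeper, lock-key)
TABLE1 = {
    "A": ("true", "true"),
    "B": ("true", "true"),
    "C": ("true", "true"),
    "D": ("true", "true"),
    "D'": ("true", "false"),
    "D''": ("false", "true"),
    "E": ("true", "true"),
    "E'": ("true", "true"),
    "F": ("true", "true"),
    "H": ("true", "true"),
    "I": ("true", "true"),
    "J": ("false", "true"),
    "K": ("true", "false"),
    "M": ("true", "not_derivable"),
    "P": ("false", "true"),
}


# ---------------------------------------------------------------------------
# atom providers
# ---------------------------------------------------------------------------

class _GridOps:
    """Vectorized goalkeeper/mistiming atoms over integer-grid arrays.

    Strains and hosts are tuples of per-factor values, each value either a
    Python int or a broadcastable numpy array.
    """

    def __init__(self, n_factors, hosts):
        self.F = n_factors
        self.hosts = hosts

    def rescues(self, fem, male, host=0):
        h = self.hosts[host]
        out = None
        for f in range(self.F):
            mod = sum((s[f] for s in male), 0)
            resc = sum((s[f] for s in fem), 0) + h[f]
            c = resc >= mod
            out = c if out is None else out & c
        return out

    def mod_minus(self, strain, host=0):
        return self.rescues([], [strain], host=host)


class _MaskOps:
    """Vectorized lock-key atoms over bitmask arrays.

    Strains are ``(locks_mask, keys_mask)`` pairs of ints or broadcastable
    integer arrays; factor type ``t`` is bit ``t``.
    """

    def rescues(self, fem, male, host=0):
        mlocks = 0
        for s in male:
            mlocks = mlocks | s[0]
        fkeys = 0
        for s in fem:
            fkeys = fkeys | s[1]
        return (mlocks & ~fkeys) == 0

    def mod_minus(self, strain, host=0):
        return strain[0] == 0


class _CoreOps:
    """Scalar atoms backed by :mod:`modresc.core` on concrete objects.

    Returns numpy bool scalars so statement bodies written with ``~``, ``&``
    and ``|`` behave identically to the vectorized path.
    """

    def __init__(self, family, hosts=()):
        self.family = family
        self.hosts = hosts

    def rescues(self, fem, male, host=0):
        h = self.hosts[host] if self.hosts else None
        return np.bool_(core.rescues(Infection.of(*fem), Infection.of(*male),
                                     host=h, model_family=self.family))

    def mod_minus(self, strain, host=0):
        h = self.hosts[host] if self.hosts else None
        return np.bool_(core.is_mod_minus(strain, host=h,
                                          model_family=self.family))


# ---------------------------------------------------------------------------
# bounded search
# ---------------------------------------------------------------------------

def _search_grid(stmt: Statement, n_factors: int, bound: int, negate: bool):
    """First grid assignment (lexicographic) satisfying the (negated) body.

    Variables are ordered strain vectors first, then host vectors, each
    vector factor-major; the search chunks over the first strain's vector
    and vectorizes the remaining scalars as broadcast axes.
    """
    G = bound
    n_vec = stmt.n_strains + stmt.n_hosts
    n_inner = (n_vec - 1) * n_factors
    shape = (G + 1,) * n_inner
    vals = np.arange(G + 1, dtype=np.int32)
    axes = [vals.reshape((1,) * k + (-1,) + (1,) * (n_inner - 1 - k))
            for k in range(n_inner)]

    for first in itertools.product(range(G + 1), repeat=n_factors):
        vecs = [tuple(first)]
        for v in range(1, n_vec):
            base = (v - 1) * n_factors
            vecs.append(tuple(axes[base + f] for f in range(n_factors)))
        strains = vecs[: stmt.n_strains]
        hosts = vecs[stmt.n_strains:]
        res = np.asarray(stmt.body(_GridOps(n_factors, hosts), strains))
        if negate:
            res = ~res
        res = np.broadcast_to(res, shape)
        if res.any():
            idx = np.unravel_index(int(np.argmax(res)), shape) if n_inner else ()
            flat = list(first) + [int(i) for i in idx]
            out = [tuple(flat[v * n_factors:(v + 1) * n_factors])
                   for v in range(n_vec)]
            return out[: stmt.n_strains], out[stmt.n_strains:]
    return None


def _lockkey_domain(k: int):
    """All (locks, keys) bitmask pairs over k factor types with keys >= locks,
    sorted ascending by (locks, keys)."""
    full = (1 << k) - 1
    dom = []
    for locks in range(1 << k):
        rest = full & ~locks
        extra = rest
        extras = []
        # enumerate submasks of the complement
        sub = rest
        while True:
            extras.append(sub)
            if sub == 0:
                break
            sub = (sub - 1) & rest
        for e in extras:
            dom.append((locks, locks | e))
    dom.sort()
    return dom


def _search_masks(stmt: Statement, k: int, negate: bool):
    """First lock-key assignment (by (locks, keys) bitmask order) satisfying
    the (negated) body; chunks over the first strain, vectorizes the rest."""
    dom = _lockkey_domain(k)
    La = np.array([d[0] for d in dom], dtype=np.int64)
    Ka = np.array([d[1] for d in dom], dtype=np.int64)
    n_inner = stmt.n_strains - 1
    shape = (len(dom),) * n_inner
    axes = []
    for v in range(n_inner):
        sh = (1,) * v + (-1,) + (1,) * (n_inner - 1 - v)
        axes.append((La.reshape(sh), Ka.reshape(sh)))

    ops = _MaskOps()
    for d0 in dom:
        strains = [d0] + axes
        res = np.asarray(stmt.body(ops, strains))
        if negate:
            res = ~res
        res = np.broadcast_to(res, shape)
        if res.any():
            idx = np.unravel_index(int(np.argmax(res)), shape) if n_inner else ()
            return [d0] + [dom[int(i)] for i in idx]
    return None


_VAR_NAMES = ("x", "y", "z")


def _mask_to_set(mask: int) -> frozenset:
    return frozenset(str(t + 1) for t in range(mask.bit_length()) if mask >> t & 1)


def _grid_assignment(stmt, strain_vecs, host_vecs):
    out = {}
    for name, vec in zip(_VAR_NAMES, strain_vecs):
        out[name] = Strain(id=name, gk=vec)
    for i, vec in enumerate(host_vecs):
        out["host" if i == 0 else f"host{i + 1}"] = \
            HostBackground(id=f"h{i + 1}", h=vec)
    return out


def _mask_assignment(stmt, mask_pairs):
    out = {}
    for name, (locks, keys) in zip(_VAR_NAMES, mask_pairs):
        out[name] = Strain(id=name, locks=_mask_to_set(locks),
                           keys=_mask_to_set(keys))
    return out


def _verify(stmt: Statement, family: str, assignment: dict, expected: bool):
    """Re-check a found assignment with the pure-Python core predicates."""
    strains = [assignment[n] for n in _VAR_NAMES[: stmt.n_strains]]
    hosts = [assignment[k] for k in ("host", "host2") if k in assignment]
    got = bool(stmt.body(_CoreOps(family, hosts), strains))
    if got != expected:
        raise RuntimeError(
            f"unsound search result for statement {stmt.id} under {family}: "
            f"assignment {assignment} re-verifies as {got}"
        )


def evaluate(statement, model_family: str,
             config: Optional[SearchConfig] = None) -> Verdict:
    """Evaluate one statement under a model family by bounded search.

    Existential statements are ``true`` iff a witness exists in the bounded
    domain; universal statements are ``false`` iff a counterexample exists.
    ``statement`` may be a :class:`Statement` or a catalog id.
    """
    if isinstance(statement, str):
        statement = _BY_ID[statement]
    if model_family not in core.MODEL_FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    config = config or SearchConfig()
    if statement.n_strains > config.max_strains:
        raise ConfigError(
            f"statement {statement.id} quantifies over {statement.n_strains} "
            f"strains, config allows {config.max_strains}")

    want = statement.quantifier == "exists"  # search body (else its negation)
    if model_family == "lockkey":
        if statement.host_dependent:
            return Verdict("not_derivable")
        found = _search_masks(statement, config.factor_types, negate=not want)
        assignment = _mask_assignment(statement, found) if found else None
    else:
        n_factors = 2 if model_family == "goalkeeper" else 1
        found = _search_grid(statement, n_factors, config.grid_bound,
                             negate=not want)
        assignment = _grid_assignment(statement, *found) if found else None

    if assignment is not None:
        _verify(statement, model_family, assignment, expected=want)
    if statement.quantifier == "exists":
        return Verdict("true" if assignment else "false", assignment)
    return Verdict("false" if assignment else "true", assignment)


def reproduce_table1(config: Optional[SearchConfig] = None) -> pd.DataFrame:
    """Evaluate the whole catalog under goalkeeper and lock-key semantics.

    Returns a DataFrame indexed by statement id with columns ``goalkeeper``
    and ``lockkey`` holding verdict strings.
    """
    rows = {}
    for stmt in _CATALOG:
        rows[stmt.id] = {
            "goalkeeper": evaluate(stmt, "goalkeeper", config).value,
            "lockkey": evaluate(stmt, "lockkey", config).value,
        }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["goalkeeper", "lockkey"])


def check_table1(config: Optional[SearchConfig] = None) -> list:
    """Compare computed verdicts with the published table.

    Returns a list of ``(statement id, family, computed, published)``
    mismatches, with the offending witness/counterexample where one exists;
    empty if the table is reproduced exactly.
    """
    mismatches = []
    for stmt in _CATALOG:
        for col, family in ((0, "goalkeeper"), (1, "lockkey")):
            verdict = evaluate(stmt, family, config)
            expected = TABLE1[stmt.id][col]
            if verdict.value != expected:
                mismatches.append((stmt.id, family, verdict, expected))
    return mismatches
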