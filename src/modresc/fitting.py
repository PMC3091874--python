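"""Fitting observed compatibility relationships.

Two exact fitting problems over a 3-valued compatibility matrix (rows =
maternal strain, columns = paternal strain, cells compatible / incompatible
/ unknown):

* :func:`min_lockkey_factors` -- the smallest number of lock/key factor
  types that reproduces every known entry, with a witness assignment.  A
  factor type is characterized by the pair ``(L, K)`` of strain sets that
  carry its lock resp. its key; a cross (female i, male j) is incompatible
  iff some factor has ``j in L`` and ``i not in K``.  For a fixed key-set
  ``K`` the inclusion-maximal admissible lock-set is determined by the
  compatible entries, so at most ``2^n`` candidate factors exist and the
  minimal count is an exact set cover over the incompatible entries.
* :func:`goalkeeper_fit` -- feasibility of the two-factor quantitative
  model, optionally with a free net host contribution.  Each incompatible
  entry must violate rescue in at least one factor; the search branches
  over which factor is violated and checks each single-factor system of
  difference constraints by negative-cycle detection, which yields exact
  integer witnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import core
from .core import HostBackground, Infection, Strain

__all__ = [
    "COMPATIBLE",
    "INCOMPATIBLE",
    "UNKNOWN",
    "CompatibilityMatrix",
    "LockKeyAssignment",
    "GoalkeeperFit",
    "FitResult",
    "matrix_from_levels",
    "lockkey_explains",
    "min_lockkey_factors",
    "goalkeeper_explains",
    "goalkeeper_fit",
]

COMPATIBLE = "C"
INCOMPATIBLE = "I"
UNKNOWN = "?"
_CELLS = (COMPATIBLE, INCOMPATIBLE, UNKNOWN)


class InfeasibleError(RuntimeError):
    pass


@dataclass(frozen=True)
class CompatibilityMatrix:
    """3-valued rescue relation over ordered strain pairs.

    ``cells[i][j]`` is the outcome of crossing a female infected with strain
    ``strains[i]`` to a male infected with strain ``strains[j]``.  Diagonal
    entries must be compatible unless the strain is flagged suicidal.
    """

    strains: tuple
    cells: tuple
    suicidal: frozenset = frozenset()

    def __post_init__(self):
        strains = tuple(self.strains)
        cells = tuple(tuple(row) for row in self.cells)
        object.__setattr__(self, "strains", strains)
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "suicidal", frozenset(self.suicidal))
        if len(set(strains)) != len(strains):
            raise ValueError("duplicate strain labels")
        n = len(strains)
        if len(cells) != n or any(len(row) != n for row in cells):
            raise ValueError("cells must be an n x n table")
        for row in cells:
            for c in row:
                if c not in _CELLS:
                    raise ValueError(f"unknown cell token {c!r}")
        for i, s in enumerate(strains):
            if cells[i][i] == COMPATIBLE and s in self.suicidal:
                raise ValueError(f"suicidal strain {s} with compatible diagonal")
            if cells[i][i] == INCOMPATIBLE and s not in self.suicidal:
                raise ValueError(
                    f"incompatible diagonal for {s}: flag the strain suicidal")

    @classmethod
    def from_dict(cls, strains: Sequence[str], entries: Mapping,
                  default: str = UNKNOWN, suicidal=frozenset()):
        """Build from ``{(maternal, paternal): cell}``; missing diagonal
        entries default to compatible (self-rescue)."""
        idx = {s: i for i, s in enumerate(strains)}
        cells = [[default] * len(strains) for _ in strains]
        for s in strains:
            if s not in suicidal:
                cells[idx[s]][idx[s]] = COMPATIBLE
        for (mat, pat), c in entries.items():
            cells[idx[mat]][idx[pat]] = c
        return cls(tuple(strains), tuple(map(tuple, cells)), frozenset(suicidal))

    def entry(self, maternal: str, paternal: str) -> str:
        i = self.strains.index(maternal)
        j = self.strains.index(paternal)
        return self.cells[i][j]

    def known_entries(self):
        """Yield ``(i, j, cell)`` for every non-unknown entry (indices)."""
        for i, row in enumerate(self.cells):
            for j, c in enumerate(row):
                if c != UNKNOWN:
                    yield i, j, c

    def to_frame(self) -> pd.DataFrame:
        """Rows = maternal strain, columns = paternal strain."""
        return pd.DataFrame([list(r) for r in self.cells],
                            index=list(self.strains),
                            columns=list(self.strains))


def matrix_from_levels(records, threshold: float = 20.0,
                       suicidal=frozenset()) -> CompatibilityMatrix:
    """Threshold corrected CI levels into a compatibility matrix.

    ``records`` is an iterable of ``(maternal, paternal, corrected_level)``
    triples or a DataFrame with columns ``maternal``, ``paternal``,
    ``level``.  Replicate crosses are averaged before thresholding; a cross
    is incompatible iff its mean corrected CI level is >= ``threshold``
    percent (default 20%).  Strains never crossed stay unknown.
    """
    if isinstance(records, pd.DataFrame):
        records = list(records[["maternal", "paternal", "level"]].itertuples(
            index=False, name=None))
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    levels = {}
    order = []
    for rec in records:
        try:
            mat, pat, level = rec
            level = float(level)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed crossing record {rec!r}") from exc
        if not 0 <= level <= 100:
            raise ValueError(f"corrected CI level out of range: {level}")
        for s in (mat, pat):
            if s not in order:
                order.append(s)
        levels.setdefault((mat, pat), []).append(level)
    entries = {}
    for pair, vals in levels.items():
        mean = sum(vals) / len(vals)
        entries[pair] = INCOMPATIBLE if mean >= threshold else COMPATIBLE
    return CompatibilityMatrix.from_dict(order, entries, suicidal=suicidal)


# ---------------------------------------------------------------------------
# lock-key factorization
# ---------------------------------------------------------------------------

@dataclass
class LockKeyAssignment:
    """Per-strain lock and key sets over factor-type labels."""

    locks: dict  # strain label -> frozenset of factor-type labels
    keys: dict

    def __post_init__(self):
        self.locks = {s: frozenset(v) for s, v in self.locks.items()}
        self.keys = {s: frozenset(v) for s, v in self.keys.items()}

    @property
    def factor_types(self) -> frozenset:
        out = frozenset()
        for v in self.locks.values():
            out |= v
        for v in self.keys.values():
            out |= v
        return out

    def strain(self, label: str, suicidal: bool = False) -> Strain:
        return Strain(id=label, locks=self.locks.get(label, frozenset()),
                      keys=self.keys.get(label, frozenset()), suicidal=suicidal)

    def to_frame(self) -> pd.DataFrame:
        """L/K layout: one row per factor type, (strain, mod/resc) columns."""
        strains = sorted(set(self.locks) | set(self.keys))
        factors = sorted(self.factor_types, key=str)
        cols = pd.MultiIndex.from_product([strains, ["mod", "resc"]])
        rows = []
        for t in factors:
            row = []
            for s in strains:
                row.append("L" if t in self.locks.get(s, ()) else "")
                row.append("K" if t in self.keys.get(s, ()) else "")
            rows.append(row)
        return pd.DataFrame(rows, index=factors, columns=cols)


def lockkey_explains(matrix: CompatibilityMatrix,
                     assignment: LockKeyAssignment) -> bool:
    """True iff the assignment reproduces every known matrix entry.

    A cross (female i, male j) is predicted compatible iff every lock of
    strain j is matched by a key of strain i.
    """
    for s in matrix.strains:
        if s not in assignment.locks and s not in assignment.keys:
            raise ValueError(f"assignment missing strain {s}")
    for i, j, cell in matrix.known_entries():
        locks = assignment.locks.get(matrix.strains[j], frozenset())
        keys = assignment.keys.get(matrix.strains[i], frozenset())
        compatible = locks <= keys
        if compatible != (cell == COMPATIBLE):
            return False
    return True


def _cover_candidates(matrix: CompatibilityMatrix, require_locks: bool):
    """Candidate factors for the set-cover formulation.

    Returns ``(candidates, n_elements)`` where each candidate is a triple
    ``(key_mask, lock_mask, element_mask)`` over strain bitmasks and the
    universe of elements to cover: one bit per incompatible entry, plus one
    bit per strain when every strain must carry a lock.
    """
    n = len(matrix.strains)
    suicidal_mask = 0
    for i, s in enumerate(matrix.strains):
        if s in matrix.suicidal:
            suicidal_mask |= 1 << i
    comp_rows = [0] * n   # per column j: rows i with known compatible entry
    i_entries = []
    for i, j, cell in matrix.known_entries():
        if cell == COMPATIBLE:
            comp_rows[j] |= 1 << i
        else:
            i_entries.append((i, j))
    n_elem = len(i_entries) + (n if require_locks else 0)
    candidates = []
    for kmask in range(1 << n):
        lmask = 0
        for j in range(n):
            if not (suicidal_mask >> j & 1) and not (kmask >> j & 1):
                continue  # self-rescue: a lock demands the matching key
            if comp_rows[j] & ~kmask:
                continue  # would break a compatible entry
            lmask |= 1 << j
        if lmask == 0:
            continue  # every factor type must be used by some strain
        emask = 0
        for e, (i, j) in enumerate(i_entries):
            if (lmask >> j & 1) and not (kmask >> i & 1):
                emask |= 1 << e
        if require_locks:
            emask |= lmask << len(i_entries)
        if emask:
            candidates.append((kmask, lmask, emask))
    return candidates, n_elem, i_entries


def min_lockkey_factors(matrix: CompatibilityMatrix,
                        require_locks: bool = True,
                        max_factors: Optional[int] = None):
    """Exact minimal number of lock/key factor types explaining the matrix.

    Returns ``(k, assignment)`` with a witness :class:`LockKeyAssignment`
    over factor types ``"1"`` .. ``"k"``.  ``require_locks`` demands that
    every strain carries at least one lock (the strains in these matrices
    are CI inducers); disable it to allow mod- strains.  The search is an
    exact branch-and-bound set cover and is guaranteed minimal.
    """
    candidates, n_elem, i_entries = _cover_candidates(matrix, require_locks)
    full = (1 << n_elem) - 1
    if n_elem == 0:
        return 0, LockKeyAssignment({s: frozenset() for s in matrix.strains},
                                    {s: frozenset() for s in matrix.strains})
    reachable = 0
    for _, _, emask in candidates:
        reachable |= emask
    if reachable != full:
        raise InfeasibleError("matrix admits no lock-key explanation")

    # covers[e]: candidates covering element e, deterministic order
    covers = [[c for c in candidates if c[2] >> e & 1] for e in range(n_elem)]
    best: list = [None]
    limit = max_factors if max_factors is not None else len(candidates)

    def dfs(covered: int, chosen: tuple):
        if best[0] is not None and len(chosen) >= len(best[0]):
            return
        if covered == full:
            best[0] = chosen
            return
        if len(chosen) >= limit:
            return
        # branch on the uncovered element with fewest remaining candidates
        pick, options = None, None
        for e in range(n_elem):
            if covered >> e & 1:
                continue
            opts = covers[e]
            if options is None or len(opts) < len(options):
                pick, options = e, opts
        for cand in options:
            dfs(covered | cand[2], chosen + (cand,))

    dfs(0, ())
    if best[0] is None:
        raise InfeasibleError(
            f"no lock-key explanation within {limit} factor types")
    chosen = sorted(best[0])  # canonical factor order: ascending key mask
    locks = {s: set() for s in matrix.strains}
    keys = {s: set() for s in matrix.strains}
    for t, (kmask, lmask, _) in enumerate(chosen, start=1):
        for i, s in enumerate(matrix.strains):
            if lmask >> i & 1:
                locks[s].add(str(t))
            if kmask >> i & 1:
                keys[s].add(str(t))
    assignment = LockKeyAssignment(locks, keys)
    assert lockkey_explains(matrix, assignment)
    return len(chosen), assignment


# ---------------------------------------------------------------------------
# goalkeeper fit
# ---------------------------------------------------------------------------

@dataclass
class GoalkeeperFit:
    """Two-factor quantities per strain plus one net host contribution."""

    g: dict  # strain label -> (q1, q2)
    h: tuple = (0, 0)

    def strain(self, label: str) -> Strain:
        return Strain(id=label, gk=self.g[label])

    def host(self) -> HostBackground:
        return HostBackground(id="fit", h=self.h)


@dataclass
class FitResult:
    feasible: bool
    fit: Optional[GoalkeeperFit] = None


def goalkeeper_explains(matrix: CompatibilityMatrix, fit: GoalkeeperFit) -> bool:
    """True iff every known matrix entry matches the goalkeeper predicate."""
    for s in matrix.strains:
        if s not in fit.g:
            raise ValueError(f"fit missing strain {s}")
    host = fit.host()
    for i, j, cell in matrix.known_entries():
        ok = core.rescues(Infection.of(fit.strain(matrix.strains[i])),
                          Infection.of(fit.strain(matrix.strains[j])),
                          host=host, model_family="goalkeeper")
        if ok != (cell == COMPATIBLE):
            return False
    return True


def _negative_cycle(n: int, edges) -> bool:
    """Bellman-Ford negative-cycle detection (edge (u, v, w): x_v <= x_u + w)."""
    dist = [0] * n
    for it in range(n):
        changed = False
        for u, v, w in edges:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            return False
    return changed


def _potentials(n: int, edges):
    dist = [0] * n
    for _ in range(n):
        for u, v, w in edges:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
    lo = min(dist)
    return [d - lo for d in dist]


def goalkeeper_fit(matrix: CompatibilityMatrix,
                   host_free: bool = True) -> FitResult:
    """Exact feasibility of the two-factor goalkeeper model for a matrix.

    A compatible entry (female i, male j) requires ``g_j <= g_i + h``
    componentwise; an incompatible entry requires ``g_j > g_i + h`` in at
    least one factor.  The search assigns each incompatible entry a violated
    factor and checks both single-factor difference-constraint systems for a
    negative cycle.  The host contribution is fixed to ``h = (n, n)`` when
    free: the per-factor system is feasible for *some* h >= 0 iff it is
    feasible at h = n (every infeasibility certificate is a constraint cycle
    with at least as many strict as non-strict edges, whose weight is
    negative for every h; all other cycles have non-negative weight once
    h >= n - 1).  Witness quantities are exact integers.

    Suicidal strains (incompatible diagonal) are structurally impossible
    under goalkeeper semantics and make the fit infeasible.
    """
    n = len(matrix.strains)
    if matrix.suicidal:
        return FitResult(False)
    h = n if host_free else 0
    c_edges = []
    i_entries = []
    for i, j, cell in matrix.known_entries():
        if i == j:
            continue
        if cell == COMPATIBLE:
            c_edges.append((i, j, h))    # x_j <= x_i + h, both factors
        else:
            i_entries.append((i, j))     # x_j >= x_i + h + 1, one factor

    # pair up symmetric entries so contradictions surface early
    i_entries.sort(key=lambda e: (min(e), max(e), e[0]))
    extra: list = [[], []]  # strict edges per factor

    def feasible(f: int) -> bool:
        return not _negative_cycle(n, c_edges + extra[f])

    def dfs(pos: int) -> bool:
        if pos == len(i_entries):
            return True
        i, j = i_entries[pos]
        factors = (0,) if pos == 0 else (0, 1)  # factor-swap symmetry
        for f in factors:
            extra[f].append((j, i, -(h + 1)))
            if feasible(f) and dfs(pos + 1):
                return True
            extra[f].pop()
        return False

    if not dfs(0):
        return FitResult(False)
    g1 = _potentials(n, c_edges + extra[0])
    g2 = _potentials(n, c_edges + extra[1])
    fit = GoalkeeperFit(
        g={s: (g1[i], g2[i]) for i, s in enumerate(matrix.strains)},
        h=(h, h))
    assert goalkeeper_explains(matrix, fit)
    return FitResult(True, fit)
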