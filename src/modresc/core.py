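"""Model semantics for *Wolbachia*-induced cytoplasmic incompatibility (CI).

Three model families are implemented over a common vocabulary of strains,
infections (finite strain sets carried by one host) and crosses:

* **goalkeeper** -- each strain contributes a fixed quantity to each of two
  factors; the same quantities act as *mod* (sperm modification) in males and
  *resc* (egg rescue) in females.  The female's host species adds a net host
  contribution to each rescue factor.  CI occurs iff at least one summed mod
  factor strictly exceeds the corresponding summed resc factor.
* **mistiming** -- the one-factor special case of the goalkeeper model
  (cell-cycle timing delay only).
* **lock-key** -- each strain deposits a set of qualitative lock types via
  sperm and key types via the egg; CI occurs iff some paternal lock type is
  not matched by a maternal key type.  Host background plays no role.

Factor quantities may be ints, :class:`~fractions.Fraction` or floats.
Integer/rational quantities are compared exactly; floats with a 1e-9
absolute tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

__all__ = [
    "Strain",
    "HostBackground",
    "Infection",
    "Cross",
    "CIOutcome",
    "UNINFECTED",
    "MODEL_FAMILIES",
    "mod_vector",
    "resc_vector",
    "ci_goalkeeper",
    "ci_mistiming",
    "ci_lockkey",
    "ci_predicate",
    "rescues",
    "is_mod_minus",
    "ci_level_goalkeeper",
    "ci_level_lockkey",
]

MODEL_FAMILIES = ("goalkeeper", "mistiming", "lockkey")

#: absolute tolerance used when either operand of a comparison is a float
FLOAT_ATOL = 1e-9


def _strictly_greater(a, b) -> bool:
    """``a > b``, exact for ints/Fractions, tolerant for floats."""
    if isinstance(a, float) or isinstance(b, float):
        return a > b + FLOAT_ATOL
    return a > b


class DimensionError(ValueError):
    """Mixed or mismatched factor dimensionality."""


@dataclass(frozen=True)
class Strain:
    """One *Wolbachia* strain with its mechanism parameters.

    Parameters
    ----------
    id:
        Short label, e.g. ``"wRi"``.
    gk:
        Per-factor quantities for the goalkeeper family (length 2) or the
        mistiming family (length 1).  ``None`` if the strain is only used
        under lock-key semantics.
    locks, keys:
        Qualitative factor-type labels for the lock-key family.  Unless the
        strain is flagged ``suicidal``, ``keys`` must cover ``locks`` so the
        strain can rescue its own modification.
    suicidal:
        Allow ``keys`` not to cover ``locks`` (representable in lock-key
        only; the goalkeeper family structurally enforces self-rescue).
    """

    id: str
    gk: Optional[tuple] = None
    locks: Optional[frozenset] = None
    keys: Optional[frozenset] = None
    suicidal: bool = False

    def __post_init__(self):
        if self.gk is not None:
            object.__setattr__(self, "gk", tuple(self.gk))
            if any(q < 0 for q in self.gk):
                raise ValueError(f"strain {self.id!r}: negative factor quantity")
            if self.suicidal:
                raise ValueError(
                    f"strain {self.id!r}: suicidal strains are not representable "
                    "with quantitative factors (self-rescue is structural)"
                )
        if self.locks is not None:
            object.__setattr__(self, "locks", frozenset(self.locks))
        if self.keys is not None:
            object.__setattr__(self, "keys", frozenset(self.keys))
        if self.locks is not None:
            ks = self.keys if self.keys is not None else frozenset()
            if not self.suicidal and not ks >= self.locks:
                raise ValueError(
                    f"strain {self.id!r}: keys must cover locks (self-rescue); "
                    "flag the strain suicidal to permit this"
                )

    @property
    def n_factors(self) -> Optional[int]:
        return None if self.gk is None else len(self.gk)


@dataclass(frozen=True)
class HostBackground:
    """Net host contribution ``h`` to the rescue factors (females only)."""

    id: str
    h: tuple = (0, 0)

    def __post_init__(self):
        object.__setattr__(self, "h", tuple(self.h))
        if any(q < 0 for q in self.h):
            raise ValueError(f"host {self.id!r}: negative contribution")

    @classmethod
    def zero(cls, n_factors: int = 2, id: str = "zero") -> "HostBackground":
        return cls(id=id, h=(0,) * n_factors)


@dataclass(frozen=True)
class Infection:
    """A finite set of strains carried by one host (empty = uninfected)."""

    strains: tuple = ()

    def __post_init__(self):
        strains = tuple(sorted(self.strains, key=lambda s: s.id))
        ids = [s.id for s in strains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate strain ids in infection: {ids}")
        object.__setattr__(self, "strains", strains)

    @classmethod
    def of(cls, *strains: Strain) -> "Infection":
        return cls(tuple(strains))

    def __iter__(self):
        return iter(self.strains)

    def __len__(self):
        return len(self.strains)

    def __bool__(self):  # uninfected is falsy
        return bool(self.strains)


UNINFECTED = Infection(())


@dataclass(frozen=True)
class Cross:
    """A mating: sperm from ``paternal`` male, egg from ``maternal`` female."""

    paternal: Infection = UNINFECTED
    maternal: Infection = UNINFECTED
    host: Optional[HostBackground] = None


@dataclass(frozen=True)
class CIOutcome:
    """Qualitative CI verdict plus quantitative level (percent scale)."""

    ci: bool
    level: float = 0.0

    def __post_init__(self):
        if not self.ci and self.level != 0:
            raise ValueError("compatible cross must have level 0")


def _infection_factors(infection: Infection, n_factors: Optional[int]) -> int:
    dims = {s.n_factors for s in infection}
    dims.discard(None)
    if len(dims) > 1:
        raise DimensionError(f"mixed factor dimensionality: {sorted(dims)}")
    if dims:
        f = dims.pop()
        if n_factors is not None and f != n_factors:
            raise DimensionError(f"expected {n_factors} factors, strains carry {f}")
        return f
    if n_factors is None:
        raise DimensionError("uninfected: factor dimensionality must be supplied")
    return n_factors


def mod_vector(paternal: Infection, n_factors: Optional[int] = 2) -> tuple:
    """Summed per-factor mod quantities deposited by the paternal infection.

    In multiple infections the magnitude of each factor is the added quantity
    contributed by each single strain; an uninfected male deposits the zero
    vector.
    """
    f = _infection_factors(paternal, n_factors)
    out = [0] * f
    for s in paternal:
        if s.gk is None:
            raise DimensionError(f"strain {s.id!r} has no factor quantities")
        for i, q in enumerate(s.gk):
            out[i] = out[i] + q
    return tuple(out)


def resc_vector(maternal: Infection, host: HostBackground) -> tuple:
    """Summed maternal rescue quantities plus the net host contribution."""
    f = _infection_factors(maternal, len(host.h))
    out = list(mod_vector(maternal, f))
    for i, q in enumerate(host.h):
        out[i] = out[i] + q
    return tuple(out)


def _host_or_zero(cross: Cross, n_factors: int = 2) -> HostBackground:
    if cross.host is not None:
        return cross.host
    # infer dimensionality from either infection if possible
    for inf in (cross.maternal, cross.paternal):
        try:
            n_factors = _infection_factors(inf, None)
            break
        except DimensionError:
            continue
    return HostBackground.zero(n_factors)


def ci_goalkeeper(cross: Cross, c: float = 10.0, norm: str = "l2") -> CIOutcome:
    """Goalkeeper CI predicate with quantitative level.

    CI manifests iff at least one mod factor strictly exceeds the
    corresponding resc factor; rescue is non-strict (equal quantities are
    rescued).  The level is ``c * ||max(0, mod - resc)||`` clipped to
    [0, 100] (see :func:`ci_level_goalkeeper`).
    """
    host = _host_or_zero(cross)
    mod = mod_vector(cross.paternal, len(host.h))
    resc = resc_vector(cross.maternal, host)
    if len(mod) != len(resc):
        raise DimensionError(f"mod has {len(mod)} factors, resc has {len(resc)}")
    ci = any(_strictly_greater(m, r) for m, r in zip(mod, resc))
    level = ci_level_goalkeeper(cross, c=c, norm=norm) if ci else 0.0
    return CIOutcome(ci=ci, level=level)


def ci_mistiming(cross: Cross, c: float = 10.0) -> CIOutcome:
    """Mistiming CI predicate: the goalkeeper predicate restricted to F=1."""
    host = _host_or_zero(cross, n_factors=1)
    if len(host.h) != 1:
        raise DimensionError("mistiming requires exactly one factor")
    return ci_goalkeeper(cross, c=c)


def ci_lockkey(cross: Cross) -> CIOutcome:
    """Lock-key CI predicate: CI iff some paternal lock lacks a maternal key.

    Multiply infected hosts produce the union of their strains' locks or
    keys.  Host background is ignored (no net host contribution is assumed
    under lock-key semantics).
    """
    locks = frozenset().union(*(s.locks or frozenset() for s in cross.paternal)) \
        if cross.paternal else frozenset()
    keys = frozenset().union(*(s.keys or frozenset() for s in cross.maternal)) \
        if cross.maternal else frozenset()
    ci = not locks <= keys
    return CIOutcome(ci=ci, level=ci_level_lockkey(cross) if ci else 0.0)


def ci_predicate(cross: Cross, model_family: str) -> bool:
    """Dispatch the CI predicate for a model family."""
    if model_family == "goalkeeper":
        return ci_goalkeeper(cross).ci
    if model_family == "mistiming":
        return ci_mistiming(cross).ci
    if model_family == "lockkey":
        return ci_lockkey(cross).ci
    raise ValueError(f"unknown model family {model_family!r}")


def rescues(
    female: Infection,
    male: Infection,
    host: Optional[HostBackground] = None,
    model_family: str = "goalkeeper",
) -> bool:
    """True iff the cross (sperm from ``male``, egg from ``female``) is compatible."""
    return not ci_predicate(Cross(paternal=male, maternal=female, host=host),
                            model_family)


def is_mod_minus(
    strain: Strain,
    host: Optional[HostBackground] = None,
    model_family: str = "goalkeeper",
) -> bool:
    """True iff a male mono-infected by ``strain`` is compatible with an
    uninfected female on ``host`` (i.e. the strain induces no CI there)."""
    return rescues(UNINFECTED, Infection.of(strain), host=host,
                   model_family=model_family)


def ci_level_goalkeeper(cross: Cross, c: float = 10.0, norm: str = "l2") -> float:
    """Quantitative goalkeeper CI level in percent.

    The level is proportional to the norm of the componentwise-clamped
    difference ``max(0, mod - resc)``: surplus rescue in one factor cannot
    offset a deficit in another (the rescue region is rectangular).  The
    proportionality constant ``c`` and the norm (``"l2"`` Euclidean,
    ``"l1"``) are configuration; the result is clipped to [0, 100].
    """
    if c < 0:
        raise ValueError("proportionality constant must be non-negative")
    if norm not in ("l2", "l1"):
        raise ValueError(f"unknown norm {norm!r}")
    host = _host_or_zero(cross)
    mod = mod_vector(cross.paternal, len(host.h))
    resc = resc_vector(cross.maternal, host)
    diff = [max(0, m - r) for m, r in zip(mod, resc)]
    if norm == "l2":
        value = c * math.sqrt(sum(float(d) ** 2 for d in diff))
    else:
        value = c * sum(float(d) for d in diff)
    return min(100.0, max(0.0, value))


def ci_level_lockkey(cross: Cross) -> float:
    """CI level under the quantitative lock-key extension, in percent.

    With ``n`` paternal lock types of which ``m`` are matched by maternal
    keys, the level is ``100 * (n - m) / n`` (e.g. ten locks with six
    matching keys give 40%).  No paternal locks give level 0.
    """
    locks = frozenset().union(*(s.locks or frozenset() for s in cross.paternal)) \
        if cross.paternal else frozenset()
    if not locks:
        return 0.0
    keys = frozenset().union(*(s.keys or frozenset() for s in cross.maternal)) \
        if cross.maternal else frozenset()
    return 100.0 * len(locks - keys) / len(locks)
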