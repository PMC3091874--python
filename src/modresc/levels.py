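"""Quantitative CI-level predictions and their scoring.

Under the goalkeeper model the CI level of a cross is proportional to the
norm of the clamped difference ``max(0, mod - resc)`` between the summed
paternal mod factors and the summed maternal resc factors (plus host
contribution).  Three qualitative predictions follow for crossing data:

1. adding strains to the female decreases (weakly) the CI level;
2. adding strains to the male increases (weakly) the CI level;
3. *equivalent* crosses -- equal clamped difference vectors -- have similar
   CI levels.

Observed embryonic mortalities are corrected for control-cross mortality,
scored against the predicted direction (type 1/2; an exact tie is a draw)
or against an absolute similarity margin (type 3, default 10 percentage
points), and the correct/false counts are tested with a one-tailed exact
binomial test against the fair-coin null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

from .core import Cross, HostBackground, Infection, Strain, mod_vector, resc_vector

__all__ = [
    "CrossRecord",
    "Prediction",
    "ScoreSummary",
    "corrected_ci",
    "diff_vector",
    "crosses_equivalent",
    "enumerate_predictions",
    "score_predictions",
    "binomial_p",
]

#: levels closer than this are treated as exactly tied (float round-off guard)
TIE_ATOL = 1e-9


def corrected_ci(raw: float, control: float) -> float:
    """Control-corrected CI level: ``100 * (raw - control) / (100 - control)``.

    ``raw`` is the embryonic mortality (%) in the focal cross, ``control``
    the mortality (%) in the compatible control cross; the result is clipped
    to [0, 100].
    """
    if not 0 <= raw <= 100:
        raise ValueError(f"raw mortality out of range: {raw}")
    if not 0 <= control < 100:
        raise ValueError(f"control mortality must be in [0, 100): {control}")
    return min(100.0, max(0.0, 100.0 * (raw - control) / (100.0 - control)))


@dataclass(frozen=True)
class CrossRecord:
    """One literature cross: infections by strain label, mortalities in %."""

    maternal: frozenset
    paternal: frozenset
    raw_mortality: float
    control_mortality: float

    def __post_init__(self):
        object.__setattr__(self, "maternal", frozenset(self.maternal))
        object.__setattr__(self, "paternal", frozenset(self.paternal))
        corrected_ci(self.raw_mortality, self.control_mortality)  # range check

    @property
    def corrected(self) -> float:
        return corrected_ci(self.raw_mortality, self.control_mortality)


def _infection(labels, strains: Mapping[str, Strain]) -> Infection:
    try:
        return Infection.of(*(strains[l] for l in sorted(labels)))
    except KeyError as exc:
        raise KeyError(f"unknown strain label {exc.args[0]!r}") from None


def diff_vector(maternal, paternal, strains: Mapping[str, Strain],
                host: HostBackground) -> tuple:
    """Clamped mod-resc difference ``max(0, mod - resc)`` for a cross."""
    mod = mod_vector(_infection(paternal, strains), len(host.h))
    resc = resc_vector(_infection(maternal, strains), host)
    return tuple(max(0, m - r) for m, r in zip(mod, resc))


def crosses_equivalent(c1: CrossRecord, c2: CrossRecord,
                       strains: Mapping[str, Strain],
                       host: HostBackground) -> bool:
    """True iff the two crosses have equal clamped difference vectors.

    Equivalence is judged on the model-derived difference vectors (not the
    raw strain label sets) so the host background is honored.
    """
    d1 = diff_vector(c1.maternal, c1.paternal, strains, host)
    d2 = diff_vector(c2.maternal, c2.paternal, strains, host)
    return all(abs(a - b) <= TIE_ATOL for a, b in zip(d1, d2))


@dataclass
class Prediction:
    """A directed or similarity prediction over a pair of cross records.

    ``kind`` 1: ``second`` adds maternal strains to ``first`` -> level should
    decrease.  ``kind`` 2: ``second`` adds paternal strains -> level should
    increase.  ``kind`` 3: the crosses are equivalent -> levels should agree
    within the margin.  ``verdict`` is filled by :func:`score_predictions`.
    """

    kind: int
    first: CrossRecord
    second: CrossRecord
    verdict: Optional[str] = None  # "correct" | "false" | "draw"


def enumerate_predictions(records: Sequence[CrossRecord],
                          strains: Mapping[str, Strain],
                          host: HostBackground) -> list:
    """All type-1/2/3 predictions over pairs of records.

    Pairs that are model-equivalent yield a type-3 prediction; otherwise a
    pair with identical paternal side and nested maternal sets yields type 1
    and a pair with identical maternal side and nested paternal sets yields
    type 2 (the predictions assume per-strain density unchanged in multiple
    infections).
    """
    preds = []
    for a in range(len(records)):
        for b in range(a + 1, len(records)):
            r1, r2 = records[a], records[b]
            if (r1.maternal, r1.paternal) == (r2.maternal, r2.paternal):
                continue
            if crosses_equivalent(r1, r2, strains, host):
                preds.append(Prediction(3, r1, r2))
            elif r1.paternal == r2.paternal and r1.maternal < r2.maternal:
                preds.append(Prediction(1, r1, r2))
            elif r1.paternal == r2.paternal and r2.maternal < r1.maternal:
                preds.append(Prediction(1, r2, r1))
            elif r1.maternal == r2.maternal and r1.paternal < r2.paternal:
                preds.append(Prediction(2, r1, r2))
            elif r1.maternal == r2.maternal and r2.paternal < r1.paternal:
                preds.append(Prediction(2, r2, r1))
    return preds


@dataclass(frozen=True)
class ScoreSummary:
    n_correct: int
    n_false: int
    n_draw: int

    @property
    def n_scored(self) -> int:
        """Trials entering the binomial test (draws excluded)."""
        return self.n_correct + self.n_false


def score_predictions(predictions: Iterable[Prediction],
                      margin: float = 10.0) -> ScoreSummary:
    """Score predictions against observed corrected CI levels.

    Type 1/2 are scored by strict direction; exact ties are draws and are
    excluded from the binomial count.  Type 3 is correct iff the absolute
    level difference is within ``margin`` percentage points.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    n_correct = n_false = n_draw = 0
    for p in predictions:
        l1, l2 = p.first.corrected, p.second.corrected
        delta = l2 - l1
        if p.kind == 3:
            p.verdict = "correct" if abs(delta) <= margin else "false"
        elif abs(delta) <= TIE_ATOL:
            p.verdict = "draw"
        elif p.kind == 1:
            p.verdict = "correct" if delta < 0 else "false"
        elif p.kind == 2:
            p.verdict = "correct" if delta > 0 else "false"
        else:
            raise ValueError(f"unknown prediction type {p.kind}")
        if p.verdict == "correct":
            n_correct += 1
        elif p.verdict == "false":
            n_false += 1
        else:
            n_draw += 1
    return ScoreSummary(n_correct, n_false, n_draw)


def binomial_p(n_correct: int, n_false: int) -> float:
    """One-tailed exact binomial p-value for ``n_correct`` successes.

    Upper-tail probability ``P(X >= n_correct)`` for ``X ~ Binomial(n, 1/2)``
    with ``n = n_correct + n_false`` (draws excluded), computed by exact
    rational summation.
    """
    if n_correct < 0 or n_false < 0:
        raise ValueError("counts must be non-negative")
    n = n_correct + n_false
    if n < 1:
        raise ValueError("at least one scored prediction required")
    total = Fraction(sum(comb(n, k) for k in range(n_correct, n + 1)), 2 ** n)
    return float(total)
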