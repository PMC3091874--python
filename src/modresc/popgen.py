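"""Deterministic cytotype-frequency recursions for CI infection dynamics.

An infinite panmictic host population with non-overlapping generations,
equal sex ratios and no fecundity differences is tracked as a frequency
vector over *cytotypes* (infection states, i.e. sets of carried strains).
Each generation:

1. mothers and fathers pair at random (cytotype frequencies multiply);
2. the zygote survives with probability ``s(father cytotype, mother
   cytotype)`` -- CI acts as embryonic mortality determined by the parental
   cytotypes only, the embryo's own infection is irrelevant;
3. surviving offspring inherit strains maternally, each strain transmitted
   independently with its per-strain probability ``t`` (a double infection
   is co-transmitted with probability ``t_A * t_B``);
4. frequencies are renormalized.

Survival matrices can be supplied explicitly or derived from a mechanism
model: under lock-key, survival is the matched-lock fraction; under the
goalkeeper model each factor kills independently with probability equal to
the (clamped, [0, 1]-bounded) mod-resc excess, so survival is the product
``prod_f (1 - min(1, max(0, mod_f - resc_f)))``.

Two standard experiments are provided: persistence of the double infection
of two unidirectionally incompatible strains (:func:`run`), and invasion of
a mutant strain into a resident-infected population without double
infections (:func:`invasion_outcome`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import Cross, HostBackground, Infection, Strain, ci_level_lockkey, \
    mod_vector, resc_vector

__all__ = [
    "ExtinctionError",
    "offspring_distribution",
    "transmission_matrix",
    "survival_goalkeeper_linear",
    "survival_matrix",
    "step",
    "run",
    "Trajectory",
    "invasion_outcome",
    "double_infection_cytotypes",
]


class ExtinctionError(RuntimeError):
    """Raised when total offspring production is zero."""


def double_infection_cytotypes(a: Strain, b: Strain) -> tuple:
    """The four cytotypes of the two-strain double-infection model:
    uninfected, A, B, AB (as frozensets of strains)."""
    return (frozenset(), frozenset([a]), frozenset([b]), frozenset([a, b]))


def offspring_distribution(mother: frozenset, t: Mapping[str, float]) -> dict:
    """Offspring cytotype distribution for one mother cytotype.

    Each carried strain is transmitted independently with probability
    ``t[strain.id]``; an AB mother therefore produces AB with probability
    ``t_A * t_B``, A with ``t_A * (1 - t_B)``, and so on.
    """
    strains = sorted(mother, key=lambda s: s.id)
    for s in strains:
        if not 0 <= t[s.id] <= 1:
            raise ValueError(f"transmission probability out of range for {s.id}")
    out: dict = {}
    for kept in itertools.product((True, False), repeat=len(strains)):
        p = 1.0
        cyt = []
        for s, k in zip(strains, kept):
            p *= t[s.id] if k else 1.0 - t[s.id]
            if k:
                cyt.append(s)
        if p > 0.0:
            key = frozenset(cyt)
            out[key] = out.get(key, 0.0) + p
    return out


def transmission_matrix(cytotypes: Sequence[frozenset],
                        t: Mapping[str, float]) -> np.ndarray:
    """``T[m, c]``: probability that a mother of cytotype ``m`` produces an
    offspring of cytotype ``c``.  Offspring cytotypes outside ``cytotypes``
    must not occur (they cannot, when ``cytotypes`` is subset-closed)."""
    index = {c: i for i, c in enumerate(cytotypes)}
    T = np.zeros((len(cytotypes), len(cytotypes)))
    for m, cyt in enumerate(cytotypes):
        for child, p in offspring_distribution(cyt, t).items():
            T[m, index[child]] += p
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("offspring distributions must sum to 1")
    return T


def survival_goalkeeper_linear(mod: Sequence[float],
                               resc: Sequence[float]) -> float:
    """Goalkeeper embryonic survival with linear per-factor death.

    Factor quantities live on the [0, 1] scale; each factor independently
    kills with probability ``min(1, max(0, mod_f - resc_f))``.
    """
    s = 1.0
    for m, r in zip(mod, resc):
        s *= 1.0 - min(1.0, max(0.0, float(m) - float(r)))
    return s


def survival_matrix(cytotypes: Sequence[frozenset], model_family: str,
                    host: Optional[HostBackground] = None) -> np.ndarray:
    """``S[f, m]``: zygote survival for a father of cytotype ``f`` and a
    mother of cytotype ``m``, derived from a mechanism model.

    Goalkeeper/mistiming use the linear-death product rule; lock-key uses
    ``1 - level/100`` with the matched-lock-fraction level.
    """
    n = len(cytotypes)
    S = np.ones((n, n))
    for fi, father in enumerate(cytotypes):
        for mi, mother in enumerate(cytotypes):
            cross = Cross(paternal=Infection.of(*father),
                          maternal=Infection.of(*mother), host=host)
            if model_family in ("goalkeeper", "mistiming"):
                hb = host or HostBackground.zero(2)
                mod = mod_vector(cross.paternal, len(hb.h))
                resc = resc_vector(cross.maternal, hb)
                S[fi, mi] = survival_goalkeeper_linear(mod, resc)
            elif model_family == "lockkey":
                S[fi, mi] = 1.0 - ci_level_lockkey(cross) / 100.0
            else:
                raise ValueError(f"unknown model family {model_family!r}")
    return S


def step(freqs: np.ndarray, T: np.ndarray, S: np.ndarray) -> np.ndarray:
    """One generation of the recursion; returns normalized frequencies.

    With random mating, the weight of the (father f, mother m) pairing is
    ``freq_f * freq_m * S[f, m]``; surviving broods follow the maternal
    transmission distribution.
    """
    freqs = np.asarray(freqs, dtype=float)
    mother_weight = (freqs @ S) * freqs       # sum_f freq_f S[f, m] * freq_m
    offspring = mother_weight @ T
    total = offspring.sum()
    if total <= 0:
        raise ExtinctionError("zero total offspring production")
    return offspring / total


@dataclass
class Trajectory:
    """Generation-by-generation frequencies plus persistence flags."""

    cytotypes: tuple
    frequencies: np.ndarray  # shape (n_generations + 1, n_cytotypes)
    converged: bool
    persistent: dict  # cytotype -> bool (final frequency > threshold)

    @property
    def final(self) -> np.ndarray:
        return self.frequencies[-1]

    def final_frequency(self, cytotype: frozenset) -> float:
        return float(self.final[self.cytotypes.index(cytotype)])


def run(initial: Mapping[frozenset, float] | np.ndarray,
        cytotypes: Sequence[frozenset], T: np.ndarray, S: np.ndarray,
        max_gen: int = 10_000, tol: float = 1e-12,
        persistence_threshold: float = 1e-6) -> Trajectory:
    """Iterate the recursion to (near) equilibrium.

    Stops when the max absolute frequency change falls below ``tol`` or
    after ``max_gen`` generations (non-convergence is flagged, not raised).
    A cytotype is *persistent* iff its final frequency exceeds
    ``persistence_threshold``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    cytotypes = tuple(cytotypes)
    if isinstance(initial, Mapping):
        state = np.array([float(initial.get(c, 0.0)) for c in cytotypes])
    else:
        state = np.asarray(initial, dtype=float).copy()
    if state.min() < 0 or not np.isclose(state.sum(), 1.0, atol=1e-9):
        raise ValueError("initial frequencies must be non-negative and sum to 1")
    state = state / state.sum()
    traj = [state]
    converged = False
    for _ in range(max_gen):
        nxt = step(state, T, S)
        delta = float(np.abs(nxt - state).max())
        state = nxt
        traj.append(state)
        if delta < tol:
            converged = True
            break
    freqs = np.vstack(traj)
    persistent = {c: bool(state[i] > persistence_threshold)
                  for i, c in enumerate(cytotypes)}
    return Trajectory(cytotypes, freqs, converged, persistent)


def invasion_outcome(resident: Strain, mutant: Strain, model_family: str,
                     host: Optional[HostBackground] = None,
                     t: float = 0.95, intro_freq: float = 0.01,
                     max_gen: int = 10_000,
                     threshold: float = 1e-6) -> str:
    """Fate of a rare mutant strain in a resident-infected population.

    Double infections are excluded: cytotypes are uninfected / resident /
    mutant.  The resident population is first run to equilibrium, the mutant
    is then introduced at ``intro_freq``, and the long-run frequencies are
    classified as ``"mutant lost"``, ``"mutant fixes"`` (resident lost) or
    ``"coexistence"``.
    """
    cytotypes = (frozenset(), frozenset([resident]), frozenset([mutant]))
    tmap = {resident.id: t, mutant.id: t}
    T = transmission_matrix(cytotypes, tmap)
    S = survival_matrix(cytotypes, model_family, host)
    base = run({frozenset(): 0.05, frozenset([resident]): 0.95},
               cytotypes, T, S, max_gen=max_gen)
    start = base.final * (1.0 - intro_freq)
    start[cytotypes.index(frozenset([mutant]))] = intro_freq
    traj = run(start / start.sum(), cytotypes, T, S, max_gen=max_gen,
               persistence_threshold=threshold)
    mut = traj.final_frequency(frozenset([mutant]))
    res = traj.final_frequency(frozenset([resident]))
    if mut <= threshold:
        return "mutant lost"
    if res <= threshold:
        return "mutant fixes"
    return "coexistence"
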