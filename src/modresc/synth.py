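"""Ground-truth world generators and noisy synthetic crossing datasets.

A *world* is a set of strains with full mechanism parameters plus one host
background, reproducible from a seed.  Worlds are the testbed for the
fitting and prediction machinery: the induced compatibility matrix of a
generated world is explainable by construction (the generating parameters
are a witness), and noiseless crossing datasets generated from a world make
every type-1/2/3 CI-level prediction a theorem of the level function.

Goalkeeper worlds draw integer factor quantities (exact arithmetic
downstream); crossing datasets add Gaussian noise on the percent scale and
clip to [0, 100] (a censoring caveat at the boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Cross, HostBackground, Infection, Strain, ci_level_goalkeeper, \
    rescues
from .fitting import COMPATIBLE, INCOMPATIBLE, CompatibilityMatrix
from .levels import CrossRecord

__all__ = [
    "World",
    "random_goalkeeper_world",
    "random_lockkey_world",
    "induced_matrix",
    "synth_cross_dataset",
]


@dataclass(frozen=True)
class World:
    """Strains with full mechanism parameters plus one host background."""

    strains: tuple
    host: HostBackground
    family: str
    seed: Optional[int] = None

    def strain_map(self) -> dict:
        return {s.id: s for s in self.strains}

    def __post_init__(self):
        object.__setattr__(self, "strains", tuple(self.strains))


def random_goalkeeper_world(n: int, bound: int = 5,
                            seed: Optional[int] = None) -> World:
    """``n`` strains with integer factor quantities in ``[0, bound]^2`` and
    one host with integer contribution in ``[0, bound]^2``."""
    if n < 1:
        raise ValueError("need at least one strain")
    rng = np.random.default_rng(seed)
    strains = tuple(
        Strain(id=f"s{i + 1}", gk=tuple(int(q) for q in
                                        rng.integers(0, bound + 1, size=2)))
        for i in range(n))
    host = HostBackground(id="host", h=tuple(
        int(q) for q in rng.integers(0, bound + 1, size=2)))
    return World(strains, host, "goalkeeper", seed)


def random_lockkey_world(n: int, k: int = 4,
                         seed: Optional[int] = None) -> World:
    """``n`` strains with random lock sets over ``k`` factor types and keys
    covering locks (each non-lock key added with probability 1/2)."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 strains and k >= 1 factor types")
    rng = np.random.default_rng(seed)
    types = [str(t + 1) for t in range(k)]
    strains = []
    for i in range(n):
        locks = frozenset(t for t in types if rng.random() < 0.5)
        keys = locks | frozenset(t for t in types
                                 if t not in locks and rng.random() < 0.5)
        strains.append(Strain(id=f"s{i + 1}", locks=locks, keys=keys))
    return World(tuple(strains), HostBackground.zero(2), "lockkey", seed)


def induced_matrix(world: World) -> CompatibilityMatrix:
    """Fully known compatibility matrix of all mono-infection crosses."""
    labels = tuple(s.id for s in world.strains)
    cells = []
    for fem in world.strains:
        row = []
        for male in world.strains:
            ok = rescues(Infection.of(fem), Infection.of(male),
                         host=world.host, model_family=world.family)
            row.append(COMPATIBLE if ok else INCOMPATIBLE)
        cells.append(tuple(row))
    return CompatibilityMatrix(labels, tuple(cells))


def synth_cross_dataset(world: World, n_records: int = 30,
                        noise_sd: float = 5.0, seed: Optional[int] = None,
                        c: float = 10.0) -> list:
    """Noisy crossing dataset emulating literature CI-level records.

    Crosses are drawn among empty / single / double infections of the
    world's strains.  The observed corrected CI level is the goalkeeper
    model level plus Gaussian noise (sd in percentage points), clipped to
    [0, 100]; control mortality is drawn uniformly in [0, 5]% and the raw
    mortality is back-computed so the correction recovers the noisy level.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if world.family != "goalkeeper":
        raise ValueError("crossing datasets are generated from goalkeeper worlds")
    rng = np.random.default_rng(seed)
    strains = list(world.strains)
    records = []
    for _ in range(n_records):
        sizes = rng.integers(0, 3, size=2)  # 0..2 strains per side
        mat = rng.choice(len(strains), size=sizes[0], replace=False)
        pat = rng.choice(len(strains), size=sizes[1], replace=False)
        maternal = frozenset(strains[i].id for i in mat)
        paternal = frozenset(strains[i].id for i in pat)
        cross = Cross(paternal=Infection.of(*(strains[i] for i in pat)),
                      maternal=Infection.of(*(strains[i] for i in mat)),
                      host=world.host)
        level = ci_level_goalkeeper(cross, c=c)
        observed = float(np.clip(level + rng.normal(0.0, noise_sd)
                                 if noise_sd > 0 else level, 0.0, 100.0))
        control = float(rng.uniform(0.0, 5.0))
        raw = control + observed * (100.0 - control) / 100.0
        records.append(CrossRecord(maternal=maternal, paternal=paternal,
                                   raw_mortality=raw,
                                   control_mortality=control))
    return records
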