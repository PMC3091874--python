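"""Packaged fixtures: the six-strain compatibility relationship.

The six *Wolbachia* strains wTei, wRi, wHa, wNo, wMel and wCer2 (all
studied in *Drosophila simulans* hosts, compatibility thresholded at a
corrected CI level of 20%) stand in the following relationship:

* wTei rescues wRi but not vice versa; wRi rescues wMel but not vice versa;
* wMel and wTei are bidirectionally incompatible;
* wHa, wNo and wCer2 are bidirectionally incompatible with every tested
  partner.

wCer2's factor repertoire beyond its first lock/key pair is unreported in
the published five-factor witness, and that witness forces every wCer2
completion to be rescued by wTei females (wTei's keys cover any lock set a
wCer2 completion may carry).  Since wCer2 was observed incompatible in
every tested cross, the cross (wTei female x wCer2 male) is the one that
cannot have been tested; it is encoded unknown and every other entry is
known.
"""

from __future__ import annotations

from .core import HostBackground, Strain
from .fitting import CompatibilityMatrix, LockKeyAssignment

__all__ = [
    "SIX_STRAINS",
    "six_strain_fixture",
    "table2_assignment",
    "unidirectional_goalkeeper_pair",
    "unidirectional_lockkey_pair",
]

SIX_STRAINS = ("wTei", "wRi", "wHa", "wNo", "wMel", "wCer2")

# rows = maternal (female), columns = paternal (male), order as SIX_STRAINS
_CELLS = (
    #        wTei wRi wHa wNo wMel wCer2   (male)
    ("C", "C", "I", "I", "I", "?"),   # wTei female
    ("I", "C", "I", "I", "C", "I"),   # wRi female
    ("I", "I", "C", "I", "I", "I"),   # wHa female
    ("I", "I", "I", "C", "I", "I"),   # wNo female
    ("I", "I", "I", "I", "C", "I"),   # wMel female
    ("I", "I", "I", "I", "I", "C"),   # wCer2 female
)


def six_strain_fixture() -> CompatibilityMatrix:
    """The six-strain compatibility matrix (rows maternal, columns paternal)."""
    return CompatibilityMatrix(SIX_STRAINS, _CELLS)


def table2_assignment() -> LockKeyAssignment:
    """The published five-factor lock/key witness for the six strains.

    wCer2's repertoire beyond the lock/key pair of factor 1 is unreported;
    the unique completion consistent with the known matrix entries (locks
    and keys {1, 3}) is used.
    """
    locks = {
        "wTei": {"1", "2"},
        "wRi": {"2", "3"},
        "wHa": {"1", "4"},
        "wNo": {"1", "5"},
        "wMel": {"3", "4"},
        "wCer2": {"1", "3"},
    }
    keys = {
        "wTei": {"1", "2", "3"},
        "wRi": {"2", "3", "4"},
        "wHa": {"1", "4"},
        "wNo": {"1", "5"},
        "wMel": {"3", "4"},
        "wCer2": {"1", "3"},
    }
    return LockKeyAssignment(locks, keys)


def unidirectional_goalkeeper_pair():
    """Two goalkeeper strains where B rescues A but not vice versa.

    Factor quantities are on the [0, 1] scale used by the population
    recursions; the host contributes nothing, so the double infection AB in
    a male can only be rescued by an AB female (the D' regime).
    Returns ``(strain_a, strain_b, host)``.
    """
    a = Strain(id="A", gk=(0.5, 0.0))
    b = Strain(id="B", gk=(0.5, 0.5))
    return a, b, HostBackground.zero(2)


def unidirectional_lockkey_pair():
    """Two lock-key strains where B rescues A but not vice versa.

    B carries the key to A's lock, so a B female also rescues the AB double
    infection in a male (the D'' regime).  Returns ``(strain_a, strain_b)``.
    """
    a = Strain(id="A", locks={"1"}, keys={"1"})
    b = Strain(id="B", locks={"2"}, keys={"1", "2"})
    return a, b
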