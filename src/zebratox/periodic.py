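"""Periodic-table positions and bond-length data.

Every atom entering the views representation is encoded by its (period,
group) position on the periodic table under IUPAC 1-18 group numbering.
The mapping is *total* over main-group and transition elements H-Rn and
raises for anything else (f-block included): a silent guess would corrupt
the representation.
"""

from __future__ import annotations

from rdkit import Chem

_PT = Chem.GetPeriodicTable()

# Noble-gas atomic numbers closing each period.
_PERIOD_ENDS = (2, 10, 18, 36, 54, 86, 118)

_MAX_Z = 86  # Rn; beyond this the spec of the representation ends

# f-block (lanthanides/actinides) has no 1-18 group assignment here.
_F_BLOCK = set(range(57, 72)) | set(range(89, 104))


class UnknownElementError(ValueError):
    """Element symbol outside the supported H-Rn main/transition block."""


def atomic_number(symbol: str) -> int:
    sym = symbol.strip()
    if not sym:
        raise UnknownElementError("empty element symbol")
    sym = sym[0].upper() + sym[1:].lower()
    try:
        z = _PT.GetAtomicNumber(sym)
    except Exception as exc:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from exc
    if z <= 0:
        raise UnknownElementError(f"unknown element symbol {symbol!r}")
    return z


def periodic_position(symbol: str) -> tuple[int, int]:
    """Map an element symbol to its (period, group), IUPAC 1-18 numbering.

    >>> periodic_position("C")
    (2, 14)
    """
    z = atomic_number(symbol)
    if z > _MAX_Z:
        raise UnknownElementError(
            f"element {symbol!r} (Z={z}) beyond Rn is not supported"
        )
    if z in _F_BLOCK:
        raise UnknownElementError(
            f"f-block element {symbol!r} has no IUPAC 1-18 group here"
        )
    period = next(i + 1 for i, end in enumerate(_PERIOD_ENDS) if z <= end)
    start = 0 if period == 1 else _PERIOD_ENDS[period - 2]
    offset = z - start  # 1-based position within the period
    if period == 1:
        group = 1 if offset == 1 else 18
    elif period in (2, 3):
        group = offset if offset <= 2 else offset + 10
    elif period in (4, 5):
        group = offset
    else:  # 6, 7 with the 14 f-block members excised
        group = offset if offset <= 2 else offset - 14
    return period, group


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Angstrom (used for distance-based bond inference)."""
    r = _PT.GetRcovalent(atomic_number(symbol))
    if r <= 0:
        raise UnknownElementError(f"no covalent radius for {symbol!r}")
    return float(r)


#: Idealized single-bond lengths (Angstrom) for fixture/synthetic geometry.
#: Unlisted pairs fall back to the sum of covalent radii.
BOND_LENGTHS: dict[frozenset[str], float] = {
    frozenset({"C"}): 1.54,
    frozenset({"C", "H"}): 1.09,
    frozenset({"C", "F"}): 1.35,
    frozenset({"C", "Cl"}): 1.77,
    frozenset({"C", "O"}): 1.43,
    frozenset({"C", "N"}): 1.47,
    frozenset({"C", "S"}): 1.82,
    frozenset({"O", "H"}): 0.96,
    frozenset({"N", "H"}): 1.01,
    frozenset({"S", "H"}): 1.34,
    frozenset({"N", "O"}): 1.40,
}


def bond_length(a: str, b: str) -> float:
    key = frozenset({a, b})
    if key in BOND_LENGTHS:
        return BOND_LENGTHS[key]
    return covalent_radius(a) + covalent_radius(b)
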