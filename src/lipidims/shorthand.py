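"""Lipid shorthand parsing and monoisotopic mass computation.

Handles phosphatidylethanolamine (PE) species at species level
(``PE 34:1``, ``PE O-38:5``, ``PE P-38:5``) and molecular-species level
(``PE O-18:0_20:4``), following LIPID MAPS-style shorthand. For
1-O-alkenyl ("P-") species the Delta-1 vinyl-ether double bond is *not*
counted in the shorthand DB number, so ``PE P-n:d`` has the same
elemental formula as ``PE O-n:(d+1)``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Linkage",
    "LipidSpecies",
    "ElementalFormula",
    "ShorthandError",
    "parse_shorthand",
    "elemental_formula",
    "mz_deprotonated",
    "MASS_ELECTRON",
    "MASS_PROTON",
]


class ShorthandError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed or resolved."""


class Linkage(str, enum.Enum):
    """sn-1 linkage type of a glycerophospholipid."""

    ACYL = "acyl"
    ALKYL = "alkyl"  # "O-" prefix, saturated ether
    ALKENYL = "alkenyl"  # "P-" prefix, Delta-1 vinyl ether (plasmalogen)

    @property
    def prefix(self) -> str:
        return {"acyl": "", "alkyl": "O-", "alkenyl": "P-"}[self.value]


_PREFIX_TO_LINKAGE = {"": Linkage.ACYL, "O-": Linkage.ALKYL, "P-": Linkage.ALKENYL}

# Monoisotopic atomic masses (NIST/CODATA), Da.
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}
MASS_ELECTRON = 0.000548579909
MASS_PROTON = ATOMIC_MASS["H"] - MASS_ELECTRON


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed identity of a lipid shorthand name.

    Parameters
    ----------
    lipid_class : str
        Head-group class token; only ``"PE"`` is supported.
    linkage : Linkage
        sn-1 linkage (acyl, alkyl or alkenyl).
    cc : int
        Cumulative side-chain carbons.
    db : int
        Cumulative side-chain double bonds as written in the shorthand.
        For alkenyl species the Delta-1 vinyl-ether bond is excluded.
    molecular_chains : tuple of (int, int), optional
        Per-chain (carbons, double_bonds) when the name was given at
        molecular-species level.
    """

    lipid_class: str
    linkage: Linkage
    cc: int
    db: int
    molecular_chains: Optional[tuple[tuple[int, int], ...]] = field(default=None)

    def __post_init__(self) -> None:
        if self.lipid_class != "PE":
            raise ShorthandError(f"unknown lipid class {self.lipid_class!r}")
        if self.cc < 2:
            raise ShorthandError(f"cumulative carbons must be >= 2, got {self.cc}")
        if self.db < 0:
            raise ShorthandError(f"double bond count must be >= 0, got {self.db}")
        if self.molecular_chains is not None:
            cc = sum(c for c, _ in self.molecular_chains)
            db = sum(d for _, d in self.molecular_chains)
            if cc != self.cc or db != self.db:
                raise ShorthandError(
                    f"molecular chains {self.molecular_chains} sum to {cc}:{db}, "
                    f"inconsistent with species level {self.cc}:{self.db}"
                )

    @property
    def species_name(self) -> str:
        """Canonical species-level rendering (chains collapsed)."""
        return f"{self.lipid_class} {self.linkage.prefix}{self.cc}:{self.db}"

    @property
    def name(self) -> str:
        """Canonical rendering at the level the species was defined."""
        if self.molecular_chains is None:
            return self.species_name
        chains = "_".join(f"{c}:{d}" for c, d in self.molecular_chains)
        return f"{self.lipid_class} {self.linkage.prefix}{chains}"

    def at_species_level(self) -> "LipidSpecies":
        """Drop molecular-chain detail, keeping the species identity."""
        if self.molecular_chains is None:
            return self
        return LipidSpecies(self.lipid_class, self.linkage, self.cc, self.db)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts of a neutral molecule (C, H, N, O, P)."""

    c: int
    h: int
    n: int
    o: int
    p: int

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "p"):
            if getattr(self, name) < 0:
                raise ShorthandError(f"negative element count for {name.upper()}")

    @property
    def monoisotopic_mass(self) -> float:
        """Monoisotopic neutral mass in Da."""
        return (
            self.c * ATOMIC_MASS["C"]
            + self.h * ATOMIC_MASS["H"]
            + self.n * ATOMIC_MASS["N"]
            + self.o * ATOMIC_MASS["O"]
            + self.p * ATOMIC_MASS["P"]
        )

    def __str__(self) -> str:
        parts = []
        for sym, count in (("C", self.c), ("H", self.h), ("N", self.n),
                           ("O", self.o), ("P", self.p)):
            if count == 1:
                parts.append(sym)
            elif count > 1:
                parts.append(f"{sym}{count}")
        return "".join(parts)


_CHAIN = r"(\d+):(\d+)"
_SPECIES_RE = re.compile(
    rf"^\s*(?P<cls>[A-Za-z]+)\s+(?P<pfx>O-|P-)?(?P<c1>\d+):(?P<d1>\d+)"
    rf"(?:_(?P<c2>\d+):(?P<d2>\d+))?\s*$"
)


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse a lipid shorthand name into a :class:`LipidSpecies`.

    Accepts species-level names (``PE 34:1``, ``PE O-38:5``,
    ``PE P-38:5``) and two-chain molecular names
    (``PE P-18:0_20:4``). Whitespace around the class token is
    tolerated.

    Raises
    ------
    ShorthandError
        If the name does not match the grammar or uses an unknown
        class token.
    """
    if not isinstance(name, str):
        raise ShorthandError(f"expected a string, got {type(name).__name__}")
    m = _SPECIES_RE.match(name)
    if m is None:
        raise ShorthandError(f"malformed lipid shorthand name: {name!r}")
    cls = m.group("cls")
    if cls != "PE":
        raise ShorthandError(f"unknown lipid class token {cls!r} in {name!r}")
    linkage = _PREFIX_TO_LINKAGE[m.group("pfx") or ""]
    c1, d1 = int(m.group("c1")), int(m.group("d1"))
    chains: Optional[tuple[tuple[int, int], ...]] = None
    if m.group("c2") is not None:
        c2, d2 = int(m.group("c2")), int(m.group("d2"))
        chains = ((c1, d1), (c2, d2))
        cc, db = c1 + c2, d1 + d2
    else:
        cc, db = c1, d1
    try:
        return LipidSpecies(cls, linkage, cc, db, chains)
    except ShorthandError as exc:
        raise ShorthandError(f"invalid species {name!r}: {exc}") from exc


def elemental_formula(species: LipidSpecies) -> ElementalFormula:
    """Neutral elemental formula of a PE species.

    Diacyl ``PE cc:db`` is C(cc+5) H(2cc-2db+10) N O8 P; the alkyl
    ether replaces one ester oxygen (−O +2H); the alkenyl ether
    additionally carries the uncounted Delta-1 double bond (−2H from
    the alkyl formula).
    """
    cc, db = species.cc, species.db
    if species.linkage is Linkage.ACYL:
        h = 2 * cc - 2 * db + 10
        o = 8
    elif species.linkage is Linkage.ALKYL:
        h = 2 * cc - 2 * db + 12
        o = 7
    else:  # alkenyl: same as alkyl with one extra (uncounted) DB
        h = 2 * cc - 2 * db + 10
        o = 7
    if h < 2:
        raise ShorthandError(
            f"{species.name}: {cc} carbons cannot host {db} double bonds"
        )
    return ElementalFormula(c=cc + 5, h=h, n=1, o=o, p=1)


def mz_deprotonated(species: LipidSpecies) -> float:
    """Monoisotopic m/z of the [M-H]- ion (charge 1)."""
    return elemental_formula(species).monoisotopic_mass - MASS_PROTON
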