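"""Pinned isotope masses and abundances for exact-mass arithmetic.

The table is a fixed transcription of the NIST/CODATA atomic mass and
isotopic composition compilation (AME2020 masses, 2021 isotopic
abundances).  Shipping the numbers inside the package keeps every mass,
isotope envelope and ppm error in the test suite bit-reproducible across
machines; an external YAML table can override it for sensitivity work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: CODATA 2018 electron mass, Da
ELECTRON_MASS = 0.000548579909065
#: CODATA 2018 proton mass, Da
PROTON_MASS = 1.007276466621

# symbol -> list of (exact mass [Da], natural abundance [fraction]),
# sorted by mass.  Monoabundant elements carry a single entry.
_ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503224, 0.999885), (2.01410177811, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483521, 0.0107)],
    "N": [(14.00307400446, 0.99636), (15.00010889894, 0.00364)],
    "O": [
        (15.99491461960, 0.99757),
        (16.99913175664, 0.00038),
        (17.99915961284, 0.00205),
    ],
    "F": [(18.99840316288, 1.0)],
    "Na": [(22.98976928199, 1.0)],
    "Mg": [
        (23.98504169700, 0.7899),
        (24.98583697600, 0.1000),
        (25.98259296800, 0.1101),
    ],
    "P": [(30.97376199857, 1.0)],
    "S": [
        (31.97207117443, 0.9499),
        (32.97145890985, 0.0075),
        (33.96786700471, 0.0425),
        (35.96708071213, 0.0001),
    ],
    "Cl": [(34.96885268237, 0.7576), (36.96590260228, 0.2424)],
    "K": [
        (38.96370648661, 0.932581),
        (39.96399816600, 0.000117),
        (40.96182525796, 0.067302),
    ],
    "Br": [(78.91833760100, 0.5069), (80.91628969600, 0.4931)],
    "I": [(126.90447185900, 1.0)],
    "Si": [
        (27.97692653442, 0.92223),
        (28.97649466434, 0.04685),
        (29.97377013600, 0.03092),
    ],
}


class UnknownElementError(KeyError):
    """Raised when a formula references an element missing from the table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - message text
        return (
            f"element {self.symbol!r} is not in the isotope table; "
            "supply a custom ElementTable with its isotopes"
        )


@dataclass(frozen=True)
class ElementTable:
    """Per-element isotope masses/abundances plus particle masses.

    Invariants (checked at construction): abundances of each element sum
    to 1 within 1e-6 and isotope masses are strictly increasing.
    """

    isotopes: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: dict(_ISOTOPES)
    )
    electron_mass: float = ELECTRON_MASS
    proton_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        for sym, rows in self.isotopes.items():
            total = sum(a for _, a in rows)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"{sym}: isotope abundances sum to {total:.8f}, not 1"
                )
            masses = [m for m, _ in rows]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"{sym}: isotope masses not strictly increasing")

    def __getitem__(self, symbol: str) -> list[tuple[float, float]]:
        try:
            return self.isotopes[symbol]
        except KeyError:
            raise UnknownElementError(symbol) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.isotopes

    def principal_isotope(self, symbol: str) -> tuple[float, float]:
        """Most abundant isotope — the monoisotopic-mass convention."""
        return max(self[symbol], key=lambda row: row[1])

    def principal_mass(self, symbol: str) -> float:
        return self.principal_isotope(symbol)[0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ElementTable":
        """Load an override table.

        Expected layout::

            electron_mass: 0.000548579909
            proton_mass: 1.007276466621
            isotopes:
              C:
                - [12.0, 0.9893]
                - [13.00335483521, 0.0107]
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        isotopes = {
            sym: [(float(m), float(a)) for m, a in rows]
            for sym, rows in raw["isotopes"].items()
        }
        return cls(
            isotopes=isotopes,
            electron_mass=float(raw.get("electron_mass", ELECTRON_MASS)),
            proton_mass=float(raw.get("proton_mass", PROTON_MASS)),
        )


#: Module-level default table used throughout the package.
DEFAULT_TABLE = ElementTable()
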