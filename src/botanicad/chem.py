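"""Exact-mass chemistry primitives.

Molecular formulas in Hill notation, electrospray adduct arithmetic
(electron mass included — 0.55 mDa matters at sub-5-ppm accuracy),
ring-and-double-bond equivalents, and nucleon-aggregated isotope
envelopes (A, A+1, A+2, ...) computed by exact convolution over the
pinned element table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .elements import DEFAULT_TABLE, ElementTable, UnknownElementError

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "IsotopePattern",
    "monoisotopic_mass",
    "dbe",
    "adduct_mz",
    "isotope_pattern",
    "COMMON_ADDUCTS",
    "adduct_by_name",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element → count map, e.g. rutin ``C27H30O16``.

    Counts may be negative only in adduct deltas; a valid standalone
    formula has nonnegative counts and at least one positive count.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: dict[str, int] | tuple[tuple[str, int], ...]):
        if isinstance(counts, tuple):
            counts = dict(counts)
        clean = {sym: int(n) for sym, n in counts.items() if n != 0}
        object.__setattr__(self, "counts", tuple(sorted(clean.items())))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-notation string such as ``"C27H30O16"``."""
        text = text.strip()
        if not text:
            raise ValueError("empty formula string")
        pos = 0
        counts: dict[str, int] = {}
        for m in _TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        return cls(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, symbol: str) -> int:
        return dict(self.counts).get(symbol, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def total_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def is_valid(self) -> bool:
        """Nonnegative counts with at least one atom."""
        return bool(self.counts) and all(n > 0 for _, n in self.counts)

    def hill(self) -> str:
        """Canonical Hill-order rendering (C, H, then alphabetical)."""
        d = self.as_dict()
        parts: list[str] = []
        if "C" in d:
            order = ["C"] + (["H"] if "H" in d else [])
            order += sorted(k for k in d if k not in ("C", "H"))
        else:
            order = sorted(d)
        for sym in order:
            n = d[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        d = self.as_dict()
        for sym, n in other.counts:
            d[sym] = d.get(sym, 0) + n
        return MolecularFormula(d)

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({sym: n * k for sym, n in self.counts})

    __rmul__ = __mul__


@dataclass(frozen=True)
class AdductSpec:
    """An electrospray ion type, e.g. ``[M+NH4]+`` or ``[2M+H]+``.

    ``n`` copies of the neutral M, plus the atoms in ``delta`` (counts
    may be negative, as in ``[M-H]-``), carrying charge ``z``.
    """

    name: str
    delta: MolecularFormula
    charge: int
    n: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"{self.name}: adduct charge must be nonzero")
        if self.n < 1:
            raise ValueError(f"{self.name}: multiplier n must be >= 1")

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"

    def delta_mass(self, table: ElementTable = DEFAULT_TABLE) -> float:
        return sum(table.principal_mass(sym) * k for sym, k in self.delta.counts)

    def mz(self, neutral_mass: float, table: ElementTable = DEFAULT_TABLE) -> float:
        return adduct_mz(neutral_mass, self, table)

    def neutral_mass(self, mz: float, table: ElementTable = DEFAULT_TABLE) -> float:
        """Invert :func:`adduct_mz`."""
        total = mz * abs(self.charge)
        return (total + self.charge * table.electron_mass - self.delta_mass(table)) / self.n


def _adduct(name: str, delta: str | dict[str, int], z: int, n: int = 1) -> AdductSpec:
    if isinstance(delta, str):
        d = MolecularFormula.parse(delta) if delta else MolecularFormula({})
    else:
        d = MolecularFormula(delta)
    return AdductSpec(name=name, delta=d, charge=z, n=n)


#: The adduct vocabulary seen in Ginkgo-type ESI data: protonation,
#: ammonium and sodium in positive mode, deprotonation and formate in
#: negative mode, and doubly charged ions for the flavonoid dimers.
COMMON_ADDUCTS: tuple[AdductSpec, ...] = (
    _adduct("[M+H]+", {"H": 1}, +1),
    _adduct("[M+NH4]+", {"N": 1, "H": 4}, +1),
    _adduct("[M+Na]+", {"Na": 1}, +1),
    _adduct("[M+2H]2+", {"H": 2}, +2),
    _adduct("[M-H]-", {"H": -1}, -1),
    _adduct("[M+HCOO]-", {"C": 1, "H": 1, "O": 2}, -1),
    _adduct("[M-2H]2-", {"H": -2}, -2),
)

_BY_NAME = {a.name: a for a in COMMON_ADDUCTS}
# Table-style aliases
_BY_NAME["[M+Formate]-"] = _BY_NAME["[M+HCOO]-"]
_BY_NAME["[M−H]−"] = _BY_NAME["[M-H]-"]


def adduct_by_name(name: str) -> AdductSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(_BY_NAME)}") from None


def monoisotopic_mass(
    formula: MolecularFormula, table: ElementTable = DEFAULT_TABLE
) -> float:
    """Sum of principal-isotope masses; empty formula gives 0.0.

    Raises :class:`UnknownElementError` naming any symbol absent from
    the element table.
    """
    total = 0.0
    for sym, n in formula.counts:
        total += table.principal_mass(sym) * n
    return total


# Valence classes for the DBE formula: halogens count like H, P like N,
# divalent O/S contribute nothing.
_H_LIKE = frozenset({"H", "F", "Cl", "Br", "I"})
_N_LIKE = frozenset({"N", "P"})
_ZERO = frozenset({"O", "S"})


def dbe(formula: MolecularFormula) -> float:
    """Ring-and-double-bond equivalents.

    DBE = nC - (nH + nHalogen)/2 + (nN + nP)/2 + 1.  Elements outside
    the CHNOSP/halogen valence table contribute 0 with a warning.
    """
    c = h = n = 0
    for sym, k in formula.counts:
        if sym == "C":
            c += k
        elif sym in _H_LIKE:
            h += k
        elif sym in _N_LIKE:
            n += k
        elif sym not in _ZERO:
            warnings.warn(
                f"element {sym} outside the DBE valence table contributes 0",
                stacklevel=2,
            )
    return c - h / 2.0 + n / 2.0 + 1.0


def adduct_mz(
    neutral_mass: float,
    adduct: AdductSpec,
    table: ElementTable = DEFAULT_TABLE,
) -> float:
    """m/z of the ion ``[nM + delta]^z`` with electron-mass correction.

    m/z = (n*M + mass(delta) - z*m_e) / |z|.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    z = adduct.charge
    return (
        adduct.n * neutral_mass
        + adduct.delta_mass(table)
        - z * table.electron_mass
    ) / abs(z)


@dataclass(frozen=True)
class IsotopePattern:
    """A nucleon-aggregated isotope envelope.

    ``masses`` are neutral masses (or m/z when computed in a charge
    context), strictly increasing; ``abundances`` are normalized so the
    base peak is exactly 100; ``offsets`` are nucleon offsets from the
    monoisotopic (A) peak.
    """

    masses: tuple[float, ...]
    abundances: tuple[float, ...]
    offsets: tuple[int, ...]
    charge: int = 0

    def __post_init__(self) -> None:
        if abs(max(self.abundances) - 100.0) > 1e-9:
            raise ValueError("base peak abundance must be exactly 100")
        if any(b <= a for a, b in zip(self.masses, self.masses[1:])):
            raise ValueError("pattern masses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.masses)

    def abundance_at(self, offset: int) -> float:
        for o, a in zip(self.offsets, self.abundances):
            if o == offset:
                return a
        return 0.0

    def label(self, i: int) -> str:
        o = self.offsets[i]
        return "A" if o == 0 else f"A+{o}" if o > 0 else f"A{o}"


def _single_atom_dist(
    sym: str, table: ElementTable
) -> list[tuple[int, float, float]]:
    """(nucleon offset from principal isotope, probability, mass)."""
    rows = table[sym]
    pmass, _ = table.principal_isotope(sym)
    return [(round(m - pmass), a, m) for m, a in rows]


def _convolve(
    a: dict[int, tuple[float, float]],
    b: dict[int, tuple[float, float]],
    prune: float,
) -> dict[int, tuple[float, float]]:
    """Convolve offset → (prob, prob-weighted mass sum) maps."""
    out: dict[int, tuple[float, float]] = {}
    for o1, (p1, s1) in a.items():
        for o2, (p2, s2) in b.items():
            p = p1 * p2
            if p < prune:
                continue
            s = p2 * s1 + p1 * s2
            o = o1 + o2
            if o in out:
                q, t = out[o]
                out[o] = (q + p, t + s)
            else:
                out[o] = (p, s)
    return out


def _element_power(
    sym: str, count: int, table: ElementTable, prune: float
) -> dict[int, tuple[float, float]]:
    """Distribution of ``count`` atoms of one element (square-and-multiply)."""
    base = {o: (p, p * m) for o, p, m in _single_atom_dist(sym, table)}
    result: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    acc = base
    k = count
    while k:
        if k & 1:
            result = _convolve(result, acc, prune)
        k >>= 1
        if k:
            acc = _convolve(acc, acc, prune)
    return result


def isotope_pattern(
    formula: MolecularFormula,
    prune_abundance: float = 1e-4,
    charge_context: AdductSpec | None = None,
    table: ElementTable = DEFAULT_TABLE,
) -> IsotopePattern:
    """Exact isotope envelope at nucleon (A, A+1, A+2, ...) resolution.

    Multinomial convolution over the element isotope distributions,
    aggregated by nucleon offset with abundance-weighted centroid
    masses (aggregation is exact: nucleon offsets are additive, so the
    centroid of a convolution equals the convolution of centroids).
    Peaks below ``prune_abundance`` of the base peak are dropped and the
    base peak is normalized to 100.

    With ``charge_context`` the envelope is computed for the full ion
    formula (n·M + delta) and masses are reported as m/z.
    """
    if not formula:
        raise ValueError("cannot compute an isotope pattern for an empty formula")
    if not (0 < prune_abundance < 1):
        raise ValueError("prune_abundance must be in (0, 1)")

    target = formula
    z = 0
    if charge_context is not None:
        target = formula * charge_context.n + charge_context.delta
        if not target.is_valid():
            raise ValueError(
                f"adduct {charge_context.name} removes atoms the formula lacks"
            )
        z = charge_context.charge

    # Hard internal prune well below the reported cutoff so the final
    # envelope is unaffected by intermediate truncation.
    internal_prune = min(prune_abundance, 1e-4) * 1e-6
    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for sym, count in target.counts:
        if sym not in table:
            raise UnknownElementError(sym)
        dist = _convolve(dist, _element_power(sym, count, table, internal_prune),
                         internal_prune)

    peaks = sorted((o, p, s / p) for o, (p, s) in dist.items() if p > 0)
    pmax = max(p for _, p, _ in peaks)
    kept = [(o, p, m) for o, p, m in peaks if p >= prune_abundance * pmax]

    masses: list[float] = []
    for o, p, m in kept:
        if z:
            masses.append((m - z * table.electron_mass) / abs(z))
        else:
            masses.append(m)
    return IsotopePattern(
        masses=tuple(masses),
        abundances=tuple(100.0 * (p / pmax) for _, p, _ in kept),
        offsets=tuple(o for o, _, _ in kept),
        charge=z,
    )
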