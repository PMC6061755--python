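"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a different route than the package
(direct polynomial expansion instead of binned convolution, exhaustive
nested loops instead of pruned search, dense-grid geometry instead of
sampled traces) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from botanicad.chem import MolecularFormula, dbe
from botanicad.elements import DEFAULT_TABLE, ElementTable


def fine_structure_pattern(
    formula: MolecularFormula,
    table: ElementTable = DEFAULT_TABLE,
) -> list[tuple[int, float, float]]:
    """Isotope envelope by direct polynomial expansion.

    Multiplies out the per-atom isotope polynomial keeping every
    fine-structure term (exact mass, probability), then aggregates to
    nucleon resolution at the very end.  Exponential in principle;
    fine for <= 40 atoms.  Returns (nucleon offset, probability,
    centroid mass) sorted by offset.
    """
    # fine-structure terms: (nucleon offset, exact mass rounded to
    # 1e-9 Da to merge identical lattice points) -> probability
    terms: dict[tuple[int, float], float] = {(0, 0.0): 1.0}
    for sym, count in formula.counts:
        rows = table[sym]
        pmass, _ = table.principal_isotope(sym)
        for _ in range(count):
            new: dict[tuple[int, float], float] = {}
            for (off, mass), prob in terms.items():
                for m_iso, a in rows:
                    key = (off + round(m_iso - pmass), round(mass + m_iso, 9))
                    new[key] = new.get(key, 0.0) + prob * a
            terms = new

    agg: dict[int, tuple[float, float]] = {}
    for (off, mass), prob in terms.items():
        p, s = agg.get(off, (0.0, 0.0))
        agg[off] = (p + prob, s + prob * mass)
    return sorted((off, p, s / p) for off, (p, s) in agg.items())


def brute_force_candidates(
    mz: float,
    adducts,
    bounds: dict[str, tuple[int, int]],
    tol_ppm: float,
    nitrogen_rule: bool = True,
    table: ElementTable = DEFAULT_TABLE,
) -> set[tuple[str, str]]:
    """Exhaustive nested loops over every element count (including H).

    Returns {(hill string, adduct name)} applying the same chemical
    filters as the package: DBE >= 0 and integer, H <= 2C + N + 2,
    and the nitrogen parity rule for singly charged ions.
    """
    import itertools

    syms = list(bounds)
    ranges = [range(lo, hi + 1) for lo, hi in bounds.values()]
    out: set[tuple[str, str]] = set()
    for adduct in adducts:
        tol_da = mz * tol_ppm * 1e-6
        lo_m = adduct.neutral_mass(mz - tol_da, table)
        hi_m = adduct.neutral_mass(mz + tol_da, table)
        for counts in itertools.product(*ranges):
            if sum(counts) == 0:
                continue
            mass = sum(table.principal_mass(s) * c
                       for s, c in zip(syms, counts))
            if not (lo_m <= mass <= hi_m):
                continue
            f = MolecularFormula(dict(zip(syms, counts)))
            d = f.as_dict()
            c, h, n = d.get("C", 0), d.get("H", 0), d.get("N", 0)
            if h > 2 * c + n + 2:
                continue
            r = dbe(f)
            if r < 0 or abs(r - round(r)) > 1e-9:
                continue
            if nitrogen_rule and abs(adduct.charge) == 1:
                nominal = sum(round(table.principal_mass(s)) * cc
                              for s, cc in d.items())
                if (nominal % 2 == 0) != (n % 2 == 0):
                    continue
            out.add((f.hill(), adduct.name))
    return out


def emg_usp_oracle(k: float) -> tuple[float, float]:
    """USP asymmetry and tailing factors of an exponnorm(K=k) peak on a
    dense analytic grid (2e6 points), via linear interpolation."""
    t = np.linspace(-8, 12 + 6 * k, 2_000_001)
    y = stats.exponnorm.pdf(t, K=k) if k > 1e-9 else stats.norm.pdf(t)
    a = int(np.argmax(y))
    apex, h = t[a], y[a]
    half = {}
    for frac in (0.05, 0.10):
        lvl = frac * h
        li = np.nonzero(y[:a] < lvl)[0][-1]
        ri = a + np.nonzero(y[a:] < lvl)[0][0] - 1
        tl = t[li] + (lvl - y[li]) / (y[li + 1] - y[li]) * (t[li + 1] - t[li])
        tr = t[ri] + (lvl - y[ri]) / (y[ri + 1] - y[ri]) * (t[ri + 1] - t[ri])
        half[frac] = (apex - tl, tr - apex)
    a10, b10 = half[0.10]
    a5, b5 = half[0.05]
    return b10 / a10, (a5 + b5) / (2 * a5)
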