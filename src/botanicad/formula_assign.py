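"""Molecular-formula assignment for accurate-mass ions.

Enumerates every elemental composition whose theoretical m/z falls
within a ppm tolerance of an observed ion under a set of candidate
adducts, then scores each composition against the measured isotope
envelope with a 0-100 composite: mass accuracy of the monoisotopic (A)
peak, abundance fit of A+1/A+2 relative to A, and exact mass spacing of
the envelope.  A score above the confidence threshold (default 90)
marks an assignment as confident.

The composite is a Gaussian-kernel surrogate for the vendor isotope-fit
score such data are usually processed with; the weights and kernel
widths are this package's own definition and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .chem import (
    AdductSpec,
    MolecularFormula,
    adduct_mz,
    dbe,
    isotope_pattern,
    monoisotopic_mass,
)
from .elements import DEFAULT_TABLE, ElementTable

__all__ = [
    "ElementBounds",
    "ObservedEnvelope",
    "FormulaCandidate",
    "ScoringWeights",
    "enumerate_candidates",
    "score_candidate",
    "rank_candidates",
    "CONFIDENT_SCORE",
]

#: Score at or above which an assignment is considered confident.
CONFIDENT_SCORE = 90.0

_MAX_COMBINATIONS = 10_000_000


@dataclass(frozen=True)
class ElementBounds:
    """Per-element count ranges for the candidate search.

    Defaults cover the CHNO-dominated chemistry of plant extracts:
    C 0-100, H 0-150, N 0-6, O 0-40.  Sulfur and phosphorus can be
    enabled by passing wider bounds.
    """

    bounds: tuple[tuple[str, int, int], ...] = (
        ("C", 0, 100),
        ("H", 0, 150),
        ("N", 0, 6),
        ("O", 0, 40),
    )
    max_total_atoms: int = 300

    def __post_init__(self) -> None:
        for sym, lo, hi in self.bounds:
            if lo < 0 or hi < lo:
                raise ValueError(f"{sym}: invalid bounds ({lo}, {hi})")

    @classmethod
    def from_dict(cls, d: dict[str, tuple[int, int]], max_total_atoms: int = 300
                  ) -> "ElementBounds":
        return cls(tuple((s, int(lo), int(hi)) for s, (lo, hi) in d.items()),
                   max_total_atoms)

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {s: (lo, hi) for s, lo, hi in self.bounds}

    def grid_size(self) -> int:
        """Search-grid cardinality over the non-hydrogen elements.

        Hydrogen is solved analytically from the residual mass, so it
        does not multiply the search.
        """
        n = 1
        for sym, lo, hi in self.bounds:
            if sym != "H":
                n *= hi - lo + 1
        return n


@dataclass(frozen=True)
class ObservedEnvelope:
    """Measured isotope envelope of one ion: (m/z, intensity) for
    A, A+1, A+2, ... with the ion charge and polarity."""

    mzs: tuple[float, ...]
    intensities: tuple[float, ...]
    charge: int = 1
    polarity: str = "+"

    def __post_init__(self) -> None:
        if not self.mzs:
            raise ValueError("envelope needs at least the A peak")
        if any(i <= 0 for i in self.intensities):
            raise ValueError("envelope intensities must be positive")
        if any(b <= a for a, b in zip(self.mzs, self.mzs[1:])):
            raise ValueError("envelope m/z values must be increasing")

    def relative_abundances(self) -> tuple[float, ...]:
        """Abundances normalized to the A peak = 100."""
        base = self.intensities[0]
        return tuple(100.0 * i / base for i in self.intensities)


@dataclass(frozen=True)
class ScoringWeights:
    """Weights and Gaussian kernel widths of the composite score.

    ``sigma_abund`` is matched to the few-percentage-point precision of
    measured A+1/A ratios; a much wider kernel washes out the abundance
    information that separates near-isobaric compositions (e.g. the
    +C +4N -4H -4O swap only 1.3 mDa away).
    """

    w_mass: float = 0.4
    w_abund: float = 0.4
    w_spacing: float = 0.2
    sigma_ppm: float = 5.0
    sigma_abund: float = 3.0  # relative-abundance percentage points
    sigma_spacing: float = 0.002  # Da
    envelope_depth: int = 2  # compare A+1 .. A+K

    def __post_init__(self) -> None:
        if min(self.w_mass, self.w_abund, self.w_spacing) < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.w_mass + self.w_abund + self.w_spacing - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if min(self.sigma_ppm, self.sigma_abund, self.sigma_spacing) <= 0:
            raise ValueError("kernel widths must be positive")


@dataclass(frozen=True)
class FormulaCandidate:
    """One candidate (formula, adduct) explanation of an observed ion."""

    formula: MolecularFormula
    adduct: AdductSpec
    ppm_error: float
    dbe: float
    score: float | None = None
    components: tuple[float, float, float] | None = None  # S_mass, S_abund, S_spacing

    @property
    def confident(self) -> bool:
        return self.score is not None and self.score >= CONFIDENT_SCORE

    def __str__(self) -> str:
        s = f"{self.formula.hill()} {self.adduct.name} {self.ppm_error:+.2f} ppm"
        if self.score is not None:
            s += f" score={self.score:.1f}"
        return s


def _heteroatoms(formula: MolecularFormula) -> int:
    return sum(n for sym, n in formula.counts if sym not in ("C", "H"))


def _nominal_mass(formula: MolecularFormula, table: ElementTable) -> int:
    return sum(round(table.principal_mass(sym)) * n for sym, n in formula.counts)


def _passes_filters(
    formula: MolecularFormula,
    adduct: AdductSpec,
    nitrogen_rule: bool,
    table: ElementTable,
) -> bool:
    d = formula.as_dict()
    c, h, n = d.get("C", 0), d.get("H", 0), d.get("N", 0)
    if h > 2 * c + n + 2:
        return False
    rdbe = dbe(formula)
    if rdbe < 0:
        return False
    # Even-electron adducts require an integer-DBE neutral.
    if abs(rdbe - round(rdbe)) > 1e-9:
        return False
    if nitrogen_rule and abs(adduct.charge) == 1:
        # Classic parity rule for even-electron singly charged ions:
        # an even-nominal-mass CHNOPS neutral carries an even N count.
        if (_nominal_mass(formula, table) % 2 == 0) != (n % 2 == 0):
            return False
    return True


def enumerate_candidates(
    mz: float,
    polarity: str,
    adducts: list[AdductSpec],
    bounds: ElementBounds = ElementBounds(),
    tol_ppm: float = 5.0,
    nitrogen_rule: bool = True,
    table: ElementTable = DEFAULT_TABLE,
) -> list[FormulaCandidate]:
    """All formulas within ``bounds`` explaining ``mz`` under any adduct.

    The search is an iterative nested counting loop over the
    non-hydrogen elements (heaviest first) with early mass pruning;
    the hydrogen count is solved from the residual mass, so runtime is
    linear in the pruned C x N x O ... grid.  Candidates are filtered by
    DBE >= 0, integer DBE (even-electron ions), the nitrogen rule for
    singly charged ions (toggleable) and H <= 2C + N + 2.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not adducts:
        raise ValueError("adduct list must not be empty")
    if bounds.grid_size() > _MAX_COMBINATIONS:
        raise ValueError(
            f"element bounds span {bounds.grid_size():.2e} combinations "
            f"(> {_MAX_COMBINATIONS:.0e}); narrow the bounds"
        )

    bdict = bounds.as_dict()
    h_lo, h_hi = bdict.get("H", (0, 0))
    heavy = [(sym, lo, hi) for sym, lo, hi in bounds.bounds if sym != "H"]
    heavy.sort(key=lambda t: table.principal_mass(t[0]), reverse=True)
    masses = [table.principal_mass(sym) for sym, _, _ in heavy]
    m_h = table.principal_mass("H")

    out: list[FormulaCandidate] = []
    seen: set[tuple[tuple[tuple[str, int], ...], str]] = set()
    for adduct in [a for a in adducts if a.polarity == polarity]:
        tol_da = mz * tol_ppm * 1e-6
        target_lo = adduct.neutral_mass(mz - tol_da, table)
        target_hi = adduct.neutral_mass(mz + tol_da, table)
        if target_hi <= 0:
            continue

        # max mass attainable by elements from index i on (including H)
        n_heavy = len(heavy)
        suffix_max = [0.0] * (n_heavy + 1)
        suffix_max[n_heavy] = m_h * h_hi
        for i in range(n_heavy - 1, -1, -1):
            suffix_max[i] = suffix_max[i + 1] + masses[i] * heavy[i][2]

        counts = [lo for _, lo, _ in heavy]
        idx = 0
        partial = [0.0] * (n_heavy + 1)  # mass consumed before element idx
        atoms = [0] * (n_heavy + 1)
        while True:
            if idx == n_heavy:
                residual = (target_lo + target_hi) / 2 - partial[idx]
                h_guess = residual / m_h
                for h in range(max(h_lo, int(h_guess) - 1),
                               min(h_hi, int(h_guess) + 2) + 1):
                    m = partial[idx] + m_h * h
                    if not (target_lo <= m <= target_hi):
                        continue
                    if atoms[idx] + h > bounds.max_total_atoms or atoms[idx] + h == 0:
                        continue
                    fdict = {heavy[i][0]: counts[i]
                             for i in range(n_heavy) if counts[i]}
                    if h:
                        fdict["H"] = h
                    formula = MolecularFormula(fdict)
                    if not _passes_filters(formula, adduct, nitrogen_rule, table):
                        continue
                    key = (formula.counts, adduct.name)
                    if key in seen:
                        continue
                    seen.add(key)
                    theo = adduct_mz(monoisotopic_mass(formula, table), adduct, table)
                    out.append(FormulaCandidate(
                        formula=formula,
                        adduct=adduct,
                        ppm_error=(mz - theo) / theo * 1e6,
                        dbe=dbe(formula),
                    ))
                idx -= 1
            else:
                sym, lo, hi = heavy[idx]
                c = counts[idx]
                if c > hi:
                    counts[idx] = lo
                    idx -= 1
                    if idx < 0:
                        break
                    counts[idx] += 1
                    continue
                m = partial[idx] + masses[idx] * c
                a = atoms[idx] + c
                # prune: overshoot, or cannot reach target_lo even maxed out
                if m > target_hi or a > bounds.max_total_atoms:
                    counts[idx] = lo
                    idx -= 1
                    if idx < 0:
                        break
                    counts[idx] += 1
                    continue
                if m + suffix_max[idx + 1] < target_lo:
                    # increasing later elements cannot help; bump this one
                    counts[idx] += 1
                    continue
                partial[idx + 1] = m
                atoms[idx + 1] = a
                idx += 1
                continue
            if idx < 0:
                break
            counts[idx] += 1

    out.sort(key=lambda c: (abs(c.ppm_error), c.formula.hill(), c.adduct.name))
    return out


def score_candidate(
    candidate: FormulaCandidate,
    observed: ObservedEnvelope,
    weights: ScoringWeights = ScoringWeights(),
    table: ElementTable = DEFAULT_TABLE,
) -> FormulaCandidate:
    """Score a candidate against a measured envelope (0-100).

    S_mass = exp(-0.5 (dppm/sigma_ppm)^2) on the A peak; S_abund and
    S_spacing are mean-squared Gaussian kernels over A+1..A+K relative
    abundances (A = 100) and adjacent-peak spacings.  A theoretical A+k
    with no observed counterpart contributes its worst-case deviation
    capped at 3 sigma.  score = 100 (w_m S_mass + w_a S_abund + w_s S_spacing).
    """
    if abs(candidate.adduct.charge) != abs(observed.charge):
        raise ValueError(
            f"charge mismatch: adduct {candidate.adduct.name} has |z|="
            f"{abs(candidate.adduct.charge)}, envelope has |z|={abs(observed.charge)}"
        )
    theo = isotope_pattern(
        candidate.formula, prune_abundance=1e-4,
        charge_context=candidate.adduct, table=table,
    )
    # normalize theoretical abundances to A = 100
    a_idx = theo.offsets.index(0)
    theo_rel = {o: 100.0 * ab / theo.abundances[a_idx]
                for o, ab in zip(theo.offsets, theo.abundances)}
    theo_mz = {o: m for o, m in zip(theo.offsets, theo.masses)}

    k_max = weights.envelope_depth
    obs_rel = observed.relative_abundances()

    dppm = (observed.mzs[0] - theo_mz[0]) / theo_mz[0] * 1e6
    s_mass = _gauss(dppm, weights.sigma_ppm)

    dev_ab, dev_sp, n_terms = 0.0, 0.0, 0
    for k in range(1, k_max + 1):
        if k not in theo_rel:
            continue
        n_terms += 1
        if k < len(obs_rel):
            dev_ab += ((obs_rel[k] - theo_rel[k]) / weights.sigma_abund) ** 2
            obs_gap = observed.mzs[k] - observed.mzs[k - 1]
            theo_gap = theo_mz[k] - theo_mz.get(k - 1, theo_mz[0])
            dev_sp += ((obs_gap - theo_gap) / weights.sigma_spacing) ** 2
        else:
            dev_ab += (min(theo_rel[k], 3 * weights.sigma_abund)
                       / weights.sigma_abund) ** 2
            dev_sp += 3.0 ** 2
    if n_terms:
        s_abund = _gauss_sq(dev_ab / n_terms)
        s_spacing = _gauss_sq(dev_sp / n_terms)
    else:
        s_abund = s_spacing = 1.0

    score = 100.0 * (weights.w_mass * s_mass
                     + weights.w_abund * s_abund
                     + weights.w_spacing * s_spacing)
    return replace(candidate, score=score,
                   components=(s_mass, s_abund, s_spacing))


def _gauss(x: float, sigma: float) -> float:
    import math
    return math.exp(-0.5 * (x / sigma) ** 2)


def _gauss_sq(mean_sq: float) -> float:
    import math
    return math.exp(-0.5 * mean_sq)


def rank_candidates(candidates: list[FormulaCandidate]) -> list[FormulaCandidate]:
    """Stable sort: score desc, |ppm| asc, heteroatom count asc, Hill string."""
    return sorted(
        candidates,
        key=lambda c: (
            -(c.score if c.score is not None else -1.0),
            abs(c.ppm_error),
            _heteroatoms(c.formula),
            c.formula.hill(),
        ),
    )
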