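"""Centroid MS processing: EICs, deisotoped features, adduct groups.

Turns time-ordered centroided spectra into chromatographic features
(centroids tracked across scans, isotopologue traces merged by their
1.00336/z Da spacing), then collapses adduct-related features — e.g.
[M+H]+ / [M+NH4]+ / a doubly charged dimer ion — into analyte groups
sharing one neutral monoisotopic mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import AdductSpec, adduct_by_name
from .chromatogram import Trace
from .elements import DEFAULT_TABLE, ElementTable
from .formula_assign import ObservedEnvelope

__all__ = [
    "CentroidSpectrum",
    "MSFeature",
    "AnalyteGroup",
    "extract_eic",
    "detect_features",
    "group_adducts",
    "read_mzml",
    "read_spectra_json",
    "write_spectra_json",
    "ISOTOPE_SPACING",
]

#: Average nucleon spacing of an isotope envelope, Da (13C-dominated).
ISOTOPE_SPACING = 1.00336


@dataclass(frozen=True)
class CentroidSpectrum:
    """One centroided scan: retention time (min), polarity, sorted m/z."""

    rt: float
    polarity: str
    mzs: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mzs, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "mzs", mz)
        object.__setattr__(self, "intensities", it)
        if mz.size != it.size:
            raise ValueError("m/z and intensity arrays must align")
        if mz.size and np.any(np.diff(mz) < 0):
            raise ValueError("centroid m/z must be sorted ascending")
        if np.any(it <= 0):
            raise ValueError("centroid intensities must be positive")

    def looks_like_profile(self) -> bool:
        """Dense, quasi-continuous m/z sampling betrays profile data."""
        if self.mzs.size < 50:
            return False
        gaps = np.diff(self.mzs)
        return float(np.median(gaps)) < 0.01


@dataclass(frozen=True)
class MSFeature:
    """A deisotoped, charge-assigned chromatographic MS feature."""

    mz: float  # monoisotopic m/z
    charge: int
    rt: float  # apex retention time, min
    area: float  # EIC area of the monoisotopic trace
    envelope: ObservedEnvelope
    polarity: str

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("feature charge must be >= 1")
        if self.area <= 0:
            raise ValueError("feature EIC area must be positive")


@dataclass(frozen=True)
class AnalyteGroup:
    """Adduct-related features explained by one neutral mass."""

    neutral_mass: float
    members: tuple[tuple[MSFeature, AdductSpec], ...]
    rt: float

    def total_area(self) -> float:
        return sum(f.area for f, _ in self.members)

    def adduct_names(self) -> tuple[str, ...]:
        return tuple(a.name for _, a in self.members)

    def best_envelope(self) -> tuple[ObservedEnvelope, AdductSpec]:
        """Envelope of the most intense member (used for scoring)."""
        f, a = max(self.members, key=lambda m: m[0].area)
        return f.envelope, a


def extract_eic(spectra: list[CentroidSpectrum], mz: float,
                tol_ppm: float = 10.0) -> Trace:
    """Extracted ion chromatogram: summed intensity within +/- tol_ppm."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    tol = mz * tol_ppm * 1e-6
    times, vals = [], []
    for s in spectra:
        lo = np.searchsorted(s.mzs, mz - tol, side="left")
        hi = np.searchsorted(s.mzs, mz + tol, side="right")
        times.append(s.rt)
        vals.append(float(s.intensities[lo:hi].sum()))
    return Trace(detector="EIC", times=np.array(times), intensities=np.array(vals))


@dataclass
class _RawTrace:
    mz_sum: float  # intensity-weighted
    weight: float
    last_scan: int
    rts: list[float]
    intens: list[float]

    @property
    def mz(self) -> float:
        return self.mz_sum / self.weight

    def apex(self) -> tuple[float, float]:
        i = int(np.argmax(self.intens))
        return self.rts[i], self.intens[i]

    def centroid_rt(self) -> float:
        """Intensity-weighted mean time — far more stable under
        scan-to-scan intensity noise than the argmax scan."""
        return float(np.average(self.rts, weights=self.intens))

    def area(self) -> float:
        if len(self.rts) == 1:
            return float(self.intens[0])
        return float(np.trapezoid(self.intens, self.rts))


def _link_traces(spectra: list[CentroidSpectrum], min_intensity: float,
                 tol_ppm: float, min_scans: int) -> list[_RawTrace]:
    """Greedy nearest-m/z linking of centroids across adjacent scans."""
    open_traces: list[_RawTrace] = []
    closed: list[_RawTrace] = []
    for i, s in enumerate(spectra):
        still_open: list[_RawTrace] = []
        for tr in open_traces:
            if tr.last_scan >= i - 1:
                still_open.append(tr)
            else:
                closed.append(tr)
        open_traces = still_open

        order = np.argsort(s.intensities)[::-1]
        taken: set[int] = set()
        for j in order:
            inten = float(s.intensities[j])
            if inten < min_intensity:
                continue
            mz = float(s.mzs[j])
            best, best_dev = None, None
            for k, tr in enumerate(open_traces):
                if k in taken or tr.last_scan != i - 1:
                    continue
                dev = abs(tr.mz - mz)
                if dev <= tr.mz * tol_ppm * 1e-6 and (best_dev is None
                                                      or dev < best_dev):
                    best, best_dev = k, dev
            if best is None:
                open_traces.append(_RawTrace(mz * inten, inten, i, [s.rt], [inten]))
                taken.add(len(open_traces) - 1)
            else:
                tr = open_traces[best]
                tr.mz_sum += mz * inten
                tr.weight += inten
                tr.last_scan = i
                tr.rts.append(s.rt)
                tr.intens.append(inten)
                taken.add(best)
    closed.extend(open_traces)
    return [tr for tr in closed if len(tr.rts) >= min_scans]


def detect_features(
    spectra: list[CentroidSpectrum],
    min_intensity: float = 0.0,
    tol_ppm: float = 10.0,
    max_charge: int = 2,
    min_scans: int = 3,
) -> list[MSFeature]:
    """Deisotoped features from centroided spectra.

    Centroids are tracked across adjacent scans into traces (a feature
    requires at least ``min_scans`` consecutive scans — at a 5 Hz
    acquisition rate that is well below chromatographic peak widths);
    co-eluting traces spaced by 1.00336/z Da are merged into one feature
    whose envelope orders A, A+1, A+2...  The monoisotopic member is the
    lowest-mass envelope member.  Dense profile-mode input is rejected.
    """
    if not spectra:
        return []
    for s in spectra:
        if s.looks_like_profile():
            raise ValueError(
                "input looks like profile-mode data; centroid it first")
    polarity = spectra[0].polarity
    rt_step = (np.median(np.diff([s.rt for s in spectra]))
               if len(spectra) > 2 else 0.01)

    traces = _link_traces(spectra, min_intensity, tol_ppm, min_scans)
    traces.sort(key=lambda tr: tr.mz)
    mz_arr = np.array([tr.mz for tr in traces])
    apexes = [tr.apex() for tr in traces]
    centers = [tr.centroid_rt() for tr in traces]
    rt_tol = max(3 * rt_step, 0.01)

    used = [False] * len(traces)
    features: list[MSFeature] = []
    # Seed envelopes from the most intense trace downward.
    for i in sorted(range(len(traces)), key=lambda k: -apexes[k][1]):
        if used[i]:
            continue
        rt_i = centers[i]
        best_chain: list[int] = [i]
        best_z = 1
        for z in range(1, max_charge + 1):
            chain = [i]
            # grow downward in mass first: the seed may be A+1 of a
            # lower monoisotopic trace
            for direction in (-1, +1):
                cur = i
                while True:
                    target = traces[cur].mz + direction * ISOTOPE_SPACING / z
                    tol = traces[cur].mz * tol_ppm * 1e-6 * 2
                    lo = np.searchsorted(mz_arr, target - tol)
                    hi = np.searchsorted(mz_arr, target + tol)
                    cand = [k for k in range(lo, hi)
                            if not used[k] and k not in chain
                            and abs(centers[k] - rt_i) <= rt_tol]
                    if not cand:
                        break
                    k = min(cand, key=lambda k: abs(mz_arr[k] - target))
                    if direction < 0:
                        chain.insert(0, k)
                    else:
                        chain.append(k)
                    cur = k
            if len(chain) > len(best_chain):
                best_chain, best_z = chain, z
        for k in best_chain:
            used[k] = True
        chain = sorted(best_chain, key=lambda k: mz_arr[k])
        mono = traces[chain[0]]
        env = ObservedEnvelope(
            mzs=tuple(mz_arr[k] for k in chain),
            intensities=tuple(apexes[k][1] for k in chain),
            charge=best_z if len(chain) > 1 else 1,
            polarity=polarity,
        )
        features.append(MSFeature(
            mz=mono.mz,
            charge=env.charge,
            rt=mono.apex()[0],
            area=mono.area(),
            envelope=env,
            polarity=polarity,
        ))
    features.sort(key=lambda f: (f.rt, f.mz))
    return features


def group_adducts(
    features: list[MSFeature],
    adducts: list[AdductSpec],
    tol_ppm: float = 5.0,
    rt_window: float = 0.05,
    table: ElementTable = DEFAULT_TABLE,
) -> list[AnalyteGroup]:
    """Merge adduct-related features into analyte groups.

    Features whose implied neutral masses (inverting the adduct m/z
    arithmetic) agree within ``tol_ppm`` and whose apexes agree within
    ``rt_window`` minutes form one group; every feature receives exactly
    one adduct.  Unexplained features become singleton groups under the
    polarity's default adduct ([M+H]+ / [M-H]-).
    """
    defaults = {"+": adduct_by_name("[M+H]+"), "-": adduct_by_name("[M-H]-")}

    def compatible(f: MSFeature) -> list[tuple[AdductSpec, float]]:
        out = []
        for a in adducts:
            if a.polarity == f.polarity and abs(a.charge) == f.charge:
                out.append((a, a.neutral_mass(f.mz, table)))
        return out

    cand = [compatible(f) for f in features]
    n = len(features)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pair_assign: dict[tuple[int, int], tuple[AdductSpec, AdductSpec, float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if abs(features[i].rt - features[j].rt) > rt_window:
                continue
            best = None
            for ai, mi in cand[i]:
                for aj, mj in cand[j]:
                    if ai.name == aj.name:
                        continue
                    dev = abs(mi - mj)
                    if dev <= max(mi, mj) * tol_ppm * 1e-6:
                        if best is None or dev < best[2]:
                            best = (ai, aj, dev)
            if best is not None:
                pair_assign[(i, j)] = best
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    groups: list[AnalyteGroup] = []
    for members in comps.values():
        if len(members) == 1:
            i = members[0]
            f = features[i]
            a = next((ad for ad, _ in cand[i]), None)
            if a is None or len(cand[i]) != 1:
                a = defaults[f.polarity] if f.charge == 1 else (
                    cand[i][0][0] if cand[i] else defaults[f.polarity])
            groups.append(AnalyteGroup(
                neutral_mass=a.neutral_mass(f.mz, table),
                members=((f, a),),
                rt=f.rt,
            ))
            continue
        # consensus assignment: per feature, the adduct voted for by its
        # pairwise matches (ties -> smallest neutral-mass disagreement)
        votes: dict[int, dict[str, tuple[int, float]]] = {m: {} for m in members}
        for (i, j), (ai, aj, dev) in pair_assign.items():
            for idx, a in ((i, ai), (j, aj)):
                if idx in votes:
                    cnt, d = votes[idx].get(a.name, (0, np.inf))
                    votes[idx][a.name] = (cnt + 1, min(d, dev))
        assignment: list[tuple[MSFeature, AdductSpec]] = []
        masses = []
        for idx in members:
            if votes[idx]:
                name = min(votes[idx],
                           key=lambda nm: (-votes[idx][nm][0], votes[idx][nm][1]))
                a = next(ad for ad, _ in cand[idx] if ad.name == name)
            else:
                a = defaults[features[idx].polarity]
            assignment.append((features[idx], a))
            masses.append(a.neutral_mass(features[idx].mz, table))
        areas = [features[idx].area for idx in members]
        rt = float(np.average([features[idx].rt for idx in members],
                              weights=areas))
        groups.append(AnalyteGroup(
            neutral_mass=float(np.median(masses)),
            members=tuple(assignment),
            rt=rt,
        ))
    groups.sort(key=lambda g: (g.rt, g.neutral_mass))
    return groups


def read_mzml(path: str | Path) -> list[CentroidSpectrum]:
    """Centroided MS1 spectra (rt, polarity, centroids) from an mzML file."""
    from pyteomics import mzml as _mzml

    spectra: list[CentroidSpectrum] = []
    with _mzml.read(str(path)) as reader:
        for sp in reader:
            if sp.get("ms level", 1) != 1:
                continue
            scan = sp["scanList"]["scan"][0]
            rt = float(scan["scan start time"])
            unit = getattr(scan.get("scan start time"), "unit_info", "minute")
            if unit and "second" in str(unit):
                rt /= 60.0
            polarity = "-" if "negative scan" in sp else "+"
            mzs = np.asarray(sp["m/z array"], dtype=float)
            its = np.asarray(sp["intensity array"], dtype=float)
            keep = its > 0
            spectra.append(CentroidSpectrum(
                rt=rt, polarity=polarity, mzs=mzs[keep], intensities=its[keep]))
    spectra.sort(key=lambda s: s.rt)
    return spectra


def read_spectra_json(path: str | Path) -> list[CentroidSpectrum]:
    """Minimal JSON spectra format used for fixtures::

        {"spectra": [{"rt": 1.0, "polarity": "+",
                      "mz": [...], "intensity": [...]}, ...]}
    """
    with open(path) as fh:
        raw = json.load(fh)
    return [
        CentroidSpectrum(rt=float(s["rt"]), polarity=s["polarity"],
                         mzs=np.array(s["mz"], dtype=float),
                         intensities=np.array(s["intensity"], dtype=float))
        for s in raw["spectra"]
    ]


def write_spectra_json(spectra: list[CentroidSpectrum], path: str | Path) -> None:
    payload = {"spectra": [
        {"rt": round(s.rt, 6), "polarity": s.polarity,
         "mz": [round(float(m), 6) for m in s.mzs],
         "intensity": [round(float(i), 4) for i in s.intensities]}
        for s in spectra
    ]}
    with open(path, "w") as fh:
        json.dump(payload, fh)
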