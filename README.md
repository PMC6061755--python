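# botanicad

Multi-detector characterization and relative quantitation of botanical
extract constituents, built for threshold-of-toxicological-concern
(TTC) safety assessments.

Botanical extracts are mixtures of dozens of constituents for which
authentic standards mostly do not exist.  A charged aerosol detector
(CAD) responds to analyte *mass* largely independent of structure, so
the share of total CAD signal under each chromatographic peak is a
standard-free estimate of each constituent's share of the extract
mass — and a high-resolution mass spectrometer on the same column
assigns each peak a molecular formula.  `botanicad` implements that
workflow end to end:

- **Chromatogram processing** — asymmetric-least-squares baseline
  (separates the broad unresolved "tannin hump" from resolved peaks),
  peak detection with an S/N ≥ 3 gate and a 0.05 %-of-total-signal
  reporting floor, USP shape metrics
  (A<sub>f</sub> = b₁₀/a₁₀, T = (a₅+b₅)/2a₅), and relative
  quantitation: %ᵢ = 100 · areaᵢ / Σ areaⱼ.
- **Exact-mass chemistry** — Hill-notation formulas over a pinned
  NIST/CODATA isotope table, electrospray adduct arithmetic with
  electron-mass correction, ring-and-double-bond equivalents
  (DBE = n꜀ − (n_H + n_X)/2 + (n_N + n_P)/2 + 1), and exact
  nucleon-aggregated isotope envelopes (A, A+1, A+2, …).
- **Formula assignment** — exhaustive candidate enumeration within ppm
  tolerance under a configurable adduct list, scored 0–100 against the
  measured envelope (mass accuracy + A+1/A+2 abundance fit + envelope
  spacing); a score ≥ 90 is a confident assignment.
- **MS feature detection** — centroid tracking across scans,
  deisotoping by the 1.00336/z Da spacing, and adduct grouping
  ([M+H]⁺/[M+NH₄]⁺/[M+Na]⁺/[M+HCOO]⁻/doubly charged ions) into analyte
  groups sharing one neutral mass.
- **Fusion and reporting** — detector time-offset calibration,
  assignment of analyte groups to CAD peaks (coelution resolved by
  narrow-mass evidence), confidence tiers (authentic standard /
  proposed / formula-only / no MS signal), and a constituent report
  with the TTC summary statistics: the largest single unidentified
  constituent and the total unidentified signal.
- **Synthetic fixtures** — a generator that renders ground-truth
  constituent lists into CAD/UV traces and centroided spectra, plus a
  packaged machine-readable transcription of a published 83-peak
  *Ginkgo biloba* characterization table.

## Worked example

```python
from botanicad import (PipelineConfig, ReferenceStandard,
                       SimulationConfig, simulate_extract)
from botanicad.report import run_pipeline
from botanicad.synthetic import example_constituents

constituents = example_constituents(10, seed=3)
sim = simulate_extract(constituents, SimulationConfig(seed=11))
standards = [ReferenceStandard(c.name, c.formula, rt=c.rt)
             for c in constituents[:4]]
report = run_pipeline(sim.cad, sim.spectra["+"], PipelineConfig(),
                      uv=sim.uv, standards=standards)
for rec in report.records[:4]:
    print(rec.peak_number, round(rec.cad_percent, 2), rec.tier.value,
          [a.formula.hill() for a in rec.analytes if a.formula])
```

prints

```
1 15.98 standard_match ['C15H10O5']
2 14.66 standard_match ['C27H30O15']
3 13.33 standard_match ['C15H22O3']
4 12.01 standard_match ['C15H14O6']
```

— each row is one CAD peak: its share of total CAD signal (≈ share of
extract mass), its identification confidence, and the molecular
formula(s) of the analyte(s) it contains.  The four standard-matched
rows are the constituents whose reference standards were supplied;
percentages match the generator's ground-truth mass fractions to a
fraction of a point.  `examples/` contains this and three more
narrative scripts (CAD quantitation with USP metrics, formula scoring
for a single ion, and the packaged 83-peak table).

A thin CLI wraps the same calls:

```sh
botanicad simulate --seed 5 --out sim/
botanicad run --cad sim/extract_cad.csv --ms sim/extract_pos.json --out out/
botanicad score --mz 611.16066 --envelope envelope.json
```

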