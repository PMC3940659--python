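# idrscape

Sequence analysis of **amyloidogenic regions (AR)** and **low-complexity
regions (LCR)** in intrinsically disordered proteins (IDPs).

Disordered proteins aggregate into amyloid fibrils in Parkinson's,
Alzheimer's and other diseases.  Aggregation is typically nucleated by
short amyloidogenic stretches, while the biased-composition low-complexity
stretches that dominate IDP sequences modulate solubility.  `idrscape`
provides the full analysis chain for studying how the two region types are
distributed, composed and balanced across a protein cohort:

- **`lcr_seg`** — LCR detection by windowed Shannon-entropy segmentation
  (window 12, trigger 2.2 bits, extension 2.5 bits, minimal-probability
  core refinement).
- **`amyloid_scan`** — AR detection by additive 6x20 position-specific
  scoring matrix (PSSM) scanning of hexapeptide windows, with a pluggable
  matrix in plain TSV.
- **`region_algebra`** — 1-based inclusive interval arithmetic: merging,
  AR x LCR overlap catalogs, content percentages
  (100 x covered residues / length), terminal-proximity counts.
- **`cohort_stats`** — disorder fraction, stratification into partially
  (PDP, <= 30%), moderately (MDP, 30-70%] and largely (LDP, > 70%)
  disordered classes, per-class aggregation, amino-acid composition and
  secondary-structure preference profiles.
- **`distribution_fit`** — alpha-stable fits (S0 parameterization,
  quantile-initialised binned maximum likelihood) to region lengths and
  contents, bivariate product-Gaussian kernel densities, negative
  hyperbolic regression y = a + b/x, Welch t-tests, discrete summaries.
- **`synthetic_data`** — ground-truthed synthetic cohorts (planted
  PSSM-detectable motifs, biased/homopolymeric LCR stretches with
  heavy-tailed stable lengths, class-spanning disorder annotations) so
  every stage is testable without database downloads.
- **`pipeline` / `idrscape` CLI** — end-to-end orchestration with
  deterministic, timestamp-free outputs.

See `docs/methods.md` for the models, parameter defaults and numerical
choices in detail.

## Worked example

The 42-residue amyloid-beta peptide carries the two classic amyloidogenic
hexapeptides KLVFFA and GGVVIA.  Scanning it with a motif fixture matrix
and computing its AR content:

```python
from idrscape import (Interval, ProteinRecord, content_percent,
                      format_percent, intersect, motif_pssm, scan_sequence)
from idrscape.examples import ABETA42_SEQUENCE

abeta = ProteinRecord("Abeta42", ABETA42_SEQUENCE)
pssm = motif_pssm(("KLVFFA", "GGVVIA"))
ars = scan_sequence(abeta, pssm, threshold=6.0)
print([(iv.start, iv.end) for iv in ars])
print(format_percent(content_percent(ars, abeta.length)))
```

prints

```
[(16, 21), (37, 42)]
29.0
```

two ARs at positions 16-21 and 37-42, together 12 of 42 residues = 28.57%,
presented as 29 after half-up integer rounding.  Overlap arithmetic on a
known transmembrane AR/LCR pair (AR 101-116 against LCR 97-112):

```python
ov = intersect(Interval(101, 116), Interval(97, 112))
print(ov.start, ov.end, ov.length)   # -> 101 112 12
```

the two regions share the 12 residues 101-112.  From the shell, a full
synthetic run:

```sh
idrscape simulate --seed 42 --n-proteins 50 --out-dir cohort/
idrscape summarize --fasta cohort/cohort.fa \
    --ar cohort/ar_truth.tsv --lcr cohort/lcr_truth.tsv \
    --disorder cohort/disorder.tsv --out-dir results/
```

writes `summaries.tsv` (one metric row per protein), `class_summary.tsv`
(PDP/MDP/LDP aggregation), `overlaps.tsv`, `composition.tsv`,
`ss_preference.tsv`, `fits.json` and `report.json` under `results/`.

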