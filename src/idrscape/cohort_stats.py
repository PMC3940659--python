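"""Per-protein disorder metrics, disorder-class stratification and
cohort-level aggregation.

Proteins are stratified by their disorder fraction (percentage of residues
annotated as intrinsically disordered): partially disordered (PDP, 0-30%),
moderately disordered (MDP, 30-70%] and largely disordered (LDP, >70%).
A protein is called amyloidogenic when it carries at least one amyloidogenic
region.  The module also profiles amino-acid composition inside regions and
tallies secondary-structure preferences, with a Chou-Fasman propensity argmax
bundled as a deterministic stand-in when no external per-residue secondary
structure annotation is supplied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .region_algebra import (
    Interval,
    RegionSet,
    content_percent,
    merge_intervals,
    overlap_catalog,
    terminal_counts,
)
from .seq_io import ProteinRecord, STANDARD_AA

CLASS_LABELS = ("PDP", "MDP", "LDP")

# class boundaries on disorder percentage: PDP = [0, 30], MDP = (30, 70], LDP = (70, 100]
DEFAULT_CLASS_BOUNDS = (30.0, 70.0)

SS_LABELS = ("H", "E", "C")

# Chou-Fasman conformational propensities (helix, sheet) per residue
CHOU_FASMAN = {
    "A": (1.42, 0.83), "R": (0.98, 0.93), "N": (0.67, 0.89), "D": (1.01, 0.54),
    "C": (0.70, 1.19), "Q": (1.11, 1.10), "E": (1.51, 0.37), "G": (0.57, 0.75),
    "H": (1.00, 0.87), "I": (1.08, 1.60), "L": (1.21, 1.30), "K": (1.14, 0.74),
    "M": (1.45, 1.05), "F": (1.13, 1.38), "P": (0.57, 0.55), "S": (0.77, 0.75),
    "T": (0.83, 1.19), "W": (1.08, 1.37), "Y": (0.69, 1.47), "V": (1.06, 1.70),
}


@dataclass(frozen=True)
class DisorderAnnotation:
    """Merged disordered intervals on one protein."""

    protein_id: str
    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", merge_intervals(self.intervals))


@dataclass(frozen=True)
class ProteinSummary:
    protein_id: str
    length: int
    disorder_pct: float
    ar_pct: float
    lcr_pct: float
    ar_count: int
    lcr_count: int
    overlap_count: int
    class_label: str
    n_terminal_ars: int
    c_terminal_ars: int

    @property
    def amyloidogenic(self) -> bool:
        return self.ar_count >= 1


@dataclass(frozen=True)
class ClassSummary:
    class_label: str
    total_proteins: int
    amyloidogenic_count: int
    amyloidogenic_pct: float
    ar_count: int
    ar_pct_mean: float
    lcr_count: int
    lcr_pct_mean: float
    overlap_region_count: int


@dataclass(frozen=True)
class CompositionProfile:
    """Residue frequencies (%) over a context: AR, LCR or whole protein."""

    context: str
    freqs: dict  # residue -> percentage, standard residues only


@dataclass(frozen=True)
class SsPreference:
    context: str
    helix_pct: float
    sheet_pct: float
    coil_pct: float


def disorder_fraction(ann: DisorderAnnotation, protein_length: int) -> float:
    """Percentage of residues inside disordered intervals."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    covered = sum(iv.length for iv in ann.intervals)
    return 100.0 * covered / protein_length


def classify_protein(
    disorder_pct: float, bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
) -> str:
    """Disorder-class label: PDP <= bounds[0] < MDP <= bounds[1] < LDP."""
    if not (0.0 <= disorder_pct <= 100.0):
        raise ValueError(f"disorder percentage {disorder_pct} outside [0, 100]")
    low, high = bounds
    if disorder_pct <= low:
        return "PDP"
    if disorder_pct <= high:
        return "MDP"
    return "LDP"


def build_protein_summary(
    record: ProteinRecord,
    ars: RegionSet,
    lcrs: RegionSet,
    disorder: Optional[DisorderAnnotation] = None,
    terminal_margin: int = 15,
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
) -> ProteinSummary:
    """Assemble the per-protein metric row from its annotations."""
    disorder = disorder or DisorderAnnotation(record.id, ())
    d_pct = disorder_fraction(disorder, record.length)
    n_term, c_term = terminal_counts(ars, record.length, terminal_margin)
    return ProteinSummary(
        protein_id=record.id,
        length=record.length,
        disorder_pct=d_pct,
        ar_pct=content_percent(ars, record.length),
        lcr_pct=content_percent(lcrs, record.length),
        ar_count=len(ars),
        lcr_count=len(lcrs),
        overlap_count=len(overlap_catalog(ars, lcrs)),
        class_label=classify_protein(d_pct, class_bounds),
        n_terminal_ars=n_term,
        c_terminal_ars=c_term,
    )


def summarize_class(summaries: Sequence[ProteinSummary]) -> list[ClassSummary]:
    """Aggregate per-protein rows into one row per disorder class + Total."""
    if not summaries:
        return []
    out = []
    groups = {label: [s for s in summaries if s.class_label == label]
              for label in CLASS_LABELS}
    for label in (*CLASS_LABELS, "Total"):
        grp = list(summaries) if label == "Total" else groups[label]
        if not grp and label != "Total":
            continue
        n = len(grp)
        amyl = sum(1 for s in grp if s.amyloidogenic)
        out.append(
            ClassSummary(
                class_label=label,
                total_proteins=n,
                amyloidogenic_count=amyl,
                amyloidogenic_pct=100.0 * amyl / n if n else 0.0,
                ar_count=sum(s.ar_count for s in grp),
                ar_pct_mean=sum(s.ar_pct for s in grp) / n if n else 0.0,
                lcr_count=sum(s.lcr_count for s in grp),
                lcr_pct_mean=sum(s.lcr_pct for s in grp) / n if n else 0.0,
                overlap_region_count=sum(s.overlap_count for s in grp),
            )
        )
    return out


def class_summary_frame(rows: Sequence[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def _context_residues(
    records: Sequence[ProteinRecord], regions: Optional[dict[str, RegionSet]]
) -> str:
    if regions is None:
        return "".join(r.sequence for r in records)
    parts = []
    for rec in records:
        rs = regions.get(rec.id)
        if rs is None:
            continue
        for iv in merge_intervals(rs.intervals):
            parts.append(rec.slice(iv.start, iv.end))
    return "".join(parts)


def composition_profile(
    records: Sequence[ProteinRecord],
    regions: Optional[dict[str, RegionSet]] = None,
    context: str = "WHOLE",
) -> CompositionProfile:
    """Residue frequencies over the concatenated in-context residues.

    Ambiguity letters are excluded from numerator and denominator.
    """
    residues = _context_residues(records, regions)
    counts = Counter(aa for aa in residues if aa in STANDARD_AA)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues in context")
    freqs = {aa: 100.0 * counts.get(aa, 0) / total for aa in STANDARD_AA}
    return CompositionProfile(context=context, freqs=freqs)


def ss_preference(
    ss_annotation: str,
    protein_length: int,
    regions: Optional[RegionSet] = None,
    context: str = "WHOLE",
    per_region: bool = False,
) -> SsPreference:
    """Secondary-structure preference of in-context residues.

    Default mode counts residues labelled H/E/C; ``per_region`` instead
    assigns each region its majority label and reports percentages over
    regions (the region-level reading of structural preference).
    """
    if len(ss_annotation) != protein_length:
        raise ValueError(
            f"annotation length {len(ss_annotation)} != protein length "
            f"{protein_length}"
        )
    bad = set(ss_annotation) - set(SS_LABELS)
    if bad:
        raise ValueError(f"unknown secondary-structure labels {sorted(bad)}")
    if regions is None:
        contexts = [ss_annotation]
    else:
        contexts = [
            ss_annotation[iv.start - 1 : iv.end]
            for iv in merge_intervals(regions.intervals)
        ]
    if per_region:
        labels = []
        for c in contexts:
            if c:
                counts = Counter(c)
                # majority label; ties resolved in H, E, C order
                labels.append(max(SS_LABELS, key=lambda s: counts.get(s, 0)))
        tally = Counter(labels)
        total = len(labels)
    else:
        tally = Counter("".join(contexts))
        total = sum(tally.values())
    if total == 0:
        raise ValueError("no residues in context")
    return SsPreference(
        context=context,
        helix_pct=100.0 * tally.get("H", 0) / total,
        sheet_pct=100.0 * tally.get("E", 0) / total,
        coil_pct=100.0 * tally.get("C", 0) / total,
    )


def chou_fasman_baseline(record: ProteinRecord) -> str:
    """Deterministic per-residue H/E/C string from Chou-Fasman propensities.

    Argmax of (helix, sheet) propensity, coil when neither exceeds 1.0;
    ambiguity letters map to coil.  A crude baseline meant only as a
    stand-in when no external secondary-structure annotation is available.
    """
    out = []
    for aa in record.sequence:
        pa, pb = CHOU_FASMAN.get(aa, (0.0, 0.0))
        if pa <= 1.0 and pb <= 1.0:
            out.append("C")
        elif pa >= pb:
            out.append("H")
        else:
            out.append("E")
    return "".join(out)
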