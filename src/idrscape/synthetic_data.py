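"""Synthetic protein cohorts with planted, ground-truthed annotations.

The generator emulates the statistical structure the analysis pipeline
assumes about disordered-protein cohorts: protein lengths log-normal with a
median around 400 residues, per-protein disorder fractions spanning the
three disorder classes, low-complexity stretches with biased (Ser/Pro/Gly/
Ala-enriched) or homopolymeric composition whose lengths follow a truncated
heavy-tailed stable law, and amyloidogenic hexapeptide motifs detectable by
the bundled fixture scoring matrix.  Every planted feature is recorded as
ground truth so each pipeline stage can be scored without external data.

Default plant rates (about 4 amyloidogenic and 2.9 low-complexity regions
per protein) and the stable length law (0.92, 0.99, 14.99, 4.67) mirror the
cohort-level statistics of curated disordered human proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .amyloid_scan import Pssm, motif_pssm, write_pssm
from .cohort_stats import DisorderAnnotation, classify_protein, disorder_fraction
from .distribution_fit import StableParams, stable_rvs
from .region_algebra import Interval
from .seq_io import (
    ProteinRecord,
    RegionTableRow,
    STANDARD_AA,
    write_fasta,
    write_region_table,
)

# experimentally characterised amyloid-nucleating hexapeptides
DEFAULT_AR_MOTIFS = ("KLVFFA", "STVIIE", "VQIVYK", "NFGAIL")

# low-complexity composition bias: Ser/Pro/Gly/Ala enriched, remainder uniform
_LCR_BIAS = {"S": 0.131, "P": 0.121, "G": 0.098, "A": 0.092}

# average composition of well-characterised proteomes, used by the
# "realistic" background mode
_REALISTIC_BACKGROUND = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}


class SyntheticSpecError(ValueError):
    """Raised when a protein cannot accommodate its requested plants."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort-generation parameters; the defaults are the study conditions."""

    n_proteins: int = 200
    length_median: float = 400.0
    length_log_sigma: float = 0.45
    min_length: int = 60
    max_length: int = 4000
    class_mix: tuple[float, float, float] = (0.48, 0.26, 0.26)  # PDP, MDP, LDP
    ar_count_mean: float = 4.0
    ar_count_fixed: Optional[int] = None  # overrides the Poisson count law
    ar_motifs: tuple[str, ...] = DEFAULT_AR_MOTIFS
    lcr_count_mean: float = 2.9
    lcr_count_fixed: Optional[int] = None
    lcr_length_law: StableParams = field(
        default_factory=lambda: StableParams(0.92, 0.99, 14.99, 4.67)
    )
    lcr_min_length: int = 6
    lcr_mode: str = "biased"  # or "homopolymer"
    background: str = "uniform"  # or "realistic"
    min_gap: int = 7  # residues kept clear between planted regions
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.lcr_mode not in ("biased", "homopolymer"):
            raise ValueError(f"unknown lcr_mode {self.lcr_mode!r}")
        if self.background not in ("uniform", "realistic"):
            raise ValueError(f"unknown background {self.background!r}")


@dataclass(frozen=True)
class GroundTruthEntry:
    protein_id: str
    length: int
    class_label: str
    ar_intervals: tuple[Interval, ...]
    lcr_intervals: tuple[Interval, ...]
    disorder_intervals: tuple[Interval, ...]


@dataclass(frozen=True)
class SyntheticCohort:
    spec: SyntheticSpec
    records: tuple[ProteinRecord, ...]
    truth: tuple[GroundTruthEntry, ...]
    pssm: Pssm


_CLASS_BANDS = {"PDP": (2.0, 28.0), "MDP": (32.0, 68.0), "LDP": (72.0, 98.0)}


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    # per-protein stream: stable under changes of n_proteins up to the prefix
    return np.random.default_rng([seed, index])


def _background_probs(spec: SyntheticSpec) -> np.ndarray:
    if spec.background == "uniform":
        return np.full(20, 0.05)
    return np.array([_REALISTIC_BACKGROUND[aa] for aa in STANDARD_AA])


def _lcr_probs() -> np.ndarray:
    rest = (1.0 - sum(_LCR_BIAS.values())) / (20 - len(_LCR_BIAS))
    return np.array([_LCR_BIAS.get(aa, rest) for aa in STANDARD_AA])


def _draw_lcr_lengths(
    spec: SyntheticSpec, k: int, protein_length: int, rng: np.random.Generator
) -> list[int]:
    lo, hi = spec.lcr_min_length, max(spec.lcr_min_length, protein_length // 2)
    lengths = []
    for _ in range(k):
        value = None
        for _ in range(50):  # truncated stable draw
            cand = float(stable_rvs(spec.lcr_length_law, 1, rng)[0])
            if lo <= cand <= hi:
                value = cand
                break
        if value is None:
            value = float(np.clip(cand, lo, hi))
        lengths.append(int(round(value)))
    return lengths


def _place_segments(
    lengths: Sequence[int], protein_length: int, gap: int, rng: np.random.Generator
) -> list[int]:
    """Random non-overlapping starts (1-based) keeping >= gap between segments."""
    k = len(lengths)
    if k == 0:
        return []
    order = rng.permutation(k)
    shuffled = [lengths[i] for i in order]
    free = protein_length - sum(shuffled) - gap * (k - 1)
    if free < 0:
        raise SyntheticSpecError("segments do not fit")
    cuts = np.sort(rng.integers(0, free + 1, size=k))
    starts_shuffled = []
    pos = 1
    prev_cut = 0
    for i, length in enumerate(shuffled):
        pos += int(cuts[i] - prev_cut)
        prev_cut = int(cuts[i])
        starts_shuffled.append(pos)
        pos += length + gap
    starts = [0] * k
    for rank, original in enumerate(order):
        starts[original] = starts_shuffled[rank]
    return starts


def _plan_plants(
    spec: SyntheticSpec,
    protein_length: int,
    index: int,
    rng: np.random.Generator,
) -> tuple[list[str], list[int]]:
    """Motifs and LCR lengths that fit, dropping surplus LCRs then ARs."""
    ar_k = (
        spec.ar_count_fixed
        if spec.ar_count_fixed is not None
        else int(rng.poisson(spec.ar_count_mean))
    )
    lcr_k = (
        spec.lcr_count_fixed
        if spec.lcr_count_fixed is not None
        else int(rng.poisson(spec.lcr_count_mean))
    )
    motifs = [spec.ar_motifs[rng.integers(len(spec.ar_motifs))] for _ in range(ar_k)]
    if sum(len(m) for m in motifs) > protein_length:
        raise SyntheticSpecError(
            f"protein {index}: planted motifs exceed protein length "
            f"{protein_length}"
        )
    lcr_lengths = _draw_lcr_lengths(spec, lcr_k, protein_length, rng)

    def fits(motifs, lcrs):
        lens = [len(m) for m in motifs] + list(lcrs)
        return (
            not lens
            or sum(lens) + spec.min_gap * (len(lens) - 1) <= protein_length
        )

    while not fits(motifs, lcr_lengths):
        if lcr_lengths:
            # trim the longest stretch to the remaining room before giving
            # it up entirely (keeps the count law and most of the tail mass)
            largest = max(lcr_lengths)
            others = sum(len(m) for m in motifs) + sum(lcr_lengths) - largest
            k = len(motifs) + len(lcr_lengths)
            room = protein_length - others - spec.min_gap * (k - 1)
            if room >= spec.lcr_min_length:
                lcr_lengths[lcr_lengths.index(largest)] = room
            else:
                lcr_lengths.remove(largest)
        elif motifs:
            motifs.pop()
    return motifs, lcr_lengths


def _disorder_intervals(
    protein_length: int, target_pct: float, rng: np.random.Generator
) -> tuple[Interval, ...]:
    n_res = int(round(target_pct * protein_length / 100.0))
    if n_res <= 0:
        return ()
    n_res = min(n_res, protein_length)
    n_parts = int(rng.integers(1, 4))
    n_parts = min(n_parts, n_res)
    # partition n_res into n_parts positive pieces
    if n_parts > 1:
        cuts = np.sort(rng.choice(np.arange(1, n_res), size=n_parts - 1, replace=False))
        pieces = np.diff(np.concatenate([[0], cuts, [n_res]])).tolist()
    else:
        pieces = [n_res]
    try:
        starts = _place_segments(pieces, protein_length, 1, rng)
    except SyntheticSpecError:
        return (Interval(1, n_res),)
    ivs = sorted(Interval(s, s + l - 1) for s, l in zip(starts, pieces))
    return tuple(ivs)


def generate_protein(
    spec: SyntheticSpec, index: int
) -> tuple[ProteinRecord, GroundTruthEntry]:
    """Generate one protein and its ground truth from its own seeded stream."""
    rng = _protein_rng(spec.seed, index)
    length = int(
        np.clip(
            round(rng.lognormal(np.log(spec.length_median), spec.length_log_sigma)),
            spec.min_length,
            spec.max_length,
        )
    )
    label = ("PDP", "MDP", "LDP")[
        rng.choice(3, p=np.asarray(spec.class_mix))
    ]
    lo, hi = _CLASS_BANDS[label]
    target_pct = float(rng.uniform(lo, hi))

    motifs, lcr_lengths = _plan_plants(spec, length, index, rng)
    segment_lengths = [len(m) for m in motifs] + lcr_lengths
    starts = _place_segments(segment_lengths, length, spec.min_gap, rng)

    aa = np.array(list(STANDARD_AA))
    seq = rng.choice(aa, size=length, p=_background_probs(spec))
    ar_ivs, lcr_ivs = [], []
    for j, motif in enumerate(motifs):
        s = starts[j]
        seq[s - 1 : s - 1 + len(motif)] = list(motif)
        ar_ivs.append(Interval(s, s + len(motif) - 1))
    lcr_probs = _lcr_probs()
    for j, lcr_len in enumerate(lcr_lengths):
        s = starts[len(motifs) + j]
        if spec.lcr_mode == "homopolymer":
            stretch = np.repeat(rng.choice(aa), lcr_len)
        else:
            stretch = rng.choice(aa, size=lcr_len, p=lcr_probs)
        seq[s - 1 : s - 1 + lcr_len] = stretch
        lcr_ivs.append(Interval(s, s + lcr_len - 1))

    pid = f"SYN{index:05d}"
    record = ProteinRecord(id=pid, sequence="".join(seq), source="synthetic")
    truth = GroundTruthEntry(
        protein_id=pid,
        length=length,
        class_label=label,
        ar_intervals=tuple(sorted(ar_ivs)),
        lcr_intervals=tuple(sorted(lcr_ivs)),
        disorder_intervals=_disorder_intervals(length, target_pct, rng),
    )
    return record, truth


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate the full cohort; byte-deterministic for a fixed seed."""
    records, truth = [], []
    for i in range(spec.n_proteins):
        rec, gt = generate_protein(spec, i)
        records.append(rec)
        truth.append(gt)
    return SyntheticCohort(
        spec=spec,
        records=tuple(records),
        truth=tuple(truth),
        pssm=motif_pssm(spec.ar_motifs),
    )


def class_of_truth(entry: GroundTruthEntry) -> str:
    """Disorder class implied by the planted disorder intervals."""
    ann = DisorderAnnotation(entry.protein_id, entry.disorder_intervals)
    return classify_protein(disorder_fraction(ann, entry.length))


def _truth_rows(cohort: SyntheticCohort, which: str, kind: str):
    rows = []
    by_id = {r.id: r for r in cohort.records}
    for gt in cohort.truth:
        for iv in getattr(gt, which):
            rows.append(
                RegionTableRow(
                    protein_id=gt.protein_id,
                    kind=kind,
                    start=iv.start,
                    end=iv.end,
                    subsequence=by_id[gt.protein_id].slice(iv.start, iv.end),
                )
            )
    return rows


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Emit cohort.fa, ar_truth.tsv, lcr_truth.tsv, disorder.tsv,
    pssm_fixture.tsv and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "cohort.fa",
        "ar_truth": out / "ar_truth.tsv",
        "lcr_truth": out / "lcr_truth.tsv",
        "disorder": out / "disorder.tsv",
        "pssm": out / "pssm_fixture.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(cohort.records, paths["fasta"])
    write_region_table(_truth_rows(cohort, "ar_intervals", "AR"), paths["ar_truth"])
    write_region_table(_truth_rows(cohort, "lcr_intervals", "LCR"), paths["lcr_truth"])
    write_region_table(
        _truth_rows(cohort, "disorder_intervals", "DISORDER"), paths["disorder"]
    )
    write_pssm(cohort.pssm, paths["pssm"])
    blob = [
        {
            "protein_id": gt.protein_id,
            "length": gt.length,
            "class_label": gt.class_label,
            "ar_intervals": [[iv.start, iv.end] for iv in gt.ar_intervals],
            "lcr_intervals": [[iv.start, iv.end] for iv in gt.lcr_intervals],
            "disorder_intervals": [
                [iv.start, iv.end] for iv in gt.disorder_intervals
            ],
        }
        for gt in cohort.truth
    ]
    paths["truth"].write_text(json.dumps(blob, indent=1, sort_keys=True))
    return paths
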