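"""Hexapeptide PSSM scanning for amyloidogenic regions.

A scoring matrix assigns a weight to every standard residue at each of six
window positions; a window's score is the sum of its six position weights and
windows scoring at or above the threshold qualify.  Qualifying windows are
unioned residue-wise and maximal runs become amyloidogenic-region intervals
(minimum length 6, by construction).  The matrix is pluggable: any 6x20 TSV
with the residue alphabet as header is accepted, and a documented fixture
matrix built from experimentally known amyloidogenic hexapeptides ships with
the synthetic-data generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .region_algebra import Interval, RegionSet
from .seq_io import ProteinRecord, STANDARD_AA

HEXAMER = 6


@dataclass(frozen=True)
class Pssm:
    """6-position x 20-residue additive scoring matrix."""

    alphabet: tuple[str, ...]
    weights: np.ndarray  # shape (6, 20)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(sorted(self.alphabet)) != tuple(sorted(STANDARD_AA)):
            raise ValueError("PSSM alphabet must cover the 20 standard residues")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (HEXAMER, len(self.alphabet)):
            raise ValueError(f"PSSM weights must be 6x20, got {w.shape}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(
            self, "_index", {aa: i for i, aa in enumerate(self.alphabet)}
        )

    def weight(self, position: int, residue: str) -> float:
        """Weight of ``residue`` (0-based window ``position``)."""
        return float(self.weights[position, self._index[residue]])


@dataclass(frozen=True)
class HexamerHit:
    protein_id: str
    start: int  # 1-based window start
    score: float
    window_seq: str


class AmbiguousWindowError(ValueError):
    """Window contains a non-standard residue and cannot be scored."""


def score_window(pssm: Pssm, hexamer: str) -> float:
    """Additive score of one 6-residue window."""
    if len(hexamer) != HEXAMER:
        raise ValueError(f"window must have {HEXAMER} residues, got {len(hexamer)}")
    hexamer = hexamer.upper()
    bad = set(hexamer) - set(STANDARD_AA)
    if bad:
        raise AmbiguousWindowError(
            f"window {hexamer!r} contains non-standard residues {sorted(bad)}"
        )
    return float(sum(pssm.weight(p, hexamer[p]) for p in range(HEXAMER)))


def scan_hits(record: ProteinRecord, pssm: Pssm) -> list[HexamerHit]:
    """Score every standard-residue hexapeptide window of the protein.

    Windows containing ambiguity letters are skipped (not scored).
    """
    hits = []
    for start in range(1, record.length - HEXAMER + 2):
        window = record.sequence[start - 1 : start - 1 + HEXAMER]
        try:
            score = score_window(pssm, window)
        except AmbiguousWindowError:
            continue
        hits.append(HexamerHit(record.id, start, score, window))
    return hits


def scan_sequence(
    record: ProteinRecord, pssm: Pssm, threshold: float
) -> RegionSet:
    """Amyloidogenic regions: maximal runs of residues covered by qualifying
    windows (score >= threshold).  Per-region peak window score is kept in
    ``peak_scores``."""
    if record.length < HEXAMER:
        warnings.warn(
            f"{record.id}: length {record.length} < {HEXAMER}; no scan",
            stacklevel=2,
        )
        return RegionSet(record.id, "AR", ())
    qualifying = [h for h in scan_hits(record, pssm) if h.score >= threshold]
    mask = np.zeros(record.length + 1, dtype=bool)  # 1-based
    peak = np.full(record.length + 1, -np.inf)
    for h in qualifying:
        mask[h.start : h.start + HEXAMER] = True
        sl = slice(h.start, h.start + HEXAMER)
        peak[sl] = np.maximum(peak[sl], h.score)
    intervals: list[Interval] = []
    peaks: list[float] = []
    pos = 1
    while pos <= record.length:
        if mask[pos]:
            end = pos
            while end + 1 <= record.length and mask[end + 1]:
                end += 1
            intervals.append(Interval(pos, end))
            peaks.append(float(peak[pos : end + 1].max()))
            pos = end + 1
        else:
            pos += 1
    return RegionSet(
        protein_id=record.id,
        kind="AR",
        intervals=tuple(intervals),
        peak_scores=tuple(peaks),
    )


def read_pssm(path: str | Path, thresholds: Optional[dict] = None) -> Pssm:
    """Read a 6x20 TSV (header = alphabet, one row per window position)."""
    df = pd.read_csv(path, sep="\t")
    alphabet = tuple(str(c) for c in df.columns)
    return Pssm(
        alphabet=alphabet,
        weights=df.to_numpy(dtype=float),
        thresholds=dict(thresholds or {}),
    )


def write_pssm(pssm: Pssm, path: str | Path) -> None:
    pd.DataFrame(pssm.weights, columns=list(pssm.alphabet)).to_csv(
        path, sep="\t", index=False
    )


def motif_pssm(
    motifs: Iterable[str], match_weight: float = 1.0, mismatch_weight: float = -1.0
) -> Pssm:
    """Build a matrix from a motif list: a residue scores ``match_weight`` at
    position p when some motif carries it there, else ``mismatch_weight``.

    With the defaults, a window reaches score 6 exactly when every position
    is drawn from the motif alphabet at that position, so any listed motif
    qualifies at threshold 6 while chance qualification stays rare.
    """
    weights = np.full((HEXAMER, 20), mismatch_weight, dtype=float)
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    for motif in motifs:
        motif = motif.upper()
        if len(motif) != HEXAMER:
            raise ValueError(f"motif {motif!r} is not a hexapeptide")
        for p, aa in enumerate(motif):
            weights[p, index[aa]] = match_weight
    return Pssm(
        alphabet=tuple(STANDARD_AA),
        weights=weights,
        thresholds={"best_overall": HEXAMER * match_weight},
    )
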