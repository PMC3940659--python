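"""Low-complexity region detection by windowed compositional entropy.

The engine follows the classical two-cutoff segmentation scheme: a sliding
window of W residues is scored by its Shannon entropy (bits); windows at or
below the trigger cutoff seed candidate regions, which extend through any
contiguous run of windows at or below the (looser) extension cutoff.  The
residue span of each run is then optionally refined to the contiguous
subsequence of length >= W whose residue composition has minimal multinomial
probability under a uniform 20-letter background — a single-pass reduction,
not the original recursive optimal-segment search.

Default parameters are the canonical triple W=12, trigger 2.2 bits,
extension 2.5 bits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .region_algebra import Interval, RegionSet, merge_intervals
from .seq_io import ProteinRecord, STANDARD_AA

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
_LOG20 = math.log(20.0)


@dataclass(frozen=True)
class SegParams:
    """Segmentation parameters (entropies in bits)."""

    window: int = 12
    trigger_entropy: float = 2.2
    extension_entropy: float = 2.5
    refine: bool = True

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.trigger_entropy > self.extension_entropy:
            raise ValueError("trigger_entropy must be <= extension_entropy")


@dataclass(frozen=True)
class ComplexityProfile:
    """Per-window entropies, one value per window start (1-based).

    Windows containing ambiguity letters carry NaN and never seed or extend
    a region.
    """

    protein_id: str
    window: int
    window_entropies: np.ndarray  # shape (L - window + 1,)


def window_entropy(window_seq: str) -> float:
    """Shannon entropy H = -sum (n_i/W) log2 (n_i/W) of a residue window."""
    if not window_seq:
        raise ValueError("empty window")
    counts = np.bincount(
        [_AA_INDEX[aa] for aa in window_seq.upper()], minlength=20
    )
    w = counts.sum()
    p = counts[counts > 0] / w
    return float(-(p * np.log2(p)).sum())


def complexity_profile(record: ProteinRecord, params: SegParams) -> ComplexityProfile:
    """Sliding-window entropies at every start position, step 1."""
    w = params.window
    L = record.length
    if L < w:
        warnings.warn(
            f"{record.id}: length {L} < window {w}; empty profile",
            stacklevel=2,
        )
        return ComplexityProfile(record.id, w, np.empty(0))
    codes = np.array([_AA_INDEX.get(aa, -1) for aa in record.sequence])
    n_win = L - w + 1
    ent = np.full(n_win, np.nan)
    # incremental count update across consecutive windows
    counts = np.zeros(20, dtype=np.int64)
    n_bad = int((codes[:w] < 0).sum())
    for c in codes[:w]:
        if c >= 0:
            counts[c] += 1
    for i in range(n_win):
        if i > 0:
            out_c, in_c = codes[i - 1], codes[i + w - 1]
            if out_c >= 0:
                counts[out_c] -= 1
            else:
                n_bad -= 1
            if in_c >= 0:
                counts[in_c] += 1
            else:
                n_bad += 1
        if n_bad == 0:
            p = counts[counts > 0] / w
            ent[i] = -(p * np.log2(p)).sum()
    return ComplexityProfile(record.id, w, ent)


def _refine_stretch(seq: str, start: int, end: int, window: int) -> Interval:
    """Minimal-composition-probability contiguous sub-window of [start, end].

    The probability of a composition (n_1..n_20) of size W under the uniform
    background is P = W!/(prod n_i!) * 20^-W.  Raw P decreases with W for
    almost any composition, which makes the longest sub-window win by
    default, so the criterion is normalised per residue: the sub-window of
    length >= window minimising log(P)/W is returned (ties: longest, then
    leftmost).  On a homopolymeric core this keeps exactly the core, since
    every pure sub-run scores -log 20 per residue and ties resolve longest.
    """
    sub = seq[start - 1 : end]
    S = len(sub)
    codes = [_AA_INDEX[aa] for aa in sub]
    tol = 1e-9  # scores this close count as tied (guards float drift on pure runs)
    best_score, best_len, best_i, best_j = math.inf, 0, -1, -1
    for i in range(S - window + 1):
        counts = np.zeros(20, dtype=np.int64)
        logp = 0.0
        for j in range(i, S):
            c = codes[j]
            w_len = j - i + 1
            # logP(i, j) = logP(i, j-1) + log(w_len) - log(n_c + 1) - log 20
            logp += math.log(w_len) - math.log(counts[c] + 1) - _LOG20
            counts[c] += 1
            if w_len < window:
                continue
            score = logp / w_len
            if score < best_score - tol or (
                score <= best_score + tol
                and (w_len > best_len or (w_len == best_len and i < best_i))
            ):
                best_score, best_len, best_i, best_j = score, w_len, i, j
    return Interval(start + best_i, start + best_j)


def detect_lcr(record: ProteinRecord, params: SegParams | None = None) -> RegionSet:
    """Detect low-complexity regions on one protein.

    Returns a :class:`RegionSet` of kind LCR; proteins shorter than the
    window contribute no regions.
    """
    params = params or SegParams()
    w = params.window
    profile = complexity_profile(record, params)
    ent = profile.window_entropies
    intervals: list[Interval] = []

    def runs_within(lo: int, hi: int) -> list[Interval]:
        """Residue spans of extension-qualifying window runs that contain a
        trigger seed, restricted to windows fully inside residues [lo, hi]."""
        spans = []
        i = lo - 1          # 0-based window index of first window at residue lo
        last = hi - w       # last window index fully inside [lo, hi]
        while i <= last:
            h = ent[i]
            if np.isnan(h) or h > params.extension_entropy:
                i += 1
                continue
            j = i
            while j + 1 <= last and not np.isnan(ent[j + 1]) and (
                ent[j + 1] <= params.extension_entropy
            ):
                j += 1
            window_ents = ent[i : j + 1]
            if np.nanmin(window_ents) <= params.trigger_entropy:
                spans.append(Interval(i + 1, j + w))
            i = j + 1
        return spans

    def segment(lo: int, hi: int) -> None:
        """Locate qualifying stretches in [lo, hi]; refine each to its
        lowest-probability core and recurse on the flanking remainders, so a
        stretch harbouring several distinct biased cores yields them all."""
        if hi - lo + 1 < w:
            return
        for span in runs_within(lo, hi):
            if not params.refine:
                intervals.append(span)
                continue
            core = _refine_stretch(record.sequence, span.start, span.end, w)
            intervals.append(core)
            segment(span.start, core.start - 1)
            segment(core.end + 1, span.end)

    if ent.size:
        segment(1, record.length)
    return RegionSet(
        protein_id=record.id, kind="LCR", intervals=tuple(merge_intervals(intervals))
    )
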