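"""Curated worked examples: known disordered and amyloidogenic proteins with
published region annotations.

These small annotation tables (protein lengths plus 1-based inclusive AR/LCR
intervals) come from curated analyses of well-characterised disordered human
proteins and experimentally validated amyloidogenic proteins.  Each entry
carries the content percentage as printed in the curation, against which the
package's interval arithmetic can be checked end to end: integer-rounded
percentages for the disordered-protein panel, two-decimal percentages for
the amyloidogenic panel.  Only internally consistent entries (where the
printed percentage agrees with the printed intervals under half-up rounding)
are included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .region_algebra import RegionSet, region_set

# amyloid-beta 1-42, the 42-residue Alzheimer peptide; its two amyloidogenic
# hexapeptides KLVFFA (16-21) and GGVVIA (37-42) are classic scanner targets
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"


@dataclass(frozen=True)
class WorkedExample:
    protein_id: str
    length: int
    lcr: tuple[tuple[int, int], ...]
    ar: tuple[tuple[int, int], ...]
    lcr_pct_printed: Optional[float]  # None when the curated value is unusable
    ar_pct_printed: Optional[float]
    decimals: int  # presentation rounding used by the curation

    def lcr_set(self) -> RegionSet:
        return region_set(self.protein_id, "LCR", self.lcr)

    def ar_set(self) -> RegionSet:
        return region_set(self.protein_id, "AR", self.ar)


# Disordered human proteins; percentages printed to 0 decimals.
DISORDERED_PANEL: tuple[WorkedExample, ...] = (
    WorkedExample("DP00016", 164, ((81, 96),), (), 10, 0, 0),
    WorkedExample("DP00039", 89, ((2, 19), (29, 65)), (), 62, 0, 0),
    WorkedExample(
        "DP00040", 107, ((2, 9), (23, 34), (54, 68), (71, 106)), (), 66, 0, 0
    ),
    WorkedExample("DP00069", 116, ((3, 24), (97, 112)), ((101, 116),), 33, 14, 0),
    WorkedExample("DP00070", 140, ((10, 23), (63, 78)), ((35, 40),), 21, 4, 0),
    WorkedExample(
        "DP00126", 441, ((129, 153), (172, 223)), ((274, 279),), 17, 1, 0
    ),
    WorkedExample("DP00174", 149, (), ((19, 23),), 0, 3, 0),
    WorkedExample(
        "DP00199",
        226,
        ((3, 15), (17, 31), (41, 53), (82, 96), (139, 159), (196, 205)),
        (),
        38,
        0,
        0,
    ),
    WorkedExample("DP00214", 314, ((81, 131), (272, 282)), (), 20, 0, 0),
    WorkedExample("DP00219", 126, ((10, 22), (72, 83), (105, 125)), (), 37, 0, 0),
    WorkedExample(
        "DP00287", 213, ((10, 57),), ((72, 76), (147, 158)), 23, 8, 0
    ),
    WorkedExample(
        "DP00332",
        317,
        ((62, 106), (145, 173), (207, 234), (252, 267), (302, 314)),
        ((310, 317),),
        41,
        3,
        0,
    ),
    WorkedExample("DP00372", 106, (), ((7, 12), (35, 40), (66, 71)), 0, 17, 0),
    WorkedExample("DP00521", 202, ((163, 173),), ((2, 7),), 5, 3, 0),
    WorkedExample(
        "DP00546", 175, ((16, 34), (116, 133)), ((167, 175),), 21, 5, 0
    ),
    WorkedExample("DP00592", 62, (), ((42, 47),), 0, 10, 0),
    WorkedExample("DP00617", 70, ((12, 22), (38, 51)), (), 36, 0, 0),
    WorkedExample("DP00630", 127, ((65, 82), (106, 125)), (), 30, 0, 0),
    WorkedExample("Abeta42", 42, (), ((16, 21), (37, 42)), 0, 29, 0),
)

# Experimentally validated amyloidogenic proteins; percentages printed to
# 2 decimals.
AMYLOID_PANEL: tuple[WorkedExample, ...] = (
    WorkedExample("P01308", 110, ((2, 24),), ((36, 42), (99, 110)), 20.91, None, 2),
    WorkedExample("P02647", 267, (), ((8, 15),), None, 3.00, 2),
    WorkedExample(
        "P27986",
        724,
        ((79, 102), (303, 314), (533, 548)),
        ((72, 78), (263, 269), (290, 296), (331, 336), (401, 406), (483, 495)),
        7.18,
        None,
        2,
    ),
    WorkedExample("P10636", 441, (), ((274, 279),), None, 1.36, 2),
    WorkedExample(
        "P01034",
        146,
        ((2, 33),),
        ((10, 20), (56, 61), (84, 92), (124, 130)),
        21.92,
        22.60,
        2,
    ),
    WorkedExample(
        "P06654",
        448,
        ((69, 114), (241, 253), (379, 413), (427, 442)),
        (),
        24.55,
        None,
        2,
    ),
    WorkedExample(
        "P04156",
        253,
        ((50, 94), (113, 135), (188, 201), (237, 252)),
        ((8, 17), (171, 176), (178, 185), (222, 227), (231, 235), (240, 253)),
        38.74,
        None,
        2,
    ),
    WorkedExample(
        "P05453",
        685,
        ((5, 64), (68, 113), (130, 142), (164, 209), (241, 253), (398, 410)),
        (),
        27.88,
        None,
        2,
    ),
)

WORKED_EXAMPLES: tuple[WorkedExample, ...] = DISORDERED_PANEL + AMYLOID_PANEL


@dataclass(frozen=True)
class OverlapExample:
    """An AR x LCR pair with its published intersection."""

    protein_id: str
    ar: tuple[int, int]
    lcr: tuple[int, int]
    overlap: tuple[int, int]


OVERLAP_EXAMPLES: tuple[OverlapExample, ...] = (
    OverlapExample("DP00069", (101, 116), (97, 112), (101, 112)),   # 12 residues
    OverlapExample("DP00332", (310, 317), (302, 314), (310, 314)),  # GQNYY
    OverlapExample("DP00119", (28, 33), (2, 29), (28, 29)),
    OverlapExample("DP00551", (12, 22), (10, 22), (12, 22)),
    OverlapExample("DP00643_A002", (126, 138), (122, 136), (126, 136)),
    OverlapExample("DP00683", (210, 225), (210, 224), (210, 224)),
    OverlapExample("P01034", (10, 20), (2, 33), (10, 20)),
)
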