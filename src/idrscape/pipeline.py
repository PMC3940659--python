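"""End-to-end orchestration: annotate -> summarize -> fit -> report.

A run takes a FASTA cohort plus either region annotation tables or the
bundled engines (entropy segmentation for LCRs, PSSM scanning for ARs),
derives per-protein summaries, disorder-class aggregates, overlap catalogs,
composition and secondary-structure profiles, and distributional fits, and
writes everything as TSV/JSON into an output directory.  Outputs carry no
timestamps, so identical configuration and seed give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amyloid_scan import Pssm, read_pssm, scan_sequence
from .cohort_stats import (
    DEFAULT_CLASS_BOUNDS,
    DisorderAnnotation,
    build_protein_summary,
    chou_fasman_baseline,
    class_summary_frame,
    composition_profile,
    ss_preference,
    summarize_class,
)
from .distribution_fit import (
    discrete_summary,
    fit_hyperbolic,
    fit_stable,
    kde2d,
    welch_ttest,
)
from .lcr_seg import SegParams, detect_lcr
from .region_algebra import RegionSet, overlap_catalog, region_set
from .seq_io import read_fasta, read_region_table

logger = logging.getLogger("idrscape")

SUMMARY_COLUMNS = [
    "protein_id",
    "length",
    "disorder_pct",
    "ar_pct",
    "lcr_pct",
    "ar_count",
    "lcr_count",
    "overlap_count",
    "class_label",
    "n_terminal_ars",
    "c_terminal_ars",
    "amyloidogenic",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    fasta: str
    out_dir: str
    ar_table: Optional[str] = None
    lcr_table: Optional[str] = None
    disorder_table: Optional[str] = None
    ss_fasta: Optional[str] = None
    pssm: Optional[str] = None
    scan_threshold: float = 6.0
    use_seg: bool = True
    seg: SegParams = field(default_factory=SegParams)
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
    terminal_margin: int = 15
    stable_method: str = "quantile"  # "mle" for the slower refined fit
    min_fit_samples: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seg" in raw:
            raw["seg"] = SegParams(**raw["seg"])
        if "class_bounds" in raw:
            raw["class_bounds"] = tuple(raw["class_bounds"])
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise ConfigurationError(f"FASTA not found: {self.fasta}")
        if self.ar_table is None and self.pssm is None:
            raise ConfigurationError(
                "no AR source: provide ar_table or a pssm for the scanner"
            )
        if self.lcr_table is None and not self.use_seg:
            raise ConfigurationError(
                "no LCR source: provide lcr_table or enable the SEG engine"
            )
        if not (0 < self.class_bounds[0] < self.class_bounds[1] < 100):
            raise ConfigurationError(
                f"class boundaries must be ordered within (0, 100): "
                f"{self.class_bounds}"
            )
        for path in (self.ar_table, self.lcr_table, self.disorder_table,
                     self.ss_fasta, self.pssm):
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"input not found: {path}")


def _regions_from_table(path: str, records, kind: str) -> dict[str, RegionSet]:
    rows = read_region_table(path, records)
    by_id: dict[str, list] = {}
    for row in rows:
        if row.kind == kind:
            by_id.setdefault(row.protein_id, []).append((row.start, row.end))
    return {pid: region_set(pid, kind, ivs) for pid, ivs in by_id.items()}


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(x, nd))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to
    ``out_dir/report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_fasta(config.fasta)
    logger.info("read %d proteins from %s", len(records), config.fasta)

    pssm: Optional[Pssm] = read_pssm(config.pssm) if config.pssm else None

    ar_sets: dict[str, RegionSet] = (
        _regions_from_table(config.ar_table, records, "AR")
        if config.ar_table
        else {}
    )
    lcr_sets: dict[str, RegionSet] = (
        _regions_from_table(config.lcr_table, records, "LCR")
        if config.lcr_table
        else {}
    )
    disorder: dict[str, DisorderAnnotation] = {}
    if config.disorder_table:
        for pid, rs in _regions_from_table(
            config.disorder_table, records, "DISORDER"
        ).items():
            disorder[pid] = DisorderAnnotation(pid, rs.intervals)
    ss: dict[str, str] = {}
    if config.ss_fasta:
        for rec_id, seq in _read_ss_fasta(config.ss_fasta).items():
            ss[rec_id] = seq

    summaries = []
    failures = 0
    per_protein_ar: dict[str, RegionSet] = {}
    per_protein_lcr: dict[str, RegionSet] = {}
    overlaps = []
    for rec in records:
        try:
            ars = ar_sets.get(rec.id)
            if ars is None:
                if pssm is None:
                    ars = region_set(rec.id, "AR", ())
                else:
                    ars = scan_sequence(rec, pssm, config.scan_threshold)
            lcrs = lcr_sets.get(rec.id)
            if lcrs is None:
                if config.use_seg:
                    lcrs = detect_lcr(rec, config.seg)
                else:
                    lcrs = region_set(rec.id, "LCR", ())
            summaries.append(
                build_protein_summary(
                    rec,
                    ars,
                    lcrs,
                    disorder.get(rec.id),
                    terminal_margin=config.terminal_margin,
                    class_bounds=config.class_bounds,
                )
            )
            per_protein_ar[rec.id] = ars
            per_protein_lcr[rec.id] = lcrs
            overlaps.extend(overlap_catalog(ars, lcrs))
        except Exception:
            logger.exception("protein %s failed; skipped", rec.id)
            failures += 1

    # --- per-protein summary table
    summary_df = pd.DataFrame(
        [
            {
                **{k: getattr(s, k) for k in SUMMARY_COLUMNS if k != "amyloidogenic"},
                "amyloidogenic": s.amyloidogenic,
            }
            for s in summaries
        ],
        columns=SUMMARY_COLUMNS,
    )
    for col in ("disorder_pct", "ar_pct", "lcr_pct"):
        if len(summary_df):
            summary_df[col] = summary_df[col].map(lambda v: _round(v))
    summary_df.to_csv(out / "summaries.tsv", sep="\t", index=False)

    class_summary_frame(summarize_class(summaries)).to_csv(
        out / "class_summary.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [
            {
                "protein_id": o.protein_id,
                "ar_start": o.ar.start,
                "ar_end": o.ar.end,
                "lcr_start": o.lcr.start,
                "lcr_end": o.lcr.end,
                "overlap_start": o.overlap.start,
                "overlap_end": o.overlap.end,
                "overlap_length": o.overlap_length,
            }
            for o in overlaps
        ],
        columns=[
            "protein_id", "ar_start", "ar_end", "lcr_start", "lcr_end",
            "overlap_start", "overlap_end", "overlap_length",
        ],
    ).to_csv(out / "overlaps.tsv", sep="\t", index=False)

    # --- composition profiles (whole / AR / LCR contexts)
    comp_rows = []
    if records:
        contexts = [("WHOLE", None), ("AR", per_protein_ar), ("LCR", per_protein_lcr)]
        for name, regions in contexts:
            try:
                prof = composition_profile(records, regions, context=name)
            except ValueError:
                continue
            comp_rows.append({"context": name, **{
                aa: _round(v) for aa, v in prof.freqs.items()
            }})
    pd.DataFrame(comp_rows).to_csv(out / "composition.tsv", sep="\t", index=False)

    # --- secondary-structure preferences (annotation or propensity baseline)
    ss_rows = []
    if records:
        ss_source = "annotation" if ss else "chou_fasman_baseline"
        ann = {
            rec.id: ss.get(rec.id, chou_fasman_baseline(rec)) for rec in records
        }
        for name, regions in (
            ("WHOLE", None), ("AR", per_protein_ar), ("LCR", per_protein_lcr)
        ):
            h = e = c = n = 0.0
            for rec in records:
                rs = None if regions is None else regions.get(rec.id)
                if regions is not None and (rs is None or len(rs) == 0):
                    continue
                try:
                    pref = ss_preference(ann[rec.id], rec.length, rs, context=name)
                except ValueError:
                    continue
                weight = (
                    rec.length
                    if rs is None
                    else sum(iv.length for iv in rs.intervals)
                )
                h += pref.helix_pct * weight
                e += pref.sheet_pct * weight
                c += pref.coil_pct * weight
                n += weight
            if n:
                ss_rows.append(
                    {
                        "context": name,
                        "source": ss_source,
                        "helix_pct": _round(h / n),
                        "sheet_pct": _round(e / n),
                        "coil_pct": _round(c / n),
                    }
                )
    pd.DataFrame(ss_rows).to_csv(out / "ss_preference.tsv", sep="\t", index=False)

    # --- distribution fits
    fits = _fit_block(summaries, per_protein_ar, per_protein_lcr, config)
    (out / "fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True))

    report = {
        "version": __version__,
        "n_proteins": len(records),
        "n_summarized": len(summaries),
        "n_failed": failures,
        "n_overlap_records": len(overlaps),
        "parameters": {
            "scan_threshold": config.scan_threshold,
            "seg_window": config.seg.window,
            "seg_trigger_entropy": config.seg.trigger_entropy,
            "seg_extension_entropy": config.seg.extension_entropy,
            "seg_refine": config.seg.refine,
            "class_bounds": list(config.class_bounds),
            "terminal_margin": config.terminal_margin,
            "stable_method": config.stable_method,
            "seed": config.seed,
            "ar_source": "table" if config.ar_table else "scanner",
            "lcr_source": "table" if config.lcr_table else "seg",
            "ss_source": "annotation" if ss else "chou_fasman_baseline",
        },
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "report.json"
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _fit_block(summaries, ar_sets, lcr_sets, config: PipelineConfig) -> dict:
    """Stable/discrete/hyperbolic/Welch layer of the run, as a JSON-able dict."""
    fits: dict = {}
    ar_pct = [s.ar_pct for s in summaries if s.ar_count > 0]
    lcr_pct = [s.lcr_pct for s in summaries if s.lcr_count > 0]
    ar_len = [iv.length for rs in ar_sets.values() for iv in rs.intervals]
    lcr_len = [iv.length for rs in lcr_sets.values() for iv in rs.intervals]
    for name, values in (
        ("ar_pct", ar_pct), ("lcr_pct", lcr_pct),
        ("ar_len", ar_len), ("lcr_len", lcr_len),
    ):
        block: dict = {"n": len(values)}
        if values:
            d = discrete_summary(values)
            block["discrete"] = {
                "min": _round(d.minimum), "max": _round(d.maximum),
                "mean": _round(d.mean), "median": _round(d.median),
                "mode": _round(d.mode),
            }
        if len(values) >= config.min_fit_samples and np.ptp(values) > 0:
            p = fit_stable(values, method=config.stable_method)
            block["stable"] = {
                "alpha": _round(p.alpha), "beta": _round(p.beta),
                "mu": _round(p.mu), "sigma": _round(p.sigma),
            }
        fits[name] = block
    # content vs length correlation (negative hyperbolic), per region kind
    for name, pct_attr, count_attr in (
        ("ar_pct_vs_length", "ar_pct", "ar_count"),
        ("lcr_pct_vs_length", "lcr_pct", "lcr_count"),
    ):
        pairs = [
            (s.length, getattr(s, pct_attr))
            for s in summaries
            if getattr(s, count_attr) > 0
        ]
        if len(pairs) >= 3 and len({x for x, _ in pairs}) >= 2:
            x, y = zip(*pairs)
            h = fit_hyperbolic(x, y)
            fits[name] = {
                "a": _round(h.a), "b": _round(h.b),
                "r_squared": _round(h.r_squared), "n": len(pairs),
            }
            if len(pairs) >= 4 and np.std(y) > 0:
                surf = kde2d(x, y)
                fits[name]["kde_bandwidths"] = [
                    _round(surf.bandwidths[0]), _round(surf.bandwidths[1])
                ]
    # pairwise class comparisons of content percentages
    tests = {}
    for metric in ("ar_pct", "lcr_pct"):
        by_class: dict[str, list[float]] = {}
        for s in summaries:
            by_class.setdefault(s.class_label, []).append(getattr(s, metric))
        labels = sorted(by_class)
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                a, b = by_class[la], by_class[lb]
                if len(a) >= 2 and len(b) >= 2 and (np.ptp(a) or np.ptp(b)):
                    w = welch_ttest(a, b)
                    tests[f"{metric}:{la}_vs_{lb}"] = {
                        "t": _round(w.t_statistic),
                        "df": _round(w.degrees_of_freedom),
                        "p": _round(w.p_value, 9),
                        "n_a": len(a),
                        "n_b": len(b),
                    }
    if tests:
        fits["welch_tests"] = tests
    return fits


def _read_ss_fasta(path: str | Path) -> dict[str, str]:
    """FASTA-like records over the H/E/C alphabet."""
    out: dict[str, str] = {}
    current = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current is not None:
                out[current] = "".join(chunks)
            current = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.upper())
    if current is not None:
        out[current] = "".join(chunks)
    return out
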