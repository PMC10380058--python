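"""End-to-end pipeline orchestration and reporting.

``run_pipeline`` wires the stages in study order — encode, QC, score,
compare, tertile odds ratios — and returns a :class:`RunReport` that can be
serialised as JSON/TSV plus a plain-text summary mirroring the structure of
a published results section: per-group mean +/- SD and range, omnibus
F(df1, df2), pairwise t(df), high-vs-low tertile ORs with CIs, and the list
of HWE-deviating loci. Histogram bin counts over integer score bins are
included in place of rendered figures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .compare import (
    ComparisonResult,
    ORResult,
    compare_groups,
    tertile_or,
    tertile_split,
)
from .genotypes import EncodedMatrix, GenotypeMatrix, encode
from .panel import Panel
from .qc import QCReport, apply_qc
from .scoring import ScoreTable, score_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_summary"]


@dataclass
class PipelineConfig:
    """Thresholds and policy knobs for a pipeline run (study defaults)."""

    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_alpha: float | None = None
    min_completeness: float = 0.9
    tertile_basis: str = "pooled"  # or "per-comparison"
    strand_flip: bool = False
    seed: int | None = None


@dataclass
class RunReport:
    config: PipelineConfig
    qc: QCReport
    scores: ScoreTable
    comparisons: dict[str, ComparisonResult]          # keyed "tgs"/"twgs"
    odds_ratios: dict[str, list[ORResult]]            # keyed "tgs"/"twgs"
    tertile_cuts: dict[str, tuple[float, float]]
    histograms: dict[str, dict[str, dict[int, int]]]  # score -> group -> bin -> count
    version: str = __version__

    def to_json(self) -> str:
        def _or(o: ORResult) -> dict:
            return asdict(o)

        obj = {
            "version": self.version,
            "config": asdict(self.config),
            "qc": {
                "failed_loci": self.qc.failed_loci,
                "failed_samples": self.qc.failed_samples,
                "hwe_deviating_loci": [
                    {"rsid": r, "hwe_p": p} for r, p in self.qc.hwe_deviating_loci
                ],
            },
            "groups": {},
            "comparisons": {},
            "odds_ratios": {k: [_or(o) for o in v] for k, v in self.odds_ratios.items()},
            "tertile_cuts": {k: list(v) for k, v in self.tertile_cuts.items()},
            "histograms": {
                sf: {g: {str(b): c for b, c in bins.items()}
                     for g, bins in by_group.items()}
                for sf, by_group in self.histograms.items()
            },
            "excluded_samples": [
                {"sample_id": s, "reason": r} for s, r in self.scores.excluded
            ],
        }
        for sf, comp in self.comparisons.items():
            obj["comparisons"][sf] = {
                "omnibus": asdict(comp.omnibus),
                "pairwise": [asdict(pt) for pt in comp.pairwise],
            }
            obj["groups"][sf] = [asdict(g) for g in comp.groups]
        return json.dumps(obj, indent=1)

    def comparisons_tsv(self) -> str:
        lines = ["score\tkind\tgroup_a\tgroup_b\tstatistic\tdf1\tdf2\tp\tmean_diff"]
        for sf, comp in self.comparisons.items():
            o = comp.omnibus
            lines.append(f"{sf}\tomnibus_F\t-\t-\t{o.F:.6g}\t{o.df1}\t{o.df2}\t{o.p:.6g}\t-")
            for t in comp.pairwise:
                lines.append(
                    f"{sf}\tpairwise_t\t{t.group_a}\t{t.group_b}\t{t.t:.6g}"
                    f"\t{t.df}\t-\t{t.p:.6g}\t{t.mean_diff:.6g}"
                )
        return "\n".join(lines) + "\n"

    def odds_ratios_tsv(self) -> str:
        lines = ["score\tgroup_a\tgroup_b\ta_high\ta_low\tb_high\tb_low"
                 "\tor\tci_low\tci_high\tcorrected"]
        for sf, ors in self.odds_ratios.items():
            for o in ors:
                lines.append(
                    f"{sf}\t{o.group_a}\t{o.group_b}\t{o.a_high}\t{o.a_low}"
                    f"\t{o.b_high}\t{o.b_low}\t{o.or_value:.6g}"
                    f"\t{o.ci_low:.6g}\t{o.ci_high:.6g}\t{o.corrected}"
                )
        return "\n".join(lines) + "\n"

    def histograms_tsv(self) -> str:
        lines = ["score\tgroup\tbin\tcount"]
        for sf, by_group in self.histograms.items():
            for g, bins in by_group.items():
                for b in sorted(bins):
                    lines.append(f"{sf}\t{g}\t{b}\t{bins[b]}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report.json": out / "report.json",
            "scores.tsv": out / "scores.tsv",
            "qc_loci.tsv": out / "qc_loci.tsv",
            "qc_samples.tsv": out / "qc_samples.tsv",
            "comparisons.tsv": out / "comparisons.tsv",
            "odds_ratios.tsv": out / "odds_ratios.tsv",
            "histograms.tsv": out / "histograms.tsv",
            "summary.txt": out / "summary.txt",
        }
        paths["report.json"].write_text(self.to_json(), encoding="utf-8")
        self.scores.write(paths["scores.tsv"])
        self.qc.write(paths["qc_loci.tsv"], paths["qc_samples.tsv"])
        paths["comparisons.tsv"].write_text(self.comparisons_tsv(), encoding="utf-8")
        paths["odds_ratios.tsv"].write_text(self.odds_ratios_tsv(), encoding="utf-8")
        paths["histograms.tsv"].write_text(self.histograms_tsv(), encoding="utf-8")
        paths["summary.txt"].write_text(render_summary(self), encoding="utf-8")
        return paths


def _histogram(values: np.ndarray) -> dict[int, int]:
    """Counts per integer score bin (value rounded to nearest integer)."""
    bins: dict[int, int] = {}
    for v in np.rint(values).astype(int):
        bins[v] = bins.get(v, 0) + 1
    return bins


def run_pipeline(
    gm: GenotypeMatrix,
    panel: Panel,
    groups: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run encode -> QC -> score -> compare -> tertile ORs on a cohort.

    Loci failing QC are excluded from scoring (they still appear in the QC
    report); samples failing the sample call-rate filter are dropped before
    scoring. Comparisons and odds ratios are computed for both TGS and TWGS.
    """
    config = config or PipelineConfig()
    em = encode(gm, panel, strand_flip=config.strand_flip)
    qc = apply_qc(
        em, maf_min=config.maf_min, call_rate_min=config.call_rate_min,
        hwe_alpha=config.hwe_alpha,
    )
    failed_loci = set(qc.failed_loci)
    failed_samples = set(qc.failed_samples)
    if failed_loci:
        logger.info("run_pipeline: excluding %d locus/loci after QC", len(failed_loci))
        em = em.drop_loci(failed_loci)
    if failed_samples:
        logger.info("run_pipeline: excluding %d sample(s) after QC", len(failed_samples))
        keep = [i for i, s in enumerate(em.sample_ids) if s not in failed_samples]
        em = EncodedMatrix(
            sample_ids=[em.sample_ids[i] for i in keep],
            locus_ids=list(em.locus_ids),
            scores=em.scores[keep],
            mismatch_count=em.mismatch_count,
            mismatch_by_locus=dict(em.mismatch_by_locus),
        )
    scores = score_cohort(
        em, panel, groups, min_completeness=config.min_completeness
    )
    comparisons: dict[str, ComparisonResult] = {}
    odds_ratios: dict[str, list[ORResult]] = {}
    tertile_cuts: dict[str, tuple[float, float]] = {}
    histograms: dict[str, dict[str, dict[int, int]]] = {}
    labels = scores.groups
    sample_groups = {r.sample_id: r.group for r in scores.records}
    for sf in ("tgs", "twgs"):
        by_group = {g: scores.values(sf, g) for g in labels}
        comparisons[sf] = compare_groups(by_group, score_field=sf)
        score_map = {r.sample_id: getattr(r, sf) for r in scores.records}
        ors: list[ORResult] = []
        if config.tertile_basis == "pooled":
            split = tertile_split(score_map, basis="pooled")
            tertile_cuts[sf] = (split.lower_cut, split.upper_cut)
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    ors.append(tertile_or(split, sample_groups, a, b))
        else:
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    pair_scores = {
                        s: v for s, v in score_map.items()
                        if sample_groups[s] in (a, b)
                    }
                    split = tertile_split(pair_scores, basis="per-comparison")
                    tertile_cuts[f"{sf}:{a}-vs-{b}"] = (split.lower_cut, split.upper_cut)
                    ors.append(tertile_or(split, sample_groups, a, b))
        odds_ratios[sf] = ors
        histograms[sf] = {g: _histogram(by_group[g]) for g in labels}
    return RunReport(
        config=config, qc=qc, scores=scores, comparisons=comparisons,
        odds_ratios=odds_ratios, tertile_cuts=tertile_cuts, histograms=histograms,
    )


def render_summary(report: RunReport) -> str:
    """Plain-text summary in the shape of a published results section.

    Display rounding: means/SDs to 1 dp, statistics to 2 dp, ORs and CIs to
    2 dp, p-values to 3 dp. The JSON report keeps full precision.
    """
    lines: list[str] = []
    sf_names = {"tgs": "TGS", "twgs": "TWGS"}
    dev = report.qc.hwe_deviating_loci
    if dev:
        devs = ", ".join(f"{r} (p = {p:.3f})" for r, p in dev)
        lines.append(f"Loci deviating from HWE (exact p < 0.05): {devs}.")
    else:
        lines.append("All loci were in HWE (exact p >= 0.05).")
    if report.qc.failed_loci:
        lines.append(
            f"Excluded after QC: {len(report.qc.failed_loci)} locus/loci "
            f"({', '.join(report.qc.failed_loci)})."
        )
    for sf, comp in report.comparisons.items():
        name = sf_names.get(sf, sf)
        lines.append("")
        ranges = "; ".join(
            f"{g.label} {g.min:.0f} to {g.max:.0f}" for g in comp.groups
        )
        lines.append(f"The {name} ranged from {ranges}.")
        o = comp.omnibus
        lines.append(
            f"Between-group {name} differences: F ({o.df1}, {o.df2}) = "
            f"{o.F:.2f}, p = {o.p:.3f}."
        )
        for g in comp.groups:
            lines.append(f"Mean {name} of {g.label}: {g.mean:.1f} ± {g.sd:.2f} (n = {g.n}).")
        for t in comp.pairwise:
            lines.append(
                f"{t.group_a} vs {t.group_b}: t ({t.df}) = {t.t:.2f}, p = {t.p:.3f}."
            )
        cuts = report.tertile_cuts.get(sf)
        if cuts is not None:
            lines.append(
                f"Tertile cuts ({name}, pooled): lower {cuts[0]:.1f}, upper {cuts[1]:.1f}."
            )
        for orr in report.odds_ratios.get(sf, []):
            lines.append(
                f"Odds of a {name} in the higher vs lower third, {orr.group_a} "
                f"relative to {orr.group_b}: OR = {orr.or_value:.2f}, "
                f"CI: {orr.ci_low:.2f}-{orr.ci_high:.2f}."
            )
    return "\n".join(lines) + "\n"
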