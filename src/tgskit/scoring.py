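"""Total genotype scores on the 0-100 scale.

TGS is the sum of per-locus 0/1/2 scores divided by its maximum (2 per typed
locus), times 100; TWGS weights each locus score by its GWAS effect size
``beta`` before normalising:

    TGS  = 100 * sum(s_j) / (2 * m)
    TWGS = 100 * sum(beta_j * s_j) / (2 * sum(beta_j))

with both sums over the m loci typed in the sample. Missing loci drop out of
numerator and denominator alike, which keeps the 0-100 scale comparable
across samples; a completeness gate excludes samples typed at too few loci
for that rescaling to be trustworthy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedStatisticError
from .genotypes import EncodedMatrix
from .panel import Panel

logger = logging.getLogger(__name__)

__all__ = ["SampleScore", "ScoreTable", "tgs", "twgs", "score_cohort"]


@dataclass(frozen=True)
class SampleScore:
    sample_id: str
    group: str
    tgs: float
    twgs: float
    n_typed: int
    completeness: float


@dataclass
class ScoreTable:
    """Per-sample TGS/TWGS records plus the exclusions the gate produced."""

    records: list[SampleScore]
    excluded: list[tuple[str, str]]  # (sample_id, reason)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    def values(self, score_field: str, group: str | None = None) -> np.ndarray:
        if score_field not in ("tgs", "twgs"):
            raise ValueError(f"score_field must be 'tgs' or 'twgs', got {score_field!r}")
        return np.array([
            getattr(r, score_field)
            for r in self.records
            if group is None or r.group == group
        ])

    def group_labels(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    def to_tsv(self) -> str:
        lines = ["sample_id\tgroup\ttgs\ttwgs\tn_typed\tcompleteness"]
        for r in self.records:
            lines.append(
                f"{r.sample_id}\t{r.group}\t{r.tgs!r}\t{r.twgs!r}"
                f"\t{r.n_typed}\t{r.completeness:.6g}"
            )
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv(), encoding="utf-8")


def tgs(scores: Sequence[float] | np.ndarray) -> float:
    """Unweighted total genotype score of one sample, scaled to 0-100."""
    s = np.asarray(scores, dtype=float)
    typed = s[~np.isnan(s)]
    if typed.size == 0:
        raise UndefinedStatisticError("TGS undefined: no typed loci")
    return float(100.0 * typed.sum() / (2.0 * typed.size))


def twgs(scores: Sequence[float] | np.ndarray, betas: Sequence[float] | np.ndarray) -> float:
    """Beta-weighted total genotype score of one sample, scaled to 0-100."""
    s = np.asarray(scores, dtype=float)
    b = np.asarray(betas, dtype=float)
    if s.shape != b.shape:
        raise ValueError(f"scores ({s.shape}) and betas ({b.shape}) are misaligned")
    if (b < 0).any():
        raise ValueError("betas must be non-negative")
    typed = ~np.isnan(s)
    denom = b[typed].sum()
    if not typed.any() or denom <= 0.0:
        raise UndefinedStatisticError(
            "TWGS undefined: no typed loci with positive weight"
        )
    return float(100.0 * (b[typed] * s[typed]).sum() / (2.0 * denom))


def score_cohort(
    em: EncodedMatrix,
    panel: Panel,
    groups: Mapping[str, str],
    min_completeness: float = 0.9,
) -> ScoreTable:
    """Score every sample in a cohort against a panel.

    ``groups`` maps sample id to group label; every sample in the matrix must
    be labelled. Completeness is the fraction of *panel* loci typed in the
    sample (so loci dropped from the matrix, e.g. by QC, count against it);
    samples below ``min_completeness`` are excluded and logged.
    """
    for rsid in em.locus_ids:
        if rsid not in panel:
            raise ConfigurationError(f"matrix locus {rsid} absent from panel {panel.name!r}")
    unlabelled = [sid for sid in em.sample_ids if sid not in groups]
    if unlabelled:
        raise ConfigurationError(
            f"{len(unlabelled)} sample(s) lack a group label, e.g. {unlabelled[0]!r}"
        )
    betas = np.array([panel[rsid].beta for rsid in em.locus_ids])
    n_panel = len(panel)
    records: list[SampleScore] = []
    excluded: list[tuple[str, str]] = []
    for i, sid in enumerate(em.sample_ids):
        row = em.scores[i]
        n_typed = int((~np.isnan(row)).sum())
        completeness = n_typed / n_panel
        if completeness < min_completeness:
            reason = (
                f"completeness {completeness:.3f} < {min_completeness:g} "
                f"({n_typed}/{n_panel} panel loci typed)"
            )
            logger.info("score_cohort: excluding %s: %s", sid, reason)
            excluded.append((sid, reason))
            continue
        records.append(SampleScore(
            sample_id=sid,
            group=groups[sid],
            tgs=tgs(row),
            twgs=twgs(row, betas),
            n_typed=n_typed,
            completeness=completeness,
        ))
    return ScoreTable(records=records, excluded=excluded)
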