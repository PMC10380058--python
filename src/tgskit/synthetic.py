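"""Synthetic genotype cohorts drawn under Hardy-Weinberg proportions.

The generator emulates a case-control style study: groups of unrelated
individuals genotyped at the panel loci, with each genotype drawn
independently per locus from HWE proportions at a per-group earlier-allele
frequency p — P(score 2) = p^2, P(1) = 2p(1-p), P(0) = (1-p)^2, i.e. the
0/1/2 score is Binomial(2, p). Uniform missingness can be layered on top.
Loci are independent (no linkage disequilibrium), which matches the additive
independence the total-genotype-score model itself assumes.

``paper_like_spec`` builds a cohort spec mirroring the reference study
design: groups CON / U12-16 / U17-23 of 240 / 86 / 73 samples at the
bundled panel's per-group frequencies. The published table proves per-SNP
allele orientation is mixed (group mean scores near 43-45 are incompatible
with the minor allele being uniformly earlier or uniformly later), and the
true orientations are not recoverable from it — so orientation is an
explicit required argument, never a silent default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeMatrix
from .panel import BUNDLED_GROUPS, Panel, bundled_panel

__all__ = [
    "CohortSpec",
    "simulate_cohort",
    "expected_scores",
    "paper_like_spec",
    "STUDY_GROUP_SIZES",
]

#: Reference study design: 240 European controls and two academy age phases.
STUDY_GROUP_SIZES: dict[str, int] = {"CON": 240, "U12-16": 86, "U17-23": 73}


@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    ``freqs`` maps each group label to its per-locus earlier-allele frequency
    vector, aligned to the panel the cohort will be simulated against.
    """

    groups: list[tuple[str, int]]
    freqs: dict[str, list[float]]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort spec needs at least one group")
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} has n={n} < 1")
            if label not in self.freqs:
                raise ValueError(f"group {label!r} has no frequency vector")
        for label, vec in self.freqs.items():
            arr = np.asarray(vec, dtype=float)
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"group {label!r}: frequencies must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")

    def to_json(self) -> str:
        return json.dumps({
            "groups": [{"label": l, "n": n} for l, n in self.groups],
            "freqs": self.freqs,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        obj = json.loads(text)
        return cls(
            groups=[(g["label"], int(g["n"])) for g in obj["groups"]],
            freqs={k: list(map(float, v)) for k, v in obj["freqs"].items()},
            missing_rate=float(obj.get("missing_rate", 0.0)),
            seed=int(obj.get("seed", 0)),
        )


def simulate_genotype_scores(
    spec: CohortSpec, n_loci: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], list[str]]:
    """Draw the 0/1/2 score matrix (NaN for missing) plus sample ids/labels."""
    blocks = []
    sample_ids: list[str] = []
    labels: list[str] = []
    for label, n in spec.groups:
        p = np.asarray(spec.freqs[label], dtype=float)
        if p.size != n_loci:
            raise ValueError(
                f"group {label!r}: frequency vector length {p.size} != panel size {n_loci}"
            )
        scores = rng.binomial(2, p, size=(n, n_loci)).astype(float)
        blocks.append(scores)
        sample_ids += [f"{label}_{i + 1:04d}" for i in range(n)]
        labels += [label] * n
    scores = np.vstack(blocks)
    if spec.missing_rate > 0.0:
        mask = rng.random(scores.shape) < spec.missing_rate
        scores[mask] = np.nan
    return scores, sample_ids, labels


def simulate_cohort(
    spec: CohortSpec, panel: Panel
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Simulate raw allele calls for a cohort under HWE.

    Returns the genotype matrix (panel loci in panel order) and the
    sample-to-group label map. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    scores, sample_ids, labels = simulate_genotype_scores(spec, len(panel), rng)
    calls = np.full(scores.shape, "", dtype="U2")
    for j, entry in enumerate(panel):
        e, l = entry.earlier_allele, entry.later_allele
        col = scores[:, j]
        calls[col == 2.0, j] = e + e
        calls[col == 1.0, j] = e + l
        calls[col == 0.0, j] = l + l
    gm = GenotypeMatrix(sample_ids=sample_ids, locus_ids=list(panel.rsids), calls=calls)
    return gm, dict(zip(sample_ids, labels))


def expected_scores(
    freqs: Sequence[float], betas: Sequence[float]
) -> dict[str, float]:
    """Analytic expected TGS/TWGS for a group under HWE.

    With E[s_j] = 2 p_j, the expectations are
    e_tgs = 100 * mean(p_j) and e_twgs = 100 * sum(beta_j p_j) / sum(beta_j).
    """
    p = np.asarray(freqs, dtype=float)
    b = np.asarray(betas, dtype=float)
    if p.size == 0:
        raise ValueError("expected_scores needs at least one locus")
    if p.shape != b.shape:
        raise ValueError("freqs and betas are misaligned")
    return {
        "e_tgs": float(100.0 * p.mean()),
        "e_twgs": float(100.0 * (b * p).sum() / b.sum()),
    }


def paper_like_spec(
    orientation: Mapping[str, bool],
    seed: int = 0,
    missing_rate: float = 0.0,
    panel: Panel | None = None,
) -> CohortSpec:
    """Cohort spec mirroring the reference study design on the bundled panel.

    ``orientation`` maps every panel rsid to ``minor_is_earlier``: when True
    the group's earlier-allele frequency is its reference MAF, otherwise
    1 - MAF. Orientation must be supplied explicitly because the true
    per-SNP orientations live in external GWAS summary statistics.
    """
    panel = panel if panel is not None else bundled_panel()
    missing = [e.rsid for e in panel if e.rsid not in orientation]
    if missing:
        raise ValueError(
            f"orientation map lacks {len(missing)} panel locus/loci, "
            f"e.g. {missing[0]!r}"
        )
    freqs: dict[str, list[float]] = {}
    for group in BUNDLED_GROUPS:
        maf = panel.ref_freq_vector(group)
        freqs[group] = [
            m if orientation[rsid] else 1.0 - m
            for rsid, m in zip(panel.rsids, maf)
        ]
    return CohortSpec(
        groups=[(g, STUDY_GROUP_SIZES[g]) for g in BUNDLED_GROUPS],
        freqs=freqs,
        missing_rate=missing_rate,
        seed=seed,
    )
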