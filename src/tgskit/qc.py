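"""Per-locus and per-sample quality control.

Implements the study-style inclusion filters — minor-allele frequency
strictly above 0.05 and call rate strictly above 95% — plus the exact
conditional Hardy-Weinberg test. HWE deviations are flagged and recorded
but do not exclude loci by default, matching pipelines that report (rather
than drop) deviating SNPs; pass ``hwe_alpha`` to make the test exclusionary.

The exact HWE test conditions on the observed minor-allele count: given
``n`` typed diploids and ``n_a`` copies of the minor allele, the number of
heterozygotes under random mating follows

    P(n_het | n, n_a) = n! / (n_AA! n_Aa! n_aa!) * 2**n_het / C(2n, n_a)

over heterozygote counts with the parity of ``n_a``. The two-sided p-value
is the total probability of all outcomes no more probable than the observed
one. Probabilities are accumulated in log space so the test is stable for
cohorts of tens of thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import UndefinedStatisticError
from .genotypes import EncodedMatrix

__all__ = [
    "LocusCounts",
    "LocusQC",
    "SampleQC",
    "QCReport",
    "tabulate",
    "minor_allele_freq",
    "locus_call_rate",
    "hwe_exact_p",
    "apply_qc",
]


@dataclass(frozen=True)
class LocusCounts:
    """Genotype-class counts at one locus: earlier-hom / het / later-hom."""

    n_hom_earlier: int
    n_het: int
    n_hom_later: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hom_earlier, self.n_het, self.n_hom_later, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_typed(self) -> int:
        return self.n_hom_earlier + self.n_het + self.n_hom_later

    @property
    def n_total(self) -> int:
        return self.n_typed + self.n_missing


@dataclass(frozen=True)
class LocusQC:
    rsid: str
    counts: LocusCounts
    maf: float | None
    locus_call_rate: float
    hwe_p: float | None
    fail_reasons: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    sample_call_rate: float
    fail_reasons: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


@dataclass
class QCReport:
    """Per-locus and per-sample QC results with the thresholds applied."""

    loci: list[LocusQC]
    samples: list[SampleQC]
    maf_min: float
    call_rate_min: float
    hwe_alpha: float | None = None

    @property
    def failed_loci(self) -> list[str]:
        return [l.rsid for l in self.loci if not l.passed]

    @property
    def failed_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if not s.passed]

    @property
    def hwe_deviating_loci(self) -> list[tuple[str, float]]:
        """Loci with exact-HWE p < 0.05, for reporting (not exclusion)."""
        return [
            (l.rsid, l.hwe_p)
            for l in self.loci
            if l.hwe_p is not None and l.hwe_p < 0.05
        ]

    def loci_tsv(self) -> str:
        lines = ["rsid\tn_hom_earlier\tn_het\tn_hom_later\tn_missing\tmaf\t"
                 "call_rate\thwe_p\tpass\tfail_reasons"]
        for l in self.loci:
            c = l.counts
            lines.append("\t".join([
                l.rsid, str(c.n_hom_earlier), str(c.n_het), str(c.n_hom_later),
                str(c.n_missing),
                "NA" if l.maf is None else f"{l.maf:.6g}",
                f"{l.locus_call_rate:.6g}",
                "NA" if l.hwe_p is None else f"{l.hwe_p:.6g}",
                str(l.passed), ";".join(l.fail_reasons),
            ]))
        return "\n".join(lines) + "\n"

    def samples_tsv(self) -> str:
        lines = ["sample_id\tcall_rate\tpass\tfail_reasons"]
        for s in self.samples:
            lines.append("\t".join([
                s.sample_id, f"{s.sample_call_rate:.6g}", str(s.passed),
                ";".join(s.fail_reasons),
            ]))
        return "\n".join(lines) + "\n"

    def write(self, loci_path: str | Path, samples_path: str | Path) -> None:
        Path(loci_path).write_text(self.loci_tsv(), encoding="utf-8")
        Path(samples_path).write_text(self.samples_tsv(), encoding="utf-8")


def tabulate(em: EncodedMatrix, rsid: str) -> LocusCounts:
    """Count genotype classes (2 / 1 / 0 / missing) in one matrix column."""
    col = em.locus_column(rsid)
    missing = int(np.isnan(col).sum())
    return LocusCounts(
        n_hom_earlier=int((col == 2.0).sum()),
        n_het=int((col == 1.0).sum()),
        n_hom_later=int((col == 0.0).sum()),
        n_missing=missing,
    )


def minor_allele_freq(c: LocusCounts) -> float:
    """Minor-allele frequency from genotype counts, in [0, 0.5]."""
    if c.n_typed == 0:
        raise UndefinedStatisticError("MAF undefined: zero typed genotypes")
    p = (2 * c.n_hom_earlier + c.n_het) / (2 * c.n_typed)
    return min(p, 1.0 - p)


def locus_call_rate(c: LocusCounts) -> float:
    if c.n_total == 0:
        return 0.0
    return c.n_typed / c.n_total


@lru_cache(maxsize=100_000)
def _hwe_exact_p_from_counts(n_typed: int, n_minor: int, n_het_obs: int) -> float:
    """Exact conditional HWE p given typed count, minor-allele count, observed hets."""
    # feasible het counts share the parity of n_minor and satisfy
    # n_het <= min(n_minor, 2n - n_minor)
    n_major = 2 * n_typed - n_minor
    het_max = min(n_minor, n_major)
    hets = np.arange(n_minor % 2, het_max + 1, 2)
    # log P(h) = log n! - log s! - log h! - log t! + h log 2 - log C(2n, n_a)
    # with s = (n_minor - h)/2 minor homs, t = n - s - h major homs
    s = (n_minor - hets) // 2
    t = n_typed - s - hets
    log_p = (
        gammaln(n_typed + 1)
        - gammaln(s + 1)
        - gammaln(hets + 1)
        - gammaln(t + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n_typed + 1) - gammaln(n_minor + 1) - gammaln(n_major + 1))
    )
    obs_idx = np.nonzero(hets == n_het_obs)[0]
    assert obs_idx.size == 1, "observed het count infeasible given allele counts"
    log_obs = log_p[obs_idx[0]]
    # probability-mass two-sided p: sum outcomes no more probable than observed;
    # the tolerance absorbs float noise in mathematically tied outcomes.
    # Self-normalising by the total (exactly 1 in exact arithmetic) cancels
    # the shared rounding error of the log-factorial constant.
    include = log_p <= log_obs + 1e-9
    log_total = logsumexp(log_p)
    return float(min(1.0, np.exp(logsumexp(log_p[include]) - log_total)))


def hwe_exact_p(c: LocusCounts) -> float:
    """Two-sided exact Hardy-Weinberg p-value (probability-mass convention).

    Conditions on the observed allele counts; monomorphic loci have a single
    feasible outcome and return exactly 1. Stable for n up to at least 10^4
    via log-space accumulation.
    """
    if c.n_typed == 0:
        raise UndefinedStatisticError("HWE test undefined: zero typed genotypes")
    n_minor = 2 * c.n_hom_earlier + c.n_het
    n_major = 2 * c.n_hom_later + c.n_het
    if n_minor > n_major:
        n_minor = n_major
    if n_minor == 0:
        return 1.0
    return _hwe_exact_p_from_counts(c.n_typed, n_minor, c.n_het)


def apply_qc(
    em: EncodedMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_alpha: float | None = None,
) -> QCReport:
    """Apply the inclusion filters to every locus and sample.

    A locus passes only if MAF > ``maf_min`` AND call rate > ``call_rate_min``
    (strict inequalities); a sample passes only if its call rate >
    ``call_rate_min``. The exact HWE p is recorded for every polymorphic
    locus; it causes failure only when ``hwe_alpha`` is set and p <
    ``hwe_alpha``.
    """
    if em.n_samples == 0 or em.n_loci == 0:
        raise ValueError("apply_qc requires a non-empty matrix")
    loci: list[LocusQC] = []
    for rsid in em.locus_ids:
        counts = tabulate(em, rsid)
        rate = locus_call_rate(counts)
        reasons: list[str] = []
        if counts.n_typed == 0:
            maf: float | None = None
            hwe_p: float | None = None
            reasons.append("no typed genotypes")
        else:
            maf = minor_allele_freq(counts)
            hwe_p = hwe_exact_p(counts)
            if not maf > maf_min:
                reasons.append(f"MAF {maf:.4g} <= {maf_min:g}")
            if hwe_alpha is not None and hwe_p < hwe_alpha:
                reasons.append(f"HWE p {hwe_p:.4g} < {hwe_alpha:g}")
        if not rate > call_rate_min:
            reasons.append(f"call rate {rate:.4g} <= {call_rate_min:g}")
        loci.append(LocusQC(
            rsid=rsid, counts=counts, maf=maf, locus_call_rate=rate,
            hwe_p=hwe_p, fail_reasons=tuple(reasons),
        ))
    samples: list[SampleQC] = []
    typed_per_sample = (~np.isnan(em.scores)).sum(axis=1)
    for i, sid in enumerate(em.sample_ids):
        rate = typed_per_sample[i] / em.n_loci
        reasons = [] if rate > call_rate_min else [
            f"call rate {rate:.4g} <= {call_rate_min:g}"
        ]
        samples.append(SampleQC(
            sample_id=sid, sample_call_rate=float(rate), fail_reasons=tuple(reasons)
        ))
    return QCReport(
        loci=loci, samples=samples, maf_min=maf_min,
        call_rate_min=call_rate_min, hwe_alpha=hwe_alpha,
    )
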