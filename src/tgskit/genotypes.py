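"""Genotype containers, file I/O, and co-dominant 0/1/2 encoding.

A :class:`GenotypeMatrix` holds raw allele-pair calls per sample x locus; a
:class:`EncodedMatrix` holds their co-dominant encoding against a panel:
homozygous for the earlier-maturity (effect) allele = 2, heterozygous = 1,
homozygous for the alternate allele = 0. Missing propagates as NaN. Calls
carrying an allele matching neither panel allele (typically strand flips in
array data) become missing and are tallied, not raised.

Supported formats: VCF 4.x (GT subfield, loci matched by the ID column) and
a simple genotype TSV dialect with one row per sample, one column per rsID,
cells like ``AG`` or ``--`` for missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .errors import ConfigurationError, GenotypeParseError
from .panel import Panel

logger = logging.getLogger(__name__)

#: Sentinel used in the TSV dialect for a missing call.
MISSING_CELL = "--"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid allele pair; ``None`` alleles mean a missing call.

    Half-calls are not representable: either both alleles are present or the
    call is wholly missing, because the co-dominant model is undefined on a
    single allele.
    """

    allele1: str | None
    allele2: str | None

    def __post_init__(self) -> None:
        if (self.allele1 is None) != (self.allele2 is None):
            raise ValueError("half-calls are not allowed; use a fully missing call")

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(None, None)


@dataclass
class GenotypeMatrix:
    """Raw allele calls for samples x loci.

    ``calls`` is a 2-D object/str array of shape (n_samples, n_loci) holding
    two-character strings like ``"AG"``, with ``""`` for missing.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="U2")
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def call(self, sample_id: str, rsid: str) -> GenotypeCall:
        i = self.sample_ids.index(sample_id)
        j = self.locus_ids.index(rsid)
        cell = str(self.calls[i, j])
        if cell == "":
            return GenotypeCall.missing()
        return GenotypeCall(cell[0], cell[1])


@dataclass
class EncodedMatrix:
    """Co-dominant 0/1/2 scores for samples x loci; NaN marks missing.

    ``mismatch_count`` tallies calls whose alleles matched neither panel
    allele and were therefore set missing during encoding.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    scores: np.ndarray
    mismatch_count: int = 0
    mismatch_by_locus: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError("scores shape does not match sample/locus ids")
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("encoded scores must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def locus_column(self, rsid: str) -> np.ndarray:
        try:
            j = self.locus_ids.index(rsid)
        except ValueError:
            raise KeyError(f"rsid {rsid!r} not in matrix") from None
        return self.scores[:, j]

    def drop_loci(self, rsids: set[str]) -> "EncodedMatrix":
        """A copy without the given loci (used to drop QC failures)."""
        keep = [j for j, r in enumerate(self.locus_ids) if r not in rsids]
        return EncodedMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[j] for j in keep],
            scores=self.scores[:, keep].copy(),
            mismatch_count=self.mismatch_count,
            mismatch_by_locus=dict(self.mismatch_by_locus),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the genotype TSV dialect.

    First column ``sample_id``, remaining columns rsIDs; cells are
    two-character allele pairs (``AG``) or ``--`` for missing.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty genotype TSV")
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise GenotypeParseError(f"{path}: first column must be 'sample_id', got {header[0]!r}")
    locus_ids = header[1:]
    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for row_no, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"{path}: line {row_no} has {len(fields)} fields, expected {len(header)}"
            )
        sample_ids.append(fields[0])
        row = []
        for col, cell in zip(locus_ids, fields[1:]):
            if cell == MISSING_CELL:
                row.append("")
            elif len(cell) == 2:
                row.append(cell)
            else:
                raise GenotypeParseError(
                    f"{path}: malformed genotype cell {cell!r} at sample "
                    f"{fields[0]!r} (line {row_no}), locus {col!r}"
                )
        rows.append(row)
    calls = np.array(rows, dtype="U2") if rows else np.empty((0, len(locus_ids)), dtype="U2")
    return GenotypeMatrix(sample_ids=sample_ids, locus_ids=locus_ids, calls=calls)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix in the genotype TSV dialect (inverse of the reader)."""
    path = Path(path)
    lines = ["\t".join(["sample_id"] + list(gm.locus_ids))]
    for i, sid in enumerate(gm.sample_ids):
        cells = [str(c) if c else MISSING_CELL for c in gm.calls[i]]
        lines.append("\t".join([sid] + cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vcf(path: str | Path, panel: Panel) -> GenotypeMatrix:
    """Read GT calls for panel loci from a VCF, matched by the ID column.

    The returned matrix has one column per panel locus in panel order; loci
    absent from the file are wholly missing (logged). Multi-allelic records
    at panel loci are set missing with a warning. Phased and unphased
    separators are both accepted; half-calls collapse to missing.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise GenotypeParseError(f"{path}: cannot read VCF: {exc}") from None
    with vcf:
        sample_ids = list(vcf.header.samples)
        locus_ids = list(panel.rsids)
        col = {r: j for j, r in enumerate(locus_ids)}
        calls = np.full((len(sample_ids), len(locus_ids)), "", dtype="U2")
        seen: set[str] = set()
        try:
            for rec in vcf:
                rsid = rec.id
                if rsid is None or rsid not in col:
                    continue
                if rsid in seen:
                    logger.warning("%s: duplicate record for %s; keeping first", path, rsid)
                    continue
                seen.add(rsid)
                alts = rec.alts or ()
                if len(alts) > 1:
                    logger.warning(
                        "%s: multi-allelic record at panel locus %s; set missing", path, rsid
                    )
                    continue
                alleles = rec.alleles  # (ref, alt?) strings
                j = col[rsid]
                for i, sid in enumerate(sample_ids):
                    gt = rec.samples[sid].get("GT")
                    if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                        continue
                    try:
                        a1, a2 = alleles[gt[0]], alleles[gt[1]]
                    except IndexError:
                        raise GenotypeParseError(
                            f"{path}: GT index out of range at {rsid}, sample {sid}"
                        ) from None
                    if len(a1) != 1 or len(a2) != 1:
                        continue  # indel alleles cannot be encoded
                    calls[i, j] = a1 + a2
        except (OSError, ValueError) as exc:
            raise GenotypeParseError(f"{path}: malformed VCF record: {exc}") from None
    for rsid in locus_ids:
        if rsid not in seen:
            logger.warning("%s: panel locus %s absent from VCF; set missing", path, rsid)
    return GenotypeMatrix(sample_ids=sample_ids, locus_ids=locus_ids, calls=calls)


def write_vcf(gm: GenotypeMatrix, panel: Panel, path: str | Path) -> None:
    """Write a matrix as a minimal VCF (placeholder positions, rsIDs as IDs).

    The panel's earlier allele is written as REF and the later allele as ALT;
    this is a plumbing convention, not a genome-build claim.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add("chrU", length=2 ** 29)
    for sid in gm.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, rsid in enumerate(gm.locus_ids):
            entry = panel[rsid]
            ref, alt = entry.earlier_allele, entry.later_allele
            rec = out.new_record(
                contig="chrU", start=j, alleles=(ref, alt), id=rsid
            )
            for i, sid in enumerate(gm.sample_ids):
                cell = str(gm.calls[i, j])
                if not cell:
                    rec.samples[sid]["GT"] = (None, None)
                    continue
                idx = []
                ok = True
                for a in cell:
                    if a == ref:
                        idx.append(0)
                    elif a == alt:
                        idx.append(1)
                    else:
                        ok = False
                rec.samples[sid]["GT"] = tuple(sorted(idx)) if ok else (None, None)
            out.write(rec)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode(
    gm: GenotypeMatrix, panel: Panel, strand_flip: bool = False
) -> EncodedMatrix:
    """Encode raw calls 0/1/2 against a panel under the co-dominant model.

    Per cell: both alleles equal to the panel's earlier allele -> 2, one of
    each -> 1, both equal to the later allele -> 0; missing propagates. A
    call containing an allele that matches neither panel allele is set
    missing and counted in the returned matrix's mismatch tally. With
    ``strand_flip=True``, such calls are first retried after complementing
    both alleles (A<->T, C<->G), which rescues reverse-strand array calls at
    non-ambiguous loci.
    """
    for rsid in gm.locus_ids:
        if rsid not in panel:
            raise ConfigurationError(f"matrix locus {rsid} absent from panel {panel.name!r}")
    scores = np.full((gm.n_samples, gm.n_loci), np.nan)
    mismatch_by_locus: dict[str, int] = {}
    for j, rsid in enumerate(gm.locus_ids):
        entry = panel[rsid]
        earlier, later = entry.earlier_allele, entry.later_allele
        col = gm.calls[:, j]
        # map each distinct cell value once; columns hold few distinct values
        uniq, inverse = np.unique(col, return_inverse=True)
        mapped = np.full(uniq.size, np.nan)
        mismatch_mask = np.zeros(uniq.size, dtype=bool)
        for u_idx, u in enumerate(uniq):
            cell = str(u)
            if not cell:
                continue
            score = _score_cell(cell, earlier, later)
            if score is None and strand_flip:
                score = _score_cell(cell.translate(_COMPLEMENT), earlier, later)
            if score is None:
                mismatch_mask[u_idx] = True
            else:
                mapped[u_idx] = score
        scores[:, j] = mapped[inverse]
        n_mismatch = int(mismatch_mask[inverse].sum())
        if n_mismatch:
            mismatch_by_locus[rsid] = n_mismatch
    total = sum(mismatch_by_locus.values())
    if total:
        logger.warning(
            "encode: %d call(s) at %d locus/loci matched neither panel allele; set missing",
            total, len(mismatch_by_locus),
        )
    return EncodedMatrix(
        sample_ids=list(gm.sample_ids),
        locus_ids=list(gm.locus_ids),
        scores=scores,
        mismatch_count=total,
        mismatch_by_locus=mismatch_by_locus,
    )


def _score_cell(cell: str, earlier: str, later: str) -> float | None:
    n_earlier = (cell[0] == earlier) + (cell[1] == earlier)
    n_later = (cell[0] == later) + (cell[1] == later)
    if n_earlier + n_later != 2:
        return None
    return float(n_earlier)
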