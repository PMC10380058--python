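"""SNP panel loading and validation.

A *panel* is the ordered set of scored loci: each entry carries a dbSNP rsID,
an effect ("earlier-maturity") allele, the alternate allele, a non-negative
GWAS effect size ``beta``, and optionally per-group reference minor-allele
frequencies. The bundled 39-locus maturity-timing panel ships with the
package; its allele letters are synthetic placeholders (earlier=A, later=G)
because the effect-allele identities live in the upstream GWAS summary
statistics, not in the study that defined the panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from .errors import PanelValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Group labels used by the bundled panel's reference frequencies.
BUNDLED_GROUPS = ("CON", "U12-16", "U17-23")


@dataclass(frozen=True)
class SNPPanelEntry:
    """One scored locus.

    Parameters
    ----------
    rsid:
        dbSNP-style identifier; used as the key to match genotype data.
    beta:
        Non-negative effect size on maturity timing (GWAS units). Only the
        relative magnitudes matter for weighted scoring.
    earlier_allele, later_allele:
        Single nucleotide characters; ``earlier_allele`` is the effect allele
        counted by the 0/1/2 encoding.
    gene:
        Annotation label only; never used in computation.
    ref_freqs:
        Optional map of group label to reference minor-allele frequency
        (a fraction in [0, 0.5]).
    synthetic_alleles:
        True when the allele letters are placeholders rather than the true
        effect-allele identities (the case for the bundled panel).
    """

    rsid: str
    beta: float
    earlier_allele: str
    later_allele: str
    gene: str = ""
    ref_freqs: dict[str, float] = field(default_factory=dict)
    synthetic_alleles: bool = False

    def __post_init__(self) -> None:
        if self.earlier_allele not in VALID_ALLELES:
            raise PanelValidationError(
                f"{self.rsid}: earlier_allele {self.earlier_allele!r} is not one of A/C/G/T"
            )
        if self.later_allele not in VALID_ALLELES:
            raise PanelValidationError(
                f"{self.rsid}: later_allele {self.later_allele!r} is not one of A/C/G/T"
            )
        if self.earlier_allele == self.later_allele:
            raise PanelValidationError(
                f"{self.rsid}: earlier and later alleles are both {self.earlier_allele!r}"
            )
        if not (self.beta >= 0.0):
            raise PanelValidationError(f"{self.rsid}: beta must be >= 0, got {self.beta}")
        for group, freq in self.ref_freqs.items():
            if not (0.0 <= freq <= 0.5):
                raise PanelValidationError(
                    f"{self.rsid}: reference MAF for group {group!r} must lie in "
                    f"[0, 0.5], got {freq}"
                )


@dataclass(frozen=True)
class Panel:
    """An ordered, rsID-unique collection of :class:`SNPPanelEntry`."""

    entries: tuple[SNPPanelEntry, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            if entry.rsid in seen:
                raise PanelValidationError(f"duplicate rsid in panel: {entry.rsid}")
            seen.add(entry.rsid)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SNPPanelEntry]:
        return iter(self.entries)

    def __getitem__(self, rsid: str) -> SNPPanelEntry:
        try:
            return self._index()[rsid]
        except KeyError:
            raise KeyError(f"rsid {rsid!r} not in panel {self.name!r}") from None

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index()

    def _index(self) -> dict[str, SNPPanelEntry]:
        # frozen dataclass: cache on the instance dict via object.__setattr__
        cached = self.__dict__.get("_rsid_index")
        if cached is None:
            cached = {e.rsid: e for e in self.entries}
            object.__setattr__(self, "_rsid_index", cached)
        return cached

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(e.rsid for e in self.entries)

    @property
    def betas(self) -> tuple[float, ...]:
        return tuple(e.beta for e in self.entries)

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels for which every entry carries a reference frequency."""
        if not self.entries:
            return ()
        common = set(self.entries[0].ref_freqs)
        for entry in self.entries[1:]:
            common &= set(entry.ref_freqs)
        # preserve first-entry ordering
        return tuple(g for g in self.entries[0].ref_freqs if g in common)

    def ref_freq_vector(self, group: str) -> tuple[float, ...]:
        """Reference MAFs for ``group`` across all loci, in panel order."""
        out = []
        for entry in self.entries:
            if group not in entry.ref_freqs:
                raise KeyError(f"{entry.rsid} has no reference frequency for group {group!r}")
            out.append(entry.ref_freqs[group])
        return tuple(out)


_REQUIRED_COLUMNS = ("rsid", "beta", "earlier_allele", "later_allele")


def _parse_rows(rows: list[dict], name: str, synthetic_alleles: bool = False) -> Panel:
    entries = []
    for i, row in enumerate(rows, start=1):
        missing = [c for c in _REQUIRED_COLUMNS if row.get(c) in (None, "")]
        if missing:
            raise PanelValidationError(f"row {i}: missing required field(s) {missing}")
        try:
            beta = float(row["beta"])
        except (TypeError, ValueError):
            raise PanelValidationError(f"row {i}: beta {row['beta']!r} is not a number") from None
        if beta < 0:
            raise PanelValidationError(f"row {i}: negative beta {beta} for {row['rsid']}")
        ref_freqs = {}
        for key, value in row.items():
            if key.startswith("maf_") and value not in (None, ""):
                try:
                    ref_freqs[key[4:]] = float(value)
                except (TypeError, ValueError):
                    raise PanelValidationError(
                        f"row {i}: frequency {value!r} in column {key!r} is not a number"
                    ) from None
        try:
            entries.append(
                SNPPanelEntry(
                    rsid=str(row["rsid"]),
                    gene=str(row.get("gene") or ""),
                    beta=beta,
                    earlier_allele=str(row["earlier_allele"]),
                    later_allele=str(row["later_allele"]),
                    ref_freqs=ref_freqs,
                    synthetic_alleles=synthetic_alleles,
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"row {i}: {exc}") from None
    if not entries:
        logger.warning("panel %r is empty (header only)", name)
    return Panel(entries=tuple(entries), name=name)


def _read_tsv_records(text: str) -> list[dict]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise PanelValidationError("panel TSV has no header row")
    header = lines[0].rstrip("\n").split("\t")
    records = []
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise PanelValidationError(
                f"panel TSV row has {len(fields)} fields, header has {len(header)}"
            )
        records.append(dict(zip(header, fields)))
    return records


def load_panel(path: str | Path, format: str | None = None) -> Panel:
    """Load and validate a panel from a TSV or JSON file.

    TSV dialect: UTF-8, tab-separated, ``#``-prefixed comment lines ignored,
    header row required with at least ``rsid``, ``beta``, ``earlier_allele``
    and ``later_allele``; optional ``gene`` and any number of per-group
    frequency columns named ``maf_<group>``. JSON holds the same fields as an
    array of records. Row order is preserved.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown panel format {format!r}")
    text = path.read_text(encoding="utf-8")
    if format == "json":
        rows = json.loads(text)
        if not isinstance(rows, list):
            raise PanelValidationError("panel JSON must be an array of records")
    else:
        rows = _read_tsv_records(text)
    return _parse_rows(rows, name=path.stem)


def write_panel(panel: Panel, path: str | Path, format: str | None = None) -> None:
    """Write a panel as TSV or JSON (inverse of :func:`load_panel`)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    groups: list[str] = []
    for entry in panel:
        for g in entry.ref_freqs:
            if g not in groups:
                groups.append(g)
    if format == "json":
        rows = []
        for e in panel:
            row: dict = {
                "rsid": e.rsid,
                "gene": e.gene,
                "beta": e.beta,
                "earlier_allele": e.earlier_allele,
                "later_allele": e.later_allele,
            }
            for g in groups:
                if g in e.ref_freqs:
                    row[f"maf_{g}"] = e.ref_freqs[g]
            rows.append(row)
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
        return
    header = ["rsid", "gene", "beta", "earlier_allele", "later_allele"]
    header += [f"maf_{g}" for g in groups]
    lines = ["\t".join(header)]
    for e in panel:
        row = [e.rsid, e.gene, f"{e.beta:g}", e.earlier_allele, e.later_allele]
        for g in groups:
            row.append(f"{e.ref_freqs[g]:g}" if g in e.ref_freqs else "")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def bundled_panel() -> Panel:
    """The packaged 39-locus maturity-timing panel.

    Betas and per-group reference MAFs (groups ``CON``, ``U12-16``,
    ``U17-23``) are the published values, stored as fractions. Allele letters
    are synthetic placeholders (``earlier_allele="A"``, ``later_allele="G"``,
    flagged via ``synthetic_alleles=True``): the true per-SNP effect-allele
    identities require the source GWAS summary statistics and must be
    supplied by the user for real genotype data.
    """
    text = (resources.files("tgskit.data") / "maturity_panel.tsv").read_text(encoding="utf-8")
    rows = _read_tsv_records(text)
    panel = _parse_rows(rows, name="maturity39", synthetic_alleles=True)
    assert len(panel) == 39, "bundled panel must have exactly 39 loci"
    return panel
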