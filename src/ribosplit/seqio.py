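"""Sequence, alignment, site-table and secondary-structure I/O.

This module owns the shared data model for the pipeline: annotated DNA
sequences (marker, individual, collection site, genotype), multiple
alignments, collection-site tables with coordinates, and pseudoknot-free
RNA secondary structures in dot-bracket notation.

All coordinates are 0-based, half-open; conversion to 1-based reporting
happens only at the reporting layer. Residues are canonicalized at the
boundary: lowercase is uppercased, U becomes T, anything outside
{A,C,G,T,N,-} becomes N (with a logged warning). No other module
re-interprets residues or indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")

#: markers understood by downstream stages
MARKERS = ("ITS2", "COI", "other")


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


def canonicalize(residues: str, *, context: str = "") -> str:
    """Uppercase, map U->T, and replace foreign characters with N."""
    s = residues.upper().replace("U", "T")
    if not set(s) <= ALPHABET:
        bad = sorted(set(s) - ALPHABET)
        logger.warning("replacing non-DNA characters %s with N%s", bad,
                       f" in {context}" if context else "")
        s = "".join(c if c in ALPHABET else "N" for c in s)
    return s


@dataclass(frozen=True)
class SeqRecord:
    """One annotated DNA sequence.

    ``residues`` may contain gaps when the record is a row of an
    alignment. ``individual``, ``site`` and ``genotype`` are free-text
    annotations ("" when unknown) that can be embedded in FASTA ids as
    ``id|individual|site|genotype`` or supplied through a site table.
    """

    id: str
    residues: str
    marker: str = "other"
    individual: str = ""
    site: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residues")
        object.__setattr__(self, "residues",
                           canonicalize(self.residues, context=self.id))
        if self.marker not in MARKERS:
            raise ValueError(f"record {self.id!r}: unknown marker {self.marker!r}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def with_residues(self, residues: str) -> "SeqRecord":
        return replace(self, residues=residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """An ordered set of equal-length gapped sequences (>= 2 rows)."""

    records: tuple[SeqRecord, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lens = {len(r.residues) for r in self.records}
        if len(lens) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lens)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in alignment")
        object.__setattr__(self, "length", lens.pop())

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def row(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


REQUIRED_SITE_COLUMNS = ("site_id", "latitude", "longitude", "individual", "genotype")


@dataclass(frozen=True)
class SiteTable:
    """Collection-site metadata: where each individual was caught and its
    genotype label. Backed by a pandas DataFrame with the canonical columns
    site_id, latitude, longitude, individual, genotype."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in REQUIRED_SITE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"site table missing required column {col!r}")
        dup = df.duplicated(subset=["site_id", "individual"])
        if dup.any():
            raise ValueError(
                f"duplicate (site_id, individual) pair at row {int(dup.idxmax())}")
        for i, lat in enumerate(df["latitude"]):
            if not -90 <= lat <= 90:
                raise ValueError(f"latitude {lat} out of range at row {i}")
        for i, lon in enumerate(df["longitude"]):
            if not -180 <= lon <= 180:
                raise ValueError(f"longitude {lon} out of range at row {i}")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure in dot-bracket notation,
    annotating the ungapped sequence named by ``seq_id``."""

    seq_id: str
    dotbracket: str

    def __post_init__(self) -> None:
        self.pairs()  # validates balance/nesting

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs (i, j), i < j, 0-based positions in the ungapped
        sequence. Raises ParseError at the first offending index."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ParseError(f"unbalanced ')' at index {i}")
                out.append((stack.pop(), i))
            elif c != ".":
                raise ParseError(f"illegal structure character {c!r} at index {i}")
        if stack:
            raise ParseError(
                f"unclosed '(' at index {stack[-1]} (end of string reached)")
        return sorted(out)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _from_bio(rec: BioSeqRecord, marker: str) -> SeqRecord:
    ident = rec.id
    individual = site = genotype = ""
    if "|" in ident:
        parts = ident.split("|")
        ident = parts[0]
        individual = parts[1] if len(parts) > 1 else ""
        site = parts[2] if len(parts) > 2 else ""
        genotype = parts[3] if len(parts) > 3 else ""
    return SeqRecord(id=ident, residues=str(rec.seq), marker=marker,
                     individual=individual, site=site, genotype=genotype)


def read_sequences(path: str | Path, format: str = "fasta",
                   marker: str = "other") -> list[SeqRecord]:
    """Read a FASTA or relaxed sequential Phylip file.

    Ids and residues are preserved apart from canonicalization; record
    order is preserved. FASTA ids of the form ``id|individual|site|genotype``
    populate the corresponding annotations.
    """
    path = Path(path)
    if format == "fasta":
        recs = [_from_bio(r, marker) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "phylip_relaxed":
        _validate_phylip_header(path)
        try:
            aln = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        recs = [_from_bio(r, marker) for r in aln]
    else:
        raise ValueError(f"unknown format {format!r}")
    if not recs:
        raise ParseError(f"{path}: no sequences found")
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sequence ids")
    return recs


def _validate_phylip_header(path: Path) -> None:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ParseError(f"{path}: line 1: empty file or blank header")
    fields = first.split()
    if len(fields) != 2 or not all(f.isdigit() for f in fields):
        raise ParseError(
            f"{path}: line 1: expected '<ntaxa> <ncolumns>' header, got {first.strip()!r}")


def read_alignment(path: str | Path, format: str = "phylip_relaxed",
                   marker: str = "other") -> MultipleAlignment:
    recs = read_sequences(path, format=format, marker=marker)
    try:
        return MultipleAlignment(tuple(recs))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sequences(records: Sequence[SeqRecord], path: str | Path,
                    format: str = "fasta") -> None:
    """Write records in FASTA or relaxed sequential Phylip. Annotations are
    embedded in FASTA ids (``id|individual|site|genotype``) only when any
    of them is non-empty."""
    path = Path(path)
    if format == "fasta":
        bio = []
        for r in records:
            ident = r.id
            if r.individual or r.site or r.genotype:
                ident = "|".join([r.id, r.individual, r.site, r.genotype])
            bio.append(BioSeqRecord(Seq(r.residues), id=ident, description=""))
        SeqIO.write(bio, str(path), "fasta")
    elif format == "phylip_relaxed":
        lens = {len(r.residues) for r in records}
        if len(lens) != 1:
            raise ValueError("phylip output requires equal-length sequences")
        width = max(len(r.id) for r in records) + 2
        with open(path, "w") as fh:
            fh.write(f" {len(records)} {lens.pop()}\n")
            for r in records:
                fh.write(f"{r.id:<{width}}{r.residues}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_site_table(path: str | Path) -> SiteTable:
    """Read a TSV site table with header columns site_id, latitude,
    longitude, individual, genotype (extra columns ignored with a
    warning). An empty data section yields an empty table."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "individual": str,
                                            "genotype": str})
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_SITE_COLUMNS]
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, extra)
        df = df[list(REQUIRED_SITE_COLUMNS)]
    df = df.astype({"latitude": float, "longitude": float})
    return SiteTable(df.reset_index(drop=True))


def write_site_table(table: SiteTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_structure(path: str | Path) -> SecondaryStructure:
    """Read a two-line structure record: sequence id, then dot-bracket."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: expected id line followed by dot-bracket line")
    seq_id = lines[0].lstrip(">")
    try:
        return SecondaryStructure(seq_id=seq_id, dotbracket=lines[1])
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def apply_site_table(records: Iterable[SeqRecord], table: SiteTable) -> list[SeqRecord]:
    """Annotate records from a site table, keyed by individual id. Site-table
    values win over annotations already embedded in the record ids."""
    by_ind = {row.individual: row for row in table.frame.itertuples()}
    out = []
    for r in records:
        row = by_ind.get(r.individual) or by_ind.get(r.id)
        if row is not None:
            r = replace(r, individual=row.individual, site=str(row.site_id),
                        genotype=row.genotype)
        out.append(r)
    return out
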