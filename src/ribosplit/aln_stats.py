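"""Alignment summary statistics, haplotype collapsing and diagnostic
substitution screening.

Column classification follows the usual parsimony convention: gaps and N
are excluded from the state counts, a column is constant when at most one
distinct state remains (all-gap columns count as constant), parsimony
informative when at least two states each occur in at least two
sequences, and variable-uninformative otherwise. Haplotype identity, in
contrast, treats the full aligned text (gaps included) as significant, so
indel variants still distinguish spacer haplotypes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from Bio.Seq import Seq

from .seqio import MultipleAlignment, SeqRecord

_EXCLUDED = {"-", "N"}


@dataclass(frozen=True)
class ColumnClassification:
    n_constant: int
    n_parsimony_informative: int
    n_variable_uninformative: int
    n_gap_columns: int            # columns containing >= 1 gap
    n_gap_or_missing_columns: int  # columns containing >= 1 gap or N
    n_gap_cells: int              # total gap/N cells across the alignment
    per_column: tuple[str, ...]   # constant | PI | VU

    @property
    def n_variable(self) -> int:
        return self.n_parsimony_informative + self.n_variable_uninformative


def classify_columns(aln: MultipleAlignment) -> ColumnClassification:
    """Classify every column as constant, parsimony informative (PI) or
    variable-uninformative (VU). The three counts always sum to the
    alignment length."""
    per_column = []
    n_gap = n_gap_missing = n_cells = 0
    for j in range(aln.length):
        col = aln.column(j)
        if "-" in col:
            n_gap += 1
        excluded = sum(1 for c in col if c in _EXCLUDED)
        if excluded:
            n_gap_missing += 1
            n_cells += excluded
        states = Counter(c for c in col if c not in _EXCLUDED)
        if len(states) <= 1:
            per_column.append("constant")
        elif sum(1 for n in states.values() if n >= 2) >= 2:
            per_column.append("PI")
        else:
            per_column.append("VU")
    counts = Counter(per_column)
    return ColumnClassification(
        n_constant=counts["constant"],
        n_parsimony_informative=counts["PI"],
        n_variable_uninformative=counts["VU"],
        n_gap_columns=n_gap,
        n_gap_or_missing_columns=n_gap_missing,
        n_gap_cells=n_cells,
        per_column=tuple(per_column),
    )


@dataclass(frozen=True)
class GCSummary:
    per_sequence: tuple[float, ...]
    mean: float
    min: float
    max: float


def gc_content(records: Sequence[SeqRecord]) -> GCSummary:
    """Per-sequence GC fraction over ungapped, non-N residues, with the
    unweighted mean/min/max across sequences."""
    fracs = []
    for r in records:
        counted = [c for c in r.residues if c not in _EXCLUDED]
        if not counted:
            raise ValueError(f"{r.id}: no countable residues (all gap/N)")
        fracs.append(sum(1 for c in counted if c in "GC") / len(counted))
    return GCSummary(tuple(fracs), sum(fracs) / len(fracs), min(fracs), max(fracs))


@dataclass(frozen=True)
class HaplotypeSet:
    """Partition of alignment rows into identical-sequence haplotypes,
    ordered by first appearance."""

    haplotypes: tuple[tuple[str, tuple[str, ...]], ...]  # (representative, member ids)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def collapse_haplotypes(aln: MultipleAlignment) -> HaplotypeSet:
    """Collapse rows to haplotypes under strict identity of the aligned
    text (gaps and N significant)."""
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for r in aln.records:
        if r.residues not in groups:
            groups[r.residues] = []
            order.append(r.residues)
        groups[r.residues].append(r.id)
    return HaplotypeSet(tuple((seq, tuple(groups[seq])) for seq in order))


#: NCBI translation table 5 (invertebrate mitochondrial), the correct code
#: for mosquito COI.
INVERTEBRATE_MITO_TABLE = 5


@dataclass(frozen=True)
class DiagnosticHit:
    column: int          # 1-based alignment column
    from_state: str      # state fixed in all other groups
    to_state: str        # state fixed in the diagnostic group
    group: str
    codon_position: int  # 1, 2 or 3
    residue_number: int  # 1-based amino-acid position in the reading frame
    syn: bool | None     # None when a gap makes the codon undetermined
    aa_from: str
    aa_to: str


def diagnostic_substitutions(aln: MultipleAlignment,
                             labels: Mapping[str, str] | Callable[[str], str],
                             frame_offset: int,
                             table: int = INVERTEBRATE_MITO_TABLE
                             ) -> list[DiagnosticHit]:
    """Find columns where one group is fixed for a state while all other
    sequences are fixed for a different state, and type each hit as
    synonymous or nonsynonymous under the given reading frame.

    ``frame_offset`` is the 0-based column where the first complete codon
    starts; it is supplied, not inferred. Gap inside an implicated codon
    leaves syn undetermined (None).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    get = labels.__getitem__ if isinstance(labels, Mapping) else labels
    by_group: dict[str, list[SeqRecord]] = {}
    for r in aln.records:
        by_group.setdefault(get(r.id), []).append(r)
    if len(by_group) < 2:
        return []

    def fixed_state(rows: Sequence[SeqRecord], j: int) -> str | None:
        states = {r.residues[j] for r in rows} - _EXCLUDED
        return states.pop() if len(states) == 1 else None

    hits: list[DiagnosticHit] = []
    for j in range(aln.length):
        col_hits: list[DiagnosticHit] = []
        for group, rows in by_group.items():
            to_state = fixed_state(rows, j)
            others = [r for g, rs in by_group.items() if g != group for r in rs]
            from_state = fixed_state(others, j)
            if to_state is None or from_state is None or to_state == from_state:
                continue
            codon_index, codon_pos = divmod(j - frame_offset, 3)
            if codon_index < 0:
                continue
            start = frame_offset + 3 * codon_index
            if start + 3 > aln.length:
                continue
            codon_other = others[0].residues[start:start + 3]
            codon_group = (codon_other[:codon_pos] + to_state
                           + codon_other[codon_pos + 1:])
            if set(codon_other + codon_group) & _EXCLUDED:
                syn, aa_from, aa_to = None, "?", "?"
            else:
                aa_from = str(Seq(codon_other).translate(table=table))
                aa_to = str(Seq(codon_group).translate(table=table))
                syn = aa_from == aa_to
            col_hits.append(DiagnosticHit(
                column=j + 1, from_state=from_state, to_state=to_state,
                group=group, codon_position=codon_pos + 1,
                residue_number=codon_index + 1,
                syn=syn, aa_from=aa_from, aa_to=aa_to))
        if len(col_hits) > 1:
            # with exactly two groups a diagnostic column is seen from both
            # sides; report it once, for the smaller (derived) group
            col_hits.sort(key=lambda h: (len(by_group[h.group]), h.group))
            col_hits = col_hits[:1]
        hits.extend(col_hits)
    return hits
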