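"""Compensatory base change (CBC) screening on a shared secondary
structure.

Given a structure (dot-bracket, defined on the ungapped template
sequence) and two aligned spacer sequences, every structural base pair
is classified:

- conserved_pair: neither partner differs; pairing canonical in both
- CBC: both partners differ, canonical pairing retained in both
- hemi_CBC: exactly one partner differs, canonical pairing retained
  (e.g. G:C -> G:U)
- disrupted: either sequence fails to form a canonical pair
- indel_overlap: an alignment gap covers either partner position

Canonical pairs are {AU, UA, GC, CG, GU, UG} with T read as U. Folding
itself is not performed here; the structure is an input (typically a
minimum-free-energy fold of one genotype's spacer) and the screen is the
inferential step linking structure conservation to species boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .seqio import MultipleAlignment, SecondaryStructure, SeqRecord

CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
             ("G", "T"), ("T", "G")}

CATEGORIES = ("conserved_pair", "CBC", "hemi_CBC", "disrupted", "indel_overlap")


@dataclass(frozen=True)
class PairClassification:
    per_pair: tuple[tuple[tuple[int, int], str], ...]  # ((col_i, col_j), category)
    totals: dict[str, int]

    @property
    def n_cbc(self) -> int:
        return self.totals["CBC"]

    @property
    def n_hemi(self) -> int:
        return self.totals["hemi_CBC"]


def map_structure(structure: SecondaryStructure, reference: SeqRecord,
                  aln: MultipleAlignment) -> list[tuple[int, int]]:
    """Map structural pairs from ungapped reference coordinates to
    alignment columns through the reference row's gap pattern."""
    row = aln.row(reference.id)
    ungapped_len = len(row.ungapped)
    if len(structure.dotbracket) != ungapped_len:
        raise ValueError(
            f"structure length {len(structure.dotbracket)} != ungapped length "
            f"{ungapped_len} of reference {reference.id!r}")
    to_column = [j for j, c in enumerate(row.residues) if c != "-"]
    return [(to_column[p], to_column[q]) for p, q in structure.pairs()]


def _is_canonical(x: str, y: str) -> bool:
    return (x, y) in CANONICAL


def classify_pairs(seq_a: SeqRecord, seq_b: SeqRecord,
                   pairs: list[tuple[int, int]]) -> PairClassification:
    """Classify each mapped structural pair for the two aligned rows.
    Categories are exhaustive and mutually exclusive; totals partition the
    pair set. CBC/hemi-CBC/conserved/disrupted totals are symmetric in
    (a, b)."""
    if len(seq_a.residues) != len(seq_b.residues):
        raise ValueError("both sequences must come from the same alignment")
    out = []
    totals = Counter({c: 0 for c in CATEGORIES})
    for i, j in pairs:
        ai, aj = seq_a.residues[i], seq_a.residues[j]
        bi, bj = seq_b.residues[i], seq_b.residues[j]
        if "-" in (ai, aj, bi, bj):
            cat = "indel_overlap"
        elif not (_is_canonical(ai, aj) and _is_canonical(bi, bj)):
            cat = "disrupted"
        else:
            n_diff = (ai != bi) + (aj != bj)
            cat = {0: "conserved_pair", 1: "hemi_CBC", 2: "CBC"}[n_diff]
        totals[cat] += 1
        out.append(((i, j), cat))
    return PairClassification(per_pair=tuple(out), totals=dict(totals))


def screen(aln: MultipleAlignment, structure: SecondaryStructure,
           id_a: str, id_b: str) -> PairClassification:
    """Full CBC screen: map the structure through its named template row,
    then classify all pairs between the two named rows."""
    template = aln.row(structure.seq_id)
    pairs = map_structure(structure, template, aln)
    return classify_pairs(aln.row(id_a), aln.row(id_b), pairs)
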