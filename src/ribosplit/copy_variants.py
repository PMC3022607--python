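"""Intragenomic rDNA copy-variant analysis.

Tandem rDNA spacer repeats are near-identical within a genome; incomplete
homogenization leaves a small number of copy variants (SNPs or short
indels relative to the majority repeat). When a spacer PCR product is
reannealed and run on a native acrylamide gel, every unordered pair of
distinct variant classes forms a mismatched heteroduplex that migrates
slower than the perfectly paired homoduplexes, so the multiset of duplex
classes is a genotype fingerprint readable from a single lane.

This module groups cloned spacer sequences from one individual into
variant classes, describes each class by its differences from the
majority class (via an affine-gap global aligner), predicts the implied
duplex-class signature, and tests whether that signature is fixed across
conspecific individuals — the hallmark of an rDNA array moving through an
interbreeding population as a single evolutionary unit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import SeqRecord

NEG_INF = -1e18

#: (match, mismatch, gap_open, gap_extend); gap of length L scores
#: gap_open + (L-1) * gap_extend. Mismatch/gap scores are <= 0.
Scoring = tuple[float, float, float, float]

DEFAULT_SCORING: Scoring = (1.0, -1.0, -4.0, -1.0)


@dataclass(frozen=True)
class AlignmentEvent:
    """One difference between two aligned sequences, in 0-based alignment
    columns: a substitution (length 1) or an insertion/deletion run.
    Insertion = residues present only in b; deletion = only in a."""

    kind: str            # substitution | insertion | deletion
    position: int
    length: int
    detail: str


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    events: tuple[AlignmentEvent, ...]

    @property
    def n_substitutions(self) -> int:
        return sum(1 for e in self.events if e.kind == "substitution")

    @property
    def indel_bp(self) -> int:
        return sum(e.length for e in self.events
                   if e.kind in ("insertion", "deletion"))


def _fill_matrices(a: str, b: str, scoring: Scoring):
    """Gotoh affine-gap DP. M ends in an aligned column; X ends with a gap
    in b (consuming a); Y ends with a gap in a (consuming b). Vectorized
    over columns; the within-row Y recurrence collapses to a running max."""
    match, mismatch, open_, ext = scoring
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch)

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = open_ + ext * np.arange(n)
    if m:
        Y[0, 1:] = open_ + ext * np.arange(m)

    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum.reduce([M[i - 1], X[i - 1], Y[i - 1]])
        M[i, 1:] = sub[i - 1] + best_prev[:-1]
        X[i, 1:] = np.maximum.reduce([
            M[i - 1, 1:] + open_, Y[i - 1, 1:] + open_, X[i - 1, 1:] + ext])
        X[i, 0] = open_ + ext * (i - 1)
        # Y[i, j] = max_{k < j} (max(M,X)[i, k] + open + (j-1-k) * ext)
        base = np.maximum(M[i, :-1], X[i, :-1])
        c = base - np.arange(m) * ext
        Y[i, 1:] = open_ + (js - 1) * ext + np.maximum.accumulate(c)
    return M, X, Y


def align_pair(a: SeqRecord, b: SeqRecord,
               scoring: Scoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global (end-to-end) alignment under affine gap scoring.

    Ties are broken deterministically: an aligned column (substitution or
    match) is preferred over a gap, and a gap in ``a`` over a gap in ``b``.
    """
    sa, sb = a.ungapped, b.ungapped
    if not sa or not sb:
        raise ValueError("align_pair requires non-empty sequences")
    match, mismatch, open_, ext = scoring
    M, X, Y = _fill_matrices(sa, sb, scoring)
    i, j = len(sa), len(sb)

    def prefer(cands):
        # cands: list of (state, score); preference M > Y > X on ties
        order = {"M": 0, "Y": 1, "X": 2}
        best = max(s for _, s in cands)
        return min((c for c in cands if c[1] == best), key=lambda c: order[c[0]])[0]

    state = prefer([("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = prefer([("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])])
        elif state == "X":  # gap in b, consumed a[i-1]
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
            state = prefer([("M", M[i, j] + open_), ("Y", Y[i, j] + open_),
                            ("X", X[i, j] + ext)])
        else:  # Y: gap in a, consumed b[j-1]
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
            state = prefer([("M", M[i, j] + open_), ("X", X[i, j] + open_),
                            ("Y", Y[i, j] + ext)])
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    score = max(M[len(sa), len(sb)], X[len(sa), len(sb)], Y[len(sa), len(sb)])
    return PairwiseAlignment(aligned_a, aligned_b, float(score),
                             tuple(extract_events(aligned_a, aligned_b)))


def extract_events(aligned_a: str, aligned_b: str) -> list[AlignmentEvent]:
    """Difference events between two equal-length gapped strings."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    events: list[AlignmentEvent] = []
    col = 0
    L = len(aligned_a)
    while col < L:
        ca, cb = aligned_a[col], aligned_b[col]
        if ca == "-" and cb != "-":
            start = col
            while col < L and aligned_a[col] == "-" and aligned_b[col] != "-":
                col += 1
            events.append(AlignmentEvent("insertion", start, col - start,
                                         aligned_b[start:col]))
        elif cb == "-" and ca != "-":
            start = col
            while col < L and aligned_b[col] == "-" and aligned_a[col] != "-":
                col += 1
            events.append(AlignmentEvent("deletion", start, col - start,
                                         aligned_a[start:col]))
        else:
            if ca != cb:
                events.append(AlignmentEvent("substitution", col, 1,
                                             f"{ca}>{cb}"))
            col += 1
    return events


@dataclass(frozen=True)
class VariantClass:
    representative: str
    clone_count: int
    diff_events: tuple[AlignmentEvent, ...]   # vs. the majority class


@dataclass(frozen=True)
class VariantSet:
    """An individual's intragenomic spacer variant classes; class 1 is the
    majority class (ties broken by lexicographically smallest sequence)."""

    individual: str
    variant_classes: tuple[VariantClass, ...]

    @property
    def n_classes(self) -> int:
        return len(self.variant_classes)


def call_variants(clones: Sequence[SeqRecord],
                  scoring: Scoring = DEFAULT_SCORING,
                  error_correct: bool = False) -> VariantSet:
    """Group one individual's cloned spacer sequences into exact-identity
    variant classes and describe each minority class by its alignment
    events against the majority class.

    ``error_correct`` optionally merges singleton classes that differ from
    a larger class by a single substitution and no indels (a Taq/PCR error
    model); off by default, treating clones as faithful copies.
    """
    if len(clones) < 2:
        raise ValueError("variant calling needs >=2 clones")
    individuals = {c.individual or c.id for c in clones}
    individual = clones[0].individual or clones[0].id
    if len(individuals) > 1:
        raise ValueError(f"clones from multiple individuals: {sorted(individuals)}")
    counts = Counter(c.ungapped for c in clones)

    if error_correct:
        majors = sorted((s for s, n in counts.items() if n > 1),
                        key=lambda s: (-counts[s], s))
        for s in [s for s, n in counts.items() if n == 1]:
            for m in majors:
                if len(m) == len(s):
                    aln = align_pair(SeqRecord(id="q", residues=s),
                                     SeqRecord(id="r", residues=m), scoring)
                    if aln.n_substitutions <= 1 and aln.indel_bp == 0:
                        counts[m] += counts.pop(s)
                        break

    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    majority = ordered[0][0]
    maj_rec = SeqRecord(id=f"{individual}.class1", residues=majority)
    classes = []
    for idx, (seq, n) in enumerate(ordered, start=1):
        if seq == majority:
            events: tuple[AlignmentEvent, ...] = ()
        else:
            events = align_pair(maj_rec,
                                SeqRecord(id=f"{individual}.class{idx}",
                                          residues=seq),
                                scoring).events
        classes.append(VariantClass(seq, n, events))
    return VariantSet(individual=individual, variant_classes=tuple(classes))


#: a duplex class: (kind, mismatch count, total indel bp)
DuplexClass = tuple[str, int, int]


@dataclass(frozen=True)
class HeteroduplexSignature:
    """The duplex classes formed when an individual's variant classes
    reanneal: one homoduplex per class plus one heteroduplex per unordered
    class pair. Display order is qualitative mobility only
    (homoduplex < snp_het < indel_het)."""

    duplex_classes: tuple[DuplexClass, ...]

    def as_multiset(self) -> Counter:
        return Counter(self.duplex_classes)

    def __eq__(self, other) -> bool:  # equality as multisets
        if not isinstance(other, HeteroduplexSignature):
            return NotImplemented
        return self.as_multiset() == other.as_multiset()

    def __hash__(self) -> int:
        return hash(frozenset(self.as_multiset().items()))


def duplex_signature(vs: VariantSet,
                     scoring: Scoring = DEFAULT_SCORING) -> HeteroduplexSignature:
    """Predict the duplex-class signature of a variant set: k homoduplexes
    and k(k-1)/2 heteroduplexes, the latter typed by mismatch count and
    indel bp between class representatives (indel heteroduplexes are the
    overt slow bands)."""
    k = vs.n_classes
    classes: list[DuplexClass] = [("homoduplex", 0, 0)] * k
    reps = [SeqRecord(id=f"c{i}", residues=c.representative)
            for i, c in enumerate(vs.variant_classes)]
    for i in range(k):
        for j in range(i + 1, k):
            aln = align_pair(reps[i], reps[j], scoring)
            kind = "indel_het" if aln.indel_bp > 0 else "snp_het"
            classes.append((kind, aln.n_substitutions, aln.indel_bp))
    order = {"homoduplex": 0, "snp_het": 1, "indel_het": 2}
    classes.sort(key=lambda d: (order[d[0]], d[1], d[2]))
    return HeteroduplexSignature(tuple(classes))


def fixation_test(group: Sequence[VariantSet],
                  scoring: Scoring = DEFAULT_SCORING
                  ) -> tuple[bool, tuple[str, str] | None]:
    """Test whether a genotype's duplex signature is fixed across
    conspecific individuals.

    Signatures are compared as multisets of (kind, mismatches, indel_bp):
    clone counts do not matter, only band presence, since gels are scored
    by band pattern rather than intensity. Returns (fixed, witness); the
    witness is the first unequal pair in input order.
    """
    if len(group) < 2:
        raise ValueError("fixation test needs >=2 individuals")
    sigs = [duplex_signature(vs, scoring) for vs in group]
    ref = sigs[0]
    for vs, sig in zip(group[1:], sigs[1:]):
        if sig != ref:
            return False, (group[0].individual, vs.individual)
    return True, None
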