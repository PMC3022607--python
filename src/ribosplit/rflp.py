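"""In-silico PCR-RFLP genotyping.

Locates restriction sites on a linear amplicon, computes the fragment
spectrum of a complete digest, applies a simple agarose-gel visibility
model (detection floor plus co-migration merging), and clusters band
patterns into genotype classes the way profiles are matched by eye
between gel lanes.

The default enzyme is MspI (C^CGG), the assay used for ITS2 genotyping
of anopheline mosquitoes. Digestion is assumed complete; the ambiguity
code N never matches a motif position (conservative site calling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .seqio import SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: recognition motif and cut offset within
    it (cut_offset = 1 for MspI means C^CGG)."""

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be non-empty over ACGT, got {self.motif!r}")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut_offset outside motif")


MSP_I = Enzyme(name="MspI", motif="CCGG", cut_offset=1)


@dataclass(frozen=True)
class GelModel:
    """Visibility model for a 3% agarose gel: fragments below
    ``min_detectable`` bp run off / are too faint; fragments within
    ``comigration_tolerance`` (fraction of the larger) co-migrate as one
    band."""

    min_detectable: int = 50
    comigration_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.min_detectable < 1:
            raise ValueError("min_detectable must be >= 1")
        if not 0 <= self.comigration_tolerance < 0.5:
            raise ValueError("comigration_tolerance must be in [0, 0.5)")


@dataclass(frozen=True)
class DigestProfile:
    """Fragment spectrum of one amplicon: all fragment lengths (descending)
    and the gel-visible band lengths derived from them."""

    seq_id: str
    fragment_lengths: tuple[int, ...]
    visible_bands: tuple[int, ...]


def find_cut_sites(seq: SeqRecord, enzyme: Enzyme = MSP_I) -> list[int]:
    """Cut positions (0-based, between-residue): position p cuts between
    residues p-1 and p. A single-strand scan is complete for palindromic
    motifs such as CCGG."""
    s = seq.residues
    if "-" in s:
        raise ValueError(f"{seq.id}: cannot digest a gapped sequence")
    motif = enzyme.motif
    cuts = []
    start = 0
    while True:
        i = s.find(motif, start)
        if i == -1:
            break
        cuts.append(i + enzyme.cut_offset)
        start = i + 1  # overlapping occurrences still counted
    return cuts


def digest(seq: SeqRecord, enzyme: Enzyme = MSP_I,
           gel: GelModel = GelModel()) -> DigestProfile:
    """Complete digest of a linear amplicon. Fragment lengths always sum
    to the amplicon length; fragment count = cuts + 1."""
    cuts = find_cut_sites(seq, enzyme)
    bounds = [0] + cuts + [len(seq.residues)]
    frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    frags.sort(reverse=True)
    return DigestProfile(seq_id=seq.id, fragment_lengths=tuple(frags),
                         visible_bands=gel_bands(frags, gel))


def gel_bands(fragment_lengths: Sequence[int],
              gel: GelModel = GelModel()) -> tuple[int, ...]:
    """Apply the gel model: drop sub-detection fragments, then merge
    co-migrating neighbours (pairwise difference <= tolerance x larger)
    into one band at their rounded mean."""
    kept = sorted((f for f in fragment_lengths if f >= gel.min_detectable),
                  reverse=True)
    bands: list[int] = []
    group: list[int] = []
    for f in kept:
        if group and group[-1] - f > gel.comigration_tolerance * group[0]:
            bands.append(round(sum(group) / len(group)))
            group = []
        group.append(f)
    if group:
        bands.append(round(sum(group) / len(group)))
    return tuple(bands)


def _bands_match(a: Sequence[int], b: Sequence[int], tolerance: float) -> bool:
    """One-to-one matching of two band patterns within co-migration
    tolerance. Greedy descending-size pairing: the i-th largest band of one
    lane is compared against the i-th largest of the other."""
    if len(a) != len(b):
        return False
    for x, y in zip(sorted(a, reverse=True), sorted(b, reverse=True)):
        if abs(x - y) > tolerance * max(x, y):
            return False
    return True


def _class_labels() -> "list[str]":
    import string
    letters = list(string.ascii_uppercase)
    return letters + [a + b for a in letters for b in letters]


def cluster_profiles(patterns: Sequence[tuple[str, Sequence[int]]],
                     gel: GelModel = GelModel()) -> dict[str, str]:
    """Cluster band patterns into genotype classes.

    Two lanes share a class iff their band counts are equal and every band
    matches one-to-one within co-migration tolerance. Classes are labelled
    A, B, C, ... in order of first appearance; the partition is stable
    under input reordering (up to relabelling).
    """
    if not patterns:
        raise ValueError("cluster_profiles needs at least one pattern")
    labels = _class_labels()
    reps: list[tuple[str, Sequence[int]]] = []   # (label, representative bands)
    assignment: dict[str, str] = {}
    for seq_id, bands in patterns:
        for label, rep in reps:
            if _bands_match(bands, rep, gel.comigration_tolerance):
                assignment[seq_id] = label
                break
        else:
            label = labels[len(reps)]
            reps.append((label, tuple(bands)))
            assignment[seq_id] = label
    return assignment


def synthesize_amplicon(seq_id: str, fragment_lengths: Sequence[int],
                        enzyme: Enzyme = MSP_I) -> SeqRecord:
    """Construct a SYNTHETIC amplicon whose complete digest yields exactly
    the given fragment lengths, in order.

    Used to turn a published band-size profile back into a digestible
    test sequence: fragment bodies are A/T-only (so the recognition motif
    cannot occur by accident) and consecutive fragments are joined so the
    motif straddles each junction with the cut at the fragment boundary.
    Requires a motif of the form X|YYY.. with cut_offset 1 (true of MspI).
    """
    if enzyme.cut_offset != 1:
        raise ValueError("amplicon synthesis assumes cut_offset 1")
    head, tail = enzyme.motif[:1], enzyme.motif[1:]
    parts = []
    for i, L in enumerate(fragment_lengths):
        body_len = L - (0 if i == 0 else len(tail)) - \
            (0 if i == len(fragment_lengths) - 1 else len(head))
        if body_len < 0:
            raise ValueError(f"fragment {L} too short for motif junctions")
        body = ("AT" * L)[:body_len]
        piece = ("" if i == 0 else tail) + body + \
            ("" if i == len(fragment_lengths) - 1 else head)
        parts.append(piece)
    seq = "".join(parts)
    return SeqRecord(id=seq_id, residues=seq, marker="ITS2")


def digest_table(records: Sequence[SeqRecord], enzyme: Enzyme = MSP_I,
                 gel: GelModel = GelModel()) -> "list[dict]":
    """Digest many amplicons and cluster them; returns one row per record
    with fragments, visible bands and assigned class."""
    profiles = [digest(r, enzyme, gel) for r in records]
    assignment = cluster_profiles(
        [(p.seq_id, p.visible_bands) for p in profiles], gel)
    return [
        {"seq_id": p.seq_id,
         "fragments": list(p.fragment_lengths),
         "bands": list(p.visible_bands),
         "rflp_class": assignment[p.seq_id]}
        for p in profiles
    ]
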