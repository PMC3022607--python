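"""Sympatry reconstruction and reproductive-isolation scoring.

Two genotypes are sympatric when they co-occur at a collection site.
Sympatric genotypes that (i) never share a spacer sequence class and
(ii) never appear as a blended restriction profile in any individual
provide evidence of reproductive isolation at the rDNA locus: if the
genotypes interbred, hybrid individuals would carry both parental rDNA
band patterns superimposed.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .rflp import GelModel, _bands_match, gel_bands
from .seqio import SiteTable


@dataclass
class SympatryReport:
    site_genotypes: dict[str, frozenset[str]]          # site -> genotypes present
    partners: dict[str, frozenset[str]]                # genotype -> sympatric partners
    sympatric: dict[str, bool]
    isolation_evidence: dict[str, bool] = field(default_factory=dict)
    reasons: dict[str, list[str]] = field(default_factory=dict)
    hybrids: list[tuple[str, tuple[str, str]]] = field(default_factory=list)

    @property
    def n_sympatric(self) -> int:
        return sum(self.sympatric.values())


def cooccurrence(site_table: SiteTable) -> SympatryReport:
    """Per-site genotype sets and the (symmetric) partner relation."""
    df = site_table.frame
    if df["genotype"].isna().any() or (df["genotype"] == "").any():
        raise ValueError("every site-table row must carry a genotype")
    site_genotypes = {
        str(site): frozenset(sub["genotype"])
        for site, sub in df.groupby("site_id", sort=False)
    }
    genotypes = sorted(set(df["genotype"]))
    partners: dict[str, set[str]] = {g: set() for g in genotypes}
    for present in site_genotypes.values():
        for g, h in itertools.combinations(sorted(present), 2):
            partners[g].add(h)
            partners[h].add(g)
    return SympatryReport(
        site_genotypes=site_genotypes,
        partners={g: frozenset(p) for g, p in partners.items()},
        sympatric={g: bool(partners[g]) for g in genotypes},
    )


def _union_bands(a: Sequence[int], b: Sequence[int],
                 gel: GelModel) -> tuple[int, ...]:
    """Band pattern of a superposition of two genotype profiles: the
    multiset union re-run through the co-migration merge."""
    return gel_bands(sorted(list(a) + list(b), reverse=True),
                     GelModel(min_detectable=1,
                              comigration_tolerance=gel.comigration_tolerance))


def isolation_evidence(report: SympatryReport,
                       its2_classes: Mapping[str, str],
                       individual_genotypes: Mapping[str, str],
                       individual_profiles: Mapping[str, Sequence[int]],
                       gel: GelModel = GelModel()) -> SympatryReport:
    """Complete a sympatry report with per-genotype isolation evidence.

    ``its2_classes`` maps individual -> spacer sequence class,
    ``individual_genotypes`` maps individual -> genotype label, and
    ``individual_profiles`` maps individual -> visible band multiset.
    Evidence for genotype g requires: g sympatric; no sequence class
    shared with any partner genotype; and no individual whose band
    pattern equals the superposition of two distinct genotype profiles
    (the hybrid test).
    """
    for ind in individual_profiles:
        if ind not in individual_genotypes:
            raise ValueError(f"individual {ind!r} has no genotype assignment")
    for ind in its2_classes:
        if ind not in individual_genotypes:
            raise ValueError(f"individual {ind!r} has no genotype assignment")

    classes_by_genotype: dict[str, set[str]] = {}
    for ind, cls in its2_classes.items():
        classes_by_genotype.setdefault(individual_genotypes[ind], set()).add(cls)

    # consensus profile per genotype = most common band pattern among its
    # individuals
    profile_by_genotype: dict[str, tuple[int, ...]] = {}
    by_geno: dict[str, Counter] = {}
    for ind, bands in individual_profiles.items():
        by_geno.setdefault(individual_genotypes[ind],
                           Counter())[tuple(bands)] += 1
    for g, ctr in by_geno.items():
        profile_by_genotype[g] = ctr.most_common(1)[0][0]

    hybrids: list[tuple[str, tuple[str, str]]] = []
    hybrid_genotypes: set[str] = set()
    for ind, bands in individual_profiles.items():
        for g, h in itertools.combinations(sorted(profile_by_genotype), 2):
            pg, ph = profile_by_genotype[g], profile_by_genotype[h]
            if pg == ph:
                continue
            union = _union_bands(pg, ph, gel)
            # a hybrid is only recognizable when the superposed pattern is
            # distinguishable from each parental pattern on its own
            if _bands_match(union, pg, gel.comigration_tolerance) or \
               _bands_match(union, ph, gel.comigration_tolerance):
                continue
            if _bands_match(tuple(bands), union, gel.comigration_tolerance):
                hybrids.append((ind, (g, h)))
                hybrid_genotypes.update((g, h))

    report.hybrids = hybrids
    for g, symp in report.sympatric.items():
        reasons = []
        if not symp:
            reasons.append("never sympatric")
        shared = {
            h for h in report.partners.get(g, frozenset())
            if classes_by_genotype.get(g, set()) & classes_by_genotype.get(h, set())
        }
        if shared:
            reasons.append(f"shares sequence classes with {sorted(shared)}")
        if g in hybrid_genotypes:
            reasons.append("hybrid-like band profile observed")
        report.isolation_evidence[g] = symp and not shared and g not in hybrid_genotypes
        report.reasons[g] = reasons or ["sympatric; no shared classes; no hybrid profiles"]
    return report
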