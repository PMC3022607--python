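"""Bundled field-survey summary tables for the *Anopheles longirostris*
cryptic-species complex of Papua New Guinea.

Four small published summary tables ship with the package so that the
tabulation and sympatry stages can be exercised without sequence data:
per-genotype specimen counts with the map sites each genotype occupied,
the per-site lists of co-occurring (sympatric) genotypes, the
restriction band sizes scored per genotype on a 3% agarose gel, and the
collection-site gazetteer with coordinates. Band sizes printed as
"<100" denote a visible fragment somewhere in [50, 100) bp whose exact
size was not resolved.

Unsubscripted "C" entries in the sympatry table are interpreted as C2,
the widespread C subtype (C1 was confined to a small northern area);
`sympatry_site_table` applies this reading.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

from .seqio import SiteTable

#: placeholder size (bp) used for bands printed as "<100": any value in
#: [50, 100) is consistent with the printed profile
SUB100_BP = 80


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("ribosplit") / "data" / name)


def genotype_abundance() -> pd.DataFrame:
    """Per-genotype specimen counts, published frequency (%) and occupied
    map sites."""
    df = pd.read_csv(_data_path("genotype_abundance.tsv"), sep="\t",
                     dtype={"genotype": str, "map_sites": str})
    df["map_sites"] = df["map_sites"].map(
        lambda s: tuple(x.strip() for x in s.split(",")))
    return df


def sympatric_sites(c_as: str = "C2") -> pd.DataFrame:
    """Per-site sympatric genotype lists; unsubscripted C mapped to
    ``c_as``."""
    df = pd.read_csv(_data_path("sympatric_sites.tsv"), sep="\t",
                     dtype={"site": str, "genotypes": str})
    df["genotypes"] = df["genotypes"].map(
        lambda s: tuple(c_as if g.strip() == "C" else g.strip()
                        for g in s.split(",")))
    return df


def sympatry_site_table(c_as: str = "C2") -> SiteTable:
    """The sympatry table recast as a SiteTable (one pseudo-individual per
    genotype presence per site) so it can feed the co-occurrence stage.
    Coordinates are not part of the published sympatry listing and are
    filled with 0."""
    rows = []
    for rec in sympatric_sites(c_as).itertuples():
        for g in rec.genotypes:
            rows.append({"site_id": rec.site, "latitude": 0.0,
                         "longitude": 0.0,
                         "individual": f"{rec.site}.{g}", "genotype": g})
    return SiteTable(pd.DataFrame(rows))


def rflp_band_sizes() -> dict[str, list[int]]:
    """Published band sizes (bp) per genotype; "<100" entries become
    SUB100_BP."""
    df = pd.read_csv(_data_path("rflp_band_sizes.tsv"), sep="\t",
                     dtype={"genotype": str, "bands": str})
    out = {}
    for rec in df.itertuples():
        out[rec.genotype] = [SUB100_BP if b.strip() == "<100" else int(b)
                             for b in rec.bands.split("/")]
    return out


def collection_sites() -> pd.DataFrame:
    """The collection-site gazetteer: map site number, field-year site
    code, coordinates and specimen counts (as printed; a parenthetical
    count marks additional specimens not genotyped)."""
    return pd.read_csv(_data_path("collection_sites.tsv"), sep="\t",
                       dtype={"map_site": str, "year_site": str,
                              "n_specimens": str})
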