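"""Simulator of rDNA spacer arrays evolving under incomplete concerted
evolution, paired with a faster-evolving single-copy mitochondrial locus
on the same species tree.

The model, deliberately the smallest that reproduces the observable:

- A species tree (supplied, or Yule/pure-birth) with ultrametric depth.
- Each species carries one rDNA array of ``array_copies`` tandem spacer
  copies. Along each branch the array experiences, in a Gillespie scheme
  with exact exponential waiting times: per-site substitutions (K2P with
  transition bias ``kappa``), intrachromosomal gene conversion (a random
  donor copy overwrites a random recipient, whole-spacer or geometric
  tract) which homogenizes the array, and tandem indels (duplication or
  deletion of a short adjacent motif). Because conversion is recurrent
  but not instantaneous, a few copy variants persist within each array
  and — since the array is inherited as a unit — are identical in every
  individual of a species: incomplete homogenization with fixation.
- A single-copy protein-coding locus ("COI") evolves on the same tree at
  ``sub_rate_coi`` (default 5x the spacer rate), optionally rejecting
  in-frame stop codons.
- Individuals inherit the species array (plus optional within-species
  noise); clones are copies sampled from the array with optional PCR
  error; species are scattered over collection sites with a configurable
  expected fraction of multi-species (sympatric) sites.

Every emitted record is described in a truth table, and known-answer
features (restriction sites, compensatory base changes, private
variants) can be engineered in for detector validation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .copy_variants import call_variants
from .seqio import MultipleAlignment, SeqRecord, SiteTable

BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS_INVERT_MITO = {"TAA", "TAG"}
_COI_GC = 0.45  # mildly AT-rich, as insect mtDNA protein genes are


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulation run.

    Rates are per unit branch length of the species tree. Defaults
    reproduce the empirical regime of the anopheline ITS2 system: ~680 bp
    amplicons (620 bp spacer + 30 bp conserved primer pad each side),
    spacer GC near 62%, a handful of fixed copy variants per species, and
    a mitochondrial locus evolving several-fold faster than the spacer.
    """

    n_species: int = 5
    tree: str | None = None            # newick; None -> Yule with birth_rate
    birth_rate: float = 1.0
    spacer_length: int = 620
    gc_target: float = 0.62
    array_copies: int = 20
    sub_rate_rdna: float = 0.04        # per site per unit time
    conversion_rate: float = 10000.0   # events per array per unit time
    conversion_tract: str = "whole_spacer"  # or "geometric:<mean bp>"
    indel_rate: float = 0.05           # events per copy per unit time
    indel_size_range: tuple[int, int] = (1, 10)
    sub_rate_coi: float = 0.2          # default 5 x sub_rate_rdna
    kappa: float = 2.0
    coi_length: int = 524
    codon_aware_coi: bool = False
    individuals_per_species: int = 3
    clones_per_individual: int = 5
    within_species_noise: float = 0.0  # per site
    pcr_error: float = 0.0             # per site per clone
    n_sites: int = 12
    sympatry_overlap: float = 0.5
    primer_pad: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.array_copies < 2:
            raise ValueError("array_copies must be >= 2")
        for name in ("sub_rate_rdna", "conversion_rate", "indel_rate",
                     "sub_rate_coi", "birth_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gc_target", "within_species_noise", "pcr_error",
                     "sympatry_overlap"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth for every emitted sequence plus per-species fixed
    variant descriptions and any engineered features."""

    records: list[dict] = field(default_factory=list)
    species_variants: dict[str, list[str]] = field(default_factory=dict)
    engineered: list[dict] = field(default_factory=list)


@dataclass
class Dataset:
    config: SimConfig
    tree: dendropy.Tree
    clones: list[SeqRecord]
    coi: list[SeqRecord]
    sites: SiteTable
    truth: TruthTable
    arrays: dict[str, list[str]]
    individual_arrays: dict[str, list[str]]
    individual_amplicons: dict[str, str]

    @property
    def coi_alignment(self) -> MultipleAlignment:
        return MultipleAlignment(tuple(self.coi))


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_tree(config: SimConfig,
                  rng: np.random.Generator | None = None) -> dendropy.Tree:
    """An ultrametric Yule (pure-birth) species tree with ``n_species``
    leaves labelled sp1..spN, or the supplied newick echoed after
    validation. Reproducible from the config seed."""
    if config.tree is not None:
        try:
            tree = dendropy.Tree.get(data=config.tree, schema="newick")
        except Exception as exc:
            raise ValueError(f"malformed supplied tree: {exc}") from exc
        return tree
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(config.n_species)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tips = [tree.seed_node]
    while len(tips) < config.n_species:
        wait = rng.exponential(1.0 / (config.birth_rate * len(tips)))
        for t in tips:
            t.edge.length = (t.edge.length or 0.0) + wait
        parent = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            tips.append(child)
    final = rng.exponential(1.0 / (config.birth_rate * len(tips)))
    for i, t in enumerate(tips):
        t.edge.length = (t.edge.length or 0.0) + final
        t.taxon = taxa[i]
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _mutate_base(base: str, kappa: float, gc: float,
                 rng: np.random.Generator) -> str:
    """One HKY mutation attempt at a site holding ``base``; may return the
    base unchanged (rejection thinning).

    HKY rates: rate(b->c) = pi_c, times kappa for transitions, with
    stationary frequencies pi set by the GC target. Sites are picked
    uniformly by the callers, so the per-base total leaving rate is
    implemented by accepting an attempt with probability Z_b / Z_max.
    Keeping the stationary composition at the GC target prevents long
    simulations from drifting toward 50% GC, mirroring the compositional
    stability of real spacers."""
    pi = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    z = {b: sum(pi[c] * (kappa if c == _TRANSITION[b] else 1.0)
                for c in "ACGT" if c != b) for b in "ACGT"}
    z_max = max(z.values())
    if rng.random() > z[base] / z_max:
        return base
    targets = [b for b in "ACGT" if b != base]
    w = np.array([pi[b] * (kappa if b == _TRANSITION[base] else 1.0)
                  for b in targets])
    return targets[int(rng.choice(3, p=w / w.sum()))]


def _apply_substitutions(seq: str, n: int, kappa: float, gc: float,
                         rng: np.random.Generator) -> str:
    if n <= 0:
        return seq
    chars = list(seq)
    for pos in rng.integers(0, len(chars), size=n):
        chars[pos] = _mutate_base(chars[pos], kappa, gc, rng)
    return "".join(chars)


def _poisson_noise(seq: str, rate: float, kappa: float, gc: float,
                   rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    return _apply_substitutions(seq, rng.poisson(rate * len(seq)), kappa, gc,
                                rng)


# ---------------------------------------------------------------------------
# array evolution
# ---------------------------------------------------------------------------

def _tract_length(tract: str, spacer_len: int, rng: np.random.Generator) -> int:
    if tract == "whole_spacer":
        return spacer_len
    if tract.startswith("geometric:"):
        mean = float(tract.split(":", 1)[1])
        return max(1, int(rng.geometric(1.0 / mean)))
    raise ValueError(f"unknown conversion_tract {tract!r}")


def _evolve_array_branch(array: list[str], t: float, config: SimConfig,
                         rng: np.random.Generator) -> list[str]:
    """Gillespie simulation of one branch: substitutions, gene
    conversions and tandem indels competing with exponential waiting
    times."""
    array = list(array)
    if config.sub_rate_rdna * t > 0.5:
        import logging
        logging.getLogger(__name__).warning(
            "branch expects %.2f substitutions/site (saturation)",
            config.sub_rate_rdna * t)
    clock = 0.0
    lo, hi = config.indel_size_range
    while True:
        total_sites = sum(len(c) for c in array)
        r_sub = config.sub_rate_rdna * total_sites
        r_conv = config.conversion_rate
        r_indel = config.indel_rate * len(array)
        r_total = r_sub + r_conv + r_indel
        if r_total <= 0:
            break
        clock += rng.exponential(1.0 / r_total)
        if clock > t:
            break
        u = rng.random() * r_total
        if u < r_sub:
            # substitution on a copy chosen in proportion to its length
            lengths = np.array([len(c) for c in array])
            ci = int(rng.choice(len(array), p=lengths / lengths.sum()))
            pos = int(rng.integers(lengths[ci]))
            c = array[ci]
            array[ci] = (c[:pos]
                         + _mutate_base(c[pos], config.kappa, config.gc_target,
                                        rng)
                         + c[pos + 1:])
        elif u < r_sub + r_conv:
            if len(array) >= 2:
                donor, recip = rng.choice(len(array), size=2, replace=False)
                L = _tract_length(config.conversion_tract,
                                  len(array[donor]), rng)
                if L >= len(array[donor]) or L >= len(array[recip]):
                    array[recip] = array[donor]
                else:
                    start = int(rng.integers(0, min(len(array[donor]),
                                                    len(array[recip])) - L + 1))
                    array[recip] = (array[recip][:start]
                                    + array[donor][start:start + L]
                                    + array[recip][start + L:])
        else:
            ci = int(rng.integers(len(array)))
            c = array[ci]
            size = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5 and len(c) > size + 1:
                pos = int(rng.integers(0, len(c) - size))
                array[ci] = c[:pos] + c[pos + size:]          # deletion
            else:
                pos = int(rng.integers(0, max(1, len(c) - size)))
                array[ci] = c[:pos + size] + c[pos:pos + size] + c[pos + size:]
    return array


def evolve_arrays(tree: dendropy.Tree, config: SimConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Evolve one spacer array down every branch of the species tree.

    Returns (arrays, fixed_variants): per-species list of spacer copies,
    and per-species human-readable diff events of each minority variant
    class relative to the majority copy.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ancestor = _random_seq(config.spacer_length, config.gc_target, rng)
    root_array = [ancestor] * config.array_copies

    arrays: dict[str, list[str]] = {}
    state: dict[int, list[str]] = {id(tree.seed_node): root_array}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_array = state[id(node.parent_node)]
        branch = node.edge.length or 0.0
        arr = _evolve_array_branch(parent_array, branch, config, rng)
        state[id(node)] = arr
        if node.is_leaf():
            arrays[node.taxon.label] = arr

    fixed_variants = {sp: describe_array_variants(sp, arr)
                      for sp, arr in arrays.items()}
    return arrays, fixed_variants


def describe_array_variants(species: str, array: Sequence[str]) -> list[str]:
    """Human-readable variant classes of an array relative to its majority
    copy (empty list when fully homogeneous)."""
    clones = [SeqRecord(id=f"{species}.copy{i}", residues=c, marker="ITS2",
                        individual=species)
              for i, c in enumerate(array)]
    vs = call_variants(clones)
    out = []
    for k, cls in enumerate(vs.variant_classes[1:], start=2):
        evs = ";".join(f"{e.kind}@{e.position}x{e.length}" for e in cls.diff_events)
        out.append(f"class{k}(n={cls.clone_count}):{evs}")
    return out


# ---------------------------------------------------------------------------
# feature engineering (known-answer planting)
# ---------------------------------------------------------------------------

def engineer_features(arrays: dict[str, list[str]], requests: list[dict],
                      truth: TruthTable | None = None) -> dict[str, list[str]]:
    """Apply minimal known-answer edits to species arrays.

    Supported requests:
      {"kind": "add_cut_site", "species": sp, "position": p}
      {"kind": "add_cbc", "species_pair": (a, b), "pair": (i, j)}
      {"kind": "add_private_variant", "individual": ind}  (deferred to
          emit_dataset, which deletes a short tract from one copy of that
          individual's array)
    Each applied request is recorded in the truth table. Conflicting
    requests (the feature already present) raise ValueError.
    """
    arrays = {sp: list(copies) for sp, copies in arrays.items()}
    truth = truth if truth is not None else TruthTable()
    for req in requests:
        kind = req["kind"]
        if kind == "add_cut_site":
            sp, p = req["species"], req["position"]
            copies = arrays[sp]
            if any(len(c) < p + 4 for c in copies):
                raise ValueError(f"position {p} outside spacer for {sp}")
            if all(c[p:p + 4] == "CCGG" for c in copies):
                raise ValueError(f"cut site already present at {p} in {sp}")
            arrays[sp] = [c[:p] + "CCGG" + c[p + 4:] for c in copies]
        elif kind == "add_cbc":
            a, b = req["species_pair"]
            i, j = req["pair"]
            if (arrays[a][0][i], arrays[a][0][j]) == ("G", "C") and \
               (arrays[b][0][i], arrays[b][0][j]) == ("A", "T"):
                raise ValueError(f"CBC already engineered at {(i, j)}")
            arrays[a] = [c[:i] + "G" + c[i + 1:j] + "C" + c[j + 1:]
                         for c in arrays[a]]
            arrays[b] = [c[:i] + "A" + c[i + 1:j] + "T" + c[j + 1:]
                         for c in arrays[b]]
        elif kind == "add_indel_variant":
            # species-level copy variant: a short deletion in the last copy
            # of the array, shared (fixed) across all individuals
            sp = req["species"]
            size = req.get("size", 3)
            copies = arrays[sp]
            c = copies[-1]
            mid = len(c) // 2
            arrays[sp] = copies[:-1] + [c[:mid] + c[mid + size:]]
        elif kind == "add_private_variant":
            pass  # applied at emission; recorded below
        else:
            raise ValueError(f"unknown request kind {kind!r}")
        truth.engineered.append(dict(req))
    return arrays


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def emit_dataset(tree: dendropy.Tree, arrays: dict[str, list[str]],
                 config: SimConfig,
                 fixed_variants: dict[str, list[str]] | None = None,
                 engineered: list[dict] | None = None,
                 rng: np.random.Generator | None = None) -> Dataset:
    """Emit clones, COI sequences, a site table and the truth table."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    truth = TruthTable(species_variants=dict(fixed_variants or {}))
    engineered = list(engineered or [])
    truth.engineered = [dict(r) for r in engineered]
    private = {r["individual"] for r in engineered
               if r["kind"] == "add_private_variant"}

    pad_left = _random_seq(config.primer_pad, 0.5, rng)
    pad_right = _random_seq(config.primer_pad, 0.5, rng)
    species = sorted(arrays)

    # COI on the same tree, faster clock
    coi_root = _make_coi_ancestor(config, rng)
    coi_by_species = _evolve_coi(tree, coi_root, config, rng)

    # site assignment: each site gets one primary species (every species
    # seeded at least once when n_sites >= n_species); with probability
    # sympatry_overlap a second, different species is added
    primary = [species[i % len(species)] for i in range(config.n_sites)]
    rng.shuffle(primary)
    site_species: list[set[str]] = []
    for sp in primary:
        present = {sp}
        if len(species) > 1 and rng.random() < config.sympatry_overlap:
            others = [s for s in species if s != sp]
            present.add(others[int(rng.integers(len(others)))])
        site_species.append(present)
    site_ids = [f"site{i + 1}" for i in range(config.n_sites)]

    clones: list[SeqRecord] = []
    coi: list[SeqRecord] = []
    site_rows: list[dict] = []
    individual_arrays: dict[str, list[str]] = {}
    individual_amplicons: dict[str, str] = {}

    for sp in species:
        candidate_sites = [i for i, pres in enumerate(site_species)
                           if sp in pres] or list(range(config.n_sites))
        for k in range(config.individuals_per_species):
            ind = f"{sp}_i{k + 1}"
            ind_array = [_poisson_noise(c, config.within_species_noise,
                                        config.kappa, config.gc_target, rng)
                         for c in arrays[sp]]
            if ind in private:
                ind_array[0] = _private_variant(ind_array[0])
            individual_arrays[ind] = ind_array
            maj = sorted(Counter(ind_array).items(),
                         key=lambda kv: (-kv[1], kv[0]))[0][0]
            individual_amplicons[ind] = pad_left + maj + pad_right
            site = site_ids[candidate_sites[int(rng.integers(len(candidate_sites)))]]
            site_rows.append({"site_id": site, "individual": ind, "genotype": sp})
            for c in range(config.clones_per_individual):
                copy = ind_array[int(rng.integers(len(ind_array)))]
                copy = _poisson_noise(copy, config.pcr_error, config.kappa,
                                      config.gc_target, rng)
                seq_id = f"{ind}_cl{c + 1}"
                clones.append(SeqRecord(id=seq_id,
                                        residues=pad_left + copy + pad_right,
                                        marker="ITS2", individual=ind,
                                        site=site, genotype=sp))
                truth.records.append({"seq_id": seq_id, "species": sp,
                                      "individual": ind, "clone_index": c + 1,
                                      "site": site, "marker": "ITS2"})
            coi_seq = _poisson_noise(coi_by_species[sp],
                                     config.within_species_noise, config.kappa,
                                     _COI_GC, rng)
            coi.append(SeqRecord(id=f"{ind}_coi", residues=coi_seq,
                                 marker="COI", individual=ind, site=site,
                                 genotype=sp))
            truth.records.append({"seq_id": f"{ind}_coi", "species": sp,
                                  "individual": ind, "clone_index": None,
                                  "site": site, "marker": "COI"})

    import pandas as pd
    lat = rng.uniform(-10.0, -2.0, size=config.n_sites)
    lon = rng.uniform(141.0, 150.0, size=config.n_sites)
    coords = {s: (la, lo) for s, la, lo in zip(site_ids, lat, lon)}
    frame = pd.DataFrame(
        [{"site_id": r["site_id"], "latitude": coords[r["site_id"]][0],
          "longitude": coords[r["site_id"]][1], "individual": r["individual"],
          "genotype": r["genotype"]} for r in site_rows])
    return Dataset(config=config, tree=tree, clones=clones, coi=coi,
                   sites=SiteTable(frame), truth=truth, arrays=arrays,
                   individual_arrays=individual_arrays,
                   individual_amplicons=individual_amplicons)


def _private_variant(copy: str) -> str:
    """A 3-bp deletion in the middle of one spacer copy: the smallest edit
    guaranteed to create an extra (indel) variant class."""
    mid = len(copy) // 2
    return copy[:mid] + copy[mid + 3:]


def _make_coi_ancestor(config: SimConfig, rng: np.random.Generator) -> str:
    seq = _random_seq(config.coi_length, _COI_GC, rng)
    if config.codon_aware_coi:
        seq = _purge_stops(seq, rng)
    return seq


def _purge_stops(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    for s in range(0, len(chars) - 2, 3):
        while "".join(chars[s:s + 3]) in _STOPS_INVERT_MITO:
            chars[s + 2] = "ACGT"[int(rng.integers(4))]
    return "".join(chars)


def _evolve_coi(tree: dendropy.Tree, root: str, config: SimConfig,
                rng: np.random.Generator) -> dict[str, str]:
    out: dict[str, str] = {}
    state = {id(tree.seed_node): root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = state[id(node.parent_node)]
        t = node.edge.length or 0.0
        n_subs = rng.poisson(config.sub_rate_coi * len(parent) * t)
        seq = _apply_substitutions(parent, n_subs, config.kappa, _COI_GC, rng)
        if config.codon_aware_coi:
            seq = _purge_stops(seq, rng)
        state[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = seq
    return out


def simulate(config: SimConfig, requests: list[dict] | None = None) -> Dataset:
    """One-call simulation: tree, arrays, optional engineered features,
    emitted dataset. Byte-deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    arrays, fixed = evolve_arrays(tree, config, rng)
    truth_engineered = list(requests or [])
    if requests:
        arrays = engineer_features(arrays, requests)
        fixed = {sp: describe_array_variants(sp, arr)
                 for sp, arr in arrays.items()}
    return emit_dataset(tree, arrays, config, fixed_variants=fixed,
                        engineered=truth_engineered, rng=rng)
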