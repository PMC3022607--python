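"""End-to-end analysis pipeline.

Wires the stages into one run: simulate (or load) a dataset, genotype
individuals by in-silico RFLP, refine genotypes by heteroduplex copy-
variant signatures, test fixation, summarize alignments, build a
distance matrix / NJ tree with bootstrap and monophyly checks, score
sympatry-based reproductive isolation, and (when a structure is
available) run the CBC screen. Produces a JSON-serializable report whose
every number is recomputable from the stage outputs it cites.

Genotype labels propagate consistently: the heteroduplex-signature
partition always refines the RFLP partition (an RFLP class whose members
carry different signatures splits into numbered subtypes, e.g. C -> C1,
C2; classes are never merged).
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .aln_stats import classify_columns, collapse_haplotypes, gc_content
from .copy_variants import call_variants, duplex_signature, fixation_test
from .distances import (bootstrap_support, divergence_summary, monophyly,
                        pairwise_steps)
from .rflp import MSP_I, Enzyme, GelModel, cluster_profiles, digest
from .seqio import (MultipleAlignment, SeqRecord, SiteTable, read_sequences,
                    read_site_table, read_structure, write_sequences,
                    write_site_table)
from .simulator import Dataset, SimConfig, simulate
from .sympatry import cooccurrence, isolation_evidence
from .cbc import screen as cbc_screen

logger = logging.getLogger(__name__)


def _majority_amplicon(clones: list[SeqRecord]) -> SeqRecord:
    """The individual's dominant PCR product: its most common clone
    sequence (ties broken lexicographically)."""
    counts = Counter(c.ungapped for c in clones)
    seq = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    return SeqRecord(id=clones[0].individual or clones[0].id, residues=seq,
                     marker="ITS2", individual=clones[0].individual)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None,
                 n_bootstrap: int = 100) -> dict[str, Any]:
    """Run the full analysis; returns the report dict (also written to
    ``outdir/report.json`` with intermediate artifacts when an output
    directory is given).

    ``config`` is a dict (or YAML path) with either a ``simulate`` block
    (SimConfig fields) or an ``inputs`` block naming clones_fasta,
    coi_alignment and sites_tsv files; an optional ``structure`` entry
    (path, plus template/pair ids) enables the CBC screen.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    gel = GelModel(**config.get("gel", {}))
    enzyme = MSP_I if "enzyme" not in config else Enzyme(**config["enzyme"])

    dataset: Dataset | None = None
    if "simulate" in config:
        sim_cfg = SimConfig(**config["simulate"])
        dataset = simulate(sim_cfg, requests=config.get("engineer"))
        clones = dataset.clones
        coi_records = dataset.coi
        sites = dataset.sites
    elif "inputs" in config:
        inputs = config["inputs"]
        clones = read_sequences(inputs["clones_fasta"], "fasta", marker="ITS2")
        coi_records = (read_sequences(inputs["coi_alignment"],
                                      inputs.get("coi_format", "phylip_relaxed"),
                                      marker="COI")
                       if "coi_alignment" in inputs else [])
        sites = (read_site_table(inputs["sites_tsv"])
                 if "sites_tsv" in inputs else None)
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")

    report: dict[str, Any] = {}

    # ---- stage: copy-variant signatures per individual -------------------
    # A native heteroduplex gel sees the bulk PCR of the whole array, so in
    # simulation mode the signature is scored on the individual's full
    # amplified pool; with file inputs it is approximated from the cloned
    # sequences (rare copy variants may then escape detection).
    by_individual: dict[str, list[SeqRecord]] = {}
    for c in clones:
        by_individual.setdefault(c.individual or c.id, []).append(c)
    if dataset is not None:
        variant_sets = {
            ind: call_variants([SeqRecord(id=f"{ind}.copy{i}", residues=c,
                                          marker="ITS2", individual=ind)
                                for i, c in enumerate(pool)])
            for ind, pool in dataset.individual_arrays.items()}
    else:
        variant_sets = {ind: call_variants(cl)
                        for ind, cl in by_individual.items() if len(cl) >= 2}
    signatures = {ind: duplex_signature(vs) for ind, vs in variant_sets.items()}

    # ---- stage: RFLP digestion & clustering ------------------------------
    # same bulk-vs-clones distinction as above: the agarose lane shows the
    # digest of the whole PCR product, whose dominant species is the
    # majority array copy
    if dataset is not None:
        amplicons = [SeqRecord(id=ind, residues=seq, marker="ITS2",
                               individual=ind)
                     for ind, seq in dataset.individual_amplicons.items()]
    else:
        amplicons = [_majority_amplicon(cl) for cl in by_individual.values()]
    profiles = {a.id: digest(a, enzyme, gel) for a in amplicons}
    rflp_assignment = cluster_profiles(
        [(a.id, profiles[a.id].visible_bands) for a in amplicons], gel)
    n_rflp = len(set(rflp_assignment.values()))

    # ---- stage: signature refinement of RFLP classes ---------------------
    genotype_of: dict[str, str] = {}
    for rflp_class in sorted(set(rflp_assignment.values())):
        members = sorted(i for i, cls in rflp_assignment.items()
                         if cls == rflp_class)
        sig_groups: dict[Any, list[str]] = {}
        for ind in members:
            sig_groups.setdefault(signatures.get(ind), []).append(ind)
        if len(sig_groups) == 1:
            for ind in members:
                genotype_of[ind] = rflp_class
        else:
            ordered = sorted(sig_groups.values(), key=lambda ms: ms[0])
            for k, inds in enumerate(ordered, start=1):
                for ind in inds:
                    genotype_of[ind] = f"{rflp_class}{k}"
    n_genotypes = len(set(genotype_of.values()))
    report["n_rflp_classes"] = n_rflp
    report["n_signature_classes"] = n_genotypes
    report["rflp_classes"] = rflp_assignment
    report["genotypes"] = genotype_of
    report["rflp_bands"] = {i: list(p.visible_bands) for i, p in profiles.items()}

    # ---- stage: fixation within genotypes --------------------------------
    fixation: dict[str, bool] = {}
    for g in sorted(set(genotype_of.values())):
        members = [variant_sets[i] for i in variant_sets
                   if genotype_of.get(i) == g]
        if len(members) >= 2:
            fixed, _ = fixation_test(members)
            fixation[g] = fixed
    report["fixation"] = fixation

    # ---- stage: alignment statistics -------------------------------------
    aln_reports: dict[str, Any] = {}
    coi_aln: MultipleAlignment | None = None
    if len(coi_records) >= 2 and len({len(r.residues) for r in coi_records}) == 1:
        coi_aln = MultipleAlignment(tuple(coi_records))
        aln_reports["COI"] = _aln_report(coi_aln)
    if len({len(c.residues) for c in clones}) == 1 and len(clones) >= 2:
        aln_reports["ITS2"] = _aln_report(MultipleAlignment(tuple(clones)))
    else:
        logger.info("ITS2 clones are length-variable (indels); column "
                    "statistics need an aligned input and were skipped")
    report["alignment_stats"] = aln_reports
    # GC needs no alignment; always reported for the spacer clones
    report["its2_gc_mean"] = round(gc_content(clones).mean, 4)

    # ---- stage: distances, tree, monophyly (COI) -------------------------
    if coi_aln is not None and len(coi_aln) >= 3:
        labels = {r.id: genotype_of.get(r.individual, r.genotype or r.id)
                  for r in coi_aln.records}
        dm = pairwise_steps(coi_aln)
        div = divergence_summary(dm, labels)
        tree = bootstrap_support(coi_aln, n_reps=n_bootstrap,
                                 seed=config.get("seed", 0))
        mono = monophyly(tree, labels)
        report["divergence"] = {
            "max_intra_steps": div.max_intra,
            "min_inter_steps": {f"{a}|{b}": v
                                for (a, b), v in div.min_inter.items()},
            "barcode_gap": div.barcode_gap,
            "overlap_witnesses": [
                {"pair": list(p), "min_inter": m, "max_intra": i}
                for p, m, i in div.overlap_witnesses],
        }
        report["monophyly"] = {g: {"monophyletic": ok, "covering_clade": n}
                               for g, (ok, n) in mono.items()}
        report["tree_newick"] = tree.as_string(schema="newick").strip()

    # ---- stage: sympatry & reproductive isolation ------------------------
    if sites is not None and len(sites) > 0:
        frame = sites.frame.copy()
        frame["genotype"] = [genotype_of.get(ind, g) for ind, g in
                             zip(frame["individual"], frame["genotype"])]
        symp = cooccurrence(SiteTable(frame))
        its2_classes = {ind: vs.variant_classes[0].representative
                        for ind, vs in variant_sets.items()}
        ind_profiles = {i: p.visible_bands for i, p in profiles.items()}
        ind_genotypes = {i: genotype_of[i] for i in genotype_of}
        symp = isolation_evidence(symp, its2_classes, ind_genotypes,
                                  ind_profiles, gel)
        report["sympatry"] = {
            "n_sympatric": symp.n_sympatric,
            "n_genotypes": len(symp.sympatric),
            "sympatric": symp.sympatric,
            "partners": {g: sorted(p) for g, p in symp.partners.items()},
            "isolation_evidence": symp.isolation_evidence,
            "hybrids": [{"individual": i, "pair": list(p)}
                        for i, p in symp.hybrids],
        }
    else:
        logger.info("empty or missing site table; sympatry stage skipped")

    # ---- stage: CBC screen (needs a structure input) ---------------------
    if "structure" in config:
        sc = config["structure"]
        structure = read_structure(sc["path"])
        aln = MultipleAlignment(tuple(clones)) if "alignment" not in sc else \
            MultipleAlignment(tuple(read_sequences(sc["alignment"], "fasta")))
        cls = cbc_screen(aln, structure, sc["seq_a"], sc["seq_b"])
        report["cbc"] = cls.totals

    report["provenance"] = {
        "version": __version__,
        "seed": config.get("simulate", {}).get("seed", config.get("seed")),
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sequences(clones, outdir / "clones.fasta", "fasta")
        if coi_records:
            write_sequences(coi_records, outdir / "coi.fasta", "fasta")
        if sites is not None:
            write_site_table(sites, outdir / "sites.tsv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       default=str))
        (outdir / "report.txt").write_text(summarize(report))
    return report


def _aln_report(aln: MultipleAlignment) -> dict[str, Any]:
    cc = classify_columns(aln)
    gc = gc_content(aln.records)
    hap = collapse_haplotypes(aln)
    return {
        "n_sequences": len(aln),
        "length": aln.length,
        "constant": cc.n_constant,
        "parsimony_informative": cc.n_parsimony_informative,
        "variable_uninformative": cc.n_variable_uninformative,
        "gap_or_missing_columns": cc.n_gap_or_missing_columns,
        "gc_mean": round(gc.mean, 4),
        "gc_min": round(gc.min, 4),
        "gc_max": round(gc.max, 4),
        "n_haplotypes": hap.n_haplotypes,
    }


def summarize(report: dict[str, Any]) -> str:
    """Short human-readable narrative of a pipeline report."""
    lines = [
        f"RFLP classes: {report.get('n_rflp_classes')}",
        f"genotypes after heteroduplex refinement: {report.get('n_signature_classes')}",
    ]
    if report.get("fixation"):
        fixed = sum(report["fixation"].values())
        lines.append(f"fixation: {fixed}/{len(report['fixation'])} genotypes "
                     "show a fixed copy-variant signature")
    for marker, st in report.get("alignment_stats", {}).items():
        lines.append(
            f"{marker}: {st['n_sequences']} seqs x {st['length']} cols; "
            f"constant {st['constant']}, PI {st['parsimony_informative']}, "
            f"VU {st['variable_uninformative']}; GC mean {st['gc_mean']:.3f}; "
            f"{st['n_haplotypes']} haplotypes")
    if "monophyly" in report:
        mono = report["monophyly"]
        ok = sum(1 for v in mono.values() if v["monophyletic"])
        lines.append(f"monophyly: {ok}/{len(mono)} genotypes monophyletic")
    if "sympatry" in report:
        s = report["sympatry"]
        lines.append(f"sympatry: {s['n_sympatric']}/{s['n_genotypes']} "
                     "genotypes sympatric")
        iso = sum(s["isolation_evidence"].values())
        lines.append(f"isolation evidence for {iso} genotypes")
    if "cbc" in report:
        lines.append(f"CBC screen: {report['cbc']}")
    return "\n".join(lines) + "\n"
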