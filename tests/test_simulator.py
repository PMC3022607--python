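"""Behavior of the incomplete-concerted-evolution simulator."""

import logging

import numpy as np
import pytest

from ribosplit.aln_stats import gc_content
from ribosplit.copy_variants import call_variants, fixation_test
from ribosplit.rflp import find_cut_sites
from ribosplit.seqio import SeqRecord
from ribosplit.simulator import (SimConfig, Dataset, engineer_features,
                                 simulate, simulate_tree)

TREE5 = "((sp1:1.6,sp2:1.6):0.8,(sp3:1.6,(sp4:1.0,sp5:1.0):0.6):0.8);"

SMALL = dict(n_species=3, tree="((sp1:1.2,sp2:1.2):0.6,sp3:1.8);",
             individuals_per_species=2, clones_per_individual=3, n_sites=6)


class TestSimulateTree:
    def test_leaf_and_internal_node_counts(self):
        tree = simulate_tree(SimConfig(n_species=9, seed=4))
        assert len(tree.leaf_nodes()) == 9
        assert len(tree.internal_nodes()) == 8

    def test_two_species_is_a_cherry(self):
        tree = simulate_tree(SimConfig(n_species=2, seed=4))
        assert len(tree.leaf_nodes()) == 2

    def test_same_seed_same_tree(self):
        a = simulate_tree(SimConfig(n_species=6, seed=9))
        b = simulate_tree(SimConfig(n_species=6, seed=9))
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_supplied_tree_echoed(self):
        tree = simulate_tree(SimConfig(n_species=5, tree=TREE5, seed=0))
        assert sorted(l.taxon.label for l in tree.leaf_nodes()) == \
            ["sp1", "sp2", "sp3", "sp4", "sp5"]

    def test_malformed_tree_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            simulate_tree(SimConfig(n_species=2, tree="((a:1,b:1;", seed=0))


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        a = simulate(SimConfig(seed=5, **SMALL))
        b = simulate(SimConfig(seed=5, **SMALL))
        assert [c.residues for c in a.clones] == [c.residues for c in b.clones]
        assert [c.residues for c in a.coi] == [c.residues for c in b.coi]
        assert a.sites.frame.equals(b.sites.frame)
        assert a.truth.records == b.truth.records

    def test_different_seed_differs(self):
        a = simulate(SimConfig(seed=5, **SMALL))
        b = simulate(SimConfig(seed=6, **SMALL))
        assert [c.residues for c in a.clones] != [c.residues for c in b.clones]


class TestLimits:
    def test_no_mutation_limit_all_copies_ancestral(self):
        ds = simulate(SimConfig(seed=2, sub_rate_rdna=0.0, indel_rate=0.0,
                                **SMALL))
        copies = {c for arr in ds.arrays.values() for c in arr}
        assert len(copies) == 1

    def test_homogenization_limit_single_class(self):
        """With conversion ~100x the array-wide mutation influx, arrays
        are (near-)homogeneous; weak conversion leaves them polymorphic."""
        base = dict(seed=2, spacer_length=200, array_copies=10,
                    indel_rate=0.0, n_species=2, tree="(sp1:0.3,sp2:0.3);",
                    individuals_per_species=1, clones_per_individual=2,
                    n_sites=2)
        influx = 200 * 10 * SimConfig(n_species=2).sub_rate_rdna
        strong = simulate(SimConfig(conversion_rate=100 * influx, **base))
        weak = simulate(SimConfig(conversion_rate=influx, **base))
        mean = lambda ds: np.mean(
            [len(v) + 1 for v in ds.truth.species_variants.values()])
        assert mean(strong) <= 1.5
        assert mean(strong) < mean(weak)

    def test_incomplete_homogenization_leaves_variants(self):
        ds = simulate(SimConfig(seed=2, **SMALL))
        assert any(len(v) > 0 for v in ds.truth.species_variants.values())

    def test_gc_tracks_target(self):
        ds = simulate(SimConfig(seed=2, **SMALL))
        recs = [SeqRecord(id=f"{sp}.{i}", residues=c)
                for sp, arr in ds.arrays.items() for i, c in enumerate(arr)]
        assert abs(gc_content(recs).mean - 0.62) < 0.02

    def test_faster_coi_clock_ordering(self):
        ds = simulate(SimConfig(seed=2, **SMALL))
        sps = sorted(ds.arrays)
        coi = {r.individual: r.residues for r in ds.coi}

        def pdist(x, y):
            n = sum(1 for a, b in zip(x, y) if a != b)
            return n / min(len(x), len(y))

        coi_d, its_d = [], []
        for i in range(len(sps)):
            for j in range(i + 1, len(sps)):
                coi_d.append(pdist(coi[f"{sps[i]}_i1"], coi[f"{sps[j]}_i1"]))
                its_d.append(pdist(ds.arrays[sps[i]][0], ds.arrays[sps[j]][0]))
        assert np.mean(coi_d) > np.mean(its_d)

    def test_saturation_warning_logged(self, caplog):
        with caplog.at_level(logging.WARNING):
            simulate(SimConfig(seed=1, sub_rate_rdna=1.0, n_species=2,
                               tree="(sp1:2,sp2:2);",
                               individuals_per_species=1,
                               clones_per_individual=2, n_sites=2))
        assert "saturation" in caplog.text


class TestEmission:
    def test_record_arithmetic(self):
        ds = simulate(SimConfig(seed=0, tree=TREE5, n_species=5))
        assert len(ds.clones) == 5 * 3 * 5
        assert len(ds.coi) == 5 * 3
        assert len(ds.truth.records) == 75 + 15

    def test_no_noise_clones_are_exact_array_copies(self):
        ds = simulate(SimConfig(seed=3, **SMALL))
        pad = ds.config.primer_pad
        for c in ds.clones:
            spacer = c.residues[pad:-pad]
            assert spacer in ds.individual_arrays[c.individual]

    def test_zero_overlap_sites_single_species(self):
        ds = simulate(SimConfig(seed=3, sympatry_overlap=0.0, **SMALL))
        per_site = ds.sites.frame.groupby("site_id")["genotype"].nunique()
        assert (per_site == 1).all()

    def test_fixation_across_conspecific_individuals(self):
        """With zero within-species noise every individual inherits the
        species array unchanged: duplex signatures are fixed."""
        ds = simulate(SimConfig(seed=4, **SMALL))
        for sp in ds.arrays:
            group = []
            for ind, pool in ds.individual_arrays.items():
                if ind.startswith(sp + "_"):
                    group.append(call_variants(
                        [SeqRecord(id=f"{ind}.c{i}", residues=s,
                                   individual=ind)
                         for i, s in enumerate(pool)]))
            fixed, _ = fixation_test(group)
            assert fixed


class TestEngineering:
    CFG = dict(n_species=2, tree="(sp1:1,sp2:1);", sub_rate_rdna=0.0,
               indel_rate=0.0, individuals_per_species=2,
               clones_per_individual=3, n_sites=4)

    def test_add_cut_site_creates_cut(self):
        ds = simulate(SimConfig(seed=1, **self.CFG),
                      requests=[{"kind": "add_cut_site", "species": "sp1",
                                 "position": 50}])
        rec = SeqRecord(id="x", residues=ds.arrays["sp1"][0])
        assert 51 in find_cut_sites(rec)
        base = SeqRecord(id="y", residues=ds.arrays["sp2"][0])
        assert 51 not in find_cut_sites(base)

    def test_conflicting_cut_site_request_errors(self):
        ds = simulate(SimConfig(seed=1, **self.CFG),
                      requests=[{"kind": "add_cut_site", "species": "sp1",
                                 "position": 50}])
        with pytest.raises(ValueError, match="already"):
            engineer_features(ds.arrays,
                              [{"kind": "add_cut_site", "species": "sp1",
                                "position": 50}])

    def test_private_variant_breaks_fixation_for_that_species_only(self):
        ds = simulate(SimConfig(seed=1, **self.CFG),
                      requests=[{"kind": "add_private_variant",
                                 "individual": "sp1_i1"}])
        result = {}
        for sp in ("sp1", "sp2"):
            group = [call_variants(
                [SeqRecord(id=f"{ind}.c{i}", residues=s, individual=ind)
                 for i, s in enumerate(pool)])
                for ind, pool in ds.individual_arrays.items()
                if ind.startswith(sp + "_")]
            result[sp], _ = fixation_test(group)
        assert result == {"sp1": False, "sp2": True}

    def test_indel_variant_is_species_wide(self):
        ds = simulate(SimConfig(seed=1, **self.CFG),
                      requests=[{"kind": "add_indel_variant",
                                 "species": "sp2", "size": 4}])
        lengths = {len(c) for c in ds.arrays["sp2"]}
        assert len(lengths) == 2
        for ind, pool in ds.individual_arrays.items():
            if ind.startswith("sp2_"):
                assert {len(c) for c in pool} == lengths

    def test_unknown_request_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown request"):
            engineer_features({"sp1": ["ACGT" * 20]}, [{"kind": "nope"}])
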