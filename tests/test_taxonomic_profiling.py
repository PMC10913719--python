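"""Classifier-family contracts: index LCA labels, path-score classification
against an exhaustive enumerator, confidence-threshold semantics,
species reestimation arithmetic, and the marker profiler."""

import numpy as np
import pytest

import mtxworkbench as wb
from mtxworkbench import _kmers
from mtxworkbench.errors import MarkerUniquenessError, ParameterError
from mtxworkbench.preprocess import run_preprocess
from mtxworkbench.reads import ReadSet
from mtxworkbench.synthetic_community import ReferenceSet
from mtxworkbench.taxonomic_profiling import (
    build_kmer_index,
    build_marker_db,
    classify_read,
    classify_readset,
    profile_markers,
    reestimate_species,
    robust_average,
)
from mtxworkbench.taxonomy import TaxonNode, TaxonomyTree

from . import oracles

K = 31


@pytest.fixture(scope="module")
def hand_universe():
    """Two congeneric species plus one species in a sibling genus, with a
    genus-shared segment and a phylum-shared segment planted explicitly."""
    rng = np.random.default_rng(99)

    def rand(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    genus_block = rand(80)
    phylum_block = rand(80)
    genomes = {
        "SA1": rand(600) + genus_block + rand(600) + phylum_block + rand(600),
        "SA2": rand(600) + genus_block + rand(1280),
        "SB1": rand(1400) + phylum_block + rand(600),
    }
    tree = TaxonomyTree([
        TaxonNode("R", None, "root", "root"),
        TaxonNode("D1", "R", "domain", "Bacteria"),
        TaxonNode("P1", "D1", "phylum", "PhylumA"),
        TaxonNode("GA", "P1", "genus", "GenusA"),
        TaxonNode("GB", "P1", "genus", "GenusB"),
        TaxonNode("SA1", "GA", "species", "SpeciesA1"),
        TaxonNode("SA2", "GA", "species", "SpeciesA2"),
        TaxonNode("SB1", "GB", "species", "SpeciesB1"),
    ])
    ref = ReferenceSet(species_genomes={s: [g] for s, g in genomes.items()})
    index = build_kmer_index(ref, tree, k=K)
    # independent canonical-kmer -> taxon map for the oracle classifier
    kmer_map = {}
    for sid, (genome,) in ((s, ref.species_genomes[s]) for s in genomes):
        for km in oracles.read_kmers(genome, K):
            canon = oracles.canonical_kmer(km)
            owners = oracles.genomes_containing(km, ref.species_genomes)
            kmer_map[canon] = oracles.lca_by_ancestors(tree, owners)
    return tree, ref, index, kmer_map


class TestKmerIndex:
    def test_unique_kmers_map_to_their_species(self, hand_universe):
        tree, ref, index, kmer_map = hand_universe
        genome = ref.species_genomes["SB1"][0]
        probe = genome[:K]  # outside any shared block
        code = _kmers.seq_canonical_codes(probe, K)
        lin = tree.linearize()
        assert lin.ids[index.table.lookup(code)[0]] == "SB1"

    def test_every_indexed_kmer_matches_brute_force_lca(self, hand_universe):
        tree, ref, index, kmer_map = hand_universe
        lin = tree.linearize()
        for canon, expected in kmer_map.items():
            code = np.array([oracles.kmer_code(canon)], dtype=np.uint64)
            assert lin.ids[index.table.lookup(code)[0]] == expected

    def test_genus_and_phylum_shared_segments_label_internal_nodes(
        self, hand_universe
    ):
        tree, ref, index, kmer_map = hand_universe
        labels = set(kmer_map.values())
        assert "GA" in labels    # genus-shared block
        assert "P1" in labels    # block shared across the two genera
        lin = tree.linearize()
        g = ref.species_genomes["SA1"][0]
        genus_kmer = g[600 + 20 : 600 + 20 + K]
        code = _kmers.seq_canonical_codes(genus_kmer, K)
        assert lin.ids[index.table.lookup(code)[0]] == "GA"

    def test_kmer_totals_count_distinct_genome_kmers(self, hand_universe):
        _, ref, index, _ = hand_universe
        for sid, (genome,) in ((s, ref.species_genomes[s]) for s in ref.species_genomes):
            expected = len({oracles.canonical_kmer(k)
                            for k in oracles.read_kmers(genome, K)})
            assert index.kmer_totals[sid] == expected

    def test_even_k_rejected(self, hand_universe):
        _, ref, _, _ = hand_universe
        tree = hand_universe[0]
        with pytest.raises(ParameterError):
            build_kmer_index(ref, tree, k=20)


class TestClassifyRead:
    def test_unique_region_read_is_fully_confident(self, hand_universe):
        tree, ref, index, _ = hand_universe
        read = ref.species_genomes["SB1"][0][100:200]
        rc = classify_read(read, index, tree, 0.05)
        assert rc.assigned_taxon == "SB1"
        assert rc.confidence == pytest.approx(1.0)

    def test_half_species_half_genus_read(self, hand_universe):
        """Genus hits sit on the species' root path, so the species wins the
        path score; its clade confidence counts only species-level hits."""
        tree, ref, index, kmer_map = hand_universe
        g = ref.species_genomes["SA1"][0]
        read = g[600 - 50 : 600 + 50]  # half unique to SA1, half genus block
        rc = classify_read(read, index, tree, 0.05)
        expected_taxon, expected_conf = oracles.classify_by_path_scores(
            read, kmer_map, tree, 0.05, K
        )
        assert rc.assigned_taxon == expected_taxon == "SA1"
        assert rc.confidence == pytest.approx(expected_conf)
        assert 0 < rc.confidence < 1

    def test_high_threshold_ascends_to_genus(self, hand_universe):
        tree, ref, index, kmer_map = hand_universe
        g = ref.species_genomes["SA1"][0]
        read = g[600 - 50 : 600 + 50]
        rc = classify_read(read, index, tree, 0.9)
        expected_taxon, _ = oracles.classify_by_path_scores(read, kmer_map, tree,
                                                            0.9, K)
        assert rc.assigned_taxon == expected_taxon
        assert tree.depth(rc.assigned_taxon) < tree.depth("SA1")

    def test_threshold_boundaries(self, hand_universe):
        tree, ref, index, _ = hand_universe
        read = ref.species_genomes["SA2"][0][50:150]
        assert classify_read(read, index, tree, 0.0).assigned_taxon == "SA2"
        assert classify_read(read, index, tree, 1.0).assigned_taxon == "SA2"
        foreign = "AC" * 50  # not in any genome
        rc = classify_read(foreign, index, tree, 0.0)
        assert rc.assigned_taxon == "unclassified"

    def test_short_read_is_unclassified_with_zero_confidence(self, hand_universe):
        tree, _, index, _ = hand_universe
        rc = classify_read("ACGT", index, tree, 0.0)
        assert rc.assigned_taxon == "unclassified"
        assert rc.confidence == 0.0

    def test_agrees_with_exhaustive_enumerator_on_simulated_reads(
        self, hand_universe
    ):
        """Oracle equivalence on ~50 error-bearing reads per threshold."""
        tree, ref, index, kmer_map = hand_universe
        rng = np.random.default_rng(5)
        genomes = [g for (g,) in ref.species_genomes.values()]
        for threshold in (0.0, 0.05, 0.2, 0.5):
            for _ in range(50):
                g = genomes[rng.integers(0, len(genomes))]
                start = int(rng.integers(0, len(g) - 100))
                read = list(g[start : start + 100])
                for pos in rng.integers(0, 100, size=rng.integers(0, 4)):
                    read[pos] = "ACGT"[rng.integers(0, 4)]
                read = "".join(read)
                rc = classify_read(read, index, tree, threshold)
                taxon, conf = oracles.classify_by_path_scores(
                    read, kmer_map, tree, threshold, K
                )
                assert rc.assigned_taxon == (taxon or "unclassified")
                assert rc.confidence == pytest.approx(conf)

    def test_classification_conservation(self, small_fixture):
        reads = wb.simulate_sample(
            small_fixture.ref, small_fixture.community,
            wb.MixSpec(0.0, 3000, 61, "cell_ratio"),
        )
        counts, unclassified, assignments = classify_readset(
            reads, small_fixture.kmer_index, 0.05
        )
        assert sum(counts.values()) + unclassified == len(reads)
        assert len(assignments) == len(reads)

    def test_raising_threshold_never_classifies_more(self, small_fixture):
        """Monotonicity behind 'precision maximized without changing recall':
        a stricter threshold can only move reads toward unclassified."""
        reads = wb.simulate_sample(
            small_fixture.ref, small_fixture.community,
            wb.MixSpec(0.7, 4000, 67, "cell_ratio"),
        )
        kept, _ = run_preprocess(reads, index=small_fixture.depletion_index)
        classified_sets = []
        fp_counts = []
        mock = {m.taxon_id for m in small_fixture.community.species}
        for threshold in (0.0, 0.05, 0.2, 0.5):
            counts, _, assignments = classify_readset(
                kept, small_fixture.kmer_index, threshold
            )
            classified_sets.append(
                {i for i, a in zip(kept.ids, assignments) if a != "unclassified"}
            )
            profile = reestimate_species(counts, small_fixture.tree,
                                         small_fixture.kmer_index.kmer_totals)
            fp_counts.append(len(profile.detected() - mock))
        for tighter, looser in zip(classified_sets[1:], classified_sets):
            assert tighter <= looser
        assert fp_counts == sorted(fp_counts, reverse=True)


class TestReestimate:
    def test_species_only_counts_are_unchanged(self, hand_universe):
        tree = hand_universe[0]
        profile = reestimate_species({"SA1": 30.0, "SB1": 10.0}, tree)
        assert profile.counts == {"SA1": 30.0, "SB1": 10.0}
        assert profile.abundances["SA1"] == pytest.approx(0.75)

    def test_internal_counts_split_proportionally_to_direct_evidence(
        self, hand_universe
    ):
        tree = hand_universe[0]
        profile = reestimate_species({"GA": 10.0, "SA1": 30.0, "SA2": 10.0}, tree)
        expected = oracles.redistribute(10.0, {"SA1": 30.0, "SA2": 10.0})
        assert profile.counts["SA1"] == pytest.approx(30.0 + expected["SA1"])
        assert profile.counts["SA2"] == pytest.approx(10.0 + expected["SA2"])

    def test_kmer_total_fallback_when_no_direct_evidence(self, hand_universe):
        tree = hand_universe[0]
        profile = reestimate_species({"GA": 12.0}, tree,
                                     kmer_totals={"SA1": 2, "SA2": 1})
        assert profile.counts["SA1"] == pytest.approx(8.0)
        assert profile.counts["SA2"] == pytest.approx(4.0)

    def test_total_count_is_conserved(self, hand_universe):
        tree = hand_universe[0]
        counts = {"R": 5.0, "P1": 3.0, "GA": 7.0, "SA1": 11.0, "SB1": 2.0}
        profile = reestimate_species(counts, tree)
        assert profile.total_count() == pytest.approx(sum(counts.values()))
        profile.check()


@pytest.fixture(scope="module")
def marker_db(small_fixture):
    return build_marker_db(small_fixture.ref, small_fixture.tree,
                           marker_len=200, markers_per_species=6, seed=2)


class TestMarkers:
    def test_marker_cardinality(self, marker_db, small_fixture):
        per_species = marker_db.species_markers()
        assert set(per_species) == set(small_fixture.ref.species_pangenomes)
        assert all(len(v) == 6 for v in per_species.values())

    def test_markers_are_unique_across_genomes(self, marker_db, small_fixture):
        """Substring-containment oracle: no marker occurs in another species'
        genome on either strand — windows overlapping the congeneric shared
        block are rejected."""
        for m in marker_db.markers:
            for sid, seqs in small_fixture.ref.species_genomes.items():
                if sid == m.species:
                    continue
                for s in seqs:
                    assert m.sequence not in s
                    assert oracles.revcomp(m.sequence) not in s

    def test_impossible_marker_request_names_the_species(self, small_fixture):
        with pytest.raises(MarkerUniquenessError, match="S01"):
            build_marker_db(small_fixture.ref, small_fixture.tree,
                            marker_len=590, markers_per_species=50, seed=1,
                            species=["S01"], max_attempts=5)

    def test_single_species_deep_coverage_profile(self, marker_db, small_fixture):
        genes = small_fixture.ref.species_pangenomes["S02"]
        rng = np.random.default_rng(8)
        seqs = []
        for gene in genes:
            for _ in range(200):
                start = int(rng.integers(0, len(gene.sequence) - 100))
                seqs.append(gene.sequence[start : start + 100])
        rs = ReadSet(ids=[f"r{i}" for i in range(len(seqs))], sequences=seqs,
                     qualities=[np.full(100, 37, np.uint8)] * len(seqs),
                     labels=["S02"] * len(seqs))
        profile = profile_markers(rs, marker_db, stat_q=0.2, g_min=1)
        assert profile.detected() == {"S02"}
        assert profile.abundances["S02"] == pytest.approx(1.0)

    def test_g_min_detection_threshold(self, marker_db, small_fixture):
        """A species with hits on exactly two markers is detected at
        g_min <= 2 and absent at g_min = 3."""
        mids = marker_db.species_markers()["S03"][:2]
        seqs = [marker_db.markers[mi].sequence[:100] for mi in mids]
        rs = ReadSet(ids=["a", "b"], sequences=seqs,
                     qualities=[np.full(100, 37, np.uint8)] * 2,
                     labels=["S03"] * 2)
        for g_min, expect in ((1, {"S03"}), (2, {"S03"}), (3, set())):
            assert profile_markers(rs, marker_db, g_min=g_min).detected() == expect


@pytest.mark.parametrize(
    "values,q",
    [
        ([0, 0, 0, 0, 10], 0.2),
        ([1, 2, 3, 4, 100], 0.2),
        ([5.0], 0.0),
        ([3, 1, 4, 1, 5, 9, 2, 6], 0.25),
        ([2, 2, 2], 0.4),
    ],
)
def test_robust_average_matches_quantile_trim_oracle(values, q):
    assert robust_average(values, q) == pytest.approx(oracles.trimmed_mean(values, q))


def test_robust_average_excludes_extremes():
    # trim drops one value from each end of the sorted coverages
    assert robust_average([1, 2, 3, 4, 100], 0.2) == pytest.approx(3.0)
    # a single hot marker among cold ones is excluded entirely
    assert robust_average([0, 0, 0, 0, 10], 0.2) == pytest.approx(0.0)
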