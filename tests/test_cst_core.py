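import io

import numpy as np
import pandas as pd
import pytest

from conftest import random_abundance, random_distance
from oracles import brute_silhouette, brute_upgma_heights

from cstkit import cst_core
from cstkit.cst_core import (
    ClusterAssignment,
    DistanceMatrix,
    call_csts,
    characterize_cst_from_summary,
    assign_to_cst,
    cut_dendrogram,
    pearson_distance,
    select_k,
    silhouette_mean,
    upgma_linkage,
)
from cstkit.exceptions import (
    DegenerateSampleError,
    NoCSTError,
    ParameterError,
    UndefinedScoreError,
)
from cstkit.profiles_io import AbundanceTable, validate_metadata


def three_point_dist():
    d = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
    return DistanceMatrix(ids=["a", "b", "c"], values=d)


class TestPearsonDistance:
    def test_identical_profiles(self):
        t = AbundanceTable(["x", "y"], ["A", "B", "C"], np.array([[0.5, 0.3, 0.1]] * 2))
        d = pearson_distance(t)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self):
        x = np.array([0.5, 0.3, 0.1])
        t = AbundanceTable(["x", "y"], ["A", "B", "C"], np.vstack([x, 0.05 + 0.5 * x]))
        assert pearson_distance(t).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # r((1,0,0),(0,1,0)) = -0.5 so d = 1.5
        t = AbundanceTable(["x", "y"], ["A", "B", "C"],
                           np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
        assert pearson_distance(t).values[0, 1] == pytest.approx(1.5, abs=1e-12)

    def test_zero_variance_sample(self):
        t = AbundanceTable(["flat", "y"], ["A", "B"], np.array([[0.2, 0.2], [0.5, 0.1]]))
        with pytest.raises(DegenerateSampleError, match="flat"):
            pearson_distance(t)

    def test_range(self):
        rng = np.random.default_rng(0)
        d = pearson_distance(random_abundance(rng, 10, 6))
        assert (d.values >= 0).all() and (d.values <= 2).all()


class TestUpgma:
    def test_three_point_example(self):
        tree = upgma_linkage(three_point_dist())
        merges = tree.merges
        assert merges[0][2] == pytest.approx(0.1)
        assert merges[1][2] == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            dm = random_distance(rng, n)
            heights = [m[2] for m in upgma_linkage(dm).merges]
            np.testing.assert_allclose(
                heights, brute_upgma_heights(dm.values), atol=1e-9
            )

    def test_ultrametric_exact(self):
        # perfect 2-level ultrametric: within-pair 0.2, across 0.8
        d = np.full((4, 4), 0.8)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.2
        np.fill_diagonal(d, 0.0)
        tree = upgma_linkage(DistanceMatrix(ids=list("abcd"), values=d))
        heights = sorted(m[2] for m in tree.merges)
        np.testing.assert_allclose(heights, [0.2, 0.2, 0.8], atol=1e-12)

    def test_size_error(self):
        with pytest.raises(ParameterError):
            upgma_linkage(DistanceMatrix(ids=["a"], values=np.zeros((1, 1))))

    def test_newick_exports_all_leaves(self):
        from Bio import Phylo

        tree = upgma_linkage(three_point_dist())
        phylo = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in phylo.get_terminals()) == ["a", "b", "c"]


class TestCutDendrogram:
    def test_k1_and_kn(self):
        tree = upgma_linkage(three_point_dist())
        assert set(cut_dendrogram(tree, 1).labels.values()) == {1}
        assert cut_dendrogram(tree, 3).k == 3

    def test_three_point_k2(self):
        labels = cut_dendrogram(upgma_linkage(three_point_dist()), 2).labels
        assert labels["a"] == labels["b"] != labels["c"]

    def test_out_of_range(self):
        tree = upgma_linkage(three_point_dist())
        for k in (0, 4):
            with pytest.raises(ParameterError):
                cut_dendrogram(tree, k)

    def test_refinement_property(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            tree = upgma_linkage(random_distance(rng, n))
            for k in range(2, n + 1):
                fine = cut_dendrogram(tree, k)
                coarse = cut_dendrogram(tree, k - 1)
                # every fine cluster maps into exactly one coarse cluster
                for c in range(1, k + 1):
                    members = fine.members(c)
                    assert len({coarse.labels[s] for s in members}) == 1


class TestSilhouette:
    def test_two_tight_groups(self):
        d = np.full((6, 6), 1.0)
        d[:3, :3] = 0.01
        d[3:, 3:] = 0.01
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(ids=[f"s{i}" for i in range(6)], values=d)
        a = ClusterAssignment({f"s{i}": 1 if i < 3 else 2 for i in range(6)}, 2)
        assert silhouette_mean(dm, a) > 0.9

    def test_identical_points_convention(self):
        dm = DistanceMatrix(ids=["a", "b", "c", "d"], values=np.zeros((4, 4)))
        a = ClusterAssignment({"a": 1, "b": 1, "c": 2, "d": 2}, 2)
        assert silhouette_mean(dm, a) == 0.0

    def test_k1_undefined(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(UndefinedScoreError):
            silhouette_mean(dm, ClusterAssignment({"a": 1, "b": 1}, 1))

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            dm = random_distance(rng, n)
            k = int(rng.integers(2, n))
            labels = rng.integers(1, k + 1, size=n)
            while len(set(labels)) != k:
                labels = rng.integers(1, k + 1, size=n)
            a = ClusterAssignment(dict(zip(dm.ids, (int(x) for x in labels))), k)
            assert silhouette_mean(dm, a) == pytest.approx(
                brute_silhouette(dm.values, labels), abs=1e-12
            )


class TestSelectK:
    def test_two_planted_groups(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0.7, 0.1, 0.05], [0.05, 0.1, 0.7]])
        vals = np.vstack([
            np.clip(centers[i % 2] + rng.normal(0, 0.01, 3), 0, 1) for i in range(20)
        ])
        vals /= np.maximum(vals.sum(axis=1, keepdims=True), 1.0)
        t = AbundanceTable([f"s{i}" for i in range(20)], ["A", "B", "C"], vals)
        dist = pearson_distance(t)
        k, _ = select_k(dist, upgma_linkage(dist), 2, 10)
        assert k == 2

    def test_tie_rule_smallest_k(self):
        # all-zero distances: every k scores 0 -> smallest k wins
        dm = DistanceMatrix(ids=[f"s{i}" for i in range(6)], values=np.zeros((6, 6)))
        tree = upgma_linkage(dm)
        k, scores = select_k(dm, tree, 2, 5)
        assert k == 2
        assert all(v == 0.0 for v in scores.values())

    def test_invalid_range(self):
        dm = three_point_dist()
        with pytest.raises(ParameterError):
            select_k(dm, upgma_linkage(dm), 5, 9)


def _mk_catalog_inputs(cluster_sizes, bioprojects, taxon="Rothia mucilaginosa"):
    """Build a table/meta/assignment where cluster c is dominated by taxon c."""
    taxa = [taxon, "Pasteurella sp.", "Filler species", "Other species"]
    ids, labels, projects, vals = [], {}, [], []
    rng = np.random.default_rng(0)
    for c, size in enumerate(cluster_sizes, start=1):
        for i in range(size):
            s = f"c{c}_{i}"
            ids.append(s)
            labels[s] = c
            projects.append(bioprojects[c - 1][i % len(bioprojects[c - 1])])
            row = np.zeros(4)
            row[c - 1] = 0.5 + rng.uniform(0, 0.1)
            row[3] = 0.1
            vals.append(row)
    table = AbundanceTable(ids, taxa, np.array(vals))
    meta = validate_metadata(
        pd.DataFrame(
            {"bioproject": projects, "sampling_method": ["sputum"] * len(ids)},
            index=pd.Index(ids, name="sample_id"),
        )
    )
    assignment = ClusterAssignment(labels, len(cluster_sizes))
    return table, meta, assignment


class TestCallCSTs:
    def test_size_filter_paper_rule(self):
        # round(0.01 * 849) = 8 by half-to-even: a 7-sample cluster fails,
        # an 8-sample cluster passes
        assert max(2, round(0.01 * 849)) == 8

    def test_small_cluster_unassigned(self):
        table, meta, assignment = _mk_catalog_inputs(
            [30, 2], [["P1", "P2"], ["P1", "P2"]]
        )
        cat = call_csts(table, meta, assignment, min_fraction=0.1)
        assert len(cat.csts) == 1
        assert len(cat.unassigned_samples) == 2

    def test_single_project_excluded(self):
        table, meta, assignment = _mk_catalog_inputs([20, 20], [["P1", "P2"], ["P3"]])
        cat = call_csts(table, meta, assignment, min_datasets=1)
        by_status = {c.status for c in cat.csts}
        assert by_status == {"cst", "putative_excluded"}
        putative = [c for c in cat.csts if c.status == "putative_excluded"][0]
        assert putative.label.startswith("Cluster-")

    def test_unresolved_defining_taxon_excluded(self):
        table, meta, assignment = _mk_catalog_inputs([20, 20], [["P1", "P2"], ["P1", "P2"]])
        cat = call_csts(table, meta, assignment)
        # cluster 2 is dominated by "Pasteurella sp."
        putative = [c for c in cat.csts if c.defining_taxon == "Pasteurella sp."]
        assert len(putative) == 1
        assert putative[0].status == "putative_excluded"

    def test_partition_invariant(self):
        table, meta, assignment = _mk_catalog_inputs(
            [20, 15, 3], [["P1", "P2"], ["P1", "P2"], ["P1", "P2"]]
        )
        cat = call_csts(table, meta, assignment, min_fraction=0.2)
        members = set(cat.unassigned_samples)
        for c in cat.csts:
            assert members.isdisjoint(c.member_samples)
            members.update(c.member_samples)
        assert members == set(table.sample_ids)

    def test_no_cst_error(self):
        table, meta, assignment = _mk_catalog_inputs([5, 5], [["P1"], ["P2"]])
        with pytest.raises(NoCSTError):
            call_csts(table, meta, assignment, min_fraction=0.9)

    def test_label_from_initials(self):
        table, meta, assignment = _mk_catalog_inputs([20, 3], [["P1", "P2"], ["P1"]])
        cat = call_csts(table, meta, assignment)
        assert cat.csts[0].label == "CST-Rm"

    def test_json_round_trip_fields(self, tmp_path):
        import json

        table, meta, assignment = _mk_catalog_inputs([20, 3], [["P1", "P2"], ["P1"]])
        cat = call_csts(table, meta, assignment)
        cat.save_json(tmp_path / "cat.json")
        payload = json.loads((tmp_path / "cat.json").read_text())
        assert payload["csts"][0]["defining_taxon"] == "Rothia mucilaginosa"
        assert payload["parameters"]["core_prevalence"] == 0.85


class TestCharacterizeFromSummary:
    def test_no_core_taxon(self):
        taxa = {"A": 10.0, "B": 5.0}
        prev = {"A": 50.0, "B": 50.0}
        assert characterize_cst_from_summary(taxa, prev) == (None, None)

    def test_tie_breaks_lexicographic(self):
        taxa = {"B taxon": 5.0, "A taxon": 5.0}
        prev = {"B taxon": 100.0, "A taxon": 100.0}
        assert characterize_cst_from_summary(taxa, prev)[0] == "A taxon"

    def test_mismatched_keys(self):
        from cstkit.exceptions import AlignmentError

        with pytest.raises(AlignmentError):
            characterize_cst_from_summary({"A": 1.0}, {"B": 1.0})


class TestAssignToCST:
    def test_centroid_maps_to_itself(self):
        table, meta, assignment = _mk_catalog_inputs([20, 3], [["P1", "P2"], ["P1"]])
        cat = call_csts(table, meta, assignment)
        centroid = cat.csts[0].mean_abundance
        probe = AbundanceTable(
            table.sample_ids + ["probe"],
            table.taxon_ids,
            np.vstack([table.values, centroid]),
        )
        label, r = assign_to_cst(cat, probe, "probe")
        assert label == cat.csts[0].label
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_member_reassigned_to_own_cst(self, default_dataset):
        cat = default_dataset["catalog"]
        table = default_dataset["table"]
        label_of = cat.label_of()
        hits = 0
        for s in table.sample_ids[::100]:
            label, _ = assign_to_cst(cat, table, s)
            hits += label == label_of[s]
        assert hits >= len(table.sample_ids[::100]) - 1

    def test_empty_catalog(self):
        cat = cst_core.CSTCatalog(csts=[], unassigned_samples=["s"], taxon_ids=["A"])
        t = AbundanceTable(["s"], ["A"], np.array([[0.5]]))
        with pytest.raises(NoCSTError):
            assign_to_cst(cat, t, "s")
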