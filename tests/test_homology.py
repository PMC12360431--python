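"""Groups parsing, relationship classes, and ortholog comparison operations."""

import numpy as np
import pandas as pd
import pytest

from orthodev import homology
from orthodev.containers import ARCHETYPES, STAGES
from orthodev.report import percentage


def write_lines(tmp_path, lines):
    path = tmp_path / "groups.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParseGroups:
    def test_one2one_single_pair(self, tmp_path):
        hs = homology.parse_groups(write_lines(tmp_path, ["OG1: A|g1 B|g2"]))
        assert hs.relationship("OG1") == "one2one"
        pairs = hs.ortholog_pairs()
        assert len(pairs) == 1
        assert pairs.iloc[0]["gene_a"] == "A|g1" and pairs.iloc[0]["gene_b"] == "B|g2"

    def test_one2many_b_two_pairs(self, tmp_path):
        hs = homology.parse_groups(write_lines(tmp_path, ["OG2: A|g1 B|g2 B|g3"]))
        assert hs.relationship("OG2") == "one2many_B"
        assert len(hs.ortholog_pairs()) == 2

    def test_member_without_taxon_prefix_errors_with_line(self, tmp_path):
        path = write_lines(tmp_path, ["OG1: A|g1 B|g2", "OG2: A|g3 nonsense"])
        with pytest.raises(ValueError, match="line 2"):
            homology.parse_groups(path)

    def test_synthetic_file_class_counts_match_recount(self, small_bundle, tmp_path):
        hs = small_bundle.homology
        homology.write_groups(hs, tmp_path / "g.txt")
        reparsed = homology.parse_groups(tmp_path / "g.txt", species=hs.species)
        rel = reparsed.relationships()
        sp_a, sp_b = hs.species
        for gid, members in hs.groups.items():
            na, nb = len(members[sp_a]), len(members[sp_b])
            expected = (
                "one2one"
                if na == nb == 1
                else "one2many_A"
                if nb == 1
                else "one2many_B"
                if na == 1
                else "many2many"
            )
            assert rel[gid] == expected


class TestRelationshipSummary:
    def test_reported_one2one_share(self):
        # 5,965 of 6,896 groups -> 86.5%
        assert percentage(5965, 6896, 1) == 86.5

    def test_all_one2one(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("OG1: A|a B|b\nOG2: A|c B|d\n")
        summary = homology.relationship_summary(homology.parse_groups(path))
        assert summary["group_percent"]["one2one"] == 100.0

    def test_percentages_sum_to_100(self, small_bundle):
        summary = homology.relationship_summary(small_bundle.homology)
        assert sum(summary["group_percent"].values()) == pytest.approx(100.0, abs=0.2)


def fake_results(up_map, comparison):
    """DE results frame from gene -> up_stage ('none' = not DE)."""
    rows = []
    for gene, up in up_map.items():
        deg = up != "none"
        rows.append(
            {
                "gene": gene,
                "comparison": comparison,
                "log2fc": 2.0 if deg else 0.0,
                "p": 0.001 if deg else 0.9,
                "padj": 0.01 if deg else 0.95,
                "is_deg": deg,
                "up_stage": up,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


@pytest.fixture()
def random_pair_fixture(rng):
    """200 one-to-one pairs with random DE labels on both sides."""
    pairs = pd.DataFrame(
        {
            "group": [f"OG{i}" for i in range(200)],
            "gene_a": [f"A|g{i}" for i in range(200)],
            "gene_b": [f"B|g{i}" for i in range(200)],
            "class": "one2one",
        }
    )
    stages = ["none", "PC", "G", "S"]
    res_a = {
        c: fake_results(
            {g: stages[rng.integers(0, 4)] for g in pairs["gene_a"]}, c
        )
        for c in ("PCvsG", "GvsS")
    }
    res_b = {
        c: fake_results(
            {g: stages[rng.integers(0, 4)] for g in pairs["gene_b"]}, c
        )
        for c in ("PCvsG", "GvsS")
    }
    return pairs, res_a, res_b


class TestSharedDEPartition:
    def test_no_degs_all_neither(self, random_pair_fixture):
        pairs, _, _ = random_pair_fixture
        part = homology.shared_de_partition(pairs, set(), set())
        assert len(part["neither"]) == len(pairs)

    def test_only_a(self, random_pair_fixture):
        pairs, _, _ = random_pair_fixture
        part = homology.shared_de_partition(pairs, {"A|g0"}, set())
        assert list(part["only_a"]["gene_a"]) == ["A|g0"]

    def test_cells_match_brute_force_and_partition(self, random_pair_fixture, rng):
        pairs, res_a, res_b = random_pair_fixture
        deg_a = {
            g
            for c in res_a
            for g in res_a[c].index[res_a[c]["is_deg"]]
        }
        deg_b = {
            g
            for c in res_b
            for g in res_b[c].index[res_b[c]["is_deg"]]
        }
        part = homology.shared_de_partition(pairs, deg_a, deg_b)
        total = sum(len(df) for df in part.values())
        assert total == len(pairs)
        brute_both = sum(
            1
            for a, b in zip(pairs["gene_a"], pairs["gene_b"])
            if a in deg_a and b in deg_b
        )
        assert len(part["both"]) == brute_both


class TestSynchrony:
    def test_reported_pc_vs_g_percent(self):
        st = homology.SynchronyStats(
            "PCvsG", same_by_stage={"PC": 131, "G": 229}, n_asynchronous=256
        )
        assert st.n_same == 360
        assert st.percent_same == 58

    def test_reported_g_vs_s_percent(self):
        st = homology.SynchronyStats(
            "GvsS", same_by_stage={"G": 50, "S": 56}, n_asynchronous=573
        )
        assert st.percent_same == 16

    def test_all_same_stage_100(self):
        st = homology.SynchronyStats("PCvsG", {"G": 12}, 0)
        assert st.percent_same == 100

    def test_counts_match_brute_force(self, random_pair_fixture):
        pairs, res_a, res_b = random_pair_fixture
        st = homology.synchrony_stats(pairs, res_a["PCvsG"], res_b["PCvsG"], "PCvsG")
        same = async_ = 0
        for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
            ua = res_a["PCvsG"].loc[a, "up_stage"]
            ub = res_b["PCvsG"].loc[b, "up_stage"]
            if ua == "none" or ub == "none":
                continue
            if ua == ub:
                same += 1
            else:
                async_ += 1
        assert st.n_same == same and st.n_asynchronous == async_


class TestStageOverlap:
    def test_identical_labels_diagonal(self, rng):
        # each gene up in exactly one stage, mirrored across species
        pairs = pd.DataFrame(
            {"gene_a": [f"A|g{i}" for i in range(100)],
             "gene_b": [f"B|g{i}" for i in range(100)]}
        )
        stages = [list(STAGES)[rng.integers(0, 3)] for _ in range(100)]
        res_a = {
            "PCvsG": fake_results(dict(zip(pairs["gene_a"], stages)), "PCvsG"),
            "GvsS": fake_results({g: "none" for g in pairs["gene_a"]}, "GvsS"),
        }
        res_b = {
            "PCvsG": fake_results(dict(zip(pairs["gene_b"], stages)), "PCvsG"),
            "GvsS": fake_results({g: "none" for g in pairs["gene_b"]}, "GvsS"),
        }
        mat = homology.stage_overlap_matrix(res_a, res_b, pairs)
        off = mat.to_numpy().sum() - np.trace(mat.to_numpy())
        assert off == 0
        assert mat.to_numpy().sum() == 100

    def test_empty_de_zero_matrix(self, random_pair_fixture):
        pairs, _, _ = random_pair_fixture
        empty = {
            c: fake_results({g: "none" for g in pairs["gene_a"]}, c)
            for c in ("PCvsG", "GvsS")
        }
        empty_b = {
            c: fake_results({g: "none" for g in pairs["gene_b"]}, c)
            for c in ("PCvsG", "GvsS")
        }
        mat = homology.stage_overlap_matrix(empty, empty_b, pairs)
        assert mat.to_numpy().sum() == 0

    def test_matches_brute_force_double_loop(self, random_pair_fixture):
        from orthodev.diffexpr import up_stages

        pairs, res_a, res_b = random_pair_fixture
        mat = homology.stage_overlap_matrix(res_a, res_b, pairs)
        brute = {(sa, sb): 0 for sa in STAGES for sb in STAGES}
        for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
            for sa in up_stages(res_a, a):
                for sb in up_stages(res_b, b):
                    brute[(sa, sb)] += 1
        for sa in STAGES:
            for sb in STAGES:
                assert mat.loc[sa, sb] == brute[(sa, sb)]


class TestClusterOverlap:
    def test_reported_trace_and_percent(self):
        diag = (75, 9, 12, 82, 28, 9)
        mat = pd.DataFrame(0, index=list(ARCHETYPES), columns=list(ARCHETYPES))
        for a, d in zip(ARCHETYPES, diag):
            mat.loc[a, a] = d
        ov = homology.ClusterOverlap(matrix=mat, n_pairs=1629, n_unassigned=0)
        assert ov.trace == 215
        assert ov.percent_same == 13.2

    def test_identical_clusters_100_percent(self, rng):
        pairs = pd.DataFrame(
            {"gene_a": [f"A|g{i}" for i in range(60)],
             "gene_b": [f"B|g{i}" for i in range(60)]}
        )
        labels = [ARCHETYPES[rng.integers(0, 6)] for _ in range(60)]
        la = pd.Series(labels, index=pairs["gene_a"].values)
        lb = pd.Series(labels, index=pairs["gene_b"].values)
        ov = homology.cluster_overlap(pairs, la, lb)
        assert ov.percent_same == 100.0

    def test_matrix_matches_brute_force_tally(self, rng):
        pairs = pd.DataFrame(
            {"gene_a": [f"A|g{i}" for i in range(300)],
             "gene_b": [f"B|g{i}" for i in range(300)]}
        )
        la = pd.Series(
            [ARCHETYPES[rng.integers(0, 6)] for _ in range(250)],
            index=pairs["gene_a"].values[:250],
        )
        lb = pd.Series(
            [ARCHETYPES[rng.integers(0, 6)] for _ in range(280)],
            index=pairs["gene_b"].values[:280],
        )
        ov = homology.cluster_overlap(pairs, la, lb)
        brute = {}
        unassigned = 0
        for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
            if a in la.index and b in lb.index:
                brute[(la[a], lb[b])] = brute.get((la[a], lb[b]), 0) + 1
            else:
                unassigned += 1
        assert ov.n_unassigned == unassigned
        for (ca, cb), n in brute.items():
            assert ov.matrix.loc[ca, cb] == n
        assert ov.matrix.to_numpy().sum() + unassigned == ov.n_pairs


class TestCores:
    def test_gastrula_core_inclusion_rules(self):
        pairs = pd.DataFrame(
            {"gene_a": ["A|g1", "A|g2"], "gene_b": ["B|g1", "B|g2"]}
        )
        res_a = {
            "PCvsG": fake_results({"A|g1": "G", "A|g2": "G"}, "PCvsG"),
            "GvsS": fake_results({"A|g1": "none", "A|g2": "none"}, "GvsS"),
        }
        res_b = {
            "PCvsG": fake_results({"B|g1": "G", "B|g2": "none"}, "PCvsG"),
            "GvsS": fake_results({"B|g1": "none", "B|g2": "S"}, "GvsS"),
        }
        core = homology.gastrula_core(pairs, res_a, res_b)
        assert list(core["gene_a"]) == ["A|g1"]  # g2's partner is up in S only

    def test_g_cluster_core_membership(self):
        pairs = pd.DataFrame(
            {"gene_a": ["A|g1", "A|g2"], "gene_b": ["B|g1", "B|g2"]}
        )
        la = pd.Series({"A|g1": "C3", "A|g2": "C2"})
        lb = pd.Series({"B|g1": "C3", "B|g2": "C5"})
        core = homology.g_cluster_core(pairs, la, lb)
        assert list(core["gene_a"]) == ["A|g1"]

    def test_cores_match_brute_force(self, random_pair_fixture, rng):
        from orthodev.diffexpr import up_stages

        pairs, res_a, res_b = random_pair_fixture
        core = homology.gastrula_core(pairs, res_a, res_b)
        brute = [
            a
            for a, b in zip(pairs["gene_a"], pairs["gene_b"])
            if "G" in up_stages(res_a, a) and "G" in up_stages(res_b, b)
        ]
        assert list(core["gene_a"]) == brute
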