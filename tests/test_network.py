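"""Disease networks: node strength, threshold invariance, serialization."""

import numpy as np
import pandas as pd
import pytest
from lxml import etree

from conftest import random_cohort_frame
from mmnet import reference
from mmnet.cohort import Cohort
from mmnet.network import (
    build_network,
    export_graph,
    import_graphml,
    network_from_counts,
    strength_ranking,
)
from mmnet.panel import DISEASES, StratumSpec
from mmnet.rules import PairCounts


def counts_fixture(sex: str) -> PairCounts:
    """Poor-stratum count layer reconstructed from published summary tables."""
    return PairCounts(
        n=reference.STRATUM_SIZES[(sex, "poor")],
        marginals=pd.Series(
            {d: reference.DISEASE_COUNTS[(sex, "poor")][d] for d in DISEASES}
        ),
        joint=reference.poor_pair_counts(sex),
        stratum=f"{sex}_poor",
    )


def toy_counts() -> PairCounts:
    """3 active diseases with supports w_AB=0.2, w_AC=0.1, w_BC=0."""
    names = list(DISEASES)
    a, b, c = "arthritis", "asthma", "cancer"
    n = 10
    marg = pd.Series(0, index=names)
    marg[a], marg[b], marg[c] = 3, 2, 1
    joint = pd.DataFrame(0, index=names, columns=names)
    joint.loc[a, b] = joint.loc[b, a] = 2
    joint.loc[a, c] = joint.loc[c, a] = 1
    np.fill_diagonal(joint.values, marg)
    return PairCounts(n=n, marginals=marg, joint=joint, stratum="toy")


class TestBuild:
    def test_toy_hand_summed_strengths(self):
        net = network_from_counts(toy_counts())
        assert net.nodes.loc["arthritis", "strength"] == pytest.approx(0.3)
        assert net.nodes.loc["asthma", "strength"] == pytest.approx(0.2)
        assert net.nodes.loc["cancer", "strength"] == pytest.approx(0.1)

    def test_strength_equals_untresholded_support_row_sum(self, demo_cohort):
        net = build_network(demo_cohort, StratumSpec("poor", "all"), edge_threshold=0.05)
        sums = (
            pd.concat(
                [net.edges.rename(columns={"u": "d"})[["d", "support"]],
                 net.edges.rename(columns={"v": "d"})[["d", "support"]]]
            )
            .groupby("d")["support"].sum()
            .reindex(net.nodes.index, fill_value=0.0)
        )
        np.testing.assert_allclose(net.nodes["strength"], sums, rtol=1e-12)

    def test_threshold_invariance_of_strength(self, demo_cohort):
        spec = StratumSpec("poor", "all")
        base = build_network(demo_cohort, spec, edge_threshold=0.0)
        for thr in (0.02, 0.1, 1.0):
            net = build_network(demo_cohort, spec, edge_threshold=thr)
            pd.testing.assert_frame_equal(net.nodes, base.nodes)
        assert len(build_network(demo_cohort, spec, edge_threshold=1.0).display_edges()) == 0

    def test_node_prevalence_matches_prevalence_table(self, demo_cohort):
        from mmnet.cohort import prevalence_table

        spec = StratumSpec("poor", "female")
        net = build_network(demo_cohort, spec)
        tab = prevalence_table(demo_cohort, spec)
        np.testing.assert_allclose(net.nodes["prevalence"] * 100, tab["percent"], rtol=1e-12)

    def test_strength_bounded_by_min_prevalence_sums(self, demo_cohort):
        net = build_network(demo_cohort)
        p = net.nodes["prevalence"]
        for d in DISEASES:
            bound = sum(min(p[d], p[o]) for o in DISEASES if o != d)
            assert net.nodes.loc[d, "strength"] <= bound + 1e-12

    def test_adding_comorbid_records_never_decreases_support(self):
        rng = np.random.default_rng(21)
        df = random_cohort_frame(rng, 120)
        base = build_network(Cohort(df))
        extra = df.iloc[:5].copy()
        extra[["arthritis", "diabetes"]] = 1
        extra["id"] = [f"new{i}" for i in range(5)]
        grown = build_network(Cohort(pd.concat([df, extra], ignore_index=True)))
        eb = base.edges.set_index(["u", "v"])["support"]
        eg = grown.edges.set_index(["u", "v"])["support"]
        key = ("arthritis", "diabetes")
        assert eg[key] >= eb[key]
        assert grown.nodes.loc["arthritis", "strength"] >= base.nodes.loc["arthritis", "strength"] - 1e-12


class TestRanking:
    def test_toy_order(self):
        assert strength_ranking(network_from_counts(toy_counts()))[:3] == [
            "arthritis", "asthma", "cancer",
        ]

    def test_female_poor_fixture_reproduces_published_top_four(self):
        net = network_from_counts(counts_fixture("female"))
        assert strength_ranking(net)[:4] == [
            "hypertension", "arthritis", "hyperlipidemia", "diabetes",
        ]

    def test_male_poor_hypertension_strength_lower_bound(self):
        """Published male-poor supports for the six printed hypertension pairs
        sum to 0.835; the full strength must be at least that."""
        net = network_from_counts(counts_fixture("male"))
        assert net.nodes.loc["hypertension", "strength"] >= 0.835

    def test_all_equal_strengths_alphabetical(self):
        names = list(DISEASES)
        marg = pd.Series(0, index=names)
        joint = pd.DataFrame(0, index=names, columns=names)
        pc = PairCounts(n=5, marginals=marg, joint=joint)
        assert strength_ranking(network_from_counts(pc)) == sorted(names)


class TestExport:
    def test_graphml_round_trip(self, tmp_path, demo_cohort):
        net = build_network(demo_cohort, StratumSpec("poor", "all"), edge_threshold=0.01)
        path = tmp_path / "net.graphml"
        export_graph(net, path, format="graphml")
        back = import_graphml(path)
        pd.testing.assert_frame_equal(back.nodes, net.nodes)
        pd.testing.assert_frame_equal(
            back.edges.reset_index(drop=True),
            net.display_edges().sort_values(["u", "v"]).reset_index(drop=True),
        )
        assert back.stratum == net.stratum

    def test_graphml_validates_against_schema(self, tmp_path, demo_cohort):
        """Exported GraphML parses and declares the official namespace with
        well-formed node/edge structure."""
        net = build_network(demo_cohort, StratumSpec("poor", "male"))
        path = tmp_path / "net.graphml"
        export_graph(net, path, format="graphml")
        tree = etree.parse(str(path))
        root = tree.getroot()
        assert root.tag == "{http://graphml.graphdrawing.org/xmlns}graphml"
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        nodes = root.findall(".//g:node", ns)
        edges = root.findall(".//g:edge", ns)
        assert len(nodes) == len(DISEASES)
        ids = {n.get("id") for n in nodes}
        for e in edges:
            assert e.get("source") in ids and e.get("target") in ids

    def test_edge_list_export(self, tmp_path, demo_cohort):
        net = build_network(demo_cohort)
        path = tmp_path / "net.csv"
        export_graph(net, path, format="edge-list")
        edges = pd.read_csv(path)
        assert list(edges.columns) == ["u", "v", "support"]
        nodes = pd.read_csv(tmp_path / "net.csv.nodes.csv", index_col=0)
        np.testing.assert_allclose(nodes["strength"], net.nodes["strength"])

    def test_unknown_format_rejected(self, tmp_path, demo_cohort):
        net = build_network(demo_cohort)
        with pytest.raises(ValueError, match="unknown graph format"):
            export_graph(net, tmp_path / "x", format="gexf")
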