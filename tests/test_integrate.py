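"""Platform combination, region overlap, correlation, filter and network."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirnet.integrate import (
    build_network,
    combine_platform_de,
    correlate_pairs,
    cross_region_overlap,
    filter_interactions,
    write_sif,
)

PROGRAMS = ["pred_mirwalk", "pred_rna22", "pred_miranda", "pred_targetscan"]


def _de_table(sig_ids, lfc=1.0, universe=None, lfc_map=None):
    ids = list(universe) if universe is not None else list(sig_ids)
    lfc_map = lfc_map or {}
    return pd.DataFrame(
        {
            "log2fc": [lfc_map.get(i, lfc) for i in ids],
            "padj": [0.01 if i in set(sig_ids) else 0.5 for i in ids],
            "significant": [i in set(sig_ids) for i in ids],
        },
        index=pd.Index(ids, name="feature_id"),
    )


class TestCombinePlatforms:
    def test_disjoint_sets_union(self):
        universe = [f"g{i}" for i in range(150)]
        a = _de_table(universe[:36], universe=universe)
        b = _de_table(universe[36:102], universe=universe)
        out = combine_platform_de(a, b)
        assert len(out) == 102

    def test_sn_arithmetic_48_78_minus_12(self):
        universe = [f"g{i}" for i in range(200)]
        rnaseq_sig = universe[:48]
        array_sig = universe[36:114]  # 12 features shared with the RNA-seq list
        out = combine_platform_de(
            _de_table(rnaseq_sig, universe=universe), _de_table(array_sig, universe=universe)
        )
        assert len(out) == 114
        assert (out["source"] == "both").sum() == 12

    def test_direction_conflict_flagged_not_averaged_away(self):
        universe = ["g1", "g2"]
        a = _de_table(["g1"], universe=universe, lfc_map={"g1": 1.0, "g2": 0.3})
        b = _de_table(["g1"], universe=universe, lfc_map={"g1": -0.5, "g2": 0.3})
        out = combine_platform_de(a, b)
        assert bool(out.loc["g1", "direction_conflict"])
        assert out.loc["g1", "mean_log2fc"] == pytest.approx(0.25)

    def test_disjoint_namespaces_rejected(self):
        a = _de_table(["g1"], universe=["g1", "g2"])
        b = _de_table(["m1"], universe=["m1", "m2"])
        with pytest.raises(ValueError, match="namespace"):
            combine_platform_de(a, b)


class TestRegionOverlap:
    def test_identical_lists(self):
        a = pd.Series({"g1": 1.0, "g2": -2.0})
        ov = cross_region_overlap(a, a.copy())
        assert ov.only_a == set() and ov.only_b == set()
        assert ov.common == {"g1", "g2"} and ov.opposite_direction == set()

    def test_hand_example_with_opposite_sign(self):
        a = pd.Series({"g1": 1.0, "g2": -1.0, "g3": 2.0})
        b = pd.Series({"g2": 1.0, "g3": 1.0})
        ov = cross_region_overlap(a, b)
        assert ov.common == {"g2", "g3"}
        assert ov.opposite_direction == {"g2"}
        assert ov.only_a == {"g1"} and ov.only_b == set()

    def test_disjoint_lists(self):
        ov = cross_region_overlap(pd.Series({"a": 1.0}), pd.Series({"b": -1.0}))
        assert ov.common == set() and ov.opposite_direction == set()

    def test_partition_conservation(self, rng):
        ids = [f"g{i}" for i in range(60)]
        a = pd.Series(rng.normal(size=40), index=rng.choice(ids, 40, replace=False))
        b = pd.Series(rng.normal(size=25), index=rng.choice(ids, 25, replace=False))
        ov = cross_region_overlap(a, b)
        assert len(ov.only_a) + len(ov.common) == len(a)
        assert len(ov.only_b) + len(ov.common) == len(b)


def _expr(rows, cols, values):
    return pd.DataFrame(values, index=rows, columns=cols)


def _map(cols):
    return pd.DataFrame({"pool": cols, "mirna_sample": cols, "mrna_sample": cols})


class TestCorrelatePairs:
    def test_perfect_anticorrelation(self):
        cols = [f"s{i}" for i in range(4)]
        mir = _expr(["m1"], cols, [[1.0, 2.0, 3.0, 4.0]])
        rna = _expr(["g1"], cols, [[5.0, 3.0, 1.0, -1.0]])
        out = correlate_pairs(mir, rna, _map(cols))
        assert out["r"].iloc[0] == pytest.approx(-1.0)
        assert out["n_matched"].iloc[0] == 4

    def test_constant_vector_gives_missing_r(self):
        cols = [f"s{i}" for i in range(4)]
        mir = _expr(["m1"], cols, [[1.0, 2.0, 3.0, 4.0]])
        rna = _expr(["g1"], cols, [[2.0, 2.0, 2.0, 2.0]])
        out = correlate_pairs(mir, rna, _map(cols))
        assert np.isnan(out["r"].iloc[0])

    def test_matches_textbook_formula(self, rng):
        cols = [f"s{i}" for i in range(6)]
        mir = _expr([f"m{i}" for i in range(3)], cols, rng.normal(size=(3, 6)))
        rna = _expr([f"g{i}" for i in range(4)], cols, rng.normal(size=(4, 6)))
        out = correlate_pairs(mir, rna, _map(cols)).set_index(["mirna_id", "gene_id"])
        for m, g in itertools.product(mir.index, rna.index):
            x, y = mir.loc[m].to_numpy(), rna.loc[g].to_numpy()
            expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
            assert out.loc[(m, g), "r"] == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self, rng):
        cols = [f"s{i}" for i in range(5)]
        mir = _expr(["m1"], cols, rng.normal(size=(1, 5)))
        rna = _expr(["g1"], cols, rng.normal(size=(1, 5)))
        r0 = correlate_pairs(mir, rna, _map(cols))["r"].iloc[0]
        r1 = correlate_pairs(mir * 3.5 + 2, rna * 0.1 - 7, _map(cols))["r"].iloc[0]
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_low_n_guard(self):
        cols = ["s0", "s1"]
        mir = _expr(["m1"], cols, [[1.0, 2.0]])
        rna = _expr(["g1"], cols, [[2.0, 1.0]])
        with pytest.raises(ValueError, match="matched samples"):
            correlate_pairs(mir, rna, _map(cols))
        with pytest.warns(UserWarning, match="proceeding"):
            out = correlate_pairs(mir, rna, _map(cols), allow_low_n=True)
        assert len(out) == 1

    def test_unmatched_columns_dropped_with_warning(self):
        mir = _expr(["m1"], ["s0", "s1", "s2"], [[1.0, 2.0, 3.0]])
        rna = _expr(["g1"], ["s0", "s1", "s2", "s3"], [[3.0, 2.0, 1.0, 9.0]])
        smap = _map(["s0", "s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="dropped"):
            out = correlate_pairs(mir, rna, smap)
        assert out["n_matched"].iloc[0] == 3


def _annotation_row(mirna, gene, mirwalk_p=np.nan, programs=(), validated=False):
    row = {"mirna_id": mirna, "gene_id": gene, "mirwalk_p": mirwalk_p, "validated": validated}
    for p in PROGRAMS:
        row[p] = p in programs
    return row


class TestFilterInteractions:
    def test_clause_i_keeps_weakly_predicted_pair(self):
        cands = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"], "r": [-0.4], "n_matched": 4})
        ann = pd.DataFrame([_annotation_row("m1", "g1", mirwalk_p=0.05, programs=("pred_rna22",))])
        out = filter_interactions(cands, ann)
        assert bool(out["kept"].iloc[0])
        assert "mirwalk_p" in out["clauses_met"].iloc[0]

    def test_correlation_floor_dominates_all_clauses(self):
        cands = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"], "r": [-0.2], "n_matched": 4})
        ann = pd.DataFrame([_annotation_row("m1", "g1", mirwalk_p=0.01, programs=PROGRAMS, validated=True)])
        out = filter_interactions(cands, ann)
        assert not out["kept"].iloc[0]

    def test_boundary_r_is_kept(self):
        cands = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"], "r": [-0.3], "n_matched": 4})
        ann = pd.DataFrame([_annotation_row("m1", "g1", validated=True)])
        assert bool(filter_interactions(cands, ann)["kept"].iloc[0])

    @staticmethod
    def independent_oracle(mirwalk_p, n_programs, validated, r, enriched, in_enriched):
        """Deliberately naive re-statement of the published filter."""
        has_evidence = False
        if not (mirwalk_p is None or np.isnan(mirwalk_p)):
            if mirwalk_p < 0.1:
                has_evidence = True
        if n_programs >= 2:
            has_evidence = True
        if validated:
            has_evidence = True
        corr_ok = (r is not None) and not np.isnan(r) and r <= -0.3
        gene_ok = in_enriched if enriched else True
        return has_evidence and corr_ok and gene_ok

    def test_exhaustive_truth_table_matches_oracle(self):
        """All evidence combinations x correlation values vs the oracle."""
        r_values = [-0.5, -0.3, -0.2, 0.4, np.nan]
        cases = []
        for has_p, n_prog, validated in itertools.product([True, False], [0, 1, 2, 4], [True, False]):
            for r in r_values:
                cases.append((has_p, n_prog, validated, r))
        rows, cands = [], []
        for i, (has_p, n_prog, validated, r) in enumerate(cases):
            m, g = f"m{i}", f"g{i}"
            cands.append({"mirna_id": m, "gene_id": g, "r": r, "n_matched": 4})
            rows.append(
                _annotation_row(
                    m, g,
                    mirwalk_p=0.05 if has_p else 0.8,
                    programs=tuple(PROGRAMS[:n_prog]),
                    validated=validated,
                )
            )
        out = filter_interactions(pd.DataFrame(cands), pd.DataFrame(rows))
        for (has_p, n_prog, validated, r), kept in zip(cases, out["kept"]):
            expected = self.independent_oracle(
                0.05 if has_p else 0.8, n_prog, validated, r, enriched=False, in_enriched=True
            )
            assert kept == expected, (has_p, n_prog, validated, r)

    def test_pairs_without_annotation_have_no_evidence(self):
        cands = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"], "r": [-0.9], "n_matched": 4})
        ann = pd.DataFrame([_annotation_row("m2", "g2", validated=True)])
        out = filter_interactions(cands, ann)
        assert not out["kept"].iloc[0]

    def test_enriched_gene_filter(self):
        cands = pd.DataFrame(
            {"mirna_id": ["m1", "m1"], "gene_id": ["g1", "g2"], "r": [-0.5, -0.5], "n_matched": 4}
        )
        ann = pd.DataFrame(
            [_annotation_row("m1", "g1", validated=True), _annotation_row("m1", "g2", validated=True)]
        )
        out = filter_interactions(cands, ann, enriched_genes={"g1"})
        kept = out.set_index("gene_id")["kept"]
        assert bool(kept["g1"]) and not bool(kept["g2"])

    def test_relaxing_thresholds_gives_superset(self, rng):
        n = 300
        cands = pd.DataFrame(
            {
                "mirna_id": [f"m{i}" for i in range(n)],
                "gene_id": [f"g{i}" for i in range(n)],
                "r": rng.uniform(-1, 1, n),
                "n_matched": 4,
            }
        )
        ann = pd.DataFrame(
            [
                _annotation_row(
                    f"m{i}", f"g{i}",
                    mirwalk_p=rng.uniform(0, 1),
                    programs=tuple(np.array(PROGRAMS)[rng.random(4) < 0.4]),
                    validated=bool(rng.random() < 0.2),
                )
                for i in range(n)
            ]
        )
        strict = filter_interactions(cands, ann, r_floor=-0.5, p_cut=0.05)
        relaxed = filter_interactions(cands, ann, r_floor=-0.1, p_cut=0.3)
        kept_strict = set(strict.loc[strict["kept"], "gene_id"])
        kept_relaxed = set(relaxed.loc[relaxed["kept"], "gene_id"])
        assert kept_strict <= kept_relaxed

    def test_positive_floor_rejected(self):
        cands = pd.DataFrame({"mirna_id": ["m1"], "gene_id": ["g1"], "r": [-0.5], "n_matched": 4})
        with pytest.raises(ValueError, match="negative correlation"):
            filter_interactions(cands, pd.DataFrame([_annotation_row("m1", "g1")]), r_floor=0.2)


class TestNetwork:
    def test_empty_input_gives_empty_graph(self):
        kept = pd.DataFrame(columns=["mirna_id", "gene_id", "r", "n_programs"])
        g = build_network(kept)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_degree_counts_incident_edges(self):
        kept = pd.DataFrame(
            {
                "mirna_id": ["m1", "m1", "m1"],
                "gene_id": ["g1", "g2", "g3"],
                "r": [-0.5, -0.6, -0.7],
                "n_programs": [1, 2, 3],
            }
        )
        g = build_network(kept, {"m1": 2.0, "g1": -1.0, "g2": -1.2, "g3": -0.8})
        assert g.nodes["m1"]["degree"] == 3
        assert g.nodes["m1"]["kind"] == "miRNA" and g.nodes["g1"]["kind"] == "mRNA"
        assert nx.is_bipartite(g.to_undirected())

    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        kept = pd.DataFrame(
            {
                "mirna_id": ["m1", "m2"],
                "gene_id": ["g1", "g1"],
                "r": [-0.45, -0.8],
                "n_programs": [2, 4],
            }
        )
        g = build_network(kept, {"m1": 1.5, "m2": 0.7, "g1": -1.1})
        path = tmp_path / "net.graphml"
        nx.write_graphml(g, path)
        g2 = nx.read_graphml(path)
        assert set(g2.nodes) == set(g.nodes)
        for n in g.nodes:
            assert g2.nodes[n]["kind"] == g.nodes[n]["kind"]
            assert g2.nodes[n]["log2fc"] == pytest.approx(g.nodes[n]["log2fc"])
            assert g2.nodes[n]["degree"] == g.nodes[n]["degree"]
        for u, v in g.edges:
            assert g2.edges[u, v]["r"] == pytest.approx(g.edges[u, v]["r"])
            assert g2.edges[u, v]["n_programs"] == g.edges[u, v]["n_programs"]

    def test_sif_export(self, tmp_path):
        kept = pd.DataFrame(
            {"mirna_id": ["m1"], "gene_id": ["g1"], "r": [-0.5], "n_programs": [1]}
        )
        g = build_network(kept)
        p = tmp_path / "net.sif"
        write_sif(g, p)
        assert p.read_text().strip() == "m1\trepresses\tg1"
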