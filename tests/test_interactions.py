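"""Ligand activity, MCDM/MO-MCDM construction, UR ranking, organ prioritization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mcdmkit import synthetic as syn
from mcdmkit.enrichment import significant_genes
from mcdmkit.interactions import (
    CellPopulation,
    LigandTargetPrior,
    build_mcdm,
    build_mo_mcdm,
    expressed_genes,
    infer_targets,
    ligand_activity,
    prioritize_organs,
    rank_urs,
    ur_target_severity,
)


def tiny_prior(weights: dict[str, dict[str, float]], secreted=(), classes=None):
    rows = [
        (lig, g, w) for lig, targ in weights.items() for g, w in targ.items()
    ]
    return LigandTargetPrior.from_edges(
        pd.DataFrame(rows, columns=["ligand", "gene", "weight"]),
        location={l: "extracellular space" for l in secreted},
        molecule_class=classes or {},
    )


class TestExpressedGenes:
    def test_zero_gene_excluded(self):
        vals = pd.DataFrame({"g1": [0.0, 0.0], "g2": [1.0, 1.0]})
        out = expressed_genes(vals)
        assert "g1" not in out and "g2" in out

    def test_backtransform_boundary(self):
        v = np.log10(1 + 2e-5)
        vals = pd.DataFrame({"g1": [v, v]})
        assert "g1" in expressed_genes(vals)
        v2 = np.log10(1 + 0.5e-5)
        assert "g1" not in expressed_genes(pd.DataFrame({"g1": [v2, v2]}))

    def test_infinite_threshold_empty(self):
        vals = pd.DataFrame({"g1": [5.0, 5.0]})
        assert expressed_genes(vals, threshold=np.inf) == set()

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            expressed_genes(pd.DataFrame({"g1": []}))


class TestLigandActivity:
    def test_proportional_potential_gives_pcc_one(self):
        genes = [f"g{i}" for i in range(10)]
        degs = set(genes[:4])
        prior = tiny_prior({"L": {g: 2.0 for g in degs}})
        # extend prior columns with zero weight for non-targets
        prior.potential = prior.potential.reindex(columns=genes, fill_value=0.0)
        act = ligand_activity(degs, genes, prior)
        assert act["L"] == pytest.approx(1.0)

    def test_empty_deg_set_skips_all(self):
        genes = [f"g{i}" for i in range(5)]
        prior = tiny_prior({"L": {"g0": 1.0}})
        prior.potential = prior.potential.reindex(columns=genes, fill_value=0.0)
        with pytest.warns(UserWarning, match="constant"):
            act = ligand_activity(set(), genes, prior)
        assert act.empty

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(500)]
        w = rng.uniform(size=500)
        degs = set(np.array(genes)[rng.uniform(size=500) < 0.2])
        prior = tiny_prior({"L": dict(zip(genes, w))})
        prior.potential = prior.potential[genes]
        act = ligand_activity(degs, genes, prior)
        y = np.array([g in degs for g in genes], dtype=float)
        expected = np.corrcoef(w, y)[0, 1]
        assert act["L"] == pytest.approx(expected, abs=1e-12)
        assert abs(act["L"]) < 0.2  # random prior vs random membership

    def test_empty_universe_raises(self):
        prior = tiny_prior({"L": {"g0": 1.0}})
        with pytest.raises(ValueError):
            ligand_activity({"g0"}, set(), prior)


class TestInferTargets:
    def test_large_top_k_is_full_intersection(self):
        prior = tiny_prior({"L": {"a": 1.0, "b": 0.5, "c": 0.2}})
        assert infer_targets("L", {"a", "c", "z"}, prior, top_k=10**6) == {"a", "c"}

    def test_disjoint_support_empty(self):
        prior = tiny_prior({"L": {"a": 1.0}})
        assert infer_targets("L", {"x", "y"}, prior) == set()

    def test_equals_sort_oracle_with_boundary_ties(self):
        weights = {"a": 5.0, "b": 4.0, "c": 3.0, "d": 3.0, "e": 1.0}
        prior = tiny_prior({"L": weights})
        degs = {"a", "c", "d", "e"}
        got = infer_targets("L", degs, prior, top_k=3)
        # sort-and-intersect oracle, ties at the boundary included
        ranked = sorted(weights, key=lambda g: -weights[g])
        cutoff = weights[ranked[2]]
        oracle = {g for g in weights if weights[g] >= cutoff} & degs
        assert got == oracle == {"a", "c", "d"}

    def test_unknown_ligand_raises(self):
        prior = tiny_prior({"L": {"a": 1.0}})
        with pytest.raises(KeyError):
            infer_targets("M", {"a"}, prior)


def organ_scenario(seed=0, fp_rate=0.0, fn_rate=0.0, n_ligands=6):
    """Two organs x three cell types with planted secreted URs."""
    return syn.multi_organ_scenario(
        seed=seed, fp_rate=fp_rate, fn_rate=fn_rate, n_ligands=n_ligands
    )


class TestBuildMCDM:
    def test_perfect_ligand_one_edge(self):
        genes = [f"g{i}" for i in range(20)]
        prior = tiny_prior({"L": {g: 1.0 for g in genes[:5]}})
        prior.potential = prior.potential.reindex(columns=genes, fill_value=0.0)
        pops = {
            "A": CellPopulation(expressed=set(genes) | {"L"}, degs=set(genes[:5]), n_cells=10),
            "B": CellPopulation(expressed=set(genes), degs=set(), n_cells=5),
        }
        g = build_mcdm(pops, prior, organ="o1")
        edges = list(g.edges(keys=True))
        # B has no DEGs; only A's DEGs attract edges, from both senders that
        # express L -- but L is only expressed in A
        assert all(key == "L" and v == ("o1", "A") for _, v, key in edges)
        assert ("o1", "A") in {u for u, _, _ in edges}

    def test_no_degs_no_edges(self):
        prior = tiny_prior({"L": {"a": 1.0}})
        pops = {"A": CellPopulation(expressed={"a", "L"}, degs=set(), n_cells=3)}
        g = build_mcdm(pops, prior)
        assert g.number_of_edges() == 0

    def test_edge_invariants_on_synthetic_run(self):
        db, truth, prior, pops, planted = organ_scenario(seed=3, fp_rate=0.01)
        joint = {k: v for k, v in pops.items() if k[0] == "joint"}
        g = build_mcdm(joint, prior)
        assert g.number_of_edges() > 0
        for u, v, data in g.edges(data=True):
            assert data["activity"] > 0
            assert data["targets"] <= g.nodes[v]["degs"]
            assert data["targets"] <= prior.targets_of(data["ligand"])

    def test_planted_ligands_dominate_permutation_null(self):
        db, truth, prior, pops, planted = organ_scenario(seed=4)
        (organ, ct), pop = sorted(pops.items())[0]
        universe = sorted(pop.expressed & prior.genes)
        act = ligand_activity(pop.degs, pop.expressed, prior)
        rng = np.random.default_rng(0)
        y = np.array([g in pop.degs for g in universe], dtype=float)
        null = {lig: [] for lig in act.index}
        pot = prior.potential[universe]
        for _ in range(200):
            perm = rng.permutation(y)
            for lig in act.index:
                x = pot.loc[lig].to_numpy()
                null[lig].append(np.corrcoef(x, perm)[0, 1])
        for lig in planted:
            assert act[lig] > np.quantile(null[lig], 0.95)


class TestMOMCDM:
    def test_no_secreted_ligand_empty(self):
        db, truth, prior, pops, planted = organ_scenario(seed=5)
        prior.location = {l: "other" for l in prior.ligands}
        mcdms = [
            build_mcdm({k: v for k, v in pops.items() if k[0] == o}, prior)
            for o in ("joint", "muscle")
        ]
        mo = build_mo_mcdm(mcdms, prior)
        assert mo.number_of_edges() == 0

    def test_only_secreted_ligands_cross(self):
        db, truth, prior, pops, planted = organ_scenario(seed=6)
        secreted = set(sorted(prior.ligands)[:2])
        prior.location = {
            l: ("extracellular space" if l in secreted else "other")
            for l in prior.ligands
        }
        mcdms = [
            build_mcdm({k: v for k, v in pops.items() if k[0] == o}, prior)
            for o in ("joint", "muscle")
        ]
        mo = build_mo_mcdm(mcdms, prior)
        ligs = {d["ligand"] for _, _, d in mo.edges(data=True)}
        assert ligs <= secreted
        for u, v, d in mo.edges(data=True):
            assert u[0] != v[0]

    def test_equals_brute_force_filter_of_pooled_graph(self):
        db, truth, prior, pops, planted = organ_scenario(seed=7, fp_rate=0.01)
        mcdms = [
            build_mcdm({k: v for k, v in pops.items() if k[0] == o}, prior)
            for o in ("joint", "muscle")
        ]
        mo = build_mo_mcdm(mcdms, prior)
        pooled = build_mcdm(pops, prior)  # all pairs, all ligands
        secreted = prior.secreted()
        oracle = {
            (u, v, d["ligand"], d["targets"], round(d["activity"], 12))
            for u, v, d in pooled.edges(data=True)
            if u[0] != v[0] and d["ligand"] in secreted
        }
        got = {
            (u, v, d["ligand"], d["targets"], round(d["activity"], 12))
            for u, v, d in mo.edges(data=True)
        }
        assert got == oracle


class TestRankURs:
    def _graph(self, edges):
        import networkx as nx

        g = nx.MultiDiGraph()
        for u, v, lig, targets in edges:
            g.add_edge(u, v, key=lig, ligand=lig, targets=frozenset(targets),
                       activity=0.5)
        return g

    def test_stated_ordering(self):
        g = self._graph(
            [
                ("a", "r1", "UR_a", [f"t{i}" for i in range(4)]),
                ("a", "r2", "UR_a", [f"t{i}" for i in range(4)]),
                ("a", "r3", "UR_a", [f"t{i}" for i in range(4)]),
                ("a", "r1", "UR_b", [f"t{i}" for i in range(6)]),
                ("a", "r2", "UR_b", [f"t{i}" for i in range(6)]),
                ("a", "r1", "UR_c", [f"t{i}" for i in range(5)]),
            ]
        )
        tab = rank_urs(g)
        assert list(tab["ur"]) == ["UR_a", "UR_b", "UR_c"]
        assert list(tab["n_targets"]) == [12, 12, 5]

    def test_single_ur(self):
        g = self._graph([("a", "b", "L", ["t1"])])
        assert rank_urs(g)["rank"].tolist() == [1]

    def test_empty_graph(self):
        import networkx as nx

        assert rank_urs(nx.MultiDiGraph()).empty

    def test_equals_recount_oracle_and_edge_order_invariance(self):
        rng = np.random.default_rng(8)
        combos = [
            (f"s{a}", f"r{b}", f"L{c}")
            for a in range(3) for b in range(4) for c in range(5)
        ]
        picked = rng.choice(len(combos), size=40, replace=False)
        edges = []
        for i in picked:
            u, v, lig = combos[i]
            targets = [f"t{j}" for j in rng.choice(30, rng.integers(1, 10), replace=False)]
            edges.append((u, v, lig, targets))
        tab = rank_urs(self._graph(edges))
        # brute-force recount from the edge list
        totals, recv = {}, {}
        for u, v, lig, targets in edges:
            d = {"ligand": lig, "targets": targets}
            totals[d["ligand"]] = totals.get(d["ligand"], 0) + len(d["targets"])
            recv.setdefault(d["ligand"], set()).add(v)
        expected = sorted(totals, key=lambda l: (-totals[l], -len(recv[l]), l))
        assert list(tab["ur"]) == expected
        tab2 = rank_urs(self._graph(list(reversed(edges))))
        assert list(tab2["ur"]) == list(tab["ur"])

    def test_planted_ur_recovery(self):
        db, truth, prior, pops, planted = organ_scenario(
            seed=9, fp_rate=0.02, fn_rate=0.2
        )
        g = build_mcdm(pops, prior)
        tab = rank_urs(g)
        top = set(tab.head(len(planted) + 2)["ur"])
        assert set(planted) <= top


class TestSeverity:
    def test_identical_groups_p_one(self):
        adata, _, _ = syn.generate_expression(["A"], 12, n_genes=30, seed=10)
        cells = list(adata.obs_names)
        tab = ur_target_severity(
            adata, list(adata.var_names[:5]),
            {"g1": cells[:6], "g2": cells[:6]},
        )
        assert np.allclose(tab["p_holm"].to_numpy(), 1.0)

    def test_separated_groups_exact_p(self):
        from math import comb

        adata, _, _ = syn.generate_expression(["A"], 8, n_genes=30, seed=11)
        x = adata.X.copy()
        x[:4, :5] = 0.0
        x[4:, :5] = np.linspace(2, 3, 20).reshape(4, 5)
        adata.X = x
        cells = list(adata.obs_names)
        tab = ur_target_severity(
            adata, list(adata.var_names[:5]), {"low": cells[:4], "high": cells[4:]}
        )
        assert tab["p"].iloc[0] == pytest.approx(2 / comb(8, 4), rel=1e-9)

    def test_three_groups_holm_scaling(self):
        adata, _, _ = syn.generate_expression(["A"], 18, n_genes=30, seed=12)
        cells = list(adata.obs_names)
        tab = ur_target_severity(
            adata, list(adata.var_names[:5]),
            {"healthy": cells[:6], "mild": cells[6:12], "severe": cells[12:]},
        )
        assert len(tab) == 3
        order = tab.sort_values("p")
        assert (order["p_holm"].to_numpy() >= order["p"].to_numpy() - 1e-12).all()
        assert order["p_holm"].is_monotonic_increasing

    def test_no_target_overlap_raises(self):
        adata, _, _ = syn.generate_expression(["A"], 6, n_genes=10, seed=13)
        with pytest.raises(ValueError):
            ur_target_severity(adata, ["nope"], {"a": [], "b": []})


class TestBootstrapDegCounts:
    def test_active_organ_yields_more_degs(self):
        from mcdmkit.interactions import bootstrap_deg_counts

        adata, _, _ = syn.generate_expression(["A"], 80, n_genes=100, seed=21)
        obs = adata.obs
        obs["organ"] = ["joint"] * 40 + ["liver"] * 40
        obs["disease_state"] = (["sick"] * 20 + ["healthy"] * 20) * 2
        x = adata.X.copy()
        planted = np.arange(30)
        sick_joint = ((obs["organ"] == "joint") & (obs["disease_state"] == "sick")).to_numpy()
        x[np.ix_(sick_joint, planted)] += 1.0  # joint responds, liver does not
        adata.X = x
        counts = bootstrap_deg_counts(adata, n_cells=20, n_rounds=3, seed=0)
        assert set(counts) == {"joint", "liver"}
        assert np.median(counts["joint"]) > np.median(counts["liver"])
        assert prioritize_organs(counts, n_keep=1) == ["joint"]


class TestPrioritizeOrgans:
    def test_zero_deg_organ_last(self):
        counts = {"joint": [50, 60], "liver": [0, 0], "lung": [30, 20]}
        ranked = prioritize_organs(counts, n_keep=3)
        assert ranked[-1] == "liver"

    def test_single_organ_returned(self):
        with pytest.warns(UserWarning):
            assert prioritize_organs({"joint": [5]}, n_keep=5) == ["joint"]

    def test_quality_exclusion(self):
        counts = {"joint": [50], "kidney": [100]}
        ranked = prioritize_organs(
            counts, n_keep=2, quality_cells={"joint": 200, "kidney": 25}
        )
        assert "kidney" not in ranked

    def test_graded_activity_excludes_inactive_organ(self):
        # six organs with graded planted DEG counts; the inactive organ must
        # drop out of the top five across seeded replicates
        rng_master = np.random.default_rng(14)
        failures = 0
        for _ in range(100):
            rng = np.random.default_rng(rng_master.integers(2**31))
            counts = {}
            for i, organ in enumerate(["o1", "o2", "o3", "o4", "o5"]):
                lam = 40 + 25 * i
                counts[organ] = list(rng.poisson(lam, size=10))
            counts["inactive"] = list(rng.poisson(2, size=10))
            top = prioritize_organs(counts, n_keep=5)
            if "inactive" in top:
                failures += 1
        assert failures <= 5
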