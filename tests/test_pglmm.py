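"""Design matrices, phylogenetic covariance, link algebra and the sampler."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nodecount.pglmm import (
    ChainSettings,
    DesignMatrix,
    ModelSpec,
    ModelSpecError,
    PosteriorFit,
    build_design,
    dic,
    expected_nodes,
    fit,
    phylo_covariance,
    summarize,
)
from nodecount.response import build_response_table
from nodecount.tree_io import TipAnnotation, parse_newick

from conftest import FAST_CHAIN, random_topology, star_cov, star_newick, star_table

FIVE_GROUPS = ["Ceratopsidae", "Hadrosauriformes", "Ornithischia_other",
               "Sauropodomorpha", "Theropoda"]


def five_group_table(n_per_group=4):
    rows = []
    for g in FIVE_GROUPS:
        for i in range(n_per_group):
            rows.append({"tip_label": f"{g}_{i}", "n_nodes": 2 + i, "time": 10.0 + i,
                         "group": g, "n_occ": 1, "log_n_occ": 0.0})
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_five_group_quadratic_with_default_restrictions(self):
        # Ceratopsidae and Hadrosauriformes keep only the Time effect, so the
        # temporal block is Time x 5 plus Time^2 x 3 = 8 columns
        spec = ModelSpec(temporal_form="quadratic", grouping="group_wise")
        d = build_design(five_group_table(), spec)
        temporal = [c for c in d.X.columns if c.startswith(("time", "sqrt"))]
        assert len(temporal) == 8
        assert sum(c.startswith("time2") for c in temporal) == 3
        assert not any(c.startswith("time2[Ceratopsidae") for c in temporal)
        intercepts = [c for c in d.X.columns if c.startswith("intercept")]
        assert len(intercepts) == 5

    def test_sqrt_restricted_groups_fall_back_to_time(self):
        spec = ModelSpec(temporal_form="sqrt", grouping="group_wise")
        d = build_design(five_group_table(), spec)
        assert "time[Ceratopsidae]" in d.X.columns
        assert "sqrt_time[Ceratopsidae]" not in d.X.columns
        assert "sqrt_time[Theropoda]" in d.X.columns

    def test_single_linear_two_columns(self):
        spec = ModelSpec(temporal_form="linear", grouping="single")
        d = build_design(five_group_table(), spec)
        assert list(d.X.columns) == ["intercept", "time"]

    def test_block_structure_zeroes_other_groups(self):
        spec = ModelSpec(temporal_form="quadratic", grouping="group_wise")
        d = build_design(five_group_table(), spec)
        theropod_rows = d.X[five_group_table()["group"] == "Theropoda"]
        cera_cols = [c for c in d.X.columns if "Ceratopsidae" in c]
        assert (theropod_rows[cera_cols] == 0).all().all()

    def test_fixed_intercept_removes_columns_and_sets_offset(self):
        spec = ModelSpec(temporal_form="linear", grouping="group_wise",
                         intercept_mode=0.0)
        d = build_design(five_group_table(), spec)
        assert not any(c.startswith("intercept") for c in d.X.columns)
        assert d.offset == 0.0

    def test_unknown_covariate_rejected(self):
        spec = ModelSpec(temporal_form="linear", grouping="single",
                         covariates=("sea_level",))
        with pytest.raises(ModelSpecError, match="sea_level"):
            build_design(five_group_table(), spec)

    def test_all_zero_column_rejected(self):
        tab = five_group_table()
        tab.loc[tab["group"] == "Theropoda", "time"] = 0.0
        spec = ModelSpec(temporal_form="linear", grouping="group_wise",
                         intercept_mode=0.0)
        with pytest.raises(ModelSpecError, match="time\\[Theropoda\\]"):
            build_design(tab, spec)

    def test_restrictions_cannot_upgrade(self):
        spec = ModelSpec(temporal_form="linear", grouping="group_wise",
                         group_restrictions={"Theropoda": "quadratic"})
        d = build_design(five_group_table(), spec)
        assert "time2[Theropoda]" not in d.X.columns


class TestPhyloCovariance:
    def test_star_tree_is_identity(self):
        t = parse_newick(star_newick(6))
        c = phylo_covariance(t)
        assert np.allclose(c.matrix, np.eye(6))

    def test_hand_computed_shared_paths(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        c = phylo_covariance(t)
        i = {l: k for k, l in enumerate(c.labels)}
        assert c.matrix[i["A"], i["B"]] == pytest.approx(0.5)
        assert c.matrix[i["A"], i["C"]] == 0.0
        assert np.allclose(np.diag(c.matrix), 1.0)  # ultrametric

    def test_positive_semidefinite_on_random_trees(self, rng):
        for _ in range(10):
            newick, _, _ = random_topology(rng, 30)
            c = phylo_covariance(parse_newick(newick))
            assert np.linalg.eigvalsh(c.matrix).min() >= -1e-8
            assert np.allclose(c.matrix, c.matrix.T)

    def test_zero_depth_tree_rejected(self):
        t = parse_newick("(A:0,B:0);")
        with pytest.raises(ModelSpecError):
            phylo_covariance(t)


class TestExpectedNodes:
    def test_inverse_link_values(self):
        assert expected_nodes(0.0, 0.0) == 1.0
        assert round(expected_nodes(1.0, 0.0), 2) == 2.72
        assert expected_nodes(0.0, np.log(7)) == pytest.approx(7.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)
    )
    def test_link_multiplicativity(self, b, r, s):
        left = expected_nodes(b, r) * expected_nodes(0.0, s)
        right = expected_nodes(b, r + s)
        assert left == pytest.approx(right, rel=1e-9)


def _tiny_fit(samples: np.ndarray, deviance=None, eta=None, y=None) -> PosteriorFit:
    n = len(samples)
    return PosteriorFit(
        coef_samples=pd.DataFrame({"b": samples}),
        sigma2_phylo=np.full(n, 0.1),
        sigma2_resid=np.full(n, 0.1),
        eta_samples=eta if eta is not None else np.zeros((n, 3)),
        deviance=deviance if deviance is not None else np.zeros(n),
        dic=np.nan, pd_effective_params=np.nan,
        ess=pd.Series(dtype=float), rhat=pd.Series(dtype=float),
        settings=FAST_CHAIN, seed=0, spec_label="x", data_hash="h",
        n_params=1, offset=0.0, y=y if y is not None else np.ones(3),
    )


class TestDic:
    def test_constant_trace_gives_zero_pd(self):
        y = np.array([2.0, 3.0, 1.0])
        eta = np.tile(np.log(y), (20, 1))
        from scipy.special import gammaln
        d = float(-2 * np.sum(y * np.log(y) - y - gammaln(y + 1)))
        f = _tiny_fit(np.zeros(20), deviance=np.full(20, d), eta=eta, y=y)
        score, pd_eff = dic(f, return_pd=True)
        assert score == pytest.approx(d)
        assert pd_eff == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        f = _tiny_fit(np.zeros(5))
        with pytest.raises(ModelSpecError):
            dic(f)


class TestSummarize:
    def test_all_positive_samples_floor_pmcmc(self):
        f = _tiny_fit(np.linspace(0.5, 1.5, 200))
        s = summarize(f)
        assert s.loc["b", "pmcmc"] == pytest.approx(2.0 / 200)
        assert bool(s.loc["b", "significant"])

    def test_symmetric_samples_not_significant(self):
        x = np.concatenate([np.linspace(-1, -0.01, 100), np.linspace(0.01, 1, 100)])
        s = summarize(_tiny_fit(x))
        assert s.loc["b", "pmcmc"] == pytest.approx(1.0)
        assert not bool(s.loc["b", "significant"])


class TestFit:
    def test_seed_determinism_bitwise(self, rng):
        tab = star_table(rng, 60, lambda t: 0.3 + 0.01 * t)
        cov = star_cov(tab["tip_label"])
        spec = ModelSpec("linear", "single", group_restrictions={})
        f1 = fit(tab, spec, cov, settings=FAST_CHAIN, seed=11)
        f2 = fit(tab, spec, cov, settings=FAST_CHAIN, seed=11)
        assert np.array_equal(f1.deviance, f2.deviance)
        assert f1.coef_samples.equals(f2.coef_samples)
        f3 = fit(tab, spec, cov, settings=FAST_CHAIN, seed=12)
        assert not np.array_equal(f1.deviance, f3.deviance)

    def test_fixed_zero_intercept_empty_design_predicts_one(self):
        n = 40
        tab = pd.DataFrame({
            "tip_label": [f"T{i}" for i in range(n)], "n_nodes": 1,
            "time": np.linspace(0, 10, n), "group": "All",
            "n_occ": 1, "log_n_occ": 0.0,
        })
        design = DesignMatrix(
            X=pd.DataFrame(index=tab.index), offset=0.0,
            column_groups={}, spec=ModelSpec("linear", "single", intercept_mode=0.0),
        )
        f = fit(tab, design.spec, star_cov(tab["tip_label"]),
                settings=FAST_CHAIN, seed=3, design=design)
        pred = float(np.exp(f.eta_samples).mean())
        assert pred == pytest.approx(1.0, abs=0.2)

    def test_chain_settings_recorded_and_sample_count(self, rng):
        tab = star_table(rng, 40, lambda t: 0.3 + 0.01 * t)
        f = fit(tab, ModelSpec("linear", "single", group_restrictions={}),
                star_cov(tab["tip_label"]), settings=FAST_CHAIN, seed=1)
        assert f.n_samples == FAST_CHAIN.n_samples
        assert (f.sigma2_phylo > 0).all() and (f.sigma2_resid > 0).all()
        assert np.isfinite(f.dic)

    def test_group_wise_fit_on_simulated_tree(self):
        from nodecount.synthetic_data import downturn_study_config, simulate_tree
        sim = simulate_tree(downturn_study_config(seed=3, min_group_tips=5))
        tab = build_response_table(sim.tree, sim.annotations)
        cov = phylo_covariance(sim.tree)
        spec = ModelSpec("quadratic", "group_wise", group_restrictions={})
        f = fit(tab, spec, cov, settings=FAST_CHAIN, seed=5)
        assert f.n_params == 9  # 3 intercepts + 3 time + 3 time2
        assert np.isfinite(f.dic)
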