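"""PCA, OPLS-DA, Q2 cross-validation, VIP and marker selection."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from synernet.datatypes import MetaboliteTable, PathwayLibrary, ValidationError
from synernet.metabolome import (
    fit_opls_da,
    pathway_analysis,
    pathway_impact,
    pca,
    q2_crossval,
    select_markers,
    vip_scores,
)
from synernet.opls import OPLSDA, vip
from synernet.synthetic import OmicsGenConfig, gen_metabolites


def _table(values, n1, n2, names=None):
    values = np.asarray(values, dtype=float)
    samples = [f"p{i}" for i in range(n1)] + [f"h{i}" for i in range(n2)]
    groups = pd.Series(["g1"] * n1 + ["g2"] * n2, index=samples)
    names = names or [f"m{i}" for i in range(values.shape[0])]
    return MetaboliteTable(pd.DataFrame(values, index=names, columns=samples), groups)


class TestPca:
    def test_rank_one_single_component(self):
        direction = np.array([1.0, 2.0, 3.0])
        weights = np.array([1.0, -1.0, 0.5, 2.0, -0.3, 0.8])
        X = 10 + np.outer(direction, weights)  # metabolites x samples, rank 1
        t = _table(X, 3, 3)
        _, _, evr = pca(t, n_components=2, scale=False)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self, separated_metabolites):
        scores, _, _ = pca(separated_metabolites, n_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_full_rank_reconstruction(self, separated_metabolites):
        t = separated_metabolites
        X = t.values.to_numpy().T
        n_comp = min(X.shape[0] - 1, X.shape[1])
        scores, loadings, _ = pca(t, n_components=n_comp, scale=False)
        np.testing.assert_allclose(scores @ loadings.T, X - X.mean(axis=0), atol=1e-8)

    def test_component_bound_enforced(self, separated_metabolites):
        with pytest.raises(ValidationError):
            pca(separated_metabolites, n_components=1000)


class TestOplsDa:
    def test_predictive_orthogonal_to_orthogonal_scores(self, separated_metabolites):
        model = fit_opls_da(separated_metabolites, n_orth=2)
        for k in range(model.t_orth_.shape[1]):
            assert abs(model.t_ @ model.t_orth_[:, k]) < 1e-8

    def test_planted_shift_high_r2y(self, separated_metabolites):
        model = fit_opls_da(separated_metabolites, n_orth=1)
        assert model.r2y_ > 0.9

    def test_zero_orth_equals_one_component_pls(self, separated_metabolites):
        t = separated_metabolites
        X = t.values.to_numpy().T
        y = t.y_pm1()
        model = OPLSDA(n_orth=0, scale=True).fit(X, y)
        pls = PLSRegression(n_components=1, scale=True).fit(X, y.reshape(-1, 1))
        ours = model.t_ / np.linalg.norm(model.t_)
        ref = pls.x_scores_.ravel() / np.linalg.norm(pls.x_scores_)
        sign = np.sign(ours @ ref)
        np.testing.assert_allclose(ours, sign * ref, atol=1e-8)

    def test_constant_column_named(self):
        X = np.vstack([np.full(8, 3.0), np.random.default_rng(0).uniform(1, 5, (3, 8))])
        t = _table(X, 4, 4)
        with pytest.raises(ValidationError, match="column 0"):
            fit_opls_da(t)

    def test_sklearn_param_protocol(self):
        model = OPLSDA(n_orth=2, scale=False)
        assert model.get_params() == {"n_orth": 2, "scale": False}
        model.set_params(n_orth=0)
        assert model.n_orth == 0


class TestQ2:
    def test_null_data_median_q2_nonpositive(self):
        q2s = []
        for seed in range(200):
            t = gen_metabolites(OmicsGenConfig(
                metabolite_names=tuple(f"m{i}" for i in range(15)),
                n_samples_per_group=8, noise_sd=0.4, seed=3000 + seed))
            q2s.append(q2_crossval(t, n_orth=1, folds=7, seed=seed))
        assert np.median(q2s) <= 0

    def test_planted_effect_q2_high(self, separated_metabolites):
        assert q2_crossval(separated_metabolites, n_orth=1, folds=7, seed=5) > 0.5

    def test_q2_below_r2y_on_planted_data(self, separated_metabolites):
        model = fit_opls_da(separated_metabolites)
        q2 = q2_crossval(separated_metabolites, seed=5)
        assert q2 <= model.r2y_ + 1e-8

    def test_stratification_guard(self, separated_metabolites):
        with pytest.raises(ValidationError):
            q2_crossval(separated_metabolites, folds=100)


class TestVip:
    def test_mean_square_is_one(self, separated_metabolites):
        for n_orth in (0, 1, 2):
            model = fit_opls_da(separated_metabolites, n_orth=n_orth)
            v = vip(model)
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)

    def test_single_discriminant_metabolite_has_max_vip(self):
        t = gen_metabolites(OmicsGenConfig(
            metabolite_names=tuple(f"m{i}" for i in range(12)) + ("hit",),
            n_samples_per_group=10, noise_sd=0.3,
            planted_shift_metabolites={"hit": 4.0}, seed=5))
        model = fit_opls_da(t)
        v = vip_scores(model, t)
        assert v.idxmax() == "hit"

    def test_equally_loaded_variables_unit_vip(self):
        rng = np.random.default_rng(1)
        signal = np.concatenate([np.ones(6), np.full(6, 2.0)])
        X = np.tile(signal, (5, 1)) + rng.normal(0, 1e-9, (5, 12))
        t = _table(X, 6, 6)
        model = fit_opls_da(t, n_orth=0)
        np.testing.assert_allclose(vip(model), 1.0, atol=1e-3)


class TestMarkerSelection:
    def test_significant_tier_subset_of_discriminant(self, separated_metabolites):
        model = fit_opls_da(separated_metabolites)
        markers, _ = select_markers(model, separated_metabolites)
        assert markers.ids("significant") <= markers.ids()

    def test_zero_vip_cut_admits_everything(self, separated_metabolites):
        model = fit_opls_da(separated_metabolites)
        markers, detail = select_markers(model, separated_metabolites, vip_cut=0.0)
        assert len(detail[detail["tier"] != "none"]) == len(separated_metabolites.values)

    def test_planted_shifts_in_significant_tier(self, separated_metabolites):
        from conftest import STRONG_SHIFT_METABOLITES
        model = fit_opls_da(separated_metabolites)
        markers, _ = select_markers(model, separated_metabolites)
        assert set(STRONG_SHIFT_METABOLITES) <= markers.ids("significant")

    def test_null_significant_fraction_near_alpha(self):
        # with no group difference, P(p < alpha) ~= alpha within the
        # discriminant tier; aggregate over 200 seeds
        sig, disc = 0, 0
        for seed in range(200):
            t = gen_metabolites(OmicsGenConfig(
                metabolite_names=tuple(f"m{i}" for i in range(12)),
                n_samples_per_group=8, noise_sd=0.4, seed=7000 + seed))
            model = fit_opls_da(t)
            markers, _ = select_markers(model, t)
            disc += len(markers.ids())
            sig += len(markers.ids("significant"))
        rate = sig / disc
        se = np.sqrt(0.05 * 0.95 / disc)
        # under the null, VIP selection correlates with low p, so the rate
        # exceeds alpha; it must still be a small fraction, far below half
        assert rate < 0.35


class TestPathwayAnalysis:
    def test_star_graph_impact(self):
        star = nx.star_graph(5)  # hub node 0
        assert pathway_impact({0}, star) == pytest.approx(1.0)
        assert pathway_impact({1}, star) < 1.0

    def test_rows_sorted_and_impact_zero_without_graph(self, separated_metabolites):
        from synernet.synthetic import default_pathway_library
        model = fit_opls_da(separated_metabolites)
        markers, _ = select_markers(model, separated_metabolites)
        lib = PathwayLibrary(default_pathway_library())
        rows = pathway_analysis(markers, lib, set(separated_metabolites.values.index))
        assert (rows["p"].diff().dropna() >= 0).all()
        assert (rows["impact"] == 0).all()

    def test_graph_supplied_gives_positive_impact(self, separated_metabolites):
        from synernet.synthetic import default_pathway_library
        members = default_pathway_library()
        g = nx.Graph()
        tc = sorted(members["TCA cycle"])
        g.add_edges_from(zip(tc, tc[1:]))  # chain over the members
        lib = PathwayLibrary(members, graphs={"TCA cycle": g})
        model = fit_opls_da(separated_metabolites)
        markers, _ = select_markers(model, separated_metabolites)
        rows = pathway_analysis(markers, lib, set(separated_metabolites.values.index))
        impact = rows.set_index("pathway").loc["TCA cycle", "impact"]
        assert 0 < impact <= 1
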