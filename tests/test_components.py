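"""PCA decomposition, selection rule, enrichment, missingness + imputation."""

import numpy as np
import pandas as pd
import pytest

from pdxplore.components import (
    ComponentDecomposition,
    decompose,
    filter_by_missingness,
    loading_enrichment,
    pca_impute,
    read_gmt,
    select_components,
    top_contributors,
    write_gmt,
)


def _random_matrix(rng, n_genes=50, n_samples=10):
    return pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                        index=[f"g{i:03d}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestDecompose:
    def test_rank_one_matrix_concentrates_variance(self, rng):
        u = rng.normal(size=30)
        v = rng.normal(size=8)
        mat = pd.DataFrame(np.outer(u, v), index=[f"g{i}" for i in range(30)],
                           columns=[f"s{j}" for j in range(8)])
        dec = decompose(mat)
        assert dec.var_fraction[0] == pytest.approx(1.0, abs=1e-6)

    def test_full_reconstruction_identity(self, rng):
        mat = _random_matrix(rng)
        dec = decompose(mat)
        centered = mat.to_numpy().T - mat.to_numpy().T.mean(axis=0)
        recon = dec.scores.to_numpy() @ dec.loadings.to_numpy().T
        assert np.linalg.norm(recon - centered) < 1e-8

    def test_orthonormal_loadings(self, rng):
        dec = decompose(_random_matrix(rng))
        gram = dec.loadings.to_numpy().T @ dec.loadings.to_numpy()
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_variance_fractions_sum_to_one_and_decrease(self, rng):
        dec = decompose(_random_matrix(rng))
        assert dec.var_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(dec.var_fraction) <= 1e-12).all()

    def test_sign_convention_deterministic(self, rng):
        mat = _random_matrix(rng)
        a, b = decompose(mat), decompose(mat)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for col in a.loadings.columns:
            top = a.loadings[col].abs().idxmax()
            assert a.loadings.loc[top, col] > 0

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            decompose(_random_matrix(rng, n_samples=1))

    def test_planted_factor_subspace_recovery(self, expression_cohort):
        from scipy.linalg import subspace_angles

        from pdxplore.deconvolution import build_tumor_matrix, cpm_log1p

        counts_h, _, _, _, truth = expression_cohort
        tumor = build_tumor_matrix(counts_h, truth.me_gene_ids)
        dec = decompose(cpm_log1p(tumor))
        angles = subspace_angles(dec.scores.iloc[:, :3].to_numpy(),
                                 truth.factor_scores.to_numpy())
        assert np.cos(angles).min() > 0.95


class TestSelectComponents:
    def _dec(self, var_fractions, scores):
        k = len(var_fractions)
        names = [f"PC{j + 1}" for j in range(k)]
        return ComponentDecomposition(
            scores=pd.DataFrame(scores, columns=names),
            loadings=pd.DataFrame(np.eye(len(scores), k), columns=names),
            var_fraction=np.asarray(var_fractions),
        )

    def test_boundary_4_9_percent_always_rejected(self):
        scores = np.random.default_rng(0).normal(size=(10, 2))
        dec = self._dec([0.90, 0.049], scores)
        select_components(dec, None)
        assert dec.rejection_reason[1] == "low_variance" and not dec.selected[1]

    def test_exactly_5_percent_rejected_strictly_more_required(self):
        scores = np.random.default_rng(0).normal(size=(10, 2))
        dec = self._dec([0.90, 0.05], scores)
        select_components(dec, None)
        assert dec.rejection_reason[1] == "low_variance"

    def test_perfect_group_separation_rejected(self):
        labels = {i: ("a" if i < 5 else "b") for i in range(10)}
        scores = np.zeros((10, 1))
        scores[:5, 0] = 1.0 + np.arange(5) * 0.1
        scores[5:, 0] = -1.0 - np.arange(5) * 0.1
        dec = self._dec([0.5], scores)
        select_components(dec, labels)
        assert dec.rejection_reason[0] == "species_separation"

    def test_degenerate_limit_selects_all(self, rng):
        dec = self._dec([0.6, 0.3, 0.1], rng.normal(size=(10, 3)))
        select_components(dec, None, min_var=0.0)
        assert dec.selected.all()

    def test_single_group_skips_separation_test(self, rng):
        labels = {i: "only" for i in range(10)}
        dec = self._dec([0.9, 0.1], rng.normal(size=(10, 2)))
        select_components(dec, labels)
        assert dec.selected[0] and np.isnan(dec.separation_p_adj[0])

    def test_planted_species_factor_rejected_biology_kept(self, expression_cohort):
        from pdxplore.deconvolution import build_tumor_matrix, cpm_log1p

        counts_h, _, meta, _, truth = expression_cohort
        tumor = build_tumor_matrix(counts_h, truth.me_gene_ids)
        dec = decompose(cpm_log1p(tumor))
        m = meta.set_index("sample")
        groups = {s: ("patient" if m.loc[s, "fraction"] == "patient" else "pdx")
                  for s in tumor.columns}
        select_components(dec, groups)
        fs = truth.factor_scores
        corr_sp = dec.scores.apply(lambda c: abs(np.corrcoef(c, fs["factor0"])[0, 1]))
        corr_bio = dec.scores.apply(lambda c: abs(np.corrcoef(c, fs["factor1"])[0, 1]))
        i_sp = dec.component_names.index(corr_sp.idxmax())
        i_bio = dec.component_names.index(corr_bio.idxmax())
        assert dec.rejection_reason[i_sp] == "species_separation"
        assert dec.selected[i_bio]


class TestTopContributors:
    def test_worked_example(self):
        loadings = pd.DataFrame({"PC1": [0.9, -0.8, 0.1]}, index=["g1", "g2", "g3"])
        out = top_contributors(loadings, "PC1", 2)
        assert list(out["gene"]) == ["g1", "g2"] and list(out["sign"]) == ["+", "-"]

    def test_ties_broken_lexicographically(self):
        loadings = pd.DataFrame({"PC1": [0.5, -0.5, 0.5]}, index=["b", "c", "a"])
        out = top_contributors(loadings, "PC1", 2)
        assert list(out["gene"]) == ["a", "b"]

    def test_matches_brute_force_sort(self, rng):
        loadings = pd.DataFrame({"PC1": rng.normal(size=40)},
                                index=[f"g{i:02d}" for i in range(40)])
        out = top_contributors(loadings, "PC1", 10)
        expected = sorted(loadings.index, key=lambda g: (-abs(loadings.loc[g, "PC1"]), g))[:10]
        assert list(out["gene"]) == expected

    def test_n_too_large_rejected(self):
        loadings = pd.DataFrame({"PC1": [0.1]}, index=["g"])
        with pytest.raises(ValueError):
            top_contributors(loadings, "PC1", 2)


class TestLoadingEnrichment:
    def _loadings(self, rng, n=200):
        return pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])

    def test_planted_top_set_enriched(self, rng):
        lo = self._loadings(rng)
        top20 = set(lo.sort_values(ascending=False).index[:20])
        out = loading_enrichment(lo, {"top": top20}, n_perm=1000, seed=1)
        assert out["es"].iloc[0] > 0 and out["p_value"].iloc[0] <= 0.01

    def test_rank_reversal_flips_es_sign_exactly(self, rng):
        lo = self._loadings(rng)
        members = set(lo.index[:30])
        a = loading_enrichment(lo, {"s": members}, n_perm=10, seed=2)
        b = loading_enrichment(-lo, {"s": members}, n_perm=10, seed=2)
        assert a["es"].iloc[0] == pytest.approx(-b["es"].iloc[0], abs=1e-12)

    def test_minimum_attainable_pvalue(self, rng):
        lo = self._loadings(rng)
        top = set(lo.sort_values(ascending=False).index[:20])
        out = loading_enrichment(lo, {"top": top}, n_perm=200, seed=3)
        assert out["p_value"].iloc[0] >= 1 / 201

    def test_small_overlap_skipped(self, rng):
        lo = self._loadings(rng)
        out = loading_enrichment(lo, {"tiny": {"g000", "g001"}}, n_perm=10)
        assert out["direction"].iloc[0] == "skipped" and np.isnan(out["es"].iloc[0])

    def test_gmt_round_trip(self, tmp_path):
        sets = {"setA": {"g1", "g2", "g3"}, "setB": {"g9"}}
        write_gmt(sets, tmp_path / "x.gmt")
        assert read_gmt(tmp_path / "x.gmt") == sets


class TestMissingnessFilter:
    def test_37_percent_missing_dropped(self):
        mat = pd.DataFrame(np.ones((1, 8)), index=["p"])
        mat.iloc[0, :3] = np.nan  # 37.5%
        kept, dropped = filter_by_missingness(mat)
        assert kept.empty and dropped["protein"].iloc[0] == "p"

    def test_fully_observed_kept(self):
        mat = pd.DataFrame(np.ones((2, 8)), index=["a", "b"])
        kept, dropped = filter_by_missingness(mat)
        assert len(kept) == 2 and dropped.empty

    def test_partition_of_rows(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 8)))
        mask = rng.random((30, 8)) < 0.3
        mat = mat.mask(mask)
        kept, dropped = filter_by_missingness(mat)
        assert len(kept) + len(dropped) == 30


class TestPcaImpute:
    def test_no_missing_is_identity(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 6)))
        out, converged, n_iter = pca_impute(mat)
        pd.testing.assert_frame_equal(out, mat)
        assert converged and n_iter == 0

    def test_observed_cells_bit_identical(self, rng):
        from pdxplore.synthetic import simulate_protein_matrix

        obs, _ = simulate_protein_matrix(n_proteins=80, n_samples=8, seed=4)
        kept, _ = filter_by_missingness(obs)
        out, _, _ = pca_impute(kept, rank=2)
        mask = kept.notna().to_numpy()
        assert (out.to_numpy()[mask] == kept.to_numpy()[mask]).all()

    def test_beats_row_mean_on_low_rank_data(self):
        from pdxplore.synthetic import simulate_protein_matrix

        wins = 0
        for seed in range(5):
            obs, complete = simulate_protein_matrix(
                n_proteins=150, n_samples=10, missing_rate=0.2,
                high_missing_fraction=0.0, seed=seed,
            )
            kept, _ = filter_by_missingness(obs)
            truth = complete.loc[kept.index]
            out, _, _ = pca_impute(kept, rank=2)
            mask = kept.isna().to_numpy()
            rmse = np.sqrt(np.mean((out.to_numpy()[mask] - truth.to_numpy()[mask]) ** 2))
            base = kept.to_numpy().copy()
            rm = np.nanmean(base, axis=1)
            base[mask] = np.take(rm, np.where(mask)[0])
            rmse_base = np.sqrt(np.mean((base[mask] - truth.to_numpy()[mask]) ** 2))
            wins += rmse < rmse_base
        assert wins == 5
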