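"""Bray–Curtis β-diversity, environmental distances, and the two-layer
path model."""

import numpy as np
import pandas as pd
import pytest

import thermonet as tn
from thermonet.preprocess import OTUTable


def _ra_table(rows, otus):
    idx = pd.Index([r[0] for r in rows], name="sample")
    meta = pd.DataFrame({"lake": [f"L{i}" for i in range(len(rows))],
                         "habitat": ["water"] * len(rows)}, index=idx)
    data = pd.DataFrame([r[1] for r in rows], index=idx, columns=otus)
    return OTUTable(data.div(data.sum(axis=1), axis=0), meta, is_relative=True)


class TestBrayCurtis:
    def test_identical_profiles(self):
        t = _ra_table([("s1", [2, 2]), ("s2", [2, 2])], ["a", "b"])
        D = tn.bray_curtis(t)
        assert D.loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_supports(self):
        t = _ra_table([("s1", [1, 0]), ("s2", [0, 1])], ["a", "b"])
        assert tn.bray_curtis(t).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # raw profiles [2,2] vs [1,3]: (1+1)/(4+4) = 0.25 — identical on
        # the relative scale since both sum to the same total
        t = _ra_table([("s1", [2, 2]), ("s2", [1, 3])], ["a", "b"])
        assert tn.bray_curtis(t).loc["s1", "s2"] == pytest.approx(0.25)

    def test_symmetry_range_zero_diagonal(self, small_community):
        _, table, _, _ = small_community
        ra = tn.relative_abundance(table)
        D = tn.bray_curtis(ra)
        M = D.to_numpy()
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0.0)
        assert (M >= -1e-12).all() and (M <= 1 + 1e-12).all()

    def test_pair_with_empty_subset_flagged(self):
        t = _ra_table([("s1", [1, 0, 1]), ("s2", [1, 0, 1])], ["a", "b", "c"])
        D = tn.bray_curtis(t, otu_subset=["b"])
        assert np.isnan(D.loc["s1", "s2"])


class TestEnvDistance:
    def test_standardized_absolute_difference(self):
        # values with SD 0.5: z-scores of 7.0 and 8.0 differ by 2.0
        env = pd.DataFrame({"pH": [7.0, 8.0, 7.5, 7.2, 7.8]},
                           index=[f"s{i}" for i in range(5)])
        sd = env["pH"].std(ddof=1)
        D = tn.env_distance(env, "pH")
        assert D.loc["s0", "s1"] == pytest.approx(1.0 / sd)

    def test_identical_values_zero(self):
        env = pd.DataFrame({"x": [3.0, 3.0, 4.0]}, index=["a", "b", "c"])
        assert tn.env_distance(env, "x").loc["a", "b"] == 0.0

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=10)
        env1 = pd.DataFrame({"x": v}, index=range(10))
        env2 = pd.DataFrame({"x": 100 + 7 * v}, index=range(10))
        assert np.allclose(tn.env_distance(env1, "x"), tn.env_distance(env2, "x"))

    def test_constant_variable_warns_zero(self, caplog):
        env = pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        D = tn.env_distance(env, "x")
        assert np.allclose(D, 0.0)

    def test_unknown_variable(self):
        env = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            tn.env_distance(env, "pH")


def _random_distances(n, rng, label_idx=None):
    idx = label_idx if label_idx is not None else [f"s{i}" for i in range(n)]
    v = rng.normal(size=n)
    D = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(D, index=idx, columns=idx)


class TestPathModel:
    def test_perfect_fit_limit(self):
        """Community β identical to one module's β, the other a pure
        noise matrix: that path's standardized coefficient ≈ 1."""
        rng = np.random.default_rng(0)
        beta = _random_distances(20, rng)
        noise = _random_distances(20, rng)
        env = {"TN": _random_distances(20, rng)}
        fit = tn.fit_path_model(env, {"A": beta, "B": noise}, beta.copy())
        assert fit.coefficient("community", "module A") == pytest.approx(1.0, abs=1e-8)
        assert abs(fit.coefficient("community", "module B")) < 1e-8
        assert fit.r2["community"] == pytest.approx(1.0)

    def test_scale_invariance_of_standardized_paths(self):
        rng = np.random.default_rng(1)
        env1 = {"TN": _random_distances(15, rng), "TP": _random_distances(15, rng)}
        beta = _random_distances(15, rng)
        comm = _random_distances(15, rng)
        fit1 = tn.fit_path_model(env1, {"A": beta}, comm)
        env2 = {k: v * 37.0 for k, v in env1.items()}
        fit2 = tn.fit_path_model(env2, {"A": beta}, comm)
        for _, row in fit1.paths.iterrows():
            assert fit2.coefficient(row["response"], row["predictor"]) == \
                pytest.approx(row["coefficient"], abs=1e-10)

    def test_planted_env_module_coefficient_recovered(self):
        """The planted TN → module coupling of 0.6 is recovered within
        ±0.15 on average over 10 seeds (23 lakes, 253 sample pairs)."""
        coefs = []
        for seed in range(10):
            cfg = tn.SynthConfig(seed=100 + seed)
            table, env, truth = tn.generate_community(cfg)
            ra = tn.relative_abundance(table)
            wat = list(ra.samples_of("water"))
            env_w = env.loc[wat]
            env_dists = {v: tn.env_distance(env_w, v, samples=wat)
                         for v in env_w.columns}
            mod_otus = [o for o, m in truth.module_of.items() if m == "M2"]
            beta = tn.bray_curtis(ra, otu_subset=mod_otus, samples=wat)
            comm = tn.bray_curtis(ra, samples=wat)
            fit = tn.fit_path_model(env_dists, {"M2": beta}, comm, seed=seed)
            assert fit.n_pairs == 23 * 22 // 2
            coefs.append(fit.coefficient("module M2", "TN"))
        assert abs(np.mean(coefs) - 0.6) < 0.15
        # sign recovery: planted |coef| >= 0.5 keeps its sign in >= 90% of seeds
        assert np.mean(np.sign(coefs) == 1.0) >= 0.9

    def test_type_one_error_calibration_under_permutation(self):
        """On pure-noise inputs the permutation option rejects at ≈ the
        nominal 5% rate (200 simulated datasets)."""
        rng = np.random.default_rng(42)
        n = 23
        rejections, total = 0, 0
        for sim in range(200):
            env = {"TN": _random_distances(n, rng), "TP": _random_distances(n, rng)}
            betas = {"A": _random_distances(n, rng), "B": _random_distances(n, rng)}
            comm = _random_distances(n, rng)
            fit = tn.fit_path_model(env, betas, comm, p_method="permutation",
                                    n_perm=199, seed=sim)
            rejections += int(fit.paths["significant"].sum())
            total += len(fit.paths)
        rate = rejections / total
        assert 0.025 < rate < 0.075

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="disagree"):
            tn.fit_path_model({"TN": _random_distances(5, rng)},
                              {"A": _random_distances(5, rng)},
                              _random_distances(6, rng))


class TestContributionSummary:
    def _result(self, coef, p):
        paths = pd.DataFrame([
            {"response": "community", "predictor": "module A",
             "coefficient": coef, "p_value": p, "significant": p < 0.05}])
        return tn.PathModelResult(paths, {"community": 0.5}, "ols", 10)

    def test_positive_significant(self):
        out = tn.module_contribution_summary(self._result(0.4, 0.01))
        assert out["summary"].iloc[0] == "positive, significant"

    def test_negative_not_significant(self):
        out = tn.module_contribution_summary(self._result(-0.2, 0.3))
        assert out["summary"].iloc[0] == "negative, n.s."
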