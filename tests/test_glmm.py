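import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import florastat as fs
from florastat.errors import ValidationError
from florastat.glmm import (
    EMMResult,
    GLMMFit,
    compact_letter_display,
    estimated_marginal_means,
    fit_binary_mixed,
    type3_wald,
)


def _fake_fit(coef, cov, levels, blocks):
    names = list(coef.keys())
    return GLMMFit(
        coef=pd.Series(coef),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma_u=0.0, factor_levels=levels, factor_blocks=blocks,
        reference={f: lv[0] for f, lv in levels.items()},
        n_obs_used=0, n_species_used=0, loglik=0.0, converged=True)


class TestWald:
    def test_null_block(self):
        fit = _fake_fit({"(Intercept)": 0.3, "f[b]": 0.0, "f[c]": 0.0},
                        np.eye(3), {"f": ["a", "b", "c"]}, {"f": [1, 2]})
        w = type3_wald(fit)
        assert w.loc[0, "chisq"] == 0.0
        assert w.loc[0, "df"] == 2
        assert w.loc[0, "p_value"] == 1.0

    def test_single_coefficient_closed_form(self):
        fit = _fake_fit({"(Intercept)": 0.0, "f[b]": 2.0},
                        np.eye(2), {"f": ["a", "b"]}, {"f": [1]})
        w = type3_wald(fit)
        assert w.loc[0, "chisq"] == pytest.approx(4.0)
        assert w.loc[0, "df"] == 1
        assert w.loc[0, "p_value"] == pytest.approx(0.0455, abs=5e-4)

    def test_singular_block_named(self):
        cov = np.zeros((3, 3))
        fit = _fake_fit({"(Intercept)": 0.0, "f[b]": 1.0, "f[c]": 1.0},
                        cov, {"f": ["a", "b", "c"]}, {"f": [1, 2]})
        with pytest.raises(ValidationError, match="'f'"):
            type3_wald(fit)


class TestEMM:
    def test_identity_all_zero(self):
        fit = _fake_fit({"(Intercept)": 0.0, "f[b]": 0.0, "g[y]": 0.0},
                        np.eye(3) * 0.01,
                        {"f": ["a", "b"], "g": ["x", "y"]},
                        {"f": [1], "g": [2]})
        emm = estimated_marginal_means(fit, "f")
        assert emm.prob["a"] == pytest.approx(0.5)
        assert emm.prob["b"] == pytest.approx(0.5)

    def test_closed_form_average(self):
        # EMM of f-level must average the g dummies with weight 1/2
        beta = {"(Intercept)": 0.2, "f[b]": 1.0, "g[y]": 0.6}
        fit = _fake_fit(beta, np.diag([0.04, 0.09, 0.01]),
                        {"f": ["a", "b"], "g": ["x", "y"]},
                        {"f": [1], "g": [2]})
        emm = estimated_marginal_means(fit, "f")
        assert emm.emm_logit["a"] == pytest.approx(0.2 + 0.5 * 0.6)
        assert emm.emm_logit["b"] == pytest.approx(0.2 + 1.0 + 0.5 * 0.6)
        # SE of a: var = var(int) + 1/4 var(g[y]) ; diagonal covariance
        assert emm.se["a"] == pytest.approx(np.sqrt(0.04 + 0.25 * 0.01))
        contrast = emm.contrasts.iloc[0]
        assert contrast["estimate"] == pytest.approx(-1.0)
        assert contrast["se"] == pytest.approx(np.sqrt(0.09))


class TestLetters:
    def _emm(self, levels, pvals):
        pairs = [(a, b) for i, a in enumerate(levels)
                 for b in levels[i + 1:]]
        contrasts = pd.DataFrame({
            "level_1": [a for a, _ in pairs],
            "level_2": [b for _, b in pairs],
            "p_holm": pvals,
        })
        return (levels, contrasts)

    def test_no_separation(self):
        letters = compact_letter_display(self._emm(["a", "b", "c"],
                                                   [0.9, 0.5, 0.2]))
        assert set(letters.values()) == {"a"}

    def test_classic_chain(self):
        # only the extreme pair differs: a / ab / b pattern
        letters = compact_letter_display(
            self._emm(["lo", "mid", "hi"], [0.5, 0.01, 0.5]))
        assert letters["lo"] != letters["hi"]
        assert len(letters["mid"]) == 2
        assert set(letters["mid"]) == set(letters["lo"]) | set(letters["hi"])

    @given(st.integers(2, 6), st.data())
    def test_letter_semantics(self, n_levels, data):
        levels = [f"L{i}" for i in range(n_levels)]
        pairs = [(a, b) for i, a in enumerate(levels)
                 for b in levels[i + 1:]]
        pvals = [data.draw(st.sampled_from([0.001, 0.2, 0.8]))
                 for _ in pairs]
        letters = compact_letter_display(self._emm(levels, pvals))
        for (a, b), p in zip(pairs, pvals):
            shared = set(letters[a]) & set(letters[b])
            if p < 0.05:
                assert not shared, (letters, pairs, pvals)
            else:
                assert shared, (letters, pairs, pvals)


@pytest.fixture(scope="module")
def balanced_dataset():
    """Moderate-success dataset, safe from quasi-separation."""
    cfg = fs.SimulationConfig(
        n_species=80, n_families=8, seed=21, p_field=0.0,
        replicate_range={"database": (6, 6), "field": (1, 5)},
        baseline_logit=0.0, beta_ln_train=0.0, sd_species=1.0,
        organ_effects={"reproductive": 0.5, "both": 0.0, "vegetative": -0.5},
        background_effects={"no_vegetation": 0.0, "non_natural": 0.0,
                            "vegetation": 0.0},
        covariate_probabilities={
            "organs": {"reproductive": 0.35, "both": 0.35, "vegetative": 0.30},
            "focus": {"single": 0.7, "multiple": 0.3},
            "background": {"no_vegetation": 0.4, "non_natural": 0.2,
                           "vegetation": 0.4}})
    obs, _, _ = fs.simulate_dataset(cfg)
    return obs


class TestFit:
    def test_min_obs_filter(self):
        cfg = fs.SimulationConfig(n_species=30, n_families=4, seed=6,
                                  p_field=0.0,
                                  replicate_range={"database": (2, 6),
                                                   "field": (1, 5)})
        obs, _, _ = fs.simulate_dataset(cfg)
        counts = obs["verified_name"].value_counts()
        eligible = counts[counts >= 3].sum()
        fit = fit_binary_mixed(obs, min_obs=3)
        assert fit.n_obs_used == eligible
        assert fit.n_species_used == (counts >= 3).sum()

    def test_row_order_invariance(self, balanced_dataset):
        obs = balanced_dataset
        fit1 = fit_binary_mixed(obs)
        rng = np.random.default_rng(0)
        shuffled = obs.sample(frac=1.0, random_state=7).reset_index(drop=True)
        fit2 = fit_binary_mixed(shuffled)
        np.testing.assert_allclose(fit1.coef.to_numpy(),
                                   fit2.coef.to_numpy(), atol=1e-6)
        assert fit1.sigma_u == pytest.approx(fit2.sigma_u, abs=1e-6)

    def test_single_level_factor_dropped(self):
        cfg = fs.SimulationConfig(
            n_species=25, n_families=4, seed=3, p_field=0.0,
            covariate_probabilities={
                "organs": {"reproductive": 0.4, "both": 0.4, "vegetative": 0.2},
                "focus": {"single": 1.0, "multiple": 0.0},
                "background": {"no_vegetation": 0.5, "non_natural": 0.1,
                               "vegetation": 0.4}})
        obs, _, _ = fs.simulate_dataset(cfg)
        fit = fit_binary_mixed(obs, min_obs=1)
        assert "focus" not in fit.factor_levels
        assert "organs" in fit.factor_levels

    def test_emm_probabilities_in_unit_interval(self, balanced_dataset):
        fit = fit_binary_mixed(balanced_dataset)
        for f in fit.factor_levels:
            emm = estimated_marginal_means(fit, f)
            for l in emm.levels:
                assert 0.0 < emm.prob[l] < 1.0
                assert emm.se[l] > 0.0

    def test_unknown_factor_rejected(self, balanced_dataset):
        fit = fit_binary_mixed(balanced_dataset)
        with pytest.raises(ValidationError):
            estimated_marginal_means(fit, "color")


class TestAgainstLme4:
    """Cross-check the Laplace fit against lme4::glmer on one dataset."""

    def test_coefficients_match(self, tmp_path, balanced_dataset):
        obs = balanced_dataset
        fit = fit_binary_mixed(obs, min_obs=3)
        counts = obs["verified_name"].value_counts()
        df = obs[obs["verified_name"].isin(counts.index[counts >= 3])].copy()
        df["y"] = (df["class_code"] == int(fs.IdentificationClass.SPECIES)
                   ).astype(int)
        csv = tmp_path / "obs.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "fit.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ organs + focus + background + (1|verified_name),
                       data=d, family=binomial)
            fe <- fixef(m)
            sdre <- sqrt(unlist(VarCorr(m))[1])
            write.csv(data.frame(name=c(names(fe), "sigma"),
                                 value=c(unname(fe), sdre)),
                      "{out}", row.names=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script],
                           capture_output=True, text=True)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(out).set_index("name")["value"]
        # same treatment coding (alphabetical reference levels) on both sides
        mapping = {
            "(Intercept)": "(Intercept)",
            "organs[reproductive]": "organsreproductive",
            "organs[vegetative]": "organsvegetative",
            "focus[single]": "focussingle",
            "background[non_natural]": "backgroundnon_natural",
            "background[vegetation]": "backgroundvegetation",
        }
        for ours, theirs in mapping.items():
            assert fit.coef[ours] == pytest.approx(ref[theirs], abs=0.05), ours
        assert fit.sigma_u == pytest.approx(ref["sigma"], abs=0.05)
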