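"""Descriptive moments, variance components (REML vs closed form), entry-mean
heritability and BLUP shrinkage."""

import numpy as np
import pandas as pd
import pytest

import dhselect as d
from dhselect import phenostats as ps
from dhselect.errors import EstimationError, InvalidArgument
from dhselect.simpop import PhenotypeBook


def _book_from_values(values, trait="DTT", env="E1"):
    rec = pd.DataFrame({
        "line": [f"L{i}" for i in range(len(values))],
        "environment": env, "replicate": 1, "trait": trait, "value": values,
    })
    return PhenotypeBook(records=rec, traits=[trait])


def _balanced_book(y, lines, envs, reps, trait="DTT"):
    idx = pd.MultiIndex.from_product(
        [lines, envs, reps], names=["line", "environment", "replicate"]
    ).to_frame(index=False)
    idx["trait"] = trait
    idx["value"] = np.asarray(y, dtype=float)
    return PhenotypeBook(records=idx, traits=[trait])


class TestDescriptiveStats:
    def test_degenerate_constant_vector(self):
        st = ps.descriptive_stats(_book_from_values([60, 60, 60]),
                                  include_combined=False)
        row = st.iloc[0]
        assert row["sd"] == 0 and row["cv_percent"] == 0
        assert row["min"] == row["max"] == 60

    def test_symmetric_vector_zero_skew(self):
        st = ps.descriptive_stats(_book_from_values([58, 60, 62]),
                                  include_combined=False)
        assert st.iloc[0]["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_moment_arithmetic(self):
        v = np.array([50, 55, 60, 65, 70], dtype=float)
        st = ps.descriptive_stats(_book_from_values(v), include_combined=False)
        row = st.iloc[0]
        # oracle: direct moment computation
        mean = v.mean()
        sd = np.sqrt(((v - mean) ** 2).sum() / (len(v) - 1))
        assert row["mean"] == pytest.approx(60.0)
        assert row["sd"] == pytest.approx(sd) and sd == pytest.approx(7.9057, abs=1e-4)
        assert row["cv_percent"] == pytest.approx(100 * sd / mean, abs=1e-9)
        assert row["cv_percent"] == pytest.approx(13.18, abs=0.01)
        m2 = ((v - mean) ** 2).mean()
        m3 = ((v - mean) ** 3).mean()
        m4 = ((v - mean) ** 4).mean()
        assert row["skewness"] == pytest.approx(m3 / m2 ** 1.5, abs=1e-12)
        assert row["kurtosis"] == pytest.approx(m4 / m2 ** 2 - 3, abs=1e-12)

    def test_missing_cell_error(self):
        book = _book_from_values([60, 61])
        with pytest.raises(Exception, match="E1"):
            ps.descriptive_stats(book, include_combined=False)


class TestHeritability:
    @pytest.mark.parametrize("comps,expected", [
        ((13.61, 9.22, 4.26), 82.75),
        ((19.84, 10.68, 4.29), 86.09),
        ((23.98, 14.12, 4.92), 85.26),
    ])
    def test_reference_components(self, comps, expected):
        h2 = ps.heritability_entry_mean(
            sigma2_g=comps[0], sigma2_ge=comps[1], sigma2_e=comps[2], E=4, R=2
        )
        assert round(100 * h2, 2) == expected

    def test_noise_free_limit(self):
        assert ps.heritability_entry_mean(
            sigma2_g=5.0, sigma2_ge=0.0, sigma2_e=0.0, E=3, R=1
        ) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(InvalidArgument):
            ps.heritability_entry_mean(sigma2_g=0, sigma2_ge=0, sigma2_e=0,
                                       E=4, R=2)

    def test_bounds_property(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = rng.uniform(0, 30, size=3)
            h2 = ps.heritability_entry_mean(
                sigma2_g=s[0], sigma2_ge=s[1], sigma2_e=s[2],
                E=int(rng.integers(1, 6)), R=int(rng.integers(1, 4)),
            )
            assert 0 <= h2 <= 1


class TestVarianceComponents:
    def test_noise_free_limit(self, small_panel):
        arch = d.flowering_architecture(small_panel, n_qtl=10, seed=1)
        arch.target_variances[:, 1:] = 0.0
        book = d.simulate_phenotypes(small_panel, arch, seed=2)
        vc = ps.fit_variance_components(book, "DTT")
        line_means = (
            book.records.query("trait == 'DTT'").groupby("line")["value"].mean()
        )
        # environment offsets inflate raw variance; genetic variance should
        # match the variance of entry means after removing env effects
        assert vc.sigma2_ge == pytest.approx(0.0, abs=1e-8)
        assert vc.sigma2_e == pytest.approx(0.0, abs=1e-8)
        assert vc.sigma2_g == pytest.approx(np.var(line_means, ddof=1), rel=1e-6)

    def test_reml_equals_anova_closed_form(self):
        """On a small balanced layout the iterative REML solution matches the
        expected-mean-squares closed form when interior."""
        rng = np.random.default_rng(3)
        lines = [f"L{i}" for i in range(5)]
        envs = ["E1", "E2"]
        reps = [1, 2]
        g = rng.normal(0, 3, 5)
        ge = rng.normal(0, 1.5, (5, 2))
        y = []
        for i in range(5):
            for j in range(2):
                for _ in range(2):
                    y.append(60 + g[i] + 2 * j + ge[i, j] + rng.normal(0, 1))
        book = _balanced_book(y, lines, envs, reps)
        anova = ps.fit_variance_components(book, "DTT", method="anova")
        reml = ps.fit_variance_components(book, "DTT", method="reml")
        if min(anova.sigma2_g, anova.sigma2_ge, anova.sigma2_e) > 0:
            assert reml.sigma2_g == pytest.approx(anova.sigma2_g, abs=1e-5)
            assert reml.sigma2_ge == pytest.approx(anova.sigma2_ge, abs=1e-5)
            assert reml.sigma2_e == pytest.approx(anova.sigma2_e, abs=1e-5)

    def test_single_environment_error(self):
        book = _book_from_values([60, 61, 62])
        with pytest.raises(EstimationError):
            ps.fit_variance_components(book, "DTT")


class TestBlups:
    def test_no_shrinkage_limit(self):
        """With σ²e → 0 and σ²ge = 0, BLUPs equal line entry means."""
        rng = np.random.default_rng(4)
        lines = [f"L{i}" for i in range(6)]
        g = rng.normal(0, 4, 6)
        y = [60 + g[i] + off for i in range(6) for off in (0.0, 1.0)]
        book = _balanced_book(y, lines, ["E1", "E2"], [1])
        vc = ps.VarianceComponents("DTT", np.var(g, ddof=1), 0.0, 1e-10, 2, 1)
        blups = ps.compute_blups(book, vc)
        entry = book.records.groupby("line")["value"].mean()
        assert np.allclose(blups["DTT"].to_numpy(),
                           entry.reindex(blups.index).to_numpy(), atol=1e-4)

    def test_closed_form_shrinkage_and_dense_mme_oracle(self):
        """Balanced 3 lines × 2 env × 1 rep: BLUPs equal the ridge shrinkage
        of entry means with λ_line = (σ²ge/E + σ²e/E)/σ²g, and the full dense
        mixed-model-equation solve."""
        lines = ["L0", "L1", "L2"]
        y = np.array([58.0, 60.0, 61.0, 64.0, 59.0, 66.0])  # L0E1,L0E2,...
        rec = pd.DataFrame({
            "line": ["L0", "L0", "L1", "L1", "L2", "L2"],
            "environment": ["E1", "E2"] * 3,
            "replicate": 1, "trait": "DTT", "value": y,
        })
        book = PhenotypeBook(records=rec, traits=["DTT"])
        s2g, s2ge, s2e, E = 4.0, 1.0, 0.5, 2
        vc = ps.VarianceComponents("DTT", s2g, s2ge, s2e, E, 1)
        blups = ps.compute_blups(book, vc)["DTT"]
        # oracle 1: closed-form ridge shrinkage of entry means
        entry = rec.groupby("line")["value"].mean()
        lam = (s2ge / E + s2e / E) / s2g
        shrink = 1.0 / (1.0 + lam)
        mu = entry.mean()
        expected = mu + shrink * (entry - mu)
        assert np.allclose(blups.to_numpy(), expected.to_numpy(), atol=1e-8)
        # oracle 2: dense Henderson system assembled independently
        X = np.array([[1, 0], [1, 1]] * 3, dtype=float)
        Zg = np.kron(np.eye(3), np.ones((2, 1)))
        Zge = np.eye(6)
        lam_g, lam_ge = s2e / s2g, s2e / s2ge
        W = np.hstack([X, Zg, Zge])
        C = W.T @ W
        C[2:5, 2:5] += lam_g * np.eye(3)
        C[5:, 5:] += lam_ge * np.eye(6)
        sol = np.linalg.solve(C, W.T @ y)
        mu_hat = sol[0] + sol[1] / 2
        oracle = mu_hat + sol[2:5]
        assert np.allclose(blups.to_numpy(), oracle, atol=1e-8)

    def test_shrinkage_inequality_and_truth_recovery(self, mid_panel):
        """BLUP variance never exceeds entry-mean variance; BLUPs track true
        genetic values on a 300-line simulated trial."""
        arch = d.flowering_architecture(mid_panel, n_qtl=30, seed=5)
        book = d.simulate_phenotypes(mid_panel, arch, seed=6)
        vcs = {t: ps.fit_variance_components(book, t) for t in book.traits}
        blups = ps.compute_blups(book, vcs)
        for trait in book.traits:
            entry = (
                book.records.query("trait == @trait")
                .groupby("line")["value"].mean()
                .reindex(blups.index)
            )
            assert blups[trait].var() <= entry.var() + 1e-9
            r = np.corrcoef(blups[trait], book.true_values[trait])[0, 1]
            assert r >= 0.85


class TestTraitCorrelations:
    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        blups = pd.DataFrame({"A": x, "B": -x, "C": rng.normal(size=30)})
        r, p, codes = ps.trait_correlations(blups)
        assert np.allclose(np.diag(r), 1.0)
        assert r.loc["A", "B"] == pytest.approx(-1.0)
        assert np.allclose(r.values, r.values.T)

    def test_zero_variance_error(self):
        blups = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(EstimationError):
            ps.trait_correlations(blups)

    def test_emulated_flowering_band(self, reference_trial):
        """Traits sharing QTLs at genetic correlation ≈ 0.95 yield BLUP
        correlations inside the published 0.88–0.99 band."""
        r, p, codes = ps.trait_correlations(reference_trial["blups"])
        assert 0.88 <= r.loc["DTP", "DTS"] <= 0.99
        assert r.loc["DTT", "DTS"] >= 0.8
        assert codes.loc["DTP", "DTS"] == "***"
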