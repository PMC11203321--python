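"""Association-scan contracts: Bonferroni arithmetic, OLS oracle equivalence,
pseudo-QTN behaviour, PVE accounting and overlap summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dhselect as d
from dhselect import datasets, mlgwas
from dhselect.errors import InvalidArgument
from dhselect.genoqc import GenotypeMatrix


def _toy_geno(dosage, chrom=None, pos=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        line_ids=[f"L{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(m)],
        chrom=chrom if chrom is not None else ["1"] * m,
        pos=pos if pos is not None else (np.arange(m) + 1) * 1000,
        dosage=dosage,
    )


def _series(y, geno):
    return pd.Series(np.asarray(y, dtype=float), index=geno.line_ids)


class TestBonferroni:
    def test_reference_marker_count(self):
        p, nl = mlgwas.bonferroni_threshold(134_785, 0.05)
        assert float(f"{p:.2e}") == pytest.approx(3.71e-7)
        assert round(nl, 1) == 6.4

    def test_single_test_identity(self):
        p, nl = mlgwas.bonferroni_threshold(1, 0.05)
        assert p == 0.05

    def test_invalid(self):
        with pytest.raises(InvalidArgument):
            mlgwas.bonferroni_threshold(0)


class TestSingleMarkerScan:
    def test_normal_equations_oracle(self):
        """p-values match a hand-rolled normal-equations OLS to 1e-10 on a
        20-line, 5-marker toy with two covariates."""
        rng = np.random.default_rng(1)
        n, m = 20, 5
        M = np.array(2.0 * rng.integers(0, 2, size=(n, m)), dtype=float)
        C = rng.normal(size=(n, 2))
        y = 0.8 * M[:, 2] + C @ [0.5, -0.3] + rng.normal(size=n)
        geno = _toy_geno(M)
        res = d.single_marker_scan(geno, _series(y, geno), C)
        for j in range(m):
            X = np.column_stack([np.ones(n), C, M[:, j]])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            df = n - X.shape[1]
            s2 = (r @ r) / df
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[-1, -1])
            t = beta[-1] / se
            p = 2 * stats.t.sf(abs(t), df)
            assert res.table["p_value"].iloc[j] == pytest.approx(p, abs=1e-10)
            assert res.table["effect"].iloc[j] == pytest.approx(beta[-1], abs=1e-10)

    def test_collinear_marker_degenerate(self):
        rng = np.random.default_rng(2)
        C = rng.normal(size=(15, 1))
        M = np.column_stack([C[:, 0], rng.normal(size=15)])
        geno = _toy_geno(M)
        y = rng.normal(size=15)
        res = d.single_marker_scan(geno, _series(y, geno), C)
        assert res.table["degenerate"].iloc[0]
        assert res.table["p_value"].iloc[0] == 1.0

    def test_null_p_values_uniform(self):
        """A phenotype independent of all markers gives uniform p-values:
        the KS test against U(0,1) is non-significant at 0.01 in at least 18
        of 20 seeds (markers drawn without LD so the KS null applies)."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            M = np.array(
                2.0 * (rng.random((300, 500)) < rng.uniform(0.1, 0.9, 500)),
                dtype=float,
            )
            geno = _toy_geno(M)
            y = rng.normal(size=300)
            res = d.single_marker_scan(geno, _series(y, geno))
            ks = stats.kstest(res.table["p_value"], "uniform")
            ok += ks.pvalue > 0.01
        assert ok >= 18


class TestMultiLocusScans:
    def test_planted_qtls_reported_as_distinct_pseudo_qtns(self, mid_panel):
        """Two planted QTLs in different positional bins are both detected
        and kept as separate pseudo-QTNs."""
        geno = mid_panel.genotypes
        rng = np.random.default_rng(3)
        q1, q2 = 150, 1500  # different chromosomes
        g = geno.dosage[:, q1] * 1.0 + geno.dosage[:, q2] * 0.8
        g = (g - g.mean()) / g.std()
        y = 2.0 * g + rng.normal(size=geno.n_lines)
        res = d.farmcpu_like_scan(geno, _series(y, geno))
        sig = res.significant_table()
        assert geno.marker_ids[q1] in res.pseudo_qtns or geno.marker_ids[q1] in set(sig["marker"])
        assert geno.marker_ids[q2] in res.pseudo_qtns or geno.marker_ids[q2] in set(sig["marker"])
        assert len(res.pseudo_qtns) >= 2
        assert res.converged

    def test_blink_ld_pruning_contract(self):
        """Two markers in perfect LD, one causal: exactly one of the pair is
        kept as a pseudo-QTN."""
        rng = np.random.default_rng(4)
        n = 100
        base = np.array(2.0 * rng.integers(0, 2, size=n), dtype=float)
        noise = np.array(2.0 * rng.integers(0, 2, size=(n, 30)), dtype=float)
        M = np.column_stack([base, base, noise])
        geno = _toy_geno(M)
        y = 1.5 * base + rng.normal(size=n)
        res = d.blink_like_scan(geno, _series(y, geno))
        pair = {"M0", "M1"}
        assert len(pair & set(res.pseudo_qtns)) == 1

    def test_determinism(self, mid_panel):
        geno = mid_panel.genotypes
        rng = np.random.default_rng(5)
        y = geno.dosage[:, 100] + rng.normal(size=geno.n_lines)
        a = d.farmcpu_like_scan(geno, _series(y, geno))
        b = d.farmcpu_like_scan(geno, _series(y, geno))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_significance_flag_matches_threshold(self, mid_panel):
        geno = mid_panel.genotypes
        rng = np.random.default_rng(6)
        y = 1.2 * geno.dosage[:, 40] + rng.normal(size=geno.n_lines)
        for scan in (d.farmcpu_like_scan, d.blink_like_scan):
            res = scan(geno, _series(y, geno))
            t = res.table
            np.testing.assert_array_equal(
                t["significant"].to_numpy(), (t["p_value"] < res.p_threshold).to_numpy()
            )


class TestSnpPve:
    def test_nested_rss_oracle(self):
        """Partial-R² PVE equals 1 − RSS_full/RSS_reduced computed by a
        brute-force regression oracle on a 30-line toy."""
        rng = np.random.default_rng(7)
        n = 30
        M = np.array(2.0 * rng.integers(0, 2, size=(n, 6)), dtype=float)
        y = 1.4 * M[:, 1] - 1.1 * M[:, 4] + 0.4 * rng.normal(size=n)
        geno = _toy_geno(M)
        cfg = mlgwas.GwasConfig(model="single_marker", alpha=0.5)
        res = d.single_marker_scan(geno, _series(y, geno), None, cfg)
        res = d.snp_pve(geno, _series(y, geno), res)
        sig = np.flatnonzero(res.table["significant"])
        assert len(sig) >= 2

        def rss(cols):
            X = np.column_stack([np.ones(n)] + [M[:, c] for c in cols])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return r @ r

        for j in sig:
            others = [k for k in sig if k != j]
            expected = 1 - rss(list(sig)) / rss(others)
            assert res.table["pve"].iloc[j] == pytest.approx(expected, abs=1e-10)

    def test_saturation_and_orthogonal_limits(self):
        rng = np.random.default_rng(8)
        n = 200
        M = np.array(2.0 * rng.integers(0, 2, size=(n, 3)), dtype=float)
        y = M[:, 0] + 1e-4 * rng.normal(size=n)
        geno = _toy_geno(M)
        cfg = mlgwas.GwasConfig(model="single_marker", alpha=0.05)
        res = d.snp_pve(geno, _series(y, geno),
                        d.single_marker_scan(geno, _series(y, geno), None, cfg))
        t = res.table
        assert t.loc[t["marker"] == "M0", "pve"].iloc[0] > 0.99
        assert (t["pve"].dropna() <= 1).all() and (t["pve"].dropna() >= 0).all()


class TestOverlapSummary:
    def test_reference_table_counts_and_pve_totals(self):
        sig = datasets.reference_significant_snps()
        summ = mlgwas.overlap_summary([sig])
        assert summ.unique_per_model["farmcpu_like"] == 10
        assert summ.unique_per_model["blink_like"] == 7
        tot = summ.total_pve.set_index(["model", "trait"])["total_pve"]
        assert round(100 * tot["blink_like", "DTT"], 2) == 20.30
        assert round(100 * tot["farmcpu_like", "DTT"], 2) == 23.42
        assert round(100 * tot["farmcpu_like", "DTP"], 2) == 15.99
        assert round(100 * tot["farmcpu_like", "DTS"], 2) == 21.29
        # the major pleiotropic SNP is detected for all three traits
        plei = summ.pleiotropic.set_index("snp")["traits"]
        assert plei["9_152140631"] == ["DTP", "DTS", "DTT"]

    def test_empty_input(self):
        summ = mlgwas.overlap_summary([pd.DataFrame()])
        assert summ.unique_per_model == {}
        assert summ.total_pve.empty


class TestReportTables:
    def test_manhattan_and_qq_shapes(self, small_panel):
        geno = small_panel.genotypes
        rng = np.random.default_rng(9)
        y = rng.normal(size=geno.n_lines)
        res = d.single_marker_scan(geno, _series(y, geno))
        man = mlgwas.manhattan_table(res)
        qq = mlgwas.qq_table(res)
        assert len(man) == len(qq) == geno.n_markers
        assert np.all(np.diff(qq["observed_neg_log10_p"]) <= 1e-12)

    def test_bin_label(self):
        assert mlgwas.bin_label("9", 152_140_631, {"9": 160_000_000}) == "9.09"
        assert mlgwas.bin_label("1", 1, {"1": 300_000_000}) == "1.00"
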