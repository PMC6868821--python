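"""Tests for tissue-specificity and enrichment controls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from circacost import (SimulationConfig, cyclic_tissue_number, detect_rhythms,
                       enrichment_amplitude_relation, generate_expression,
                       generate_genesets, generate_organ_panel,
                       group_amplitude_contrast, hypergeometric_enrichment,
                       partial_correlation, tissue_controlled_coupling)


def _rhythm_frame(ids, cycling, amplitude=None, expression=None):
    n = len(ids)
    return pd.DataFrame({
        "transcript_id": ids,
        "is_cycling": cycling,
        "amplitude": amplitude if amplitude is not None else np.ones(n),
        "mean_expression": expression if expression is not None else np.ones(n),
    })


class TestCyclicTissueNumber:
    def test_counts_match_planted_membership(self):
        """Oracle: the generator's organ-membership table."""
        cfg = SimulationConfig(n_genes=150, n_organs=8, seed=21)
        _, truth = generate_organ_panel(cfg)
        member = truth.organ_membership
        organ_rhythms = {
            organ: _rhythm_frame(member.index.tolist(),
                                 member[organ].to_numpy())
            for organ in member.columns
        }
        counts = cyclic_tissue_number(organ_rhythms)
        expected = member.sum(axis=1)
        assert counts.sort_index().equals(expected.sort_index().rename(counts.name))
        rhythmic = truth.genes.set_index("gene_id")["is_rhythmic"]
        assert (counts[rhythmic] >= 1).all()
        assert (counts[~rhythmic] == 0).all()

    def test_extremes(self):
        ids = ["a", "b"]
        organ_rhythms = {f"o{k}": _rhythm_frame(ids, [True, False])
                         for k in range(12)}
        counts = cyclic_tissue_number(organ_rhythms)
        assert counts["a"] == 12 and counts["b"] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cyclic_tissue_number({})


class TestPartialCorrelation:
    def test_uncorrelated_control_reduces_to_raw(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # unrelated control
        raw = np.corrcoef(x, y)[0, 1]
        assert partial_correlation(x, y, z) == pytest.approx(raw, abs=0.02)

    def test_formula_evaluation_one_third(self):
        """All three pairwise correlations 0.5 -> partial r = 1/3."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 3))
        Z = X - X.mean(axis=0)
        L = np.linalg.cholesky(np.linalg.inv(np.cov(Z.T)))
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        W = (Z @ L) @ np.linalg.cholesky(R).T  # sample correlations exactly 0.5
        assert partial_correlation(W[:, 0], W[:, 1], W[:, 2]) == pytest.approx(1 / 3)

    def test_identical_variables(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        assert partial_correlation(x, x, z) == pytest.approx(1.0)

    def test_residual_correlation_oracle(self):
        """r_xy.z equals the correlation of OLS residuals of x~z and y~z."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 60
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = -0.7 * z + 0.3 * x + rng.normal(size=n)
            rx = x - np.polyval(np.polyfit(z, x, 1), z)
            ry = y - np.polyval(np.polyfit(z, y, 1), z)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert partial_correlation(x, y, z) == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("xyz"))
        ours = partial_correlation(df["x"], df["y"], df["z"])
        theirs = pingouin.partial_corr(df, x="x", y="y", covar="z")["r"].iloc[0]
        assert ours == pytest.approx(float(theirs), abs=1e-10)

    def test_collinear_control_rejected(self):
        x = np.arange(10.0)
        y = np.random.default_rng(5).normal(size=10)
        with pytest.raises(ValueError):
            partial_correlation(x, y, 2 * x + 1)


class TestHypergeometricEnrichment:
    def test_fold_and_exact_tail(self):
        background = [f"g{i}" for i in range(100)]
        cycling = background[:20]
        term = background[:5] + background[50:55]  # K=10, k=5
        rec = hypergeometric_enrichment(cycling, background, {"t": term})
        row = rec.iloc[0]
        assert row["fold_enrichment"] == pytest.approx(2.5)
        # oracle: explicit hypergeometric tail summation
        from math import comb
        N, K, n = 100, 10, 20
        p_exact = sum(comb(K, k) * comb(N - K, n - k) for k in range(5, 11)) / comb(N, n)
        assert row["p"] == pytest.approx(p_exact, abs=1e-12)

    def test_no_enrichment_fold_one(self):
        background = [f"g{i}" for i in range(50)]
        cycling = background[:10]  # n/N = 0.2
        term = background[:2] + background[10:18]  # K=10, k=2 = n*K/N
        rec = hypergeometric_enrichment(cycling, background, {"t": term})
        assert rec.iloc[0]["fold_enrichment"] == pytest.approx(1.0)

    def test_term_equals_background(self):
        background = [f"g{i}" for i in range(30)]
        rec = hypergeometric_enrichment(background[:6], background,
                                        {"all": background})
        assert rec.iloc[0]["fold_enrichment"] == pytest.approx(1.0)
        assert rec.iloc[0]["p"] == pytest.approx(1.0)

    def test_random_terms_match_explicit_sum(self):
        from math import comb
        rng = np.random.default_rng(6)
        background = [f"g{i}" for i in range(60)]
        cycling = list(rng.choice(background, size=25, replace=False))
        sets = {f"t{k}": list(rng.choice(background, size=rng.integers(3, 30),
                                         replace=False)) for k in range(20)}
        rec = hypergeometric_enrichment(cycling, background, sets).set_index("term_id")
        N, n = 60, 25
        for term, members in sets.items():
            K = len(set(members))
            k = len(set(members) & set(cycling))
            p_exact = sum(comb(K, i) * comb(N - K, n - i)
                          for i in range(k, min(K, n) + 1)) / comb(N, n)
            assert rec.loc[term, "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_cycling_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["x"], ["a", "b"], {})


class TestEnrichmentAmplitudeRelation:
    def _enrichment(self, seed):
        """Collection mixing unbiased and strongly expression-biased sets,
        so terms differ in their members' expression (the confounder)."""
        cfg = SimulationConfig(n_genes=1500, seed=seed)
        matrix, truth = generate_expression(cfg)
        rhythms = detect_rhythms(matrix)
        sets = {}
        for bias, tag in ((0.0, "u"), (3.0, "b")):
            s = generate_genesets(truth, n_sets=40, size_range=(20, 80),
                                  expression_bias=bias,
                                  seed=1000 * seed + int(bias * 10))
            sets.update({f"{tag}_{k}": v for k, v in s.items()})
        return hypergeometric_enrichment(
            rhythms.loc[rhythms["is_cycling"], "transcript_id"],
            rhythms["transcript_id"], sets, rhythms=rhythms)

    def test_underpowered_with_two_terms(self):
        rec = pd.DataFrame({"term_id": ["a", "b"], "fold_enrichment": [2.0, 1.5],
                            "adj_p": [0.01, 0.02], "mean_amplitude": [1.0, 2.0],
                            "mean_expression": [3.0, 4.0]})
        rep = enrichment_amplitude_relation(rec)
        assert rep["underpowered"] and "r" not in rep

    def test_independent_terms_near_zero_r(self):
        rng = np.random.default_rng(7)
        n = 500
        rec = pd.DataFrame({
            "term_id": [f"t{i}" for i in range(n)],
            "fold_enrichment": rng.lognormal(0.5, 0.3, n),
            "adj_p": np.full(n, 0.001),
            "mean_amplitude": rng.normal(size=n),
            "mean_expression": rng.normal(size=n),
        })
        rep = enrichment_amplitude_relation(rec)
        assert abs(rep["r"]) < 3 / np.sqrt(n)

    def test_expression_control_shrinks_confounded_r(self):
        """With expression-biased gene sets on coupled data the raw
        fold-enrichment/amplitude correlation exceeds the partial one."""
        wins = 0
        total = 0
        for seed in range(20):
            rec = self._enrichment(40 + seed)
            rep = enrichment_amplitude_relation(rec, control="expression")
            if rep["underpowered"]:
                continue
            total += 1
            wins += rep["r"] > rep["partial_r"]
        assert total >= 15
        assert wins > total / 2


class TestGroupContrast:
    def test_identical_groups(self):
        rng = np.random.default_rng(8)
        ids = [f"g{i}" for i in range(50)]
        rec = _rhythm_frame(ids, np.ones(50, bool), rng.lognormal(0, 1, 50))
        out = group_amplitude_contrast(ids, ids, rec)
        assert out["mean_log_amplitude_diff"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        ids = [f"g{i}" for i in range(400)]
        amp = rng.lognormal(0, 0.3, 400)
        amp[:200] *= 2.0
        rec = _rhythm_frame(ids, np.ones(400, bool), amp)
        out = group_amplitude_contrast(ids[:200], ids[200:], rec)
        assert out["mean_log_amplitude_diff"] > 0.5
        assert out["p"] < 0.01

    def test_null_calibration(self):
        """Disjoint groups from the same distribution reject at ~alpha."""
        rng = np.random.default_rng(10)
        rejections = 0
        trials = 200
        ids = [f"g{i}" for i in range(120)]
        for _ in range(trials):
            rec = _rhythm_frame(ids, np.ones(120, bool),
                                rng.lognormal(0, 0.5, 120))
            out = group_amplitude_contrast(ids[:60], ids[60:], rec)
            rejections += out["p"] < 0.05
        se = np.sqrt(0.05 * 0.95 / trials)
        assert rejections / trials <= 0.05 + 3 * se

    def test_insufficient_overlap_rejected(self):
        rec = _rhythm_frame(["a", "b", "c"], [True, True, False])
        with pytest.raises(ValueError):
            group_amplitude_contrast(["a"], ["c"], rec)


class TestTissueControlledCoupling:
    def test_control_changes_little(self):
        """Expression-amplitude coupling survives controlling for the number
        of organs a gene cycles in (tissue sharing is not the driver)."""
        cfg = SimulationConfig(n_genes=2000, n_organs=6, seed=31)
        mats, truth = generate_organ_panel(cfg)
        organ_rhythms = {o: detect_rhythms(m) for o, m in mats.items()}
        rep = tissue_controlled_coupling(organ_rhythms)
        assert len(rep) == 6
        assert (rep["raw_r"] > 0.5).all()
        assert (np.abs(rep["raw_r"] - rep["partial_r_tissue_number"]) < 0.1).all()
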