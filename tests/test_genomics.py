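"""Case definition, association scan, wGMV, condFDR/conjFDR, clumping, PGS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lifetraj.genomics import (
    assoc_scan,
    clump_loci,
    compute_wgmv,
    cond_fdr,
    conj_fdr,
    define_cases,
    ld_prune,
    prs_correlation,
)
from lifetraj.synth import generate_genotypes, simulate_phenotype


def brute_force_cond_fdr(p1, p2, monotone=True):
    """O(n^2) double-loop evaluation of the conditional-FDR definition."""
    n = len(p1)
    raw = np.empty(n)
    for i in range(n):
        denom = np.sum(p2 <= p2[i])
        count = np.sum((p1 <= p1[i]) & (p2 <= p2[i]))
        raw[i] = min(1.0, p1[i] * denom / count)
    if not monotone:
        return raw
    out = np.empty(n)
    for i in range(n):
        out[i] = raw[(p1 <= p1[i]) & (p2 >= p2[i])].max()
    return out


class TestDefineCases:
    def test_majority_tie_and_single_visit(self):
        flags = pd.Series(
            [1, 1, 0, 1, 0, 1],
            index=pd.Index(["a", "a", "a", "b", "b", "c"], name="participant_id"),
        )
        lab = define_cases(flags)
        assert lab["a"] and not lab["b"] and lab["c"]  # 2/3 case; 1/2 control

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            define_cases(pd.Series(dtype=float))


class TestAssocScan:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        G, _ = generate_genotypes(1000, 10_000, seed=0)
        res = assoc_scan(G, rng.standard_normal(1000))
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)

    def test_planted_effect_in_top_percent(self):
        G, _ = generate_genotypes(2000, 1000, seed=1)
        beta = np.zeros(1000)
        beta[500] = 1.0
        y = simulate_phenotype(G, beta, h2=0.05, seed=1)
        res = assoc_scan(G, y)
        assert (res["p"] < res["p"][500]).mean() < 0.01

    def test_allele_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        G, _ = generate_genotypes(500, 50, seed=2)
        y = rng.standard_normal(500)
        z1 = assoc_scan(G, y)["z"]
        z2 = assoc_scan(2 - G, y)["z"]
        assert np.allclose(z1, -z2)

    def test_monomorphic_skipped_and_missing_imputed(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, size=(300, 5)).astype(float)
        G[:, 0] = 1.0
        G[::7, 2] = np.nan
        with pytest.warns(UserWarning):
            res = assoc_scan(G, rng.standard_normal(300))
        assert np.isnan(res["z"][0]) and np.isfinite(res["z"][2])

    def test_binary_trait_calibrated(self):
        rng = np.random.default_rng(4)
        G, _ = generate_genotypes(800, 2000, seed=4)
        y = rng.integers(0, 2, 800).astype(float)
        res = assoc_scan(G, y, trait="binary")
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.015)


class TestWgmv:
    def test_zero_weights_give_zero_scores(self, rng):
        cent = pd.DataFrame(rng.random((50, 3)), columns=["a", "b", "c"])
        w = pd.Series(0.0, index=["a", "b", "c"])
        assert (compute_wgmv(cent, w).scores == 0).all()

    def test_linearity_and_missing_roi(self, rng):
        cent = pd.DataFrame({"a": [0.75]})
        assert compute_wgmv(cent, pd.Series({"a": 2.0})).scores.iloc[0] == 1.5
        with pytest.raises(ValueError):
            compute_wgmv(cent, pd.Series({"zzz": 1.0}))

    def test_invariant_under_matched_permutation(self, rng):
        cent = pd.DataFrame(rng.random((20, 4)), columns=list("abcd"))
        w = pd.Series(rng.standard_normal(4), index=list("abcd"))
        s1 = compute_wgmv(cent, w).scores
        perm = ["c", "a", "d", "b"]
        s2 = compute_wgmv(cent[perm], w[perm]).scores
        assert np.allclose(s1, s2)


class TestCondFdr:
    def test_matches_brute_force_oracle_with_ties(self, rng):
        p1 = rng.random(300)
        p2 = rng.random(300)
        p1[10] = p1[20]
        p2[30] = p2[40]
        for mono in (True, False):
            assert np.array_equal(
                cond_fdr(p1, p2, monotone=mono), brute_force_cond_fdr(p1, p2, mono)
            )

    def test_hand_computed_conditional_cdf(self):
        """p1 = (0.01, 0.2, 0.5, 0.9) with every p2 = 1e-9: all 4 SNPs
        qualify for SNP 1's stratum, so condFDR_1 = 0.01 * 4 / 1 = 0.04."""
        p1 = np.concatenate([[0.01, 0.2, 0.5, 0.9], np.linspace(0.95, 0.999, 96)])
        p2 = np.concatenate([np.full(4, 1e-9), np.full(96, 1.0)])
        out = cond_fdr(p1, p2, monotone=False)
        assert out[0] == pytest.approx(0.04)

    def test_bounds_hold(self, rng):
        p1, p2 = rng.random(500), rng.random(500)
        c = cond_fdr(p1, p2)
        assert np.all(c <= 1.0) and np.all(c >= p1)

    def test_null_median_near_one(self, rng):
        p1, p2 = rng.random(20_000), rng.random(20_000)
        assert np.median(cond_fdr(p1, p2)) > 0.9

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            cond_fdr(rng.random(50), rng.random(50))
        with pytest.raises(ValueError):
            cond_fdr(np.zeros(200), rng.random(200))


class TestConjFdr:
    def test_symmetric_inputs_collapse(self, rng):
        p = rng.random(300)
        tab = pd.DataFrame(dict(P1=p, P2=p))
        out = conj_fdr(tab)
        assert np.allclose(out["conjFDR"], out["condFDR_1_2"])

    def test_small_table_equals_brute_force(self, rng):
        p1, p2 = rng.random(120), rng.random(120)
        out = conj_fdr(pd.DataFrame(dict(P1=p1, P2=p2)))
        assert np.array_equal(out["condFDR_1_2"], brute_force_cond_fdr(p1, p2))
        assert np.array_equal(out["condFDR_2_1"], brute_force_cond_fdr(p2, p1))
        assert np.array_equal(
            out["conjFDR"], np.maximum(out["condFDR_1_2"], out["condFDR_2_1"])
        )

    def test_alpha_monotone_significant_set(self, rng):
        p1, p2 = rng.random(500) ** 2, rng.random(500) ** 2
        tab = pd.DataFrame(dict(P1=p1, P2=p2))
        s_small = set(conj_fdr(tab, alpha=0.01).query("significant").index)
        s_big = set(conj_fdr(tab, alpha=0.10).query("significant").index)
        assert s_small <= s_big


class TestClump:
    def _tab(self, chrs, poss, fdrs):
        return pd.DataFrame(dict(SNP=[f"s{i}" for i in range(len(chrs))],
                                 CHR=chrs, POS=poss, conjFDR=fdrs))

    def test_nearby_merge_and_cross_chromosome_split(self):
        out = clump_loci(self._tab([1, 1], [100_000, 110_000], [0.01, 0.02]))
        assert out["locus"].nunique() == 1
        out2 = clump_loci(self._tab([1, 2], [100_000, 100_000], [0.01, 0.02]))
        assert out2["locus"].nunique() == 2

    def test_greedy_chain_behavior(self):
        """A-B-C each 200 kb apart (window 250 kb): B joins A, C seeds new."""
        out = clump_loci(
            self._tab([1, 1, 1], [1_000_000, 1_200_000, 1_400_000], [0.001, 0.01, 0.02])
        )
        assert out.loc[0, "locus"] == out.loc[1, "locus"]
        assert out.loc[2, "locus"] != out.loc[0, "locus"]
        assert out["is_index"].sum() == 2


class TestPrune:
    def test_uncorrelated_snps_all_kept(self, rng):
        G = rng.integers(0, 3, size=(500, 20)).astype(float)
        meta = pd.DataFrame(dict(SNP=[f"s{i}" for i in range(20)], CHR=1,
                                 POS=np.arange(20) * 10_000))
        keep = ld_prune(G, meta, rng.random(20))
        assert keep.all()

    def test_correlated_pair_drops_larger_p(self, rng):
        g = rng.integers(0, 3, size=500).astype(float)
        G = np.column_stack([g, g, rng.integers(0, 3, size=500)])
        meta = pd.DataFrame(dict(SNP=["a", "b", "c"], CHR=1, POS=[1000, 2000, 3000]))
        keep = ld_prune(G, meta, np.array([0.5, 0.001, 0.9]))
        assert list(keep) == [False, True, True]

    def test_planted_signal_pgs_correlates(self):
        G, meta = generate_genotypes(2000, 400, seed=6)
        rng = np.random.default_rng(6)
        beta = np.where(rng.random(400) < 0.1, rng.normal(0, 0.3, 400), 0.0)
        y = simulate_phenotype(G, beta, h2=0.2, seed=6)
        train = pd.DataFrame(dict(SNP=meta["SNP"], BETA=beta, P=rng.random(400)))
        pgs, r, p, keep = prs_correlation(train, G, meta, y)
        assert r > 0 and p < 0.01
        assert keep.sum() >= 1


@given(st.integers(0, 2**31 - 1))
def test_conjfdr_exceeds_both_conditionals(seed):
    rng = np.random.default_rng(seed)
    p1, p2 = rng.random(150), rng.random(150)
    out = conj_fdr(pd.DataFrame(dict(P1=p1, P2=p2)))
    assert (out["conjFDR"] >= out["condFDR_1_2"] - 1e-15).all()
    assert (out["conjFDR"] >= out["condFDR_2_1"] - 1e-15).all()
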