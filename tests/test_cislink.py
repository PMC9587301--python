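"""Cis linkage, Spearman correlation, permutation FDR, pair classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methlink as ml


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "tss"])


def _probes(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


class TestLinking:
    def test_window_boundary_is_closed(self):
        genes = _genes([("g", "chr1", 100_000, 110_000, "+", 100_000)])
        probes = _probes([("p_in", "chr1", 95_000), ("p_out", "chr1", 94_999)])
        pairs = ml.link_dmps_to_genes(probes, genes, window=5_000)
        assert pairs["probe_id"].tolist() == ["p_in"]
        assert pairs.loc[0, "distance"] == -5_000

    def test_minus_strand_distance_sign(self):
        genes = _genes([("g", "chr1", 50_000, 60_000, "-", 60_000)])
        probes = _probes([("p", "chr1", 58_000)])
        pairs = ml.link_dmps_to_genes(probes, genes, window=5_000)
        assert pairs.loc[0, "distance"] == 2_000  # downstream of transcription

    def test_probe_within_two_windows_yields_two_pairs(self):
        genes = _genes([("g1", "chr1", 100_000, 101_000, "+", 100_000),
                        ("g2", "chr1", 104_000, 105_000, "+", 104_000)])
        probes = _probes([("p", "chr1", 102_000)])
        pairs = ml.link_dmps_to_genes(probes, genes, window=5_000)
        assert sorted(pairs["gene_id"]) == ["g1", "g2"]

    def test_chr_prefix_normalized(self):
        genes = _genes([("g", "1", 100_000, 110_000, "+", 100_000)])
        probes = _probes([("p", "chr1", 99_000)])
        pairs = ml.link_dmps_to_genes(probes, genes, window=5_000)
        assert len(pairs) == 1

    def test_disjoint_chromosomes_raise(self):
        genes = _genes([("g", "chr2", 100_000, 110_000, "+", 100_000)])
        probes = _probes([("p", "chr1", 99_000)])
        with pytest.raises(ValueError, match="no shared chromosome"):
            ml.link_dmps_to_genes(probes, genes, window=5_000)


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert ml.spearman_rho([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert ml.spearman_rho([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tied_example_equals_rank_then_pearson(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rho, _ = ml.spearman_rho(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-14)

    def test_matches_brute_force_on_random_vectors_with_ties(self):
        """200 random pairs, n in 3..10, with ties: rho equals the
        rank-then-Pearson oracle to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 5, n).astype(float)   # ties likely
            y = rng.normal(size=n)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            if rx.std() == 0 or ry.std() == 0:
                with pytest.raises(ValueError):
                    ml.spearman_rho(x, y)
                continue
            rho, p = ml.spearman_rho(x, y)
            assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.1, 5, 12)
        y = rng.uniform(0.1, 5, 12)
        base = ml.spearman_rho(x, y)[0]
        assert ml.spearman_rho(np.exp(x), y)[0] == pytest.approx(base, abs=1e-12)
        assert ml.spearman_rho(x, np.log(y))[0] == pytest.approx(base, abs=1e-12)

    def test_zero_rank_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            ml.spearman_rho([1, 1, 1], [1, 2, 3])


def _matrices(n_genes=3, n_samples=4, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{j}" for j in range(n_samples)]
    expr = pd.DataFrame(rng.uniform(10, 100, (n_genes, n_samples)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=samples)
    meth = pd.DataFrame(rng.uniform(0.05, 0.95, (n_genes, n_samples)),
                        index=[f"p{i}" for i in range(n_genes)],
                        columns=samples)
    pairs = pd.DataFrame({"gene_id": expr.index, "probe_id": meth.index,
                          "distance": 0})
    return expr, meth, pairs


class TestCorrelatePairs:
    def test_rho_matches_spearman_per_pair(self):
        expr, meth, pairs = _matrices(seed=1)
        out = ml.correlate_pairs(expr, meth, pairs)
        for r in out.itertuples(index=False):
            expected = ml.spearman_rho(expr.loc[r.gene_id],
                                       meth.loc[r.probe_id])[0]
            assert r.rho == pytest.approx(expected, abs=1e-12)

    def test_joint_sample_permutation_leaves_rho_unchanged(self):
        expr, meth, pairs = _matrices(n_samples=8, seed=2)
        out1 = ml.correlate_pairs(expr, meth, pairs)
        perm = ["s3", "s1", "s7", "s0", "s2", "s6", "s4", "s5"]
        out2 = ml.correlate_pairs(expr[perm], meth[perm], pairs)
        assert np.allclose(out1["rho"], out2["rho"])

    def test_constant_probe_dropped_with_warning(self):
        expr, meth, pairs = _matrices(seed=3)
        meth.loc["p1"] = 0.5
        with pytest.warns(UserWarning, match="zero rank variance"):
            out = ml.correlate_pairs(expr, meth, pairs)
        assert "p1" not in set(out["probe_id"])

    def test_sample_mismatch_raises(self):
        expr, meth, pairs = _matrices()
        with pytest.raises(ValueError, match="sample sets"):
            ml.correlate_pairs(expr, meth.iloc[:, ::-1], pairs)


def brute_force_permutation_fdr(expr, meth, pairs):
    """Independent oracle: enumerate all n! shared column permutations
    with scipy's Spearman, then apply the plug-in FDR estimator."""
    n = expr.shape[1]
    obs = np.array([stats.spearmanr(expr.loc[g], meth.loc[p]).statistic
                    for g, p in zip(pairs["gene_id"], pairs["probe_id"])])
    perms = list(itertools.permutations(range(n)))
    null = np.empty((len(perms), len(pairs)))
    for b, pi in enumerate(perms):
        cols = [meth.columns[j] for j in pi]
        for i, (g, p) in enumerate(zip(pairs["gene_id"], pairs["probe_id"])):
            null[b, i] = stats.spearmanr(
                expr.loc[g].to_numpy(),
                meth.loc[p, cols].to_numpy()).statistic
    anull, aobs = np.abs(null), np.abs(obs)
    tol = 1e-12
    p = (anull >= aobs[None, :] - tol).sum(axis=0) / len(perms)
    q = np.empty(len(pairs))
    for i, t in enumerate(aobs):
        v = (anull >= t - tol).sum() / len(perms)
        r = (aobs >= t - tol).sum()
        q[i] = min(1.0, v / max(r, 1))
    order = np.argsort(aobs)
    best = np.inf
    for i in order:
        best = min(best, q[i])
        q[i] = best
    return obs, p, q


class TestPermutationFDR:
    def test_exhaustive_mode_equals_brute_force_oracle(self):
        """n = 4 samples -> all 24 permutations enumerated; p_perm and
        q_perm agree exactly with an independent scipy-based oracle on a
        3-pair fixture."""
        expr, meth, pairs = _matrices(n_genes=3, n_samples=4, seed=5)
        filled = ml.correlate_pairs(expr, meth, pairs)
        out = ml.permutation_fdr(filled, expr, meth, n_perm=50, seed=0)
        obs, p_oracle, q_oracle = brute_force_permutation_fdr(expr, meth, pairs)
        assert np.allclose(out["rho"], obs, atol=1e-12)
        assert np.allclose(out["p_perm"], p_oracle, atol=1e-12)
        assert np.allclose(out["q_perm"], q_oracle, atol=1e-12)

    def test_monotone_pair_has_p_two_over_twentyfour(self):
        # |rho| = 1 is matched only by the identity and the full reversal
        samples = [f"s{j}" for j in range(4)]
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                            columns=samples)
        meth = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["p"],
                            columns=samples)
        pairs = pd.DataFrame({"gene_id": ["g"], "probe_id": ["p"],
                              "distance": [0]})
        out = ml.permutation_fdr(ml.correlate_pairs(expr, meth, pairs),
                                 expr, meth, n_perm=10, seed=0)
        assert out.loc[0, "p_perm"] == pytest.approx(2 / 24)

    def test_sampled_mode_converges_to_exhaustive(self):
        expr, meth, pairs = _matrices(n_genes=3, n_samples=4, seed=6)
        filled = ml.correlate_pairs(expr, meth, pairs)
        ex = ml.permutation_fdr(filled, expr, meth, n_perm=10, seed=0)
        sa = ml.permutation_fdr(filled, expr, meth, n_perm=10_000, seed=1,
                                exhaustive_cap=1)
        assert np.allclose(ex["q_perm"], sa["q_perm"], atol=0.02)
        assert np.allclose(ex["p_perm"], sa["p_perm"], atol=0.02)

    def test_q_in_unit_interval_and_monotone_in_abs_rho(self):
        expr, meth, pairs = _matrices(n_genes=12, n_samples=8, seed=7)
        filled = ml.correlate_pairs(expr, meth, pairs)
        out = ml.permutation_fdr(filled, expr, meth, n_perm=300, seed=3)
        assert out["q_perm"].between(0, 1).all()
        s = out.sort_values("rho", key=lambda c: c.abs())
        assert (np.diff(s["q_perm"].to_numpy()) <= 1e-12).all()

    def test_sampled_p_never_zero(self):
        expr, meth, pairs = _matrices(n_genes=3, n_samples=8, seed=8)
        filled = ml.correlate_pairs(expr, meth, pairs)
        out = ml.permutation_fdr(filled, expr, meth, n_perm=100, seed=2)
        assert (out["p_perm"] >= 1 / 101).all()


class TestClassifyPairs:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "probe_id", "distance",
                                           "rho", "p_perm", "q_perm"])

    def test_gene_may_carry_both_labels(self):
        pairs = self._pairs([("g", "p1", 0, -0.9, 0.001, 0.01),
                             ("g", "p2", 0, 0.8, 0.001, 0.01)])
        out, genes = ml.classify_pairs(pairs)
        assert set(out["pair_class"]) == {"canonical", "non_canonical"}
        row = genes.set_index("gene_id").loc["g"]
        assert row["canonical"] and row["non_canonical"]
        assert row["rep_probe_id"] == "p1"  # max |rho|

    def test_ns_pairs_give_no_label(self):
        pairs = self._pairs([("g", "p1", 0, -0.5, 0.4, 0.8)])
        out, genes = ml.classify_pairs(pairs)
        assert out.loc[0, "pair_class"] == "ns"
        row = genes.set_index("gene_id").loc["g"]
        assert not row["canonical"] and not row["non_canonical"]
        assert row["n_sig"] == 0

    def test_representative_tie_breaks_on_q_then_probe_id(self):
        pairs = self._pairs([("g", "pB", 0, 0.9, 0.001, 0.02),
                             ("g", "pA", 0, -0.9, 0.001, 0.02),
                             ("g", "pC", 0, -0.9, 0.001, 0.01)])
        _, genes = ml.classify_pairs(pairs)
        assert genes.set_index("gene_id").loc["g", "rep_probe_id"] == "pC"

    def test_label_proportions_recover_planted_fractions(self):
        """30% canonical / 20% non-canonical planted coupled genes:
        recovered gene-label proportions over the planted DE universe are
        within 10 percentage points of the planted fractions."""
        cfg = ml.SynthConfig(n_genes=500, background_probes=300)
        ds = ml.generate_dataset(cfg, seed=3)
        factors = ml.size_factors(ds.counts)
        de = ml.test_de(ds.counts, ds.design, ("WT", "KO"), factors)
        kept, _ = ml.filter_probes(ds.manifest, ds.beta)
        bn = ml.normalize_betas(ds.beta.loc[kept], ds.manifest)
        dmp = ml.test_dmp(bn, ds.design, ("WT", "KO"))
        genes = ds.annotation[ds.annotation["gene_id"].isin(
            set(de.degs["gene_id"]))]
        pos = ds.manifest[ds.manifest["probe_id"].isin(
            set(dmp.dmps["probe_id"]))]
        cis = ml.CisCorrelation(ds.counts / factors, bn, pos, genes,
                                ml.IntegrationConfig(n_perm=500)).fit(seed=1)
        truth = ds.truth.genes.set_index("gene_id")
        de_ids = truth[truth["de_status"] != "null"].index
        gt = cis.gene_table.set_index("gene_id")
        can = gt["canonical"].reindex(de_ids, fill_value=False).mean()
        non = gt["non_canonical"].reindex(de_ids, fill_value=False).mean()
        assert can == pytest.approx(0.30, abs=0.10)
        assert non == pytest.approx(0.20, abs=0.10)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 11475, 4.36e-6),
        (0.05, 1, 0.05),
        (0.05, 5, 0.01),
    ])
    def test_threshold(self, alpha, m, expected):
        assert ml.bonferroni_threshold(alpha, m) == pytest.approx(
            expected, rel=5e-3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ml.bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            ml.bonferroni_threshold(0.0, 10)
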