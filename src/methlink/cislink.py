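"""Cis linkage of methylation probes to gene TSSs, Spearman correlation,
and permutation-based FDR.

A (gene, probe) pair is cis-linked when the probe lies within a fixed
window (default +/- 5 kb) of the gene's transcription start site.
Each pair's Spearman rank correlation is computed between normalized
expression and beta values across all samples. Significance comes from
an empirical null built by permuting the methylation matrix's sample
columns with one shared permutation per round — this breaks the
expression/methylation pairing while preserving cross-probe and
cross-gene structure. The plug-in FDR estimator compares, at each
observed |rho| threshold, the average number of null exceedances per
permutation with the observed number of exceedances. Pairs significant
with rho < 0 are canonical (methylation tracks repression); rho > 0
non-canonical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntegrationConfig",
    "link_dmps_to_genes",
    "spearman_rho",
    "correlate_pairs",
    "permutation_fdr",
    "classify_pairs",
    "bonferroni_threshold",
    "CisCorrelation",
    "CisResults",
]


@dataclass
class IntegrationConfig:
    window: int = 5000
    n_perm: int = 1000
    fdr_threshold: float = 0.05
    exhaustive_cap: int = 720
    shared_permutation: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _norm_chrom(c: str) -> str:
    return c[3:] if c.lower().startswith("chr") else c


def link_dmps_to_genes(dmp_positions: pd.DataFrame, genes: pd.DataFrame,
                       window: int = 5000) -> pd.DataFrame:
    """Emit every (gene, probe) pair with |pos - tss| <= window on the
    same chromosome.

    ``dmp_positions`` needs columns probe_id, chrom, pos; ``genes``
    needs gene_id, chrom, tss, strand. Distance is pos - tss, sign
    flipped for minus-strand genes so positive always means downstream
    of transcription. Many-to-many: probes may pair with several genes
    and vice versa.
    """
    pchrom = set(dmp_positions["chrom"].map(_norm_chrom))
    gchrom = set(genes["chrom"].map(_norm_chrom))
    if pchrom and gchrom and not (pchrom & gchrom):
        raise ValueError(
            "no shared chromosome between probes and genes after chr-prefix "
            f"normalization; probes on {sorted(pchrom)}, genes on {sorted(gchrom)}")

    rows = []
    probes = dmp_positions.assign(_c=dmp_positions["chrom"].map(_norm_chrom))
    for c, sub in probes.groupby("_c"):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        pids = sub["probe_id"].to_numpy()
        gsub = genes[genes["chrom"].map(_norm_chrom) == c]
        for g in gsub.itertuples(index=False):
            lo = np.searchsorted(pos, g.tss - window, side="left")
            hi = np.searchsorted(pos, g.tss + window, side="right")
            for k in range(lo, hi):
                dist = int(pos[k] - g.tss)
                if g.strand == "-":
                    dist = -dist
                rows.append((g.gene_id, pids[k], dist))
    return pd.DataFrame(rows, columns=["gene_id", "probe_id", "distance"])


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman correlation (average ranks) with the asymptotic t-based
    p-value. Raises on zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance in ranks; rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def _rank_unit_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centred and scaled to unit norm; rows
    with zero rank variance become all-NaN."""
    r = np.apply_along_axis(stats.rankdata, 1, mat)
    r = r - r.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = r / norms
    u[norms[:, 0] == 0] = np.nan
    return u


def correlate_pairs(expr: pd.DataFrame, meth: pd.DataFrame,
                    pairs: pd.DataFrame) -> pd.DataFrame:
    """Fill Spearman rho per pair across all shared samples.

    ``expr`` is the size-factor-normalized expression matrix. Pairs
    whose expression or beta vector has zero rank variance are dropped
    with a warning.
    """
    if list(expr.columns) != list(meth.columns):
        raise ValueError("expression and methylation sample sets differ")
    out = pairs.copy()
    if len(out) == 0:
        out["rho"] = np.array([], dtype=float)
        return out
    ux = _rank_unit_rows(expr.loc[out["gene_id"]].to_numpy(dtype=float))
    uy = _rank_unit_rows(meth.loc[out["probe_id"]].to_numpy(dtype=float))
    rho = np.einsum("ij,ij->i", ux, uy)
    bad = ~np.isfinite(rho)
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} pair(s) with zero rank variance")
    out["rho"] = rho
    return out[~bad].reset_index(drop=True)


def _null_abs_rho(ux: np.ndarray, uy: np.ndarray,
                  perms: np.ndarray) -> np.ndarray:
    """|rho| for every (permutation, pair): permute the methylation
    columns by each row of ``perms``."""
    out = np.empty((len(perms), len(ux)))
    for b, pi in enumerate(perms):
        out[b] = np.abs(np.einsum("ij,ij->i", ux, uy[:, pi]))
    return out


def _plugin_q(obs_abs: np.ndarray, null_abs: np.ndarray) -> np.ndarray:
    """q(t) = min(1, mean-per-permutation #{null >= t} / max(#{obs >= t}, 1))
    at t = |rho_i|, then made monotone non-increasing in |rho|."""
    n_perm = null_abs.shape[0]
    flat = np.sort(null_abs.ravel())
    sorted_obs = np.sort(obs_abs)
    q = np.empty_like(obs_abs)
    for i, t in enumerate(obs_abs):
        v = (len(flat) - np.searchsorted(flat, t, side="left")) / n_perm
        r = len(sorted_obs) - np.searchsorted(sorted_obs, t, side="left")
        q[i] = min(1.0, v / max(r, 1))
    # monotone enforcement: a stronger pair never gets a larger q than a
    # weaker one -> cumulative min walking from smallest to largest |rho|
    order = np.argsort(obs_abs)  # ascending: weakest pair first
    best = np.inf
    for i in order:
        best = min(best, q[i])
        q[i] = best
    return q


def permutation_fdr(pairs: pd.DataFrame, expr: pd.DataFrame,
                    meth: pd.DataFrame, n_perm: int = 1000,
                    seed: int = 0, exhaustive_cap: int = 720,
                    shared_permutation: bool = True) -> pd.DataFrame:
    """Attach permutation p-values and plug-in q-values to pairs.

    One shared column permutation of the methylation matrix per round
    (``shared_permutation=False`` draws an independent permutation per
    pair instead). When n_samples! <= exhaustive_cap all permutations
    are enumerated and the +1 small-sample correction is dropped;
    otherwise n_perm permutations are sampled and
    p = (1 + #{null >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(pairs) == 0:
        raise ValueError("no pairs with defined rho")
    if list(expr.columns) != list(meth.columns):
        raise ValueError("expression and methylation sample sets differ")
    n = expr.shape[1]
    ux = _rank_unit_rows(expr.loc[pairs["gene_id"]].to_numpy(dtype=float))
    uy = _rank_unit_rows(meth.loc[pairs["probe_id"]].to_numpy(dtype=float))
    obs = np.abs(np.einsum("ij,ij->i", ux, uy))

    exhaustive = math.factorial(n) <= exhaustive_cap
    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = np.array(list(iter_permutations(range(n))), dtype=np.intp)
    elif shared_permutation:
        perms = np.array([rng.permutation(n) for _ in range(n_perm)],
                         dtype=np.intp)
    else:
        perms = None

    if perms is not None:
        null_abs = _null_abs_rho(ux, uy, perms)
    else:
        null_abs = np.empty((n_perm, len(pairs)))
        for b in range(n_perm):
            for i in range(len(pairs)):
                null_abs[b, i] = abs(float(np.dot(ux[i], uy[i, rng.permutation(n)])))

    tol = 1e-12  # |rho| comparisons up to float noise
    exceed = null_abs >= (obs[None, :] - tol)
    if exhaustive:
        p = exceed.sum(axis=0) / null_abs.shape[0]
    else:
        p = (1.0 + exceed.sum(axis=0)) / (null_abs.shape[0] + 1.0)

    out = pairs.copy()
    out["p_perm"] = p
    out["q_perm"] = _plugin_q(obs + 0.0, null_abs + tol)  # see note below
    # note: adding tol to the null before thresholding mirrors the >= with
    # tolerance used for p, so ties at identical |rho| count as exceedances
    return out


def classify_pairs(pairs: pd.DataFrame, genes: pd.DataFrame | None = None,
                   fdr_threshold: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label pairs canonical (rho < 0), non-canonical (rho > 0) or ns,
    and roll up per-gene labels.

    A gene carries a label iff at least one of its pairs has that label
    (so a gene may carry both). The gene table also records the
    representative significant pair (max |rho|; ties broken by smaller
    q_perm then lexicographic probe id) used downstream for
    direction-of-correlation comparisons.
    """
    out = pairs.copy()
    sig = out["q_perm"] < fdr_threshold
    out["pair_class"] = np.where(
        sig & (out["rho"] < 0), "canonical",
        np.where(sig & (out["rho"] > 0), "non_canonical", "ns"))

    rows = []
    for gid, sub in out.groupby("gene_id", sort=True):
        has_can = bool((sub["pair_class"] == "canonical").any())
        has_non = bool((sub["pair_class"] == "non_canonical").any())
        ssig = sub[sub["pair_class"] != "ns"]
        if len(ssig):
            ssig = ssig.sort_values(
                by=["rho", "q_perm", "probe_id"],
                key=lambda s: -s.abs() if s.name == "rho" else s)
            rep = ssig.iloc[0]
            rep_probe, rep_rho, rep_q = rep["probe_id"], rep["rho"], rep["q_perm"]
        else:
            rep_probe, rep_rho, rep_q = "", np.nan, np.nan
        rows.append((gid, len(sub), int((sub["pair_class"] != "ns").sum()),
                     has_can, has_non, rep_probe, rep_rho, rep_q))
    gene_table = pd.DataFrame(rows, columns=[
        "gene_id", "n_pairs", "n_sig", "canonical", "non_canonical",
        "rep_probe_id", "rep_rho", "rep_q"])
    return out, gene_table


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


class CisResults:
    """Pairs with correlation/FDR statistics plus the per-gene summary."""

    def __init__(self, pairs: pd.DataFrame, gene_table: pd.DataFrame,
                 config: IntegrationConfig):
        self.pairs = pairs
        self.gene_table = gene_table
        self.config = config

    def summary(self) -> str:
        n_can = int(self.gene_table["canonical"].sum())
        n_non = int(self.gene_table["non_canonical"].sum())
        return "\n".join([
            "Cis methylation-expression integration",
            f"  window:          +/-{self.config.window} bp of TSS",
            f"  pairs tested:    {len(self.pairs)}",
            f"  significant:     {int((self.pairs['pair_class'] != 'ns').sum())} "
            f"(q_perm < {self.config.fdr_threshold:g})",
            f"  genes linked:    {len(self.gene_table)}",
            f"  canonical genes: {n_can}; non-canonical genes: {n_non}",
        ])


class CisCorrelation:
    """End-to-end cis integration model.

    Built from normalized expression, (normalized) betas, probe
    positions and the TSS annotation of the genes of interest; ``fit``
    links, correlates, permutes and classifies in one pass.
    """

    def __init__(self, expr: pd.DataFrame, meth: pd.DataFrame,
                 probe_positions: pd.DataFrame, genes: pd.DataFrame,
                 config: IntegrationConfig | None = None):
        self.expr = expr
        self.meth = meth
        self.probe_positions = probe_positions
        self.genes = genes
        self.config = config or IntegrationConfig()

    def fit(self, seed: int = 0) -> CisResults:
        cfg = self.config
        pairs = link_dmps_to_genes(self.probe_positions, self.genes,
                                   window=cfg.window)
        pairs = pairs[pairs["probe_id"].isin(self.meth.index)
                      & pairs["gene_id"].isin(self.expr.index)].reset_index(drop=True)
        pairs = correlate_pairs(self.expr, self.meth, pairs)
        if len(pairs) == 0:
            pairs["p_perm"] = np.array([], dtype=float)
            pairs["q_perm"] = np.array([], dtype=float)
        else:
            pairs = permutation_fdr(pairs, self.expr, self.meth,
                                    n_perm=cfg.n_perm, seed=seed,
                                    exhaustive_cap=cfg.exhaustive_cap,
                                    shared_permutation=cfg.shared_permutation)
        pairs, gene_table = classify_pairs(pairs, self.genes,
                                           fdr_threshold=cfg.fdr_threshold)
        return CisResults(pairs, gene_table, cfg)
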