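"""Probe filtering, beta normalization, and differential methylation.

Probes are removed when they overlap SNPs, interrogate non-CpG context,
lie on a sex chromosome, or carry any missing beta value. Normalization
is between-sample quantile normalization applied separately within the
two Infinium design-type strata (a beta-level stand-in for
intensity-level normalization, which needs raw channel intensities this
pipeline never sees). Differential methylation is tested on M-values
(logit2 of beta) with a two-group linear model and empirical-Bayes
variance moderation: the probe-wise residual variances are squeezed
toward a common prior fitted by method of moments on the log sample
variances, exactly the scaled-inverse-chi-square hierarchy of the limma
family. Promoter and gene-body regions are scored by a directional
Stouffer combination of member-probe z-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_probes",
    "normalize_betas",
    "beta_to_m",
    "test_dmp",
    "aggregate_dmrs",
    "ModeratedDifferentialMethylation",
    "DMPResults",
    "fit_variance_prior",
    "FilterReport",
]

DEFAULT_EPS = 0.01
PROMOTER_UP = 1500
PROMOTER_DOWN = 500


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_removed: int
    by_reason: dict[str, int]


def filter_probes(manifest: pd.DataFrame,
                  beta: pd.DataFrame) -> tuple[list[str], FilterReport]:
    """Retain probes passing all filters; report removals per reason.

    A probe flagged for several reasons is counted in each reason's
    tally but only once in the union total.
    """
    man = manifest.set_index("probe_id")
    missing_manifest = [p for p in beta.index if p not in man.index]
    if missing_manifest:
        raise ValueError(
            f"probes absent from manifest: {missing_manifest[:10]}"
            + ("..." if len(missing_manifest) > 10 else ""))
    man = man.loc[beta.index]
    snp = man["snp_overlap"].to_numpy(dtype=bool)
    ctx = man["context_nonCpG"].to_numpy(dtype=bool)
    sex = man["sex_chrom"].to_numpy(dtype=bool)
    miss = beta.isna().any(axis=1).to_numpy()
    removed = snp | ctx | sex | miss
    report = FilterReport(
        n_input=len(beta),
        n_retained=int((~removed).sum()),
        n_removed=int(removed.sum()),
        by_reason={
            "snp_overlap": int(snp.sum()),
            "context_nonCpG": int(ctx.sum()),
            "sex_chrom": int(sex.sum()),
            "missing_value": int(miss.sum()),
        },
    )
    return beta.index[~removed].tolist(), report


def normalize_betas(beta: pd.DataFrame,
                    manifest: pd.DataFrame) -> pd.DataFrame:
    """Between-sample quantile normalization within design-type strata.

    Within each stratum every sample is mapped onto the mean of the
    per-sample sorted beta vectors, so all samples share an identical
    sorted distribution afterwards. Ties receive the mean of the
    reference values at their rank positions. Strata with fewer than
    two probes pass through unchanged (with a warning).
    """
    man = manifest.set_index("probe_id").loc[beta.index]
    out = beta.copy()
    for dtype, idx in man.groupby("design_type").groups.items():
        idx = beta.index.intersection(idx)
        if len(idx) < 2:
            warnings.warn(
                f"design-type {dtype} stratum has {len(idx)} probe(s); "
                "passed through unnormalized")
            continue
        sub = beta.loc[idx].to_numpy(dtype=float)
        ref = np.sort(sub, axis=0).mean(axis=1)
        norm = np.empty_like(sub)
        for j in range(sub.shape[1]):
            ranks = stats.rankdata(sub[:, j], method="average")
            # fractional rank -> mean of neighbouring reference values
            lo = np.floor(ranks).astype(int) - 1
            hi = np.ceil(ranks).astype(int) - 1
            norm[:, j] = 0.5 * (ref[lo] + ref[hi])
        out.loc[idx] = norm
    return out


def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """M-value transform: log2((beta + eps) / (1 - beta + eps)).

    Strictly increasing on [0, 1]; eps > 0 keeps the endpoints finite.
    """
    b = np.asarray(beta, dtype=float)
    if np.nanmin(b) < 0 or np.nanmax(b) > 1:
        raise ValueError("beta values must lie in [0, 1]")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    with np.errstate(divide="ignore"):
        m = np.log2((b + eps) / (1.0 - b + eps))
    return m if m.shape else float(m)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square prior
    (d0, s0^2) to probe-wise sample variances with ``df`` residual df,
    working on log variances.

    Returns (d0, s0sq); d0 = inf when the observed spread of log
    variances is no larger than the chi-square sampling spread alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.log(s2[ok]).mean())) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0)
                        - np.log(d0 / 2.0)))
    return d0, s0sq


class DMPResults:
    """Moderated-t results per probe for one contrast.

    ``table`` columns: probe_id, delta_m, delta_beta, t_mod, df, p, q,
    is_dmp. ``prior`` holds the fitted (d0, s0sq).
    """

    def __init__(self, table: pd.DataFrame, contrast: tuple[str, str],
                 prior: tuple[float, float], fdr_threshold: float):
        self.table = table
        self.contrast = contrast
        self.prior = prior
        self.fdr_threshold = fdr_threshold

    @property
    def dmps(self) -> pd.DataFrame:
        return self.table[self.table["is_dmp"]]

    def summary(self) -> str:
        a, b = self.contrast
        nd = int(self.table["is_dmp"].sum())
        hypo = int((self.table["is_dmp"] & (self.table["delta_beta"] < 0)).sum())
        d0 = self.prior[0]
        return "\n".join([
            "Moderated-t differential methylation (M-values)",
            f"  contrast:        {b} vs {a}",
            f"  probes tested:   {len(self.table)}",
            f"  prior df d0:     {'inf' if np.isinf(d0) else f'{d0:.2f}'}, "
            f"s0^2 = {self.prior[1]:.4g}",
            f"  DMPs (q < {self.fdr_threshold:g}): {nd}  "
            f"({hypo} hypo, {nd - hypo} hyper in {b})",
        ])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<DMPResults {self.contrast[1]} vs {self.contrast[0]}, n={len(self.table)}>"


class ModeratedDifferentialMethylation:
    """Two-group moderated-t model on M-values derived from betas.

    Parameters
    ----------
    beta : probes x samples DataFrame of beta values (post filtering).
    design : DataFrame with sample_id and condition columns.
    eps : offset of the M-value transform.
    """

    def __init__(self, beta: pd.DataFrame, design: pd.DataFrame,
                 eps: float = DEFAULT_EPS):
        self.beta = beta
        self.design = design
        self.eps = eps
        self.m = pd.DataFrame(beta_to_m(beta.to_numpy(), eps),
                              index=beta.index, columns=beta.columns)

    def _group_columns(self, condition: str) -> list[str]:
        ids = self.design.loc[self.design["condition"] == condition,
                              "sample_id"].tolist()
        cols = [s for s in ids if s in self.beta.columns]
        if len(cols) < 2:
            raise ValueError(
                f"condition {condition!r} has < 2 replicates in the matrix")
        return cols

    def fit(self, contrast: tuple[str, str], fdr_threshold: float = 0.05,
            prior_df: float | None = None) -> DMPResults:
        """Test ``contrast[1]`` versus ``contrast[0]``.

        ``prior_df`` overrides the fitted d0; 0 disables moderation and
        reproduces the ordinary per-probe t-test.
        """
        a, b = contrast
        cols_a, cols_b = self._group_columns(a), self._group_columns(b)
        xa = self.m[cols_a].to_numpy(dtype=float)
        xb = self.m[cols_b].to_numpy(dtype=float)
        na, nb = xa.shape[1], xb.shape[1]
        df_res = na + nb - 2
        if df_res <= 0:
            raise ValueError("zero residual degrees of freedom")

        delta_m = xb.mean(axis=1) - xa.mean(axis=1)
        ba = self.beta[cols_a].to_numpy(dtype=float)
        bb = self.beta[cols_b].to_numpy(dtype=float)
        delta_beta = bb.mean(axis=1) - ba.mean(axis=1)

        ssq = (xa.var(axis=1, ddof=1) * (na - 1)
               + xb.var(axis=1, ddof=1) * (nb - 1)) / df_res
        if prior_df is None:
            d0, s0sq = fit_variance_prior(ssq, df_res)
        elif prior_df == 0:
            d0, s0sq = 0.0, 1.0
        else:
            d0 = float(prior_df)
            _, s0sq = fit_variance_prior(ssq, df_res)
        if np.isinf(d0):
            s_post = np.full_like(ssq, s0sq)
            df_total = np.inf
        else:
            s_post = (d0 * s0sq + df_res * ssq) / (d0 + df_res)
            df_total = d0 + df_res

        c = np.sqrt(1.0 / na + 1.0 / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = delta_m / (np.sqrt(s_post) * c)
        t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t_mod))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

        table = pd.DataFrame({
            "probe_id": self.beta.index,
            "delta_m": delta_m,
            "delta_beta": delta_beta,
            "t_mod": t_mod,
            "df": df_total,
            "p": p,
            "q": q,
            "is_dmp": q < fdr_threshold,
        }).reset_index(drop=True)
        return DMPResults(table, (a, b), (d0, s0sq), fdr_threshold)


def test_dmp(beta: pd.DataFrame, design: pd.DataFrame,
             contrast: tuple[str, str], eps: float = DEFAULT_EPS,
             fdr_threshold: float = 0.05,
             prior_df: float | None = None) -> DMPResults:
    """Functional wrapper over :class:`ModeratedDifferentialMethylation`."""
    return ModeratedDifferentialMethylation(beta, design, eps).fit(
        contrast, fdr_threshold=fdr_threshold, prior_df=prior_df)


def aggregate_dmrs(dmps: pd.DataFrame, annotation: pd.DataFrame,
                   manifest: pd.DataFrame, fdr_threshold: float = 0.05,
                   min_probes: int = 2) -> pd.DataFrame:
    """Stouffer aggregation of probe statistics over promoters and gene
    bodies.

    Promoter: 1500 bp upstream to 500 bp downstream of the TSS, oriented
    by strand. Gene body: the annotated interval. A region needs at
    least ``min_probes`` member probes; z_comb = sum of directional
    probe z-values over sqrt(k), with z_i the magnitude of the normal
    quantile of the one-sided probe p-value, signed by delta_beta.
    Regions are BH-adjusted within each region kind.
    """
    man = manifest.set_index("probe_id")
    dm = dmps.set_index("probe_id")
    common = dm.index.intersection(man.index)
    dm = dm.loc[common]
    pos = man.loc[common, "pos"].to_numpy()
    chrom = man.loc[common, "chrom"].to_numpy()

    one_sided = np.clip(dm["p"].to_numpy() / 2.0, 1e-300, 1.0)
    z_mag = stats.norm.isf(one_sided)
    sign = np.sign(dm["delta_beta"].to_numpy())
    z_dir = np.where(sign == 0, 0.0, sign * z_mag)
    delta_beta = dm["delta_beta"].to_numpy()

    rows = []
    for rec in annotation.itertuples(index=False):
        if rec.strand == "+":
            prom = (rec.tss - PROMOTER_UP, rec.tss + PROMOTER_DOWN)
        else:
            prom = (rec.tss - PROMOTER_DOWN, rec.tss + PROMOTER_UP)
        for kind, (lo, hi) in (("promoter", prom),
                               ("gene_body", (rec.start, rec.end))):
            sel = (chrom == rec.chrom) & (pos >= lo) & (pos <= hi)
            k = int(sel.sum())
            if k < min_probes:
                continue
            z_comb = z_dir[sel].sum() / np.sqrt(k)
            p = 2.0 * stats.norm.sf(abs(z_comb))
            mean_db = delta_beta[sel].mean()
            rows.append((f"{rec.gene_id}:{kind}", kind, rec.gene_id,
                         rec.chrom, lo, hi, k, z_comb, p,
                         "hypo" if mean_db < 0 else "hyper", mean_db))
    out = pd.DataFrame(rows, columns=[
        "region_id", "region_kind", "gene_id", "chrom", "start", "end",
        "n_probes", "z_comb", "p", "direction", "mean_delta_beta"])
    if out.empty:
        out["q"] = []
        out["is_dmr"] = []
        return out
    q = np.full(len(out), np.nan)
    for kind in out["region_kind"].unique():
        m = (out["region_kind"] == kind).to_numpy()
        q[m] = multipletests(out.loc[m, "p"].to_numpy(), method="fdr_bh")[1]
    out["q"] = q
    out["is_dmr"] = out["q"] < fdr_threshold
    return out
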