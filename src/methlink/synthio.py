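"""Paired transcriptome/methylome simulation with known ground truth.

Emulates a four-condition knockout/rescue experiment (wild type, DNMT3A
knockout, and re-expression of either DNMT3A isoform, n replicates each)
or a two-group in vivo design: negative-binomial gene counts, bimodal
beta-value methylation with global knockout hypomethylation, planted
rescue structure, and cis-coupled (gene, probe) pairs whose expression
and methylation share a latent factor with canonical (negative) or
non-canonical (positive) sign within a window of the gene's TSS.

Every random draw comes from a named sub-stream spawned from one master
seed, so structural draws (gene layout, planted effects) are stable when
noise seeds change — this is what makes "twin" datasets with identical
planted truth but independent noise possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SyntheticDataset",
    "EffectTable",
    "generate_dataset",
    "generate_ortholog_map",
    "nb_sample",
]

KO_RESCUE_CONDITIONS = ("WT", "KO", "R1", "R2")
TWO_GROUP_CONDITIONS = ("FLFL", "DIEC")

# spawn keys for the named sub-streams
_S_LAYOUT = 0      # gene/probe placement, manifest flags
_S_EFFECTS = 1     # planted de/rescue/coupling truth
_S_EXPR = 2        # count noise
_S_METH = 3        # beta noise
_S_LATENT = 4      # shared coupling latent variables
_S_MISSING = 5     # missing-value mask


@dataclass
class SynthConfig:
    """Parameters of the simulated study.

    Defaults mirror the emulated study's design (four conditions, four
    replicates, ~85% of knockout-dysregulated features rescued, a 5 kb
    cis window) at a desk scale of a few hundred genes.
    """

    # scale
    n_genes: int = 500
    probes_per_gene: int = 3
    background_probes: int = 500
    replicates: int = 4
    design: str = "ko_rescue"  # or "two_group"
    species: str = "human"

    # genome geometry
    n_chroms: int = 2
    chrom_length: int = 30_000_000
    gene_spacing: int = 50_000
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    window: int = 5_000

    # planted expression effects
    de_fraction: float = 0.2
    log2fc: float = 1.0
    de_min_mu: float = 100.0
    rescue_both: float = 0.55
    rescue_r1_only: float = 0.15
    rescue_r2_only: float = 0.15
    rescue_none: float = 0.15

    # planted coupling (fractions of DE genes)
    canonical_fraction: float = 0.3
    noncanonical_fraction: float = 0.2
    coupling_strength_expr: float = 0.15  # log2-mean loading of the latent
    coupling_strength_meth: float = 0.35  # logit-beta loading of the latent

    # expression marginals
    mu_meanlog: float = np.log(200.0)
    mu_sdlog: float = 1.0
    mu_floor: float = 20.0
    dispersion_meanlog: float = np.log(0.01)
    dispersion_sdlog: float = 0.3
    libsize_sdlog: float = 0.15

    # methylation marginals
    beta_mix_a: float = 2.0
    beta_mix_b: float = 10.0
    meth_noise_sd: float = 0.35           # logit scale
    ko_logit_shift: float = 1.5
    meth_affected_hypo: float = 0.70      # of affected probes: shifted down
    meth_affected_hyper: float = 0.05     # of affected probes: shifted up
    meth_background_affected: float = 0.3

    # manifest flags
    type_ii_fraction: float = 0.8
    snp_rate: float = 0.02
    context_rate: float = 0.02
    sex_chrom_fraction: float = 0.02      # of background probes, on chrX
    missing_rate: float = 0.002

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.design not in ("ko_rescue", "two_group"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        fracs = {
            "de_fraction": self.de_fraction,
            "canonical_fraction": self.canonical_fraction,
            "noncanonical_fraction": self.noncanonical_fraction,
            "meth_affected_hypo": self.meth_affected_hypo,
            "meth_affected_hyper": self.meth_affected_hyper,
            "meth_background_affected": self.meth_background_affected,
            "type_ii_fraction": self.type_ii_fraction,
            "snp_rate": self.snp_rate,
            "context_rate": self.context_rate,
            "sex_chrom_fraction": self.sex_chrom_fraction,
            "missing_rate": self.missing_rate,
            "rescue_both": self.rescue_both,
            "rescue_r1_only": self.rescue_r1_only,
            "rescue_r2_only": self.rescue_r2_only,
            "rescue_none": self.rescue_none,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        rescue_total = (self.rescue_both + self.rescue_r1_only
                        + self.rescue_r2_only + self.rescue_none)
        if abs(rescue_total - 1.0) > 1e-9:
            raise ValueError(f"rescue proportions sum to {rescue_total}, not 1")
        if self.canonical_fraction + self.noncanonical_fraction > 1.0 + 1e-9:
            raise ValueError("coupling fractions sum to more than 1")
        if self.meth_affected_hypo + self.meth_affected_hyper > 1.0 + 1e-9:
            raise ValueError("methylation shift fractions sum to more than 1")
        if self.window <= 0:
            raise ValueError("window must be positive")

    @property
    def conditions(self) -> tuple[str, ...]:
        return (KO_RESCUE_CONDITIONS if self.design == "ko_rescue"
                else TWO_GROUP_CONDITIONS)

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EffectTable:
    """Planted ground truth, at gene and at probe resolution.

    ``genes`` columns: gene_id, de_status (null/up_in_KO/down_in_KO),
    rescue_truth (both/R1_only/R2_only/none/not_applicable),
    linked_probe_ids (comma-joined), coupling (none/canonical/
    non_canonical), log2fc_KO, delta_beta_KO (logit-scale shift applied
    to the gene's affected linked probes).

    ``probes`` columns: probe_id, gene_id ('' for background),
    meth_status (null/hypo/hyper), rescue_truth, delta_logit.
    """

    genes: pd.DataFrame
    probes: pd.DataFrame


@dataclass
class SyntheticDataset:
    design: pd.DataFrame
    annotation: pd.DataFrame
    manifest: pd.DataFrame
    counts: pd.DataFrame
    beta: pd.DataFrame
    truth: EffectTable
    config: SynthConfig
    seed: int


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def nb_sample(rng: np.random.Generator, mu, alpha, size=None) -> np.ndarray:
    """Negative-binomial draws with mean ``mu`` and variance ``mu + alpha*mu**2``.

    Gamma–Poisson mixture: lambda ~ Gamma(shape=1/alpha, scale=mu*alpha).
    alpha == 0 degenerates to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if size is None:
        size = np.broadcast_shapes(mu.shape, alpha.shape)
    mu, alpha = np.broadcast_to(mu, size), np.broadcast_to(alpha, size)
    out = np.empty(size, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        lam = rng.gamma(1.0 / alpha[~pois], mu[~pois] * alpha[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _make_design(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    for cond in cfg.conditions:
        for r in range(1, cfg.replicates + 1):
            rows.append((f"{cond}_{r}", cond, r, cfg.species))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate",
                                       "species"])


def _make_annotation(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    per_chrom = int(np.ceil(n / cfg.n_chroms))
    lo, hi = cfg.gene_length_range
    rows = []
    g = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for i in range(per_chrom):
            if g >= n:
                break
            anchor = (i + 1) * cfg.gene_spacing
            start = anchor + int(rng.integers(0, cfg.gene_spacing // 5))
            length = int(rng.integers(lo, hi + 1))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            rows.append((f"g{g:04d}", chrom, start, end, strand, tss))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "tss"])


def _place_probes(cfg: SynthConfig, ann: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Linked probes uniform in [tss - window, tss + window]; background
    probes uniform on the autosomes, plus a small chrX fraction."""
    rows = []
    pid = 0
    for rec in ann.itertuples(index=False):
        offs = rng.integers(-cfg.window, cfg.window + 1,
                            size=cfg.probes_per_gene)
        for off in offs:
            pos = max(int(rec.tss + off), 0)
            rows.append((f"cg{pid:06d}", rec.chrom, pos, rec.gene_id))
            pid += 1
    n_bg = cfg.background_probes
    n_x = int(round(cfg.sex_chrom_fraction * n_bg))
    for i in range(n_bg):
        if i < n_x:
            chrom = "chrX"
        else:
            chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        pos = int(rng.integers(0, cfg.chrom_length))
        rows.append((f"cg{pid:06d}", chrom, pos, ""))
        pid += 1
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene_id"])


def _make_manifest(cfg: SynthConfig, probes: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = len(probes)
    man = probes[["probe_id", "chrom", "pos"]].copy()
    man["design_type"] = np.where(rng.random(n) < cfg.type_ii_fraction,
                                  "II", "I")
    man["snp_overlap"] = rng.random(n) < cfg.snp_rate
    man["context_nonCpG"] = rng.random(n) < cfg.context_rate
    man["sex_chrom"] = man["chrom"].isin(["chrX", "chrY"])
    return man


def _plant_effects(cfg: SynthConfig, ann: pd.DataFrame, probes: pd.DataFrame,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = cfg.n_genes
    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_status = np.full(n, "null", dtype=object)
    lfc_sign = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    de_status[de_idx] = np.where(lfc_sign > 0, "up_in_KO", "down_in_KO")
    log2fc = np.zeros(n)
    log2fc[de_idx] = lfc_sign * cfg.log2fc

    # always consume the same draws regardless of design, so twin
    # datasets built on one structure seed share every later assignment
    rescue = np.full(n, "not_applicable", dtype=object)
    probs = [cfg.rescue_both, cfg.rescue_r1_only, cfg.rescue_r2_only,
             cfg.rescue_none]
    drawn = rng.choice(["both", "R1_only", "R2_only", "none"],
                       size=n_de, p=probs)
    rescue[de_idx] = drawn if cfg.design == "ko_rescue" else "none"

    coupling = np.full(n, "none", dtype=object)
    u = rng.random(n_de)
    coupling[de_idx] = np.where(
        u < cfg.canonical_fraction, "canonical",
        np.where(u < cfg.canonical_fraction + cfg.noncanonical_fraction,
                 "non_canonical", "none"))

    # probe-level planted methylation shifts
    linked = probes["gene_id"].to_numpy() != ""
    gene_of = probes["gene_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(ann["gene_id"])}
    meth_status = np.full(len(probes), "null", dtype=object)
    delta_logit = np.zeros(len(probes))
    probe_rescue = np.full(len(probes), "not_applicable", dtype=object)

    u_all = rng.random(len(probes))  # affected? and direction, one stream
    dir_u = rng.random(len(probes))
    bg_drawn = rng.choice(
        ["both", "R1_only", "R2_only", "none"], size=len(probes),
        p=[cfg.rescue_both, cfg.rescue_r1_only, cfg.rescue_r2_only,
           cfg.rescue_none])
    bg_rescue = (bg_drawn if cfg.design == "ko_rescue"
                 else np.full(len(probes), "none", dtype=object))

    for j in range(len(probes)):
        if linked[j]:
            # only cis-coupled genes imprint a condition-aligned shift on
            # their linked probes; other genes' probes stay untouched so
            # the canonical/non-canonical pair universe is exactly the
            # planted coupled set
            gi = gene_pos[gene_of[j]]
            coup = coupling[gi]
            if de_status[gi] == "null" or coup == "none":
                continue
            if coup == "canonical":
                # methylation moves opposite to expression in the knockout
                sign = -np.sign(log2fc[gi])
            else:
                sign = np.sign(log2fc[gi])
        else:
            if u_all[j] >= cfg.meth_background_affected:
                continue
            if dir_u[j] < cfg.meth_affected_hypo:
                sign = -1.0
            elif dir_u[j] < cfg.meth_affected_hypo + cfg.meth_affected_hyper:
                sign = 1.0
            else:
                continue  # affected bucket but no shift drawn
        meth_status[j] = "hypo" if sign < 0 else "hyper"
        delta_logit[j] = sign * cfg.ko_logit_shift
        if linked[j]:
            probe_rescue[j] = rescue[gene_pos[gene_of[j]]]
        else:
            probe_rescue[j] = bg_rescue[j]

    linked_ids = (probes.loc[linked, ["probe_id", "gene_id"]]
                  .groupby("gene_id")["probe_id"]
                  .apply(lambda s: ",".join(sorted(s))))
    genes = pd.DataFrame({
        "gene_id": ann["gene_id"],
        "de_status": de_status,
        "rescue_truth": rescue,
        "linked_probe_ids": ann["gene_id"].map(linked_ids).fillna(""),
        "coupling": coupling,
        "log2fc_KO": log2fc,
        "delta_beta_KO": [
            (-cfg.ko_logit_shift if coupling[i] == "canonical" and log2fc[i] > 0
             else cfg.ko_logit_shift if coupling[i] == "canonical"
             else cfg.ko_logit_shift if coupling[i] == "non_canonical" and log2fc[i] > 0
             else -cfg.ko_logit_shift if coupling[i] == "non_canonical"
             else 0.0) if de_status[i] != "null" else 0.0
            for i in range(n)],
    })
    probe_truth = pd.DataFrame({
        "probe_id": probes["probe_id"],
        "gene_id": probes["gene_id"],
        "meth_status": meth_status,
        "rescue_truth": probe_rescue,
        "delta_logit": delta_logit,
    })
    return genes, probe_truth


def _condition_dose(condition: np.ndarray, rescue_truth: str) -> np.ndarray:
    """Per-sample effect multiplier x in {0, 1}: 1 where the knockout
    effect is present, 0 where the feature is at wild-type level."""
    x = np.zeros(condition.shape, dtype=float)
    x[condition == "KO"] = 1.0
    x[condition == "DIEC"] = 1.0
    in_r1 = condition == "R1"
    in_r2 = condition == "R2"
    if rescue_truth in ("both", "R1_only"):
        x[in_r1] = 0.0
    else:
        x[in_r1] = 1.0
    if rescue_truth in ("both", "R2_only"):
        x[in_r2] = 0.0
    else:
        x[in_r2] = 1.0
    return x


def generate_dataset(config: SynthConfig, seed: int,
                     structure_seed: int | None = None) -> SyntheticDataset:
    """Simulate one paired dataset.

    ``structure_seed`` (default: ``seed``) drives gene layout, manifest
    flags and planted truth; ``seed`` drives all noise. Two calls with
    the same ``structure_seed`` and config geometry but different
    ``seed`` yield twin datasets: identical planted truth, independent
    measurement noise.
    """
    config.validate()
    s_seed = seed if structure_seed is None else structure_seed

    design = _make_design(config)
    ann = _make_annotation(config, _rng(s_seed, _S_LAYOUT, 0))
    probes = _place_probes(config, ann, _rng(s_seed, _S_LAYOUT, 1))
    manifest = _make_manifest(config, probes, _rng(s_seed, _S_LAYOUT, 2))
    gene_truth, probe_truth = _plant_effects(
        config, ann, probes, _rng(s_seed, _S_EFFECTS))

    cond = design["condition"].to_numpy()
    n_samp = len(design)
    n_genes = config.n_genes

    # expression marginals (structural: stable under noise reseeding)
    rng_marg = _rng(s_seed, _S_EFFECTS, 1)
    mu = np.exp(rng_marg.normal(config.mu_meanlog, config.mu_sdlog, n_genes))
    mu = np.maximum(mu, config.mu_floor)
    de_mask = gene_truth["de_status"].to_numpy() != "null"
    mu[de_mask] = np.maximum(mu[de_mask], config.de_min_mu)
    alpha = np.exp(rng_marg.normal(config.dispersion_meanlog,
                                   config.dispersion_sdlog, n_genes))
    base_logit = _baseline_logits(config, len(probes),
                                  _rng(s_seed, _S_EFFECTS, 2))
    # probes planted to lose methylation start methylated (and vice
    # versa), so a logit shift of the configured size moves beta by a
    # sizeable margin instead of sliding along a saturated tail
    rng_base = _rng(s_seed, _S_EFFECTS, 3)
    dl = probe_truth["delta_logit"].to_numpy()
    a, b = config.beta_mix_a, config.beta_mix_b
    for j in np.flatnonzero(dl != 0.0):
        comp = rng_base.beta(b, a) if dl[j] < 0 else rng_base.beta(a, b)
        comp = float(np.clip(comp, 1e-4, 1 - 1e-4))
        base_logit[j] = np.log(comp / (1 - comp))

    rng_lib = _rng(seed, _S_EXPR, 0)
    libfac = np.exp(rng_lib.normal(0.0, config.libsize_sdlog, n_samp))

    # shared latent per coupled gene: one value per sample
    rng_lat = _rng(seed, _S_LATENT)
    coupling = gene_truth["coupling"].to_numpy()
    latent = np.zeros((n_genes, n_samp))
    coupled = coupling != "none"
    latent[coupled] = rng_lat.standard_normal((int(coupled.sum()), n_samp))

    # counts
    log2fc = gene_truth["log2fc_KO"].to_numpy()
    rescue = gene_truth["rescue_truth"].to_numpy()
    mean_mat = np.empty((n_genes, n_samp))
    for i in range(n_genes):
        x = _condition_dose(cond, rescue[i])
        log2mean = np.log2(mu[i]) + x * log2fc[i]
        if coupled[i]:
            log2mean = log2mean + config.coupling_strength_expr * latent[i]
        mean_mat[i] = libfac * np.exp2(log2mean)
    rng_counts = _rng(seed, _S_EXPR, 1)
    counts = nb_sample(rng_counts, mean_mat, alpha[:, None],
                       size=(n_genes, n_samp))
    counts_df = pd.DataFrame(counts, index=pd.Index(ann["gene_id"].tolist()),
                             columns=design["sample_id"].tolist())
    counts_df.index.name = "gene_id"

    # methylation
    gene_pos = {g: i for i, g in enumerate(ann["gene_id"])}
    delta = probe_truth["delta_logit"].to_numpy()
    p_rescue = probe_truth["rescue_truth"].to_numpy()
    p_gene = probe_truth["gene_id"].to_numpy()
    rng_meth = _rng(seed, _S_METH)
    logit = np.empty((len(probes), n_samp))
    for j in range(len(probes)):
        row = np.full(n_samp, base_logit[j])
        if delta[j] != 0.0:
            row = row + _condition_dose(cond, p_rescue[j]) * delta[j]
        if p_gene[j] and coupled[gene_pos[p_gene[j]]]:
            gi = gene_pos[p_gene[j]]
            sgn = -1.0 if coupling[gi] == "canonical" else 1.0
            row = row + sgn * config.coupling_strength_meth * latent[gi]
        logit[j] = row
    logit = logit + rng_meth.normal(0.0, config.meth_noise_sd, logit.shape)
    beta = _logistic(logit)

    rng_miss = _rng(seed, _S_MISSING)
    if config.missing_rate > 0:
        miss = rng_miss.random(beta.shape) < config.missing_rate
        beta = np.where(miss, np.nan, beta)
    beta_df = pd.DataFrame(beta, index=pd.Index(probes["probe_id"].tolist()),
                           columns=design["sample_id"].tolist())
    beta_df.index.name = "probe_id"

    return SyntheticDataset(
        design=design, annotation=ann, manifest=manifest, counts=counts_df,
        beta=beta_df, truth=EffectTable(genes=gene_truth, probes=probe_truth),
        config=config, seed=seed)


def _baseline_logits(cfg: SynthConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Bimodal probe baselines: a symmetric two-component Beta mixture with
    modes near 0.1 and 0.9, expressed on the logit scale."""
    hi = rng.random(n) < 0.5
    a, b = cfg.beta_mix_a, cfg.beta_mix_b
    base = np.where(hi, rng.beta(b, a, n), rng.beta(a, b, n))
    base = np.clip(base, 1e-4, 1 - 1e-4)
    return np.log(base / (1 - base))


def generate_ortholog_map(annotation_a: pd.DataFrame,
                          annotation_b: pd.DataFrame,
                          frac_mapped: float, seed: int) -> pd.DataFrame:
    """One-to-one ortholog pairs between two gene sets.

    Pairs the i-th sampled index of each annotation (genes in annotation
    order), so twin datasets built from the same structural seed map
    each simulated gene to itself. Returns columns (gene_a, gene_b).
    """
    if not 0.0 <= frac_mapped <= 1.0:
        raise ValueError("frac_mapped must be in [0, 1]")
    n = min(len(annotation_a), len(annotation_b))
    k = int(round(frac_mapped * n))
    rng = _rng(seed, 7)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return pd.DataFrame({
        "gene_a": annotation_a["gene_id"].to_numpy()[idx],
        "gene_b": annotation_b["gene_id"].to_numpy()[idx],
    })
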