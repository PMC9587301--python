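"""One-configuration orchestration of the whole analysis.

Stages: simulate paired data, normalize and test expression, filter /
normalize / test methylation, classify rescue at gene and probe level,
link knockout DMPs to rescued-gene TSSs and score the pairs by
permutation FDR, and (optionally) intersect with a twin two-group
dataset through an ortholog map. Re-running with the same configuration
and seed reproduces every output file byte for byte; the run manifest
records the seed, a parameter hash and a checksum per output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cislink, exprdiff, io as mio, methdiff, rescue, synthio, xspecies

__all__ = ["PipelineConfig", "ConfigError", "run", "load_config"]

CONTRASTS = {
    "KO_vs_WT": ("WT", "KO"),
    "R1_vs_WT": ("WT", "R1"),
    "R2_vs_WT": ("WT", "R2"),
    "R1_vs_KO": ("KO", "R1"),
    "R2_vs_KO": ("KO", "R2"),
}
TWO_GROUP_CONTRAST = ("FLFL", "DIEC")


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any stage runs)."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "methlink_run"
    deg_fdr: float = 0.05
    dmp_fdr: float = 0.05
    require_reversal: bool = True
    cis_universe: str = "rescued_both"  # or "ko_degs"
    window: int = 5000
    n_perm: int = 1000
    cis_fdr: float = 0.05
    exhaustive_cap: int = 720
    xspecies_enabled: bool = True
    frac_mapped: float = 1.0
    synth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ConfigError("window must be positive")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        for name in ("deg_fdr", "dmp_fdr", "cis_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.cis_universe not in ("rescued_both", "ko_degs"):
            raise ConfigError(f"unknown cis_universe {self.cis_universe!r}")
        try:
            self.synth_config()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid synth section: {exc}") from exc

    def synth_config(self, **overrides) -> synthio.SynthConfig:
        known = {f.name for f in dataclasses.fields(synthio.SynthConfig)}
        unknown = set(self.synth) - known
        if unknown:
            raise ConfigError(f"unknown synth keys: {sorted(unknown)}")
        kw = {**self.synth, **overrides}
        kw.setdefault("window", self.window)
        return synthio.SynthConfig(**kw)

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: list[str] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        if p.exists():
            raise RuntimeError(f"output {name} already exists (write-once run dir)")
        self.files.append(name)
        return p


def _analyse_dataset(ds: synthio.SyntheticDataset, cfg: PipelineConfig,
                     run: _Run, prefix: str, seed: int) -> dict:
    """DE + DMP on every contrast of the dataset's design, rescue where
    the design has rescue arms, then cis integration. Returns the stage
    objects needed downstream."""
    contrasts = (CONTRASTS if ds.config.design == "ko_rescue"
                 else {"DIEC_vs_FLFL": TWO_GROUP_CONTRAST})

    factors = exprdiff.size_factors(ds.counts)
    mio.write_tsv(factors.rename_axis("sample_id").reset_index(),
                  run.path(f"{prefix}size_factors.tsv"))
    model = exprdiff.NBDifferentialExpression(ds.counts, ds.design, factors)
    de = {name: model.fit(c, fdr_threshold=cfg.deg_fdr)
          for name, c in contrasts.items()}
    for name, res in de.items():
        mio.write_tsv(res.table, run.path(f"{prefix}de_{name}.tsv"))

    retained, filt = methdiff.filter_probes(ds.manifest, ds.beta)
    beta_f = ds.beta.loc[retained]
    beta_n = methdiff.normalize_betas(beta_f, ds.manifest)
    meth_model = methdiff.ModeratedDifferentialMethylation(beta_n, ds.design)
    dmp = {name: meth_model.fit(c, fdr_threshold=cfg.dmp_fdr)
           for name, c in contrasts.items()}
    for name, res in dmp.items():
        mio.write_tsv(res.table, run.path(f"{prefix}dmp_{name}.tsv"))
    ko_name = "KO_vs_WT" if "KO_vs_WT" in dmp else "DIEC_vs_FLFL"
    dmrs = methdiff.aggregate_dmrs(dmp[ko_name].table, ds.annotation,
                                   ds.manifest, fdr_threshold=cfg.dmp_fdr)
    mio.write_tsv(dmrs, run.path(f"{prefix}dmr.tsv"))
    _write_dmr_bed(dmrs, run.path(f"{prefix}dmr.bed"))

    gene_rescue = probe_rescue = None
    if ds.config.design == "ko_rescue":
        rules = rescue.RescueRules(fdr_threshold=cfg.deg_fdr,
                                   require_reversal=cfg.require_reversal)
        gene_rescue = rescue.classify_rescue(
            de["KO_vs_WT"], de["R1_vs_WT"], de["R2_vs_WT"],
            de["R1_vs_KO"], de["R2_vs_KO"], rules)
        mrules = rescue.RescueRules(fdr_threshold=cfg.dmp_fdr,
                                    require_reversal=cfg.require_reversal)
        probe_rescue = rescue.classify_methylation_rescue(
            dmp["KO_vs_WT"], dmp["R1_vs_WT"], dmp["R2_vs_WT"],
            dmp["R1_vs_KO"], dmp["R2_vs_KO"], mrules)
        mio.write_tsv(gene_rescue, run.path(f"{prefix}rescue_genes.tsv"))
        mio.write_tsv(probe_rescue, run.path(f"{prefix}rescue_probes.tsv"))
        summary = pd.concat([
            rescue.rescue_summary(gene_rescue).assign(feature_kind="gene"),
            rescue.rescue_summary(probe_rescue).assign(feature_kind="probe"),
        ])
        mio.write_tsv(summary, run.path(f"{prefix}rescue_summary.tsv"))

    # cis integration: knockout DMPs against the chosen gene universe
    ko_de = de[ko_name]
    deg_ids = set(ko_de.degs["gene_id"])
    if ds.config.design == "ko_rescue" and cfg.cis_universe == "rescued_both":
        deg_ids &= set(gene_rescue.loc[gene_rescue["status"] == "both",
                                       "feature_id"])
    genes = ds.annotation[ds.annotation["gene_id"].isin(deg_ids)]
    dmp_ids = set(dmp[ko_name].dmps["probe_id"])
    positions = ds.manifest[ds.manifest["probe_id"].isin(dmp_ids)]
    norm_counts = ds.counts / factors

    cis_res = None
    if len(genes) and len(positions):
        model = cislink.CisCorrelation(
            norm_counts, beta_n, positions, genes,
            cislink.IntegrationConfig(
                window=cfg.window, n_perm=cfg.n_perm,
                fdr_threshold=cfg.cis_fdr,
                exhaustive_cap=cfg.exhaustive_cap))
        cis_res = model.fit(seed=seed)
        mio.write_tsv(cis_res.pairs, run.path(f"{prefix}pairs.tsv"))
        mio.write_tsv(cis_res.gene_table, run.path(f"{prefix}gene_labels.tsv"))
        _write_sig_pair_bed(cis_res.pairs, ds.manifest,
                            run.path(f"{prefix}sig_pairs.bed"))

    return {"de": de, "dmp": dmp, "filter": filt, "cis": cis_res,
            "gene_rescue": gene_rescue, "probe_rescue": probe_rescue,
            "dmrs": dmrs}


def _write_dmr_bed(dmrs: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for r in dmrs.itertuples(index=False):
            fh.write("\t".join([r.chrom, str(r.start), str(r.end + 1),
                                r.region_id, "0", "."]) + "\n")


def _write_sig_pair_bed(pairs: pd.DataFrame, manifest: pd.DataFrame,
                        path: Path) -> None:
    man = manifest.set_index("probe_id")
    with open(path, "w") as fh:
        for r in pairs[pairs["pair_class"] != "ns"].itertuples(index=False):
            chrom = man.loc[r.probe_id, "chrom"]
            pos = int(man.loc[r.probe_id, "pos"])
            fh.write("\t".join([chrom, str(pos), str(pos + 1),
                                f"{r.gene_id}|{r.probe_id}", "0", "."]) + "\n")


def _write_dataset(ds: synthio.SyntheticDataset, run: _Run,
                   prefix: str) -> None:
    mio.write_tsv(ds.design, run.path(f"{prefix}design.tsv"))
    mio.write_matrix(ds.counts, run.path(f"{prefix}counts.tsv"))
    mio.write_matrix(ds.beta, run.path(f"{prefix}beta.tsv"))
    mio.write_manifest(ds.manifest, run.path(f"{prefix}manifest.csv"))
    mio.write_gtf(ds.annotation, run.path(f"{prefix}annotation.gtf"))
    mio.write_bed6(ds.annotation, run.path(f"{prefix}annotation.bed"))
    mio.write_tsv(ds.truth.genes, run.path(f"{prefix}truth_genes.tsv"))
    mio.write_tsv(ds.truth.probes, run.path(f"{prefix}truth_probes.tsv"))


def run(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result bundle keyed by stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runctx = _Run(outdir)
    seed = config.seed

    ds = synthio.generate_dataset(config.synth_config(), seed=seed)
    _write_dataset(ds, runctx, "")
    primary = _analyse_dataset(ds, config, runctx, "", seed=seed)

    bundle = {"dataset": ds, **primary}
    if config.xspecies_enabled:
        twin_cfg = config.synth_config(design="two_group", species="mouse")
        ds2 = synthio.generate_dataset(twin_cfg, seed=seed + 1_000_003,
                                       structure_seed=seed)
        _write_dataset(ds2, runctx, "mouse_")
        secondary = _analyse_dataset(ds2, config, runctx, "mouse_",
                                     seed=seed + 2_000_003)
        orth = synthio.generate_ortholog_map(
            ds.annotation, ds2.annotation, config.frac_mapped, seed)
        mio.write_tsv(orth, runctx.path("orthologs.tsv"))
        if primary["cis"] is not None and secondary["cis"] is not None:
            report = xspecies.intersect_linked_genes(
                primary["cis"].gene_table, secondary["cis"].gene_table, orth)
            mio.write_tsv(report.table, runctx.path("concordance.tsv"))
            bundle["concordance"] = report
        bundle["mouse"] = {"dataset": ds2, **secondary}

    manifest = {
        "seed": seed,
        "param_hash": config.param_hash(),
        "config": dataclasses.asdict(config),
        "outputs": {name: _sha256(outdir / name)
                    for name in sorted(runctx.files)},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
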