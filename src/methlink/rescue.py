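"""Rescue classification over a knockout plus two-isoform-rescue design.

A feature (gene or probe) dysregulated in the knockout is "rescued" by
an isoform when its signal returns to wild-type level upon re-expression
of that isoform. The default rule requires both loss of significance
versus wild type and a significant reversal versus the knockout (the
reversal clause guards against calling low-power features rescued and
can be switched off for the permissive definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RescueRules", "classify_rescue", "classify_methylation_rescue",
           "rescue_summary"]

STATUSES = ("both", "R1_only", "R2_only", "none", "not_applicable")


@dataclass
class RescueRules:
    fdr_threshold: float = 0.05
    require_reversal: bool = True


def _frame(results, id_col: str, effect_col: str) -> pd.DataFrame:
    """Accept a Results object (with .table) or a plain DataFrame."""
    tab = getattr(results, "table", results)
    return tab.set_index(id_col)[[effect_col, "q"]].rename(
        columns={effect_col: "effect"})


def _classify(ko, r1_wt, r2_wt, r1_ko, r2_ko, rules: RescueRules,
              id_col: str, effect_col: str, feature_kind: str) -> pd.DataFrame:
    frames = {name: _frame(res, id_col, effect_col)
              for name, res in [("ko", ko), ("r1_wt", r1_wt),
                                ("r2_wt", r2_wt), ("r1_ko", r1_ko),
                                ("r2_ko", r2_ko)]}
    universe = frames["ko"].index
    for name, f in frames.items():
        if not universe.equals(f.index) and set(universe) != set(f.index):
            raise ValueError(
                f"feature universe of contrast {name!r} differs from KO-vs-WT")
        frames[name] = f.loc[universe]

    thr = rules.fdr_threshold
    ko_q = frames["ko"]["q"].to_numpy()
    ko_eff = frames["ko"]["effect"].to_numpy()
    is_ko = ko_q < thr
    ko_call = np.where(~is_ko, "null", np.where(ko_eff > 0, "up", "down"))

    def rescued(vs_wt: pd.DataFrame, vs_ko: pd.DataFrame) -> np.ndarray:
        quiet = vs_wt["q"].to_numpy() >= thr
        if not rules.require_reversal:
            return quiet
        rev = ((vs_ko["q"].to_numpy() < thr)
               & (np.sign(vs_ko["effect"].to_numpy()) == -np.sign(ko_eff)))
        return quiet & rev

    r1 = rescued(frames["r1_wt"], frames["r1_ko"]) & is_ko
    r2 = rescued(frames["r2_wt"], frames["r2_ko"]) & is_ko

    status = np.where(
        ~is_ko, "not_applicable",
        np.where(r1 & r2, "both",
                 np.where(r1, "R1_only",
                          np.where(r2, "R2_only", "none"))))
    return pd.DataFrame({
        "feature_id": universe,
        "feature_kind": feature_kind,
        "ko_call": ko_call,
        "rescued_R1": r1,
        "rescued_R2": r2,
        "status": status,
    }).reset_index(drop=True)


def classify_rescue(de_ko_vs_wt, de_r1_vs_wt, de_r2_vs_wt,
                    de_r1_vs_ko, de_r2_vs_ko,
                    rules: RescueRules | None = None) -> pd.DataFrame:
    """Gene-level rescue table from the five expression contrasts.

    Contrast orientation: each input tests (reference, condition) so its
    effect sign is condition-over-reference; the reversal clause demands
    the isoform-vs-KO effect oppose the KO-vs-WT effect.
    """
    return _classify(de_ko_vs_wt, de_r1_vs_wt, de_r2_vs_wt,
                     de_r1_vs_ko, de_r2_vs_ko, rules or RescueRules(),
                     "gene_id", "log2fc", "gene")


def classify_methylation_rescue(dmp_ko_vs_wt, dmp_r1_vs_wt, dmp_r2_vs_wt,
                                dmp_r1_vs_ko, dmp_r2_vs_ko,
                                rules: RescueRules | None = None) -> pd.DataFrame:
    """Probe-level rescue table from the five methylation contrasts."""
    return _classify(dmp_ko_vs_wt, dmp_r1_vs_wt, dmp_r2_vs_wt,
                     dmp_r1_vs_ko, dmp_r2_vs_ko, rules or RescueRules(),
                     "probe_id", "delta_beta", "probe")


def rescue_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts per rescue status plus the rescued fraction among
    knockout-dysregulated features."""
    counts = table["status"].value_counts().reindex(STATUSES, fill_value=0)
    n_ko = int((table["status"] != "not_applicable").sum())
    n_rescued = int(counts[["both", "R1_only", "R2_only"]].sum())
    out = counts.rename_axis("status").reset_index(name="n")
    out.attrs["n_ko_features"] = n_ko
    out.attrs["fraction_rescued"] = (n_rescued / n_ko) if n_ko else np.nan
    return out
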