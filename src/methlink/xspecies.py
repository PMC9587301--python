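"""Cross-dataset intersection of DNAm-linked genes through an ortholog map.

Two cis-integration runs (e.g. a human in vitro knockout/rescue line and
a mouse in vivo conditional knockout) are intersected over a strict 1:1
ortholog map; a gene pair is "shared" when both members carry at least
one significant cis pair, and concordant when the representative
correlations agree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConcordanceReport", "intersect_linked_genes"]


@dataclass
class ConcordanceReport:
    n_shared: int
    n_same_direction: int
    table: pd.DataFrame  # gene_a, gene_b, rho_a, rho_b, concordant

    def summary(self) -> str:
        frac = (self.n_same_direction / self.n_shared
                if self.n_shared else float("nan"))
        return "\n".join([
            "Cross-dataset DNAm-linked gene concordance",
            f"  shared linked genes:   {self.n_shared}",
            f"  same direction:        {self.n_same_direction} "
            f"({frac:.1%})" if self.n_shared else
            "  same direction:        0",
        ])


def _check_one_to_one(orth: pd.DataFrame) -> None:
    for col in ("gene_a", "gene_b"):
        dup = orth[col][orth[col].duplicated()].unique().tolist()
        if dup:
            raise ValueError(
                f"ortholog map is not 1:1; duplicated {col}: {dup[:10]}")


def intersect_linked_genes(labels_a: pd.DataFrame, labels_b: pd.DataFrame,
                           ortholog_map: pd.DataFrame) -> ConcordanceReport:
    """Build the concordance report from two per-gene cis summaries.

    ``labels_a``/``labels_b`` are gene tables from cis classification
    (columns gene_id, n_sig, rep_rho, ...); ``ortholog_map`` has columns
    gene_a, gene_b and must be a bijection on its rows.
    """
    orth = ortholog_map.rename(columns=dict(zip(
        ortholog_map.columns[:2], ["gene_a", "gene_b"])))
    _check_one_to_one(orth)

    def linked(tbl: pd.DataFrame) -> pd.DataFrame:
        t = tbl[tbl["n_sig"] > 0]
        return t.set_index("gene_id")[["rep_rho"]]

    la, lb = linked(labels_a), linked(labels_b)
    shared = orth[orth["gene_a"].isin(la.index)
                  & orth["gene_b"].isin(lb.index)].copy()
    shared["rho_a"] = la.loc[shared["gene_a"], "rep_rho"].to_numpy()
    shared["rho_b"] = lb.loc[shared["gene_b"], "rep_rho"].to_numpy()
    shared["concordant"] = (np.sign(shared["rho_a"])
                            == np.sign(shared["rho_b"]))
    shared = shared.reset_index(drop=True)
    return ConcordanceReport(
        n_shared=len(shared),
        n_same_direction=int(shared["concordant"].sum()),
        table=shared[["gene_a", "gene_b", "rho_a", "rho_b", "concordant"]],
    )
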