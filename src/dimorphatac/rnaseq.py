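"""Expression arm: TPM, differential expression via the shared NB count
machinery (pooled normalization — expression is not X-stratified), and the
neighbor-gene expression-bias test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffacc import bh_adjust, estimate_dispersion, nb_wald_test, size_factors


def tpm(counts: pd.DataFrame, lengths: pd.Series | np.ndarray,
        sample_ids: list[str],
        replicate_groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Transcripts-per-million per sample; each column sums to 1e6.

    ``replicate_groups`` (condition -> sample ids) adds replicate-averaged
    columns named ``tpm_mean_<condition>``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    out = counts[["gene_id"]].copy() if "gene_id" in counts else pd.DataFrame(
        index=counts.index)
    out["length"] = lengths
    for sid in sample_ids:
        rate = counts[sid].to_numpy(dtype=float) / lengths
        total = rate.sum()
        if total == 0:
            raise ValueError(f"sample {sid}: zero total rate")
        out[f"tpm_{sid}"] = 1e6 * rate / total
    if replicate_groups:
        for cond, ids in replicate_groups.items():
            out[f"tpm_mean_{cond}"] = np.mean(
                [out[f"tpm_{s}"] for s in ids], axis=0)
    return out


def de_genes(counts: pd.DataFrame, samples: pd.DataFrame, target: str,
             reference: str) -> pd.DataFrame:
    """NB Wald differential expression, pooled normalization, BH over all
    genes. log2fc oriented target/reference."""
    sample_ids = list(samples["sample_id"])
    mat = counts[sample_ids].to_numpy()
    ref_idx = np.flatnonzero((samples["condition"] == reference).to_numpy())
    tgt_idx = np.flatnonzero((samples["condition"] == target).to_numpy())
    if len(ref_idx) < 2 or len(tgt_idx) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    sf = size_factors(mat)
    disp = estimate_dispersion(mat, sf, [ref_idx, tgt_idx])
    res = nb_wald_test(mat, sf, disp.final, ref_idx, tgt_idx)
    res.insert(0, "gene_id", counts["gene_id"].to_numpy())
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    res["comparison"] = f"{target}_vs_{reference}"
    res.attrs["orientation"] = f"log2fc = log2({target} / {reference})"
    return res


@dataclass
class NeighborExpressionTest:
    """Welch two-sample t-test of expression log2fc between genes near
    target-opened vs target-closed peaks."""

    group_open: np.ndarray
    group_closed: np.ndarray
    t_statistic: float
    df: float
    pvalue: float

    def summary(self) -> str:
        return (
            "Neighbor-gene expression bias (Welch two-sample t-test)\n"
            f"  genes near opened peaks : n={len(self.group_open)}, "
            f"mean log2fc={self.group_open.mean():+.3f}\n"
            f"  genes near closed peaks : n={len(self.group_closed)}, "
            f"mean log2fc={self.group_closed.mean():+.3f}\n"
            f"  t={self.t_statistic:.3f}, df={self.df:.1f}, p={self.pvalue:.3g}"
        )


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df, two-sided p."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def neighbor_expression_bias(de: pd.DataFrame, annotations: pd.DataFrame,
                             specificity: pd.DataFrame) -> NeighborExpressionTest:
    """Compare expression log2fc of genes nearest to opened vs closed
    peaks. Genes are deduplicated within a group; a gene near both peak
    classes appears in both groups.
    """
    ann = annotations.set_index("region")["nearest_gene"]
    lfc = de.set_index("gene_id")["log2fc"]

    def group_values(status: str) -> np.ndarray:
        regions = specificity.loc[specificity["status"] == status, "region"]
        genes = sorted(set(ann.loc[regions].dropna()))
        genes = [g for g in genes if g in lfc.index]
        return lfc.loc[genes].to_numpy(dtype=float)

    open_vals = group_values("opened_in_target")
    closed_vals = group_values("closed_in_target")
    if len(open_vals) < 2 or len(closed_vals) < 2:
        raise ValueError("each neighbor-gene group needs >= 2 genes")
    t, df, p = welch_t(open_vals, closed_vals)
    return NeighborExpressionTest(group_open=open_vals,
                                  group_closed=closed_vals,
                                  t_statistic=t, df=df, pvalue=p)
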