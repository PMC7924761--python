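"""Condition-specific regulatory elements by intersecting two differential
comparisons with a direction-concordance rule.

A region is called specific to the target condition when it passes the FDR
threshold in *both* comparisons (each oriented target/reference); shared
sign decides opened vs closed in the target, while significant-but-
opposite-sign regions are reported as discordant rather than dropped —
zero discordance is a finding, not an assumption.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


def intersect_classify(res_a: pd.DataFrame, res_b: pd.DataFrame,
                       fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Classify each region across two comparisons sharing a consensus.

    Returns one row per region with status in
    {opened_in_target, closed_in_target, discordant, not_specific}.
    """
    a = res_a.set_index("region")
    b = res_b.set_index("region")
    if set(a.index) != set(b.index):
        raise ValueError("the two comparisons must share one region set")
    b = b.loc[a.index]

    sig = (a["fdr"] < fdr_threshold).to_numpy() & (b["fdr"] < fdr_threshold).to_numpy()
    same_pos = (a["log2fc"] > 0).to_numpy() & (b["log2fc"] > 0).to_numpy()
    same_neg = (a["log2fc"] < 0).to_numpy() & (b["log2fc"] < 0).to_numpy()
    status = np.where(
        sig & same_pos, "opened_in_target",
        np.where(sig & same_neg, "closed_in_target",
                 np.where(sig, "discordant", "not_specific")),
    )
    n_disc = int((status == "discordant").sum())
    if n_disc:
        warnings.warn(f"{n_disc} discordant regions (significant in both "
                      "comparisons with opposite signs)")
    out = pd.DataFrame({
        "region": a.index,
        "chrom": a["chrom"].to_numpy(), "start": a["start"].to_numpy(),
        "end": a["end"].to_numpy(), "stratum": a["stratum"].to_numpy(),
        "status": status,
        "log2fc_1": a["log2fc"].to_numpy(), "fdr_1": a["fdr"].to_numpy(),
        "log2fc_2": b["log2fc"].to_numpy(), "fdr_2": b["fdr"].to_numpy(),
    })
    return out.reset_index(drop=True)


@dataclass
class UpSetSummary:
    counts: pd.DataFrame  # columns: subset (sorted "+"-joined names), count

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())


def upset_counts(named_sets: dict[str, set]) -> UpSetSummary:
    """Exact exclusive-membership counts for every non-empty subset."""
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(named_sets)
    union = set().union(*named_sets.values())
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(union)
            for n in combo:
                inside &= named_sets[n]
            for n in names:
                if n not in combo:
                    inside -= named_sets[n]
            if inside:
                rows.append({"subset": "+".join(combo), "count": len(inside)})
    df = pd.DataFrame(rows, columns=["subset", "count"])
    return UpSetSummary(counts=df)
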