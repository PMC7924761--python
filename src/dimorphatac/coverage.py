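"""Locus- and gene-scale coverage analytics.

All assignment is by fragment midpoint, consistent with the counting rule
used everywhere else in the package. Gene-scale counting deliberately uses
whole gene spans (not exons): broad low-lying accessibility across a long
locus — the signature of a gene whose many intronic enhancers are each
active in a small cell subpopulation — only shows up when the full span is
aggregated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomeSpec, GenomicInterval


@dataclass
class WindowAggregate:
    locus: GenomicInterval
    window: int
    counts: pd.DataFrame       # window_start, window_end + one column/sample
    fold_change: pd.DataFrame | None  # window_start, window_end, fold_change


def windowed_counts(fragments: dict[str, pd.DataFrame],
                    locus: GenomicInterval, genome: GenomeSpec,
                    window: int = 5000,
                    condition_a_samples: list[str] | None = None,
                    condition_b_samples: list[str] | None = None,
                    size_factors: dict[str, float] | None = None,
                    moderation: float = 0.5) -> WindowAggregate:
    """Fixed-width window counts across a locus; the last partial window
    keeps its true width. Optional per-window normalized fold change
    (B over A) between two sample groups."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if locus.chrom not in genome or locus.end > genome.length(locus.chrom):
        raise ValueError("locus outside genome")
    starts = np.arange(locus.start, locus.end, window)
    ends = np.minimum(starts + window, locus.end)
    out = pd.DataFrame({"window_start": starts, "window_end": ends})
    for sid, df in fragments.items():
        sub = df[df["chrom"] == locus.chrom]
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        mids = mids[(mids >= locus.start) & (mids < locus.end)]
        idx = ((mids - locus.start) // window).astype(np.int64)
        counts = np.bincount(idx, minlength=len(starts))
        out[sid] = counts

    fc = None
    if condition_a_samples and condition_b_samples:
        sf = size_factors or {}

        def norm_mean(ids):
            cols = [out[s].to_numpy() / sf.get(s, 1.0) for s in ids]
            return np.mean(cols, axis=0)

        a = norm_mean(condition_a_samples)
        b = norm_mean(condition_b_samples)
        fc = pd.DataFrame({
            "window_start": starts, "window_end": ends,
            "mean_a": a, "mean_b": b,
            "fold_change": (b + moderation) / (a + moderation),
        })
    return WindowAggregate(locus=locus, window=window, counts=out, fold_change=fc)


def gene_scale_counts(fragments: dict[str, pd.DataFrame],
                      genes: list[GeneModel]) -> pd.DataFrame:
    """Whole-span fragment counts per gene per sample (midpoint rule;
    a fragment counts once in every overlapping gene span)."""
    rows = {
        "gene_id": [g.gene_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "length": [g.span.length for g in genes],
    }
    spans = [(g.chrom, g.span.start, g.span.end) for g in genes]
    for sid, df in fragments.items():
        counts = np.zeros(len(genes), dtype=np.int64)
        for chrom, sub in df.groupby("chrom"):
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            for i, (gchrom, s, e) in enumerate(spans):
                if gchrom != chrom:
                    continue
                counts[i] += int(((mids >= s) & (mids < e)).sum())
        rows[sid] = counts
    df = pd.DataFrame(rows)
    for sid in fragments:
        df[f"{sid}_per_bp"] = df[sid] / df["length"]
    return df


@dataclass
class AnchoredMatrix:
    matrix: np.ndarray          # regions x bins, NaN where masked
    mean_profile: np.ndarray    # column means ignoring masked bins
    mode: str
    bins: int


def anchored_signal(track: dict[str, np.ndarray],
                    regions: list[GenomicInterval], mode: str = "center",
                    flank: int = 1000, bins: int = 50,
                    body_bins: int | None = None) -> AnchoredMatrix:
    """Signal profiles anchored on regions.

    center mode: each region contributes the per-bp signal over
    [midpoint - flank, midpoint + flank) averaged within ``bins`` equal
    bins. scaled-body mode: the region body rescaled into ``body_bins``
    bins flanked by native-bp flanks of ``bins`` bins each; minus-strand
    regions are reversed. Bins extending past a chromosome are masked
    (NaN) and excluded from the mean profile.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if mode not in ("center", "scaled_body"):
        raise ValueError(f"unknown mode {mode!r}")

    def bin_mean(arr: np.ndarray, start: int, end: int, nbins: int) -> np.ndarray:
        """Mean signal in nbins equal bins over [start,end); out-of-bounds -> NaN."""
        out = np.full(nbins, np.nan)
        n = len(arr)
        edges = np.linspace(start, end, nbins + 1)
        for i in range(nbins):
            s, e = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
            s2, e2 = max(s, 0), min(e, n)
            if s >= 0 and e <= n and e2 > s2:
                out[i] = arr[s2:e2].mean()
        return out

    rows = []
    if mode == "center":
        total_bins = bins
        for r in regions:
            arr = track[r.chrom]
            mid = r.midpoint
            rows.append(bin_mean(arr, mid - flank, mid + flank, bins))
    else:
        body_bins = body_bins or bins
        total_bins = bins + body_bins + bins
        for r in regions:
            arr = track[r.chrom]
            left = bin_mean(arr, r.start - flank, r.start, bins)
            body = bin_mean(arr, r.start, r.end, body_bins)
            right = bin_mean(arr, r.end, r.end + flank, bins)
            row = np.concatenate([left, body, right])
            if r.strand == "-":
                row = row[::-1]
            rows.append(row)
    matrix = np.vstack(rows) if rows else np.empty((0, total_bins))
    if len(rows):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            mean_profile = np.nanmean(matrix, axis=0)
    else:
        mean_profile = np.array([])
    return AnchoredMatrix(matrix=matrix, mean_profile=mean_profile,
                          mode=mode, bins=total_bins)


def sample_correlation(fragments: dict[str, pd.DataFrame], genome: GenomeSpec,
                       bin_size: int = 10_000) -> pd.DataFrame:
    """Pairwise Spearman correlation of binned midpoint counts."""
    if len(fragments) < 2:
        raise ValueError("need >= 2 samples")
    per_sample = {}
    for sid, df in fragments.items():
        pieces = []
        for chrom, length, _ in genome.chroms:
            nbins = int(np.ceil(length / bin_size))
            sub = df[df["chrom"] == chrom]
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            pieces.append(np.bincount(np.minimum(mids // bin_size, nbins - 1),
                                      minlength=nbins))
        per_sample[sid] = np.concatenate(pieces)
    ids = list(per_sample)
    mat = np.eye(len(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rho = stats.spearmanr(per_sample[ids[i]], per_sample[ids[j]]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=ids, columns=ids)


def chrom_read_fractions(fragments: dict[str, pd.DataFrame],
                         genome: GenomeSpec) -> pd.DataFrame:
    """Per-sample fraction of fragments per stratum (sums to 1)."""
    strata = sorted({s for _, _, s in genome.chroms})
    rows = []
    for sid, df in fragments.items():
        total = len(df)
        row = {"sample_id": sid}
        for stratum in strata:
            chroms = {n for n, _, s in genome.chroms if s == stratum}
            row[stratum] = (df["chrom"].isin(chroms).sum() / total
                            if total else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def accessibility_expression_r2(accessibility: pd.Series,
                                expression: pd.Series) -> float:
    """Squared Pearson correlation of log10(x + 1) accessibility-per-bp vs
    log10(TPM + 1) over shared genes."""
    shared = accessibility.index.intersection(expression.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    x = np.log10(accessibility.loc[shared].to_numpy(dtype=float) + 1)
    y = np.log10(expression.loc[shared].to_numpy(dtype=float) + 1)
    r = stats.pearsonr(x, y).statistic
    return float(r ** 2)
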