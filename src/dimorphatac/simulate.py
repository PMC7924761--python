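"""Synthetic chromatin-fragment simulator.

Emulates the statistical structure of a sex-sorted neuronal ATAC-seq
experiment in *Drosophila*: four conditions (male/female x fru+/fru-) with
replicates, a diploid-female / haploid-male X chromosome, dosage-
compensation-complex (DCC) boosted sites on the male X, planted
Fru^M-opened and Fru^M-closed peaks present only in male fru+ samples,
per-peak cell-fraction heterogeneity (peak height tracks the proportion
of cells using an element), a bimodal sub-/mono-nucleosomal fragment
length mixture, and motif instances planted preferentially in closed
regions.

Expected count for peak i in sample j:

    mu_ij = s_j * f_i * mu_base * x_ij * d_ij * g_ij

with x_ij = 2 for female samples at X peaks (two X copies), d_ij =
dcc_boost for male samples at DCC peaks, g_ij = 2^(+/-delta) only for the
male fru+ condition at Fru^M-opened/closed peaks, f_i the per-peak cell
fraction, and s_j a per-sample library size factor. Counts are negative
binomial with mean mu_ij and dispersion alpha (variance mu + alpha*mu^2);
alpha = 0 degenerates to Poisson.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeSpec, GenomicInterval
from .motif import PWM, reverse_complement

CONDITIONS = ("male_fru_plus", "male_fru_minus", "female_fru_plus", "female_fru_minus")
COMPARISONS = {
    # target, reference — orientation target/reference
    "male_vs_female_fruplus": ("male_fru_plus", "female_fru_plus"),
    "fruplus_vs_fruminus_male": ("male_fru_plus", "male_fru_minus"),
    "male_vs_female_fruminus": ("male_fru_minus", "female_fru_minus"),
}


def default_genome() -> GenomeSpec:
    return GenomeSpec([("chrX", 2_000_000, "X"),
                       ("chr2", 3_000_000, "autosome"),
                       ("chr3", 3_000_000, "autosome")])


@dataclass
class SimulationConfig:
    """All knobs of the generative model, with study-like defaults."""

    seed: int = 0
    genome: GenomeSpec = field(default_factory=default_genome)
    n_peaks_per_chrom: int = 200
    peak_width: int = 400
    baseline_mu: float = 50.0       # expected fragments/peak/replicate
    dispersion: float = 0.05        # NB alpha
    replicates: int = 2
    frac_dcc_sites_on_x: float = 0.10
    dcc_boost: float = 2.0
    n_open_planted: int = 40
    n_closed_planted: int = 30
    planted_abs_log2fc: float = 2.0
    cell_fraction_range: tuple[float, float] = (0.5, 1.0)
    background_rate: float = 1e-4   # fragments/bp genome-wide per sample
    fragment_length_mix: tuple = ((0.65, 80.0, 25.0), (0.35, 200.0, 40.0))
    motif_plant_prob: dict = field(default_factory=lambda: {
        "FruM_closed": 0.8, "FruM_open": 0.1, "unchanged": 0.1, "DCC": 0.1})
    gc_content: float = 0.42
    size_factor_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        if self.planted_abs_log2fc < 0:
            raise ValueError("planted_abs_log2fc must be >= 0")
        if self.dcc_boost < 1:
            raise ValueError("dcc_boost must be >= 1")
        if not (0 < self.cell_fraction_range[0] <= self.cell_fraction_range[1] <= 1):
            raise ValueError("cell_fraction_range must satisfy 0 < low <= high <= 1")
        for p in self.motif_plant_prob.values():
            if not 0 <= p <= 1:
                raise ValueError("motif plant probabilities must be in [0,1]")


@dataclass
class SimulationTruth:
    """Ground truth: planted peak classes, factors, and tether sites."""

    peaks: pd.DataFrame       # one row per peak
    tether_sites: list[GenomicInterval]
    samples: pd.DataFrame     # sample id, condition, replicate, size factor

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak_id)
            for r in self.peaks.itertuples()
        ]


@dataclass
class CountMatrix:
    """Integer fragments-per-region-per-sample with stratum labels."""

    regions: list[GenomicInterval]
    strata: np.ndarray            # per-region "X"/"autosome"
    samples: pd.DataFrame         # columns: sample_id, condition, replicate
    counts: np.ndarray            # regions x samples, int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape mismatch")

    def sample_ids(self, condition: str | None = None) -> list[str]:
        df = self.samples
        if condition is not None:
            df = df[df["condition"] == condition]
        return list(df["sample_id"])

    def column(self, sample_id: str) -> np.ndarray:
        idx = list(self.samples["sample_id"]).index(sample_id)
        return self.counts[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=list(self.samples["sample_id"])
        )
        df.insert(0, "chrom", [r.chrom for r in self.regions])
        df.insert(1, "start", [r.start for r in self.regions])
        df.insert(2, "end", [r.end for r in self.regions])
        df.insert(3, "stratum", self.strata)
        return df


def _sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = config.size_factor_range
    for cond in CONDITIONS:
        for rep in range(1, config.replicates + 1):
            s = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rows.append({"sample_id": f"{cond}_rep{rep}", "condition": cond,
                         "replicate": rep, "size_factor": s})
    return pd.DataFrame(rows)


def _layout_peaks(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Evenly spaced non-overlapping peaks with jitter, plus class labels."""
    rows = []
    for chrom, length, stratum in config.genome.chroms:
        n = config.n_peaks_per_chrom
        slot = length // (n + 1)
        if slot <= config.peak_width:
            raise ValueError(f"{chrom}: too many peaks for chromosome length")
        for i in range(n):
            center = (i + 1) * slot + int(rng.integers(-slot // 4, slot // 4 + 1))
            start = max(0, center - config.peak_width // 2)
            end = min(length, start + config.peak_width)
            rows.append({"peak_id": f"{chrom}_peak{i:04d}", "chrom": chrom,
                         "start": start, "end": end, "stratum": stratum})
    peaks = pd.DataFrame(rows)

    # class assignment: DCC on X only; FruM classes autosomal only by default
    peaks["peak_class"] = "unchanged"
    x_idx = peaks.index[peaks["stratum"] == "X"].to_numpy()
    n_dcc = int(round(config.frac_dcc_sites_on_x * len(x_idx)))
    dcc = rng.choice(x_idx, size=n_dcc, replace=False)
    peaks.loc[dcc, "peak_class"] = "DCC"

    auto_idx = peaks.index[peaks["stratum"] == "autosome"].to_numpy()
    n_planted = config.n_open_planted + config.n_closed_planted
    if n_planted > len(auto_idx):
        raise ValueError("planted peak count exceeds available autosomal peaks")
    chosen = rng.choice(auto_idx, size=n_planted, replace=False)
    peaks.loc[chosen[: config.n_open_planted], "peak_class"] = "FruM_open"
    peaks.loc[chosen[config.n_open_planted:], "peak_class"] = "FruM_closed"
    return peaks


def expected_counts(config: SimulationConfig, peaks: pd.DataFrame,
                    samples: pd.DataFrame,
                    cell_fraction: np.ndarray) -> np.ndarray:
    """The mean matrix mu_ij = s_j * f_i * mu_base * x_ij * d_ij * g_ij."""
    n_peaks, n_samples = len(peaks), len(samples)
    mu = np.empty((n_peaks, n_samples))
    is_x = (peaks["stratum"] == "X").to_numpy()
    is_dcc = (peaks["peak_class"] == "DCC").to_numpy()
    is_open = (peaks["peak_class"] == "FruM_open").to_numpy()
    is_closed = (peaks["peak_class"] == "FruM_closed").to_numpy()
    delta = config.planted_abs_log2fc
    for j, srow in enumerate(samples.itertuples()):
        female = srow.condition.startswith("female")
        male_fruplus = srow.condition == "male_fru_plus"
        x_factor = np.where(is_x & female, 2.0, 1.0)
        d_factor = np.where(is_dcc & (not female), config.dcc_boost, 1.0)
        g_factor = np.ones(n_peaks)
        if male_fruplus:
            g_factor = np.where(is_open, 2.0 ** delta, g_factor)
            g_factor = np.where(is_closed, 2.0 ** (-delta), g_factor)
        mu[:, j] = (srow.size_factor * cell_fraction * config.baseline_mu
                    * x_factor * d_factor * g_factor)
    return mu


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _true_log2fc(peaks: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-comparison true log2 fold change (target/reference) per peak."""
    delta = config.planted_abs_log2fc
    is_x = (peaks["stratum"] == "X").to_numpy()
    is_dcc = (peaks["peak_class"] == "DCC").to_numpy()
    is_open = (peaks["peak_class"] == "FruM_open").to_numpy()
    is_closed = (peaks["peak_class"] == "FruM_closed").to_numpy()
    out = {}
    for comp, (target, ref) in COMPARISONS.items():
        t_female = target.startswith("female")
        r_female = ref.startswith("female")
        lfc = np.zeros(len(peaks))
        # X copy number (within-stratum normalization removes the genome-wide
        # depth component, but per-peak dosage differences remain for DCC)
        lfc += np.where(is_x & t_female, 1.0, 0.0) - np.where(is_x & r_female, 1.0, 0.0)
        boost = np.log2(config.dcc_boost)
        lfc += (np.where(is_dcc & (not t_female), boost, 0.0)
                - np.where(is_dcc & (not r_female), boost, 0.0))
        t_g = np.where(is_open, delta, 0.0) - np.where(is_closed, delta, 0.0)
        lfc += np.where(target == "male_fru_plus", t_g, 0.0)
        lfc -= np.where(ref == "male_fru_plus", t_g, 0.0)
        out[f"true_log2fc_{comp}"] = lfc
    return pd.DataFrame(out)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """Draw the peak x sample NB count matrix and its ground truth."""
    rng = np.random.default_rng(config.seed)
    samples = _sample_sheet(config, rng)
    peaks = _layout_peaks(config, rng)
    f = rng.uniform(*config.cell_fraction_range, size=len(peaks))
    mu = expected_counts(config, peaks, samples, f)
    counts = _nb_draw(rng, mu, config.dispersion)

    peaks = peaks.copy()
    peaks["cell_fraction"] = f
    peaks = pd.concat([peaks, _true_log2fc(peaks, config)], axis=1)
    peaks["motif_planted"] = False
    peaks["motif_position"] = -1

    tether = [
        GenomicInterval(r.chrom, r.start + (r.end - r.start) // 2,
                        r.start + (r.end - r.start) // 2 + 1, name=r.peak_id)
        for r in peaks.itertuples() if r.peak_class == "DCC"
    ]
    regions = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak_id)
        for r in peaks.itertuples()
    ]
    cm = CountMatrix(regions=regions, strata=peaks["stratum"].to_numpy(),
                     samples=samples[["sample_id", "condition", "replicate"]].copy(),
                     counts=counts)
    truth = SimulationTruth(peaks=peaks, tether_sites=tether, samples=samples)
    return cm, truth


def _draw_lengths(rng: np.random.Generator, n: int, mix) -> np.ndarray:
    """Two-component normal mixture of fragment lengths, truncated >= 20."""
    weights = np.array([m[0] for m in mix])
    weights = weights / weights.sum()
    comp = rng.choice(len(mix), size=n, p=weights)
    lengths = np.empty(n)
    for k, (_, mean, sd) in enumerate(mix):
        mask = comp == k
        lengths[mask] = rng.normal(mean, sd, size=int(mask.sum()))
    lengths = np.maximum(np.rint(lengths), 20).astype(np.int64)
    return lengths


def simulate_fragments(config: SimulationConfig, counts: CountMatrix,
                       ) -> dict[str, pd.DataFrame]:
    """Per-sample fragment tables (BED columns + origin flag).

    Peak fragments have midpoints uniform within their peak so that
    re-counting midpoints reproduces the count matrix exactly; background
    fragments are uniform genome-wide at ``background_rate`` per bp.
    Fragments are clipped to chromosome bounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genome = config.genome
    out = {}
    for j, srow in enumerate(counts.samples.itertuples()):
        chroms, starts, ends, names = [], [], [], []
        for i, region in enumerate(counts.regions):
            k = int(counts.counts[i, j])
            if k == 0:
                continue
            mids = rng.integers(region.start, region.end, size=k)
            lens = _draw_lengths(rng, k, config.fragment_length_mix)
            s = mids - lens // 2
            e = s + lens
            clen = genome.length(region.chrom)
            s = np.maximum(s, 0)
            e = np.minimum(e, clen)
            chroms.extend([region.chrom] * k)
            starts.extend(s.tolist())
            ends.extend(e.tolist())
            names.extend([f"peak:{region.name}"] * k)
        # background, uniform genome-wide
        for chrom, clen, _ in genome.chroms:
            n_bg = rng.poisson(config.background_rate * clen)
            if n_bg == 0:
                continue
            mids = rng.integers(0, clen, size=n_bg)
            lens = _draw_lengths(rng, n_bg, config.fragment_length_mix)
            s = np.maximum(mids - lens // 2, 0)
            e = np.minimum(s + lens, clen)
            chroms.extend([chrom] * int(n_bg))
            starts.extend(s.tolist())
            ends.extend(e.tolist())
            names.extend(["background"] * int(n_bg))
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends,
                           "name": names})
        # fix rare clip-induced empties
        df.loc[df["end"] <= df["start"], "end"] = df["start"] + 20
        out[srow.sample_id] = df
    return out


def write_fragment_beds(fragments: dict[str, pd.DataFrame], outdir) -> dict[str, str]:
    from pathlib import Path
    paths = {}
    for sample_id, df in fragments.items():
        p = Path(outdir) / f"fragments_{sample_id}.bed"
        bed = df.copy()
        bed["score"] = 0
        bed["strand"] = "."
        bed.to_csv(p, sep="\t", header=False, index=False)
        paths[sample_id] = str(p)
    return paths


def simulate_sequences(config: SimulationConfig, truth: SimulationTruth,
                       motif: PWM) -> list[tuple[str, str]]:
    """Peak sequences with class-dependent motif planting.

    Background bases are i.i.d. at the configured GC content; with
    probability ``motif_plant_prob[class]`` the motif consensus is embedded
    at a uniform position on a uniform strand. Planted flag and position
    are recorded in the truth table (mutated in place).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    consensus = motif.consensus
    w = len(consensus)
    records = []
    planted_flags, positions = [], []
    class_map = {"opened": "FruM_open", "closed": "FruM_closed"}
    for row in truth.peaks.itertuples():
        length = row.end - row.start
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=base_p)])
        cls = row.peak_class
        prob = config.motif_plant_prob.get(cls, 0.0)
        planted, pos = False, -1
        if rng.uniform() < prob:
            if length < w:
                import warnings
                warnings.warn(
                    f"peak {row.peak_id} shorter than motif; planting skipped"
                )
            else:
                pos = int(rng.integers(0, length - w + 1))
                ins = consensus if rng.uniform() < 0.5 else reverse_complement(consensus)
                seq = seq[:pos] + ins + seq[pos + w:]
                planted = True
        planted_flags.append(planted)
        positions.append(pos)
        label = {"FruM_open": "opened", "FruM_closed": "closed"}.get(cls, "unchanged")
        records.append((f"{row.peak_id} class={label}", seq))
    truth.peaks["motif_planted"] = planted_flags
    truth.peaks["motif_position"] = positions
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def simulate_genes(config: SimulationConfig, genes_per_chrom: int = 60,
                   n_exons: tuple[int, int] = (2, 6),
                   exon_len: tuple[int, int] = (150, 800),
                   intron_len: tuple[int, int] = (200, 3000),
                   ) -> list["GeneModel"]:
    """Non-overlapping multi-exon gene models tiled along each chromosome."""
    from .intervals import GeneModel
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = []
    for chrom, length, _ in config.genome.chroms:
        slot = length // (genes_per_chrom + 1)
        for i in range(genes_per_chrom):
            start = (i + 1) * slot - slot // 3
            pos = start
            exons = []
            k = int(rng.integers(n_exons[0], n_exons[1] + 1))
            for _ in range(k):
                elen = int(rng.integers(*exon_len))
                if pos + elen > min((i + 2) * slot, length):
                    break
                exons.append((pos, pos + elen))
                pos += elen + int(rng.integers(*intron_len))
            if not exons:
                continue
            strand = "+" if rng.uniform() < 0.5 else "-"
            gid = f"{chrom}_gene{i:03d}"
            genes.append(GeneModel(
                gid, chrom, strand,
                [GenomicInterval(chrom, s, e, name=gid, strand=strand)
                 for s, e in exons],
            ))
    return genes


def simulate_fru_like_locus(seed: int = 0, n_enhancers: int = 10,
                            n_other_genes: int = 25,
                            baseline_mu: float = 50.0,
                            dispersion: float = 0.05,
                            ) -> tuple[SimulationConfig, CountMatrix,
                                       SimulationTruth, "list"]:
    """A 100-kb multi-intron gene whose intronic enhancers open only in
    male fru+ cells, among ordinary single-peak genes.

    Models a long locus dense with small condition-specific regulatory
    elements: no single enhancer dominates, but aggregated over the whole
    gene span the condition difference is large. Returns (config, counts,
    truth, gene models); fragments follow via :func:`simulate_fragments`.
    """
    from .intervals import GeneModel
    genome = GenomeSpec([("chr2", 3_000_000, "autosome")])
    config = SimulationConfig(
        seed=seed, genome=genome, baseline_mu=baseline_mu,
        dispersion=dispersion, cell_fraction_range=(1.0, 1.0),
        n_open_planted=0, n_closed_planted=0, frac_dcc_sites_on_x=0.0,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))

    gene_start, gene_end = 1_000_000, 1_100_000
    n_exons = 8
    exon_starts = np.linspace(gene_start, gene_end - 500, n_exons).astype(int)
    fru_like = GeneModel(
        "fru_like", "chr2", "+",
        [GenomicInterval("chr2", int(s), int(s) + 400, name="fru_like",
                         strand="+") for s in exon_starts],
    )
    genes = [fru_like]
    rows = []
    # intronic enhancers, open only in male fru+ (class FruM_open)
    enh_pos = np.linspace(gene_start + 2000, gene_end - 2000, n_enhancers).astype(int)
    for k, pos in enumerate(enh_pos):
        rows.append({"peak_id": f"enh{k:02d}", "chrom": "chr2",
                     "start": int(pos), "end": int(pos) + 400,
                     "stratum": "autosome", "peak_class": "FruM_open"})
    # ordinary genes elsewhere, one unchanged promoter peak each
    slot = 60_000
    for k in range(n_other_genes):
        s = 1_200_000 + k * slot
        gid = f"other{k:02d}"
        genes.append(GeneModel(
            gid, "chr2", "+",
            [GenomicInterval("chr2", s, s + 600, name=gid, strand="+"),
             GenomicInterval("chr2", s + 4000, s + 4600, name=gid, strand="+")],
        ))
        rows.append({"peak_id": f"prom_{gid}", "chrom": "chr2",
                     "start": s - 200, "end": s + 200,
                     "stratum": "autosome", "peak_class": "unchanged"})
    peaks = pd.DataFrame(rows)

    samples = _sample_sheet(config, rng)
    f = np.ones(len(peaks))
    mu = expected_counts(config, peaks, samples, f)
    counts = _nb_draw(rng, mu, config.dispersion)
    peaks = peaks.copy()
    peaks["cell_fraction"] = f
    peaks = pd.concat([peaks, _true_log2fc(peaks, config)], axis=1)
    regions = [GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak_id)
               for r in peaks.itertuples()]
    cm = CountMatrix(regions=regions, strata=peaks["stratum"].to_numpy(),
                     samples=samples[["sample_id", "condition", "replicate"]].copy(),
                     counts=counts)
    truth = SimulationTruth(peaks=peaks, tether_sites=[], samples=samples)
    return config, cm, truth, genes


# ---------------------------------------------------------------------------
# expression arm
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int = 1000,
    seed: int = 0,
    replicates: int = 2,
    baseline_mu: float = 100.0,
    dispersion: float = 0.05,
    female_biased_genes: list[int] | None = None,
    delta_expr: float = 0.5,
    gene_lengths: np.ndarray | None = None,
    accessibility: np.ndarray | None = None,
    accessibility_slope: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level RNA counts for the four conditions.

    ``female_biased_genes`` get a +delta_expr log2 shift in female samples
    (models the observed female bias of genes near Fru^M-closed elements).
    If a per-gene ``accessibility`` vector is given, baseline expression is
    mildly coupled to it (slope on the standardized log scale), so
    accessibility and expression correlate without being redundant.
    Returns (counts wide table with gene_id/length, sample sheet).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if gene_lengths is None:
        gene_lengths = rng.integers(500, 10_000, size=n_genes)
    shift = 0.0
    if accessibility is not None:
        a = np.log10(np.asarray(accessibility, dtype=float) + 1)
        sd = a.std()
        if sd > 0:
            shift = accessibility_slope * (a - a.mean()) / sd * np.log(10)
    base = rng.lognormal(mean=np.log(baseline_mu) + shift, sigma=1.0,
                         size=n_genes)
    bias = np.zeros(n_genes)
    if female_biased_genes is not None:
        bias[np.asarray(female_biased_genes, dtype=int)] = delta_expr
    rows = {"gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "length": gene_lengths}
    sheet = []
    for cond in CONDITIONS:
        female = cond.startswith("female")
        for rep in range(1, replicates + 1):
            mu = base * (2.0 ** bias if female else 1.0)
            sid = f"{cond}_rna_rep{rep}"
            rows[sid] = _nb_draw(rng, mu, dispersion)
            sheet.append({"sample_id": sid, "condition": cond, "replicate": rep})
    return pd.DataFrame(rows), pd.DataFrame(sheet)
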