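"""Readers and writers for BED, GTF (exon rows), MEME minimal motifs,
bedGraph tracks, and tab-separated tables.

All parsers validate strictly and report the offending line number; files
whose chromosomes are checked against a :class:`GenomeSpec` fail hard on
unknown names rather than silently dropping records.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomeSpec, GenomicInterval


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, format: str = "BED6") -> list[GenomicInterval]:
    """Read a BED3 or BED6 file into a list of intervals, order preserved."""
    if format not in ("BED3", "BED6"):
        raise ValueError(f"unsupported format {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            want = 3 if format == "BED3" else 6
            if len(fields) < want:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {want} tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: empty or inverted interval {start}-{end}"
                )
            name = score = None
            strand = "."
            if format == "BED6":
                name = fields[3] or None
                try:
                    score = float(fields[4]) if fields[4] not in (".", "") else None
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
                strand = fields[5]
                if strand not in ("+", "-", "."):
                    raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                out.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(path: str | Path, intervals: list[GenomicInterval],
                    format: str = "BED6") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if format == "BED3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "0" if iv.score is None else f"{iv.score:g}"
                name = iv.name if iv.name is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def check_chroms(intervals: list[GenomicInterval], genome: GenomeSpec) -> None:
    """Unknown chromosomes are a hard error: stratum assignment must be total."""
    known = set(genome.names)
    for iv in intervals:
        if iv.chrom not in known:
            raise ValueError(
                f"interval on chromosome {iv.chrom!r} absent from genome spec"
            )


# ---------------------------------------------------------------------------
# GTF (exon rows only)
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Build one GeneModel per gene_id from GTF exon rows.

    GTF coordinates are 1-based inclusive; converted here to 0-based
    half-open. Rows whose feature is not ``exon`` are ignored.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise ParseError(f"{path}:{lineno}: exon without gene_id attribute")
            gene_id = m.group(1)
            try:
                s0, e0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if gene_id in meta:
                pchrom, pstrand = meta[gene_id]
                if strand != pstrand:
                    raise ParseError(
                        f"{path}:{lineno}: gene {gene_id} has mixed strands"
                    )
                if chrom != pchrom:
                    raise ParseError(
                        f"{path}:{lineno}: gene {gene_id} spans chromosomes"
                    )
            else:
                meta[gene_id] = (chrom, strand)
            exons.setdefault(gene_id, []).append(
                GenomicInterval(chrom, s0, e0, name=gene_id, strand=strand)
            )
    models = [
        GeneModel(g, meta[g][0], meta[g][1], exons[g]) for g in sorted(exons)
    ]
    return models


def write_gene_models(path: str | Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for i, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tdimorphatac\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f'{g.strand}\t.\tgene_id "{g.gene_id}"; exon_number "{i}";\n'
                )


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_motifs(path: str | Path, pseudocount: float = 0.1):
    """Parse PWMs from MEME minimal text (ACGT alphabet).

    Column sums are validated to 1 +/- 1e-3 then renormalized exactly.
    Returns a list of :class:`~dimorphatac.motif.PWM`.
    """
    from .motif import PWM  # local import avoids a cycle

    text = Path(path).read_text()
    lines = text.splitlines()
    background = np.full(4, 0.25)
    for i, line in enumerate(lines):
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
            break

    motifs = []
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            toks = lines[i].split()
            motif_id = toks[1] if len(toks) > 1 else f"motif_{len(motifs) + 1}"
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].startswith("letter-probability"):
                j += 1
            if j == len(lines):
                raise ParseError(f"{path}: MOTIF {motif_id} lacks a probability matrix")
            rows = []
            j += 1
            while j < len(lines):
                stripped = lines[j].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = stripped.split()
                if len(vals) != 4:
                    raise ParseError(
                        f"{path}:{j + 1}: expected 4 probabilities per matrix row"
                    )
                rows.append([float(v) for v in vals])
                j += 1
            if not rows:
                raise ParseError(f"{path}: MOTIF {motif_id} has width 0")
            probs = np.array(rows)  # width x 4
            sums = probs.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-3)[0]
            if bad.size:
                raise ParseError(
                    f"{path}: MOTIF {motif_id} column {bad[0]} sums to "
                    f"{sums[bad[0]]:.4f}, outside 1 +/- 1e-3"
                )
            probs = probs / sums[:, None]
            motifs.append(
                PWM(motif_id=motif_id, probs=probs, background=background.copy(),
                    pseudocount=pseudocount)
            )
            i = j
        else:
            i += 1
    if not motifs:
        raise ParseError(f"{path}: no MOTIF records found")
    return motifs


def write_motifs(path: str | Path, pwms) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in pwm.probs:
                fh.write(" ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, genome: GenomeSpec) -> dict[str, np.ndarray]:
    """Load a bedGraph as per-base float arrays, one per chromosome.

    Overlapping lines are an error; uncovered positions are 0.
    """
    tracks = {name: np.zeros(length) for name, length, _ in genome.chroms}
    covered = {name: np.zeros(length, dtype=bool) for name, length, _ in genome.chroms}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in tracks:
                raise ValueError(
                    f"{path}:{lineno}: chromosome {chrom!r} absent from genome spec"
                )
            if end > len(tracks[chrom]):
                raise ParseError(f"{path}:{lineno}: interval exceeds chromosome length")
            if covered[chrom][start:end].any():
                raise ParseError(f"{path}:{lineno}: overlapping bedGraph lines")
            covered[chrom][start:end] = True
            tracks[chrom][start:end] = value
    return tracks


def write_bedgraph(path: str | Path, tracks: dict[str, np.ndarray]) -> None:
    """Write per-base arrays as run-length-collapsed bedGraph (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom, arr in tracks.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
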