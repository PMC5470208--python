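"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA in/out goes through Biopython; interval tracks are written as BED /
bedGraph, reads as 3-column TSV (chrom, pos, count), and contact matrices
as dense TSV with a header row and column of bin start coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .boundaries import BoundaryConsensus, ContactMatrix
from .fragmap import FragmentMap
from .peaks import PeakSet


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fragmap_bed(fmap: FragmentMap, path: str | Path) -> None:
    """BED with name=index, score=length and blind/short flags as extra columns."""
    with open(path, "w") as fh:
        for chrom, frs in fmap.fragments.items():
            for f in frs:
                fh.write(f"{chrom}\t{f.start}\t{f.end}\t{f.index}\t{f.length}"
                         f"\t{int(f.blind)}\t{int(f.short)}\n")


def read_reads_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "count"],
                     dtype={"chrom": str, "pos": int, "count": int},
                     comment="#")
    return list(df.itertuples(index=False, name=None))


def write_reads_tsv(reads: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, count in reads:
            fh.write(f"{chrom}\t{pos}\t{count}\n")


def write_bedgraph(profile, layer: str, path: str | Path,
                   chrom: str | None = None) -> None:
    """One bedGraph per profile layer; intervals are single end coordinates."""
    vals = getattr(profile, layer)
    if vals is None:
        raise ValueError(f"layer {layer!r} not filled")
    chrom = chrom or profile.viewpoint.chrom
    name = f"{profile.viewpoint.name}_{layer}"
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for e, v in zip(profile.ends, vals):
            fh.write(f"{chrom}\t{e}\t{e + 1}\t{v:.6g}\n")


def write_peaks_bed(pset: PeakSet, path: str | Path) -> None:
    """BED6; score is the max residual scaled to [0, 1000] across the set."""
    top = max((p.max_residual for p in pset.peaks), default=0.0)
    with open(path, "w") as fh:
        for rank, p in enumerate(sorted(pset.peaks,
                                        key=lambda q: -q.max_residual), 1):
            score = int(round(1000 * p.max_residual / top)) if top > 0 else 0
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{rank}\t{score}\t.\n")


def write_matrix_tsv(m: ContactMatrix, path: str | Path) -> None:
    n = m.n_bins
    starts = m.origin[1] + np.arange(n) * m.bin_size
    df = pd.DataFrame(m.values, index=starts, columns=starts)
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, chrom: str = "region") -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    starts = df.index.to_numpy(dtype=int)
    bin_size = int(starts[1] - starts[0]) if starts.size > 1 else 1
    return ContactMatrix(values=df.to_numpy(dtype=float), bin_size=bin_size,
                         origin=(chrom, int(starts[0])))


def write_di_bedgraph(track, m: ContactMatrix, path: str | Path) -> None:
    chrom, start = m.origin
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="DI_w{track.window_bins}"\n')
        for i, v in enumerate(track.di):
            a = start + i * m.bin_size
            fh.write(f"{chrom}\t{a}\t{a + m.bin_size}\t{v:.6g}\n")


def write_boundaries_bed(cons: BoundaryConsensus, m: ContactMatrix,
                         path: str | Path, selected_only: bool = True) -> None:
    """BED with the per-candidate support fraction in the score column."""
    chrom, start = m.origin
    items = cons.selected if selected_only else cons.candidates
    with open(path, "w") as fh:
        for c in items:
            a = start + c.bin * m.bin_size
            fh.write(f"{chrom}\t{a}\t{a + m.bin_size}\tboundary"
                     f"\t{c.support:.3f}\t.\n")


def write_segments_tsv(dg, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tsource_start\tsource_end\tderivative_start\n")
        for src, s0, s1, off in dg.segments:
            fh.write(f"{src}\t{s0}\t{s1}\t{off}\n")


def write_models_tsv(er, path: str | Path) -> None:
    """Kept-cluster models as XYZ-style TSV plus a score manifest column."""
    with open(path, "w") as fh:
        fh.write("model\tscore\tparticle\tx\ty\tz\n")
        members = (er.clusters.get(er.kept_cluster, er.selected)
                   if er.kept_cluster is not None else er.selected)
        for mi in members:
            m = er.models[mi]
            for p, (x, y, z) in enumerate(m.coords):
                fh.write(f"{mi}\t{m.score:.6g}\t{p}\t{x:.6g}\t{y:.6g}\t{z:.6g}\n")
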