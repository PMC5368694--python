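"""Operon binning and RPKM normalisation.

Operon sequences are partitioned into consecutive 300-nt bins in
*transcript* orientation: bin 0 always sits at the 5' end of the
transcription unit, regardless of genomic strand, so that bin onset
times increase with distance from the promoter.  Transcript coordinates
are 1-based inclusive ("bin 0 = 1-300 nt"); genomic I/O follows each
format's native convention (BED 0-based half-open, GFF3 1-based
inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:
    from .synthetic import TimeSeriesDesign

__all__ = [
    "OperonAnnotation",
    "Bin",
    "BinnedExpression",
    "partition_operon",
    "counts_to_rpkm",
    "bin_counts_from_intervals",
    "read_counts_tsv",
    "transcript_to_genomic",
    "read_operons_bed",
    "read_operons_gff3",
    "attach_sequences",
    "reads_from_sam",
]

BIN_SIZE_DEFAULT = 300


@dataclass(frozen=True)
class Bin:
    """One bin in transcript coordinates (1-based inclusive)."""

    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        """Mean position of the bin, nt from the transcription start.

        Defined as (start - 1 + end) / 2 so that bin 2401-2700 has
        midpoint 2550.
        """
        return (self.start - 1 + self.end) / 2


@dataclass
class OperonAnnotation:
    """Genomic location and sequence of one transcription unit."""

    name: str
    chrom: str
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    genes: tuple[str, ...] = ()
    sequence: str | None = None  # 5'->3' of the transcript

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.name}: end < start")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be + or -")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != "
                f"annotation length {self.length}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class BinnedExpression:
    """Counts and RPKM per bin x timepoint x replicate for one operon."""

    operon: str
    bins: list[Bin]
    counts: np.ndarray  # (n_bins, n_times, n_reps) int
    rpkm: np.ndarray  # same shape, float
    design: "TimeSeriesDesign"

    def __post_init__(self) -> None:
        nb = len(self.bins)
        if self.counts.shape[0] != nb or self.rpkm.shape[0] != nb:
            raise ValueError("counts/rpkm first axis must match bins")
        if np.any(self.rpkm < 0):
            raise ValueError("rpkm must be nonnegative")

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bins])

    def replicate_mean_rpkm(self) -> np.ndarray:
        """(n_bins, n_times) mean over replicates."""
        return self.rpkm.mean(axis=2)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: operon, bin, coordinates, time, replicate, count, rpkm."""
        nb, nt, nr = self.counts.shape
        bi, ti, ri = np.meshgrid(np.arange(nb), np.arange(nt), np.arange(nr),
                                 indexing="ij")
        return pd.DataFrame({
            "operon": self.operon,
            "bin_index": bi.ravel(),
            "bin_start": np.array([b.start for b in self.bins])[bi.ravel()],
            "bin_end": np.array([b.end for b in self.bins])[bi.ravel()],
            "time_s": np.asarray(self.design.sample_times)[ti.ravel()],
            "replicate": ri.ravel() + 1,
            "count": self.counts.ravel(),
            "rpkm": self.rpkm.ravel(),
        })


def partition_operon(annotation: OperonAnnotation | int,
                     bin_size: int = BIN_SIZE_DEFAULT) -> list[Bin]:
    """Split an operon into consecutive bins of ``bin_size`` nt.

    Accepts an annotation or a plain transcript length.  Bin 0 starts at
    transcript position 1 (the 5' end); the last bin is truncated to the
    operon end.  An operon shorter than one bin yields a single short
    bin with a warning.
    """
    length = annotation if isinstance(annotation, int) else annotation.length
    if length < 1:
        raise ValueError("operon length must be >= 1")
    if length < bin_size:
        warnings.warn(
            f"operon length {length} < bin size {bin_size}: single short bin",
            stacklevel=2)
    starts = np.arange(1, length + 1, bin_size)
    return [Bin(index=i, start=int(s), end=int(min(s + bin_size - 1, length)))
            for i, s in enumerate(starts)]


def counts_to_rpkm(count, library_size, feature_length):
    """Reads per kilobase per million mapped reads.

    RPKM = count / (library_size/1e6 * feature_length/1e3).  Accepts
    scalars or broadcastable arrays.
    """
    count = np.asarray(count, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    feature_length = np.asarray(feature_length, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    if np.any(feature_length <= 0):
        raise ValueError("feature length must be positive")
    out = count / (library_size / 1e6 * feature_length / 1e3)
    return float(out) if out.ndim == 0 else out


def transcript_to_genomic(annotation: OperonAnnotation, position: int) -> int:
    """Map a 1-based transcript position to its genomic coordinate."""
    if not 1 <= position <= annotation.length:
        raise ValueError(f"transcript position {position} outside operon")
    if annotation.strand == "+":
        return annotation.start + position - 1
    return annotation.end - position + 1


def bin_genomic_interval(annotation: OperonAnnotation,
                         b: Bin) -> tuple[int, int]:
    """Genomic (start, end), 1-based inclusive, covered by a bin."""
    g1 = transcript_to_genomic(annotation, b.start)
    g2 = transcript_to_genomic(annotation, b.end)
    return (min(g1, g2), max(g1, g2))


def bin_counts_from_intervals(reads: Iterable[tuple],
                              bins: Sequence[Bin],
                              annotation: OperonAnnotation) -> tuple[np.ndarray, int]:
    """Assign read intervals to bins by their 5'-most transcribed base.

    ``reads`` are tuples ``(chrom, start, end)`` in genomic 1-based
    inclusive coordinates.  A read is counted in the single bin
    containing its 5'-most base in transcript orientation (genomic start
    for a plus-strand operon, genomic end for minus), so straddling
    reads are never double-counted.  Reads on another chromosome or
    whose 5' base falls outside the operon are ignored.

    Returns (counts per bin, number of ignored reads).
    """
    bin_size = bins[0].length if len(bins) == 1 else bins[1].start - bins[0].start
    counts = np.zeros(len(bins), dtype=int)
    ignored = 0
    for read in reads:
        chrom, start, end = read[0], int(read[1]), int(read[2])
        if chrom != annotation.chrom:
            ignored += 1
            continue
        g5 = start if annotation.strand == "+" else end
        if not annotation.start <= g5 <= annotation.end:
            ignored += 1
            continue
        t = (g5 - annotation.start + 1 if annotation.strand == "+"
             else annotation.end - g5 + 1)
        counts[(t - 1) // bin_size] += 1
    if ignored:
        warnings.warn(f"{ignored} reads ignored (wrong chromosome or outside "
                      f"operon {annotation.name})", stacklevel=2)
    return counts, ignored


def read_counts_tsv(counts_path, library_sizes_path) -> list[BinnedExpression]:
    """Rebuild binned expression objects from the long-format TSVs.

    Inverse of the synthetic module's writers: the counts table carries
    (operon, bin_index, bin_start, bin_end, time_s, replicate, count),
    the library-size table (time_s, replicate, library_size).  RPKM is
    recomputed from counts and library sizes.
    """
    from .synthetic import TimeSeriesDesign

    counts = pd.read_csv(counts_path, sep="\t")
    libs = pd.read_csv(library_sizes_path, sep="\t")
    times = np.sort(libs["time_s"].unique())
    reps = np.sort(libs["replicate"].unique())
    lib = (libs.pivot(index="time_s", columns="replicate",
                      values="library_size")
           .loc[times, reps].to_numpy())
    design = TimeSeriesDesign(sample_times=tuple(float(t) for t in times),
                              n_replicates=len(reps), library_sizes=lib)
    out = []
    for operon, grp in counts.groupby("operon", sort=False):
        binfo = (grp[["bin_index", "bin_start", "bin_end"]]
                 .drop_duplicates().sort_values("bin_index"))
        bins = [Bin(index=int(r.bin_index), start=int(r.bin_start),
                    end=int(r.bin_end)) for r in binfo.itertuples()]
        arr = (grp.pivot_table(index="bin_index", columns=["time_s", "replicate"],
                               values="count", aggfunc="first")
               .loc[[b.index for b in bins]])
        c = arr.to_numpy().reshape(len(bins), len(times), len(reps)).astype(np.int64)
        lengths = np.array([b.length for b in bins], dtype=float)
        rpkm = counts_to_rpkm(c, lib[None, :, :], lengths[:, None, None])
        out.append(BinnedExpression(operon=str(operon), bins=bins, counts=c,
                                    rpkm=rpkm, design=design))
    return out


def read_operons_bed(path) -> list[OperonAnnotation]:
    """Operon annotations from BED (0-based half-open -> 1-based inclusive)."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=cols, usecols=range(6))
    return [OperonAnnotation(name=str(r.name_), chrom=str(r.chrom),
                             start=int(r.start) + 1, end=int(r.end),
                             strand=str(r.strand))
            for r in df.rename(columns={"name": "name_"}).itertuples()]


def read_operons_gff3(path, feature_type: str = "operon") -> list[OperonAnnotation]:
    """Operon annotations from GFF3 (1-based inclusive, native)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for feat in db.features_of_type(feature_type):
        genes = tuple(feat.attributes.get("genes", []))
        name = (feat.attributes.get("Name") or feat.attributes.get("ID")
                or [feat.id])[0]
        out.append(OperonAnnotation(name=name, chrom=feat.seqid,
                                    start=feat.start, end=feat.end,
                                    strand=feat.strand, genes=genes))
    return out


def attach_sequences(operons: Sequence[OperonAnnotation], fasta_path) -> None:
    """Fill each annotation's transcript sequence from a genome FASTA.

    Minus-strand operons get the reverse complement so the stored
    sequence always reads 5'->3' of the transcript.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq

    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    for op in operons:
        if op.chrom not in genome:
            raise KeyError(f"{op.chrom} not in FASTA")
        seg = genome[op.chrom][op.start - 1:op.end]
        if op.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        op.sequence = seg.upper()


def reads_from_sam(path, chrom: str) -> list[tuple[str, int, int]]:
    """Aligned read intervals (1-based inclusive) from a SAM/BAM file."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name != chrom:
                continue
            out.append((aln.reference_name, aln.reference_start + 1,
                        aln.reference_end))
    return out
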