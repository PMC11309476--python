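"""Haploid genome-size estimation from sequencing-depth spectra.

Two classical estimators are provided:

* **k-mer spectrum method** — locate the main peak of a k-mer frequency
  histogram at depth ``C``; the haploid genome size is ``GS = N / (C * p)``
  where ``N`` is the total number of genomic k-mers (histogram mass at or
  above the error cutoff) and ``p`` the ploidy. Estimates from several k
  values are averaged.
* **Lander-Waterman coverage method** — from reads mapped to a draft
  assembly, ``GS = L * N / C`` with ``L`` the read length, ``N`` the number
  of mapped reads and ``C`` the modal per-contig coverage.

Low-depth k-mers are dominated by sequencing errors (the "error spike" at
depths 1-3); the cutoff separating the spike from the genomic peak is placed
at the first local minimum of a lightly smoothed histogram and can be
overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DepthHistogram",
    "GenomeSizeEstimate",
    "kmer_gs",
    "analyze_kmer_histogram",
    "multi_k_average",
    "coverage_mode",
    "lander_waterman_gs",
    "half_sample_mode",
    "DEFAULT_K_LIST",
]

#: k-mer lengths averaged in the multi-k protocol.
DEFAULT_K_LIST = (17, 19, 21, 23, 25, 27, 29, 31)


class PeakDetectionError(RuntimeError):
    """No usable genomic peak could be located in a depth histogram."""


@dataclass
class DepthHistogram:
    """Two-column depth spectrum (depth -> number of distinct k-mers/bases)."""

    depth: np.ndarray
    count: np.ndarray
    kind: str = "kmer"  # or "coverage"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.float64)
        if self.depth.ndim != 1 or self.depth.shape != self.count.shape:
            raise ValueError("depth and count must be 1-D and equal length")
        if len(self.depth) < 3:
            raise ValueError("histogram needs at least 3 rows")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.depth <= 0):
            raise ValueError("depths must be positive")
        if np.any(self.count < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_tsv(cls, path, kind: str = "kmer") -> "DepthHistogram":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["depth", "count"])
        return cls(df["depth"].to_numpy(), df["count"].to_numpy(), kind=kind)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"depth": self.depth, "count": self.count.astype(np.int64)}) \
            .to_csv(path, sep="\t", index=False, header=False)


@dataclass
class GenomeSizeEstimate:
    gs_bp: float
    n_total: float
    peak_depth: float
    ploidy: int = 1
    read_length: float | None = None
    cutoff: int | None = None
    per_k: dict[int, float] = field(default_factory=dict)


def kmer_gs(n_kmers: float, peak_depth: float, ploidy: int = 1) -> float:
    """Genome size from total genomic k-mers: GS = N / (C * p)."""
    if n_kmers <= 0:
        raise ValueError("total k-mer count N must be positive")
    if peak_depth <= 0:
        raise ValueError("peak depth C must be positive")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return n_kmers / (peak_depth * ploidy)


def _error_cutoff(depth: np.ndarray, count: np.ndarray) -> int:
    """Depth separating the error spike from the genomic peak.

    Works on a 3-bin moving average of the counts (smoothing avoids cutoffs
    at single-bin noise dips): the cutoff is the first minimum of the
    initial descending run, i.e. the valley floor before the first strict
    rise toward the main peak. Zero-count plateaus between spike and peak
    are tolerated. A spectrum that never rises (monotone decreasing or
    flat) has no detectable genomic peak and raises; one that rises
    immediately has no error spike and the cutoff is the smallest depth.
    """
    if len(count) < 3:
        raise PeakDetectionError("histogram too short to locate a minimum")
    kernel = np.ones(3) / 3.0
    padded = np.concatenate([count[:1], count, count[-1:]])  # edge padding
    smooth = np.convolve(padded, kernel, mode="valid")
    rises = np.where(smooth[1:] > smooth[:-1])[0]
    if len(rises) == 0:
        raise PeakDetectionError(
            "no peak detected: smoothed histogram never rises "
            "(monotone spectrum?)"
        )
    first_rise = int(rises[0])
    if first_rise == 0:
        return int(depth[0])  # rises from the start: no error spike
    valley = smooth[: first_rise + 1]
    return int(depth[int(np.argmin(valley))])


def analyze_kmer_histogram(
    hist: DepthHistogram,
    ploidy: int = 1,
    cutoff: int | None = None,
) -> GenomeSizeEstimate:
    """Estimate haploid genome size from a k-mer frequency histogram.

    The error cutoff (first local minimum between the low-depth error spike
    and the genomic peak) is found automatically unless ``cutoff`` is given;
    the peak is the highest-count depth at or above the cutoff, and
    ``N = sum(d * count(d) for d >= cutoff)``.
    """
    if hist.kind != "kmer":
        raise ValueError("analyze_kmer_histogram expects a k-mer histogram")
    d, c = hist.depth, hist.count
    if cutoff is None:
        cutoff = _error_cutoff(d, c)
    keep = d >= cutoff
    if not keep.any() or c[keep].sum() == 0:
        raise PeakDetectionError("all histogram mass lies below the error cutoff")
    peak_depth = float(d[keep][np.argmax(c[keep])])
    n_total = float(np.sum(d[keep] * c[keep]))
    gs = kmer_gs(n_total, peak_depth, ploidy)
    return GenomeSizeEstimate(
        gs_bp=gs, n_total=n_total, peak_depth=peak_depth,
        ploidy=ploidy, cutoff=int(cutoff),
    )


def multi_k_average(per_k: dict[int, float]) -> float:
    """Arithmetic mean of per-k genome-size estimates."""
    if not per_k:
        raise ValueError("per_k map is empty")
    return float(np.mean(list(per_k.values())))


def half_sample_mode(x: np.ndarray) -> float:
    """Robust mode by repeated halving to the densest half-mass interval.

    At each step the narrowest interval of consecutive distinct values
    carrying at least half the total mass is retained (mass = multiplicity,
    so the estimate is exactly invariant to duplicating every observation).
    Two remaining distinct values resolve to the heavier one, or their
    midpoint on equal mass. Robust to the right skew typical of per-contig
    coverage distributions.
    """
    vals, cnts = np.unique(np.asarray(x, dtype=float), return_counts=True)
    cnts = cnts.astype(float)
    while len(vals) > 2:
        half = cnts.sum() / 2.0
        # narrowest contiguous window with mass >= half (two-pointer scan)
        csum = np.concatenate([[0.0], np.cumsum(cnts)])
        best_width = np.inf
        best = (0, len(vals) - 1)
        j = 0
        for i in range(len(vals)):
            if j < i:
                j = i
            while j < len(vals) and csum[j + 1] - csum[i] < half:
                j += 1
            if j == len(vals):
                break
            width = vals[j] - vals[i]
            if width < best_width:
                best_width = width
                best = (i, j)
        i, j = best
        vals, cnts = vals[i : j + 1], cnts[i : j + 1]
    if len(vals) == 1:
        return float(vals[0])
    if cnts[0] > cnts[1]:
        return float(vals[0])
    if cnts[1] > cnts[0]:
        return float(vals[1])
    return float(vals.mean())


@dataclass
class ContigCoverageTable:
    """Per-contig length and mean mapped coverage."""

    frame: pd.DataFrame  # columns: contig_id, length, mean_coverage

    def __post_init__(self) -> None:
        need = {"contig_id", "length", "mean_coverage"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"coverage table needs columns {sorted(need)}")
        if (self.frame["length"] <= 0).any():
            raise ValueError("contig lengths must be positive")
        if (self.frame["mean_coverage"] < 0).any():
            raise ValueError("coverages must be nonnegative")

    @classmethod
    def from_tsv(cls, path) -> "ContigCoverageTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def coverage_mode(table: ContigCoverageTable) -> float:
    """Half-sample mode of the per-contig mean-coverage distribution."""
    cov = table.frame["mean_coverage"].to_numpy(dtype=float)
    if len(cov) < 10:
        raise ValueError(
            f"need >= 10 contigs for a stable mode estimate, got {len(cov)}"
        )
    return half_sample_mode(cov)


def lander_waterman_gs(
    read_length: float,
    n_mapped_reads: float | None = None,
    modal_coverage: float | None = None,
    total_bases: float | None = None,
) -> float:
    """Lander-Waterman genome size GS = L * N / C.

    ``total_bases`` (= L * N) may be supplied instead of ``n_mapped_reads``.
    """
    if modal_coverage is None or modal_coverage <= 0:
        raise ValueError("modal coverage C must be positive")
    if total_bases is None:
        if read_length is None or read_length <= 0:
            raise ValueError("read length L must be positive")
        if n_mapped_reads is None or n_mapped_reads <= 0:
            raise ValueError("mapped read count N must be positive")
        total_bases = read_length * n_mapped_reads
    if total_bases <= 0:
        raise ValueError("total mapped bases must be positive")
    return total_bases / modal_coverage
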