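"""Read-depth preprocessing: binning, N-masking, GC correction, segmentation.

The pipeline here turns a per-bin (or per-base) read-count table into a
GC-corrected, denoised, piecewise-constant read-depth profile:

1. ``bin_and_mask``    — fixed-width bins, GC fraction from the reference,
                         bins touching any 'N' base masked out;
2. ``gc_correct``      — stratified mean-ratio correction
                         (RD'_i = RD_i * RD_m / RD_gc);
3. ``denoise_and_segment`` — exact fused-lasso (total-variation) fit, with
                         maximal constant runs reported as segments.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._tv import tv_denoise

__all__ = [
    "BinProfile",
    "SegmentProfile",
    "bin_and_mask",
    "gc_correct",
    "default_lambda",
    "denoise_and_segment",
    "bin_counts_from_bam",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass
class BinProfile:
    """Per-bin read depth with GC fraction and N-mask for one chromosome.

    ``read_depth`` holds the mean per-base count of each bin; masked bins
    (``n_masked``) are retained positionally but excluded from every
    downstream statistic.
    """

    chrom: str
    bin_size: int
    start: np.ndarray
    end: np.ndarray
    read_depth: np.ndarray
    gc_fraction: np.ndarray
    n_masked: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.start)
        for name in ("end", "read_depth", "gc_fraction", "n_masked"):
            if len(getattr(self, name)) != n:
                raise ValueError("BinProfile arrays must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def unmasked(self) -> np.ndarray:
        return ~np.asarray(self.n_masked, dtype=bool)

    def filtered(self) -> "BinProfile":
        """Copy with masked bins dropped."""
        keep = self.unmasked
        return BinProfile(
            chrom=self.chrom,
            bin_size=self.bin_size,
            start=np.asarray(self.start)[keep].copy(),
            end=np.asarray(self.end)[keep].copy(),
            read_depth=np.asarray(self.read_depth, dtype=float)[keep].copy(),
            gc_fraction=np.asarray(self.gc_fraction, dtype=float)[keep].copy(),
            n_masked=np.zeros(int(keep.sum()), dtype=bool),
        )


@dataclass
class SegmentProfile:
    """Ordered constant-value read-depth segments from the fused-lasso fit.

    ``first_bin``/``last_bin`` index into the *filtered* bin vector (inclusive);
    ``start``/``end`` are the genomic coordinates of each segment; ``value``
    is the fitted constant; ``n_bins`` the number of member bins.
    """

    chrom: str
    first_bin: np.ndarray
    last_bin: np.ndarray
    start: np.ndarray
    end: np.ndarray
    value: np.ndarray
    n_bins: np.ndarray
    bin_values: np.ndarray = field(repr=False)  # filtered per-bin depths

    @property
    def n_segments(self) -> int:
        return len(self.value)

    def mean_value(self, weighting: str = "bin") -> float:
        """Global mean segment depth (RDS_m).

        ``weighting="bin"`` weights each segment by its bin count — invariant
        to how a constant stretch happens to be split, and identical to the
        mean of the per-bin depths at the fused-lasso optimum.
        ``weighting="segment"`` is the plain mean over segment values.
        """
        if weighting == "bin":
            return float(np.sum(self.value * self.n_bins) / np.sum(self.n_bins))
        if weighting == "segment":
            return float(np.mean(self.value))
        raise ValueError(f"unknown weighting {weighting!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "rds_value": self.value,
                "n_bins": self.n_bins,
            }
        )


# ---------------------------------------------------------------------------
# binning


def _sequence_for(reference, chrom: str) -> str:
    """Accept a pyfaidx.Fasta, a {chrom: seq} mapping, a path, or a raw string."""
    if reference is None:
        return None
    if isinstance(reference, str) and set(reference.upper()) <= set("ACGTN"):
        return reference
    if isinstance(reference, str):  # path to a FASTA file
        import pyfaidx

        reference = pyfaidx.Fasta(reference)
    try:
        return str(reference[chrom][:])
    except (KeyError, TypeError):
        raise ValueError(f"reference does not contain chromosome {chrom!r}")


def _gc_and_mask(seq: str, starts: np.ndarray, ends: np.ndarray):
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    is_n = ~((arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T"))
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    n_in_bin = cum_n[ends] - cum_n[starts]
    gc_in_bin = cum_gc[ends] - cum_gc[starts]
    width = ends - starts
    non_n = width - n_in_bin
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(non_n > 0, gc_in_bin / np.maximum(non_n, 1), np.nan)
    return gc, n_in_bin > 0


def bin_and_mask(
    counts: pd.DataFrame,
    reference=None,
    bin_size: int = 2000,
    *,
    gc: np.ndarray | None = None,
    chrom: str | None = None,
) -> BinProfile:
    """Build a :class:`BinProfile` from a count table and a reference.

    Two table dialects are accepted:

    * per-base — columns ``chrom, pos, count`` (0-based positions); bins get
      the mean per-base count;
    * per-bin — columns ``chrom, bin_start, bin_end, count`` (the simulator's
      output); the bin's mean per-base count is ``count / bin_size``.

    GC fraction and the N-mask come from ``reference`` (FASTA path,
    ``pyfaidx.Fasta``, mapping, or raw sequence string); alternatively a
    precomputed per-bin ``gc`` vector may be supplied.  Any bin containing at
    least one 'N' base is masked.  A trailing bin shorter than ``bin_size``
    is dropped.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    cols = set(counts.columns)
    if chrom is None:
        chroms = counts["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError(
                "count table spans multiple chromosomes; pass chrom= explicitly"
            )
        chrom = str(chroms[0])
    else:
        counts = counts[counts["chrom"] == chrom]

    seq = _sequence_for(reference, chrom)

    if {"bin_start", "bin_end", "count"} <= cols:
        tab = counts.sort_values("bin_start")
        widths = (tab["bin_end"] - tab["bin_start"]).to_numpy()
        keep = widths == bin_size  # drop a short trailing bin
        starts = tab["bin_start"].to_numpy()[keep].astype(np.int64)
        ends = tab["bin_end"].to_numpy()[keep].astype(np.int64)
        depth = tab["count"].to_numpy(dtype=float)[keep] / bin_size
    elif {"pos", "count"} <= cols:
        tab = counts.sort_values("pos")
        pos = tab["pos"].to_numpy(dtype=np.int64)
        val = tab["count"].to_numpy(dtype=float)
        length = int(pos.max()) + 1 if len(pos) else 0
        if seq is not None:
            if length > len(seq):
                raise ValueError("count positions extend beyond the reference")
            length = len(seq)
        per_base = np.zeros(length, dtype=float)
        per_base[pos] = val
        n_bins = length // bin_size
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = starts + bin_size
        depth = per_base[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    else:
        raise ValueError(
            "count table must have columns (chrom,pos,count) or "
            "(chrom,bin_start,bin_end,count)"
        )

    if seq is not None:
        if len(starts) and int(ends.max()) > len(seq):
            raise ValueError("count positions extend beyond the reference")
        gc_vec, mask = _gc_and_mask(seq, starts, ends)
    elif gc is not None:
        gc_vec = np.asarray(gc, dtype=float)
        if len(gc_vec) < len(starts):
            raise ValueError("gc vector shorter than the number of bins")
        gc_vec = gc_vec[: len(starts)]
        mask = np.zeros(len(starts), dtype=bool)
    else:
        raise ValueError("either a reference sequence or a gc vector is required")

    if np.any(depth < 0):
        raise ValueError("negative read counts")
    return BinProfile(
        chrom=chrom,
        bin_size=bin_size,
        start=starts,
        end=ends,
        read_depth=depth,
        gc_fraction=gc_vec,
        n_masked=np.asarray(mask, dtype=bool),
    )


# ---------------------------------------------------------------------------
# GC correction


def gc_correct(profile: BinProfile, ndigits: int = 2) -> BinProfile:
    """Stratified GC-bias correction: RD'_i = RD_i * RD_m / RD_gc.

    RD_m is the mean depth over all unmasked bins; RD_gc the mean over the
    bins whose GC fraction (rounded to ``ndigits``, default 1% strata) equals
    bin i's.  After correction every stratum mean equals RD_m, and the global
    mean is preserved.  A stratum with zero mean depth cannot be rescaled;
    its bins are masked and a warning is emitted.
    """
    keep = profile.unmasked
    if not keep.any():
        raise ValueError("no unmasked bins to correct")
    depth = np.asarray(profile.read_depth, dtype=float).copy()
    mask = np.asarray(profile.n_masked, dtype=bool).copy()
    gc_key = np.round(np.asarray(profile.gc_fraction, dtype=float), ndigits)

    rd_m = depth[keep].mean()
    corrected = depth.copy()
    for stratum in np.unique(gc_key[keep]):
        sel = keep & (gc_key == stratum)
        rd_gc = depth[sel].mean()
        if rd_gc == 0:
            warnings.warn(
                f"GC stratum {stratum:.{ndigits}f} has zero mean depth; "
                f"masking {int(sel.sum())} bin(s)",
                stacklevel=2,
            )
            mask[sel] = True
            continue
        corrected[sel] = depth[sel] * rd_m / rd_gc
    return replace(profile, read_depth=corrected, n_masked=mask)


# ---------------------------------------------------------------------------
# segmentation


def default_lambda(y: np.ndarray) -> float:
    """Universal-threshold fusion penalty: 2 * sigma_hat * sqrt(log n).

    sigma_hat is a robust noise-scale estimate from first differences:
    1.4826 * median(|diff y|) / sqrt(2) (the factor sqrt(2) because a first
    difference of iid noise has twice the variance of the noise itself).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        return 0.0
    sigma = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2.0)
    return 2.0 * sigma * np.sqrt(np.log(n))


def denoise_and_segment(profile: BinProfile, lam: float | None = None) -> SegmentProfile:
    """Fused-lasso denoising of the unmasked depth vector, then segmentation.

    The exact total-variation fit is piecewise constant; maximal runs of
    equal fitted values become segments.  ``lam=None`` uses
    :func:`default_lambda`; ``lam=0`` keeps every bin as its own segment.
    """
    filt = profile.filtered()
    y = np.asarray(filt.read_depth, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two unmasked bins to segment")
    if lam is None:
        lam = default_lambda(y)
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    beta = tv_denoise(y, lam)

    # Runs of equal fitted value (bitwise-equal by construction; tolerate
    # rounding with a tiny relative threshold).
    scale = max(1.0, float(np.max(np.abs(beta))))
    breaks = np.flatnonzero(np.abs(np.diff(beta)) > 1e-10 * scale)
    first = np.concatenate([[0], breaks + 1])
    last = np.concatenate([breaks, [len(beta) - 1]])
    values = np.array([beta[i] for i in first])
    return SegmentProfile(
        chrom=profile.chrom,
        first_bin=first,
        last_bin=last,
        start=np.asarray(filt.start)[first],
        end=np.asarray(filt.end)[last],
        value=values,
        n_bins=(last - first + 1).astype(np.int64),
        bin_values=y,
    )


# ---------------------------------------------------------------------------
# I/O helpers


def bin_counts_from_bam(
    path: str,
    chrom: str,
    bin_size: int = 2000,
    min_mapq: int = 0,
) -> pd.DataFrame:
    """Per-bin read counts from an alignment file (BAM/SAM/CRAM).

    Reads are assigned to the bin containing their leftmost aligned base;
    unmapped, secondary, duplicate and low-mapping-quality reads are skipped.
    Returns the per-bin table dialect (``chrom, bin_start, bin_end, count``).
    """
    import pysam

    with pysam.AlignmentFile(path) as af:
        try:
            length = af.get_reference_length(chrom)
        except (KeyError, ValueError):
            raise ValueError(f"chromosome {chrom!r} not in alignment header")
        n_bins = length // bin_size
        counts = np.zeros(n_bins, dtype=np.int64)
        for read in af.fetch(chrom) if af.has_index() else af:
            if af.has_index() is False and read.reference_name != chrom:
                continue
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            b = read.reference_start // bin_size
            if 0 <= b < n_bins:
                counts[b] += 1
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    return pd.DataFrame(
        {"chrom": chrom, "bin_start": starts, "bin_end": starts + bin_size, "count": counts}
    )


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
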