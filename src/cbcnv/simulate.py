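"""Matched tumor/normal read-depth simulation with embedded CNVs.

Emulates the study conditions used to benchmark read-depth CNV callers on a
single chromosome: a diploid normal sample and a tumor sample of purity TP
sequenced at fold-coverage SC, with 22 copy-number variants (12 gains, 4
heterozygous losses, 6 homozygous losses) of lengths 2–100 kb embedded in
the tumor.  The expected depth of a bin with tumor copy number c is the
diploid baseline scaled by the purity mixture

    f(c, TP) = (TP * c + (1 - TP) * 2) / 2,

so a homozygous deletion in a pure tumor drops to zero while low purity
compresses every event toward the diploid level.  Counts are drawn from a
negative-binomial noise model (Poisson in the zero-dispersion limit), with
a smooth GC profile and a quadratic GC-depth response so that GC correction
is exercised non-trivially.

Outputs are per-bin count tables (``chrom  bin_start  bin_end  count``) and
a BED3+2 truth file (``chrom  start  end  copy_number  type``); coordinates
are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .preprocess import BinProfile

__all__ = [
    "SimConfig",
    "TruthRegion",
    "SimResult",
    "expected_depth_factor",
    "plan_truth_regions",
    "default_gc_profile",
    "gc_depth_response",
    "simulate_pair",
    "write_truth_bed",
    "read_truth_bed",
    "write_reference_fasta",
]

#: CNV length levels (bp) sampled by default, mirroring the six evaluated
#: length strata from 2 kb to 100 kb.
LENGTH_LEVELS = (2_000, 6_000, 10_000, 30_000, 50_000, 100_000)

#: Copy numbers used for gain regions (drawn uniformly).
GAIN_COPY_NUMBERS = (3, 4, 5, 6)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults reproduce the benchmark conditions."""

    genome_length: int = 40_000_000
    bin_size: int = 2_000
    purity: float = 0.3
    coverage: float = 10.0
    read_length: int = 100
    n_regions: int = 22
    gain_count: int = 12
    het_loss_count: int = 4
    hom_loss_count: int = 6
    length_range: tuple[int, int] = (2_000, 100_000)
    length_levels: tuple[int, ...] | None = LENGTH_LEVELS
    gc_profile: np.ndarray | None = None
    depth_noise: float = 0.005
    chrom: str = "chr21"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        if self.coverage <= 0 or self.read_length <= 0 or self.bin_size <= 0:
            raise ValueError("coverage, read_length and bin_size must be positive")
        if self.gain_count + self.het_loss_count + self.hom_loss_count != self.n_regions:
            raise ValueError("gain + het-loss + hom-loss counts must equal n_regions")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid length_range")
        if self.length_levels is not None:
            for lev in self.length_levels:
                if not (lo <= lev <= hi):
                    raise ValueError("length_levels must lie within length_range")
        if self.depth_noise < 0:
            raise ValueError("depth_noise must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.genome_length // self.bin_size

    @property
    def baseline_depth(self) -> float:
        """Expected reads per bin in a diploid region (lambda)."""
        return self.coverage * self.bin_size / self.read_length


@dataclass(frozen=True)
class TruthRegion:
    """A simulated CNV interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    copy_number: int
    type: str = field(default="")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.copy_number == 2 or self.copy_number < 0:
            raise ValueError("truth copy number must be a non-negative integer != 2")
        expected = "gain" if self.copy_number > 2 else "loss"
        if not self.type:
            object.__setattr__(self, "type", expected)
        elif self.type != expected:
            raise ValueError(f"type {self.type!r} inconsistent with copy number")

    @property
    def length(self) -> int:
        return self.end - self.start


class SimResult(NamedTuple):
    tumor: pd.DataFrame
    normal: pd.DataFrame
    truth: list
    gc: np.ndarray


def expected_depth_factor(copy_number: int, purity: float) -> float:
    """Depth multiplier of a tumor region relative to the diploid baseline.

    A sequenced tumor sample is a mixture of tumor cells (fraction ``purity``,
    carrying ``copy_number`` copies) and normal cells (diploid), so the mean
    depth scales by (purity * c + (1 - purity) * 2) / 2.
    """
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    return (purity * copy_number + (1.0 - purity) * 2.0) / 2.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def plan_truth_regions(config: SimConfig, seed=None) -> list[TruthRegion]:
    """Place the configured CNV regions disjointly on the simulated genome.

    Lengths are drawn uniformly from ``config.length_levels`` (or uniformly
    from ``length_range`` when levels are ``None``) and snapped to whole
    bins; regions keep at least one normal bin between them.  Placement is
    by bounded rejection sampling; an infeasibly crowded configuration
    raises ``RuntimeError``.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    if config.n_regions == 0:
        return []
    bs = config.bin_size
    n_bins = config.n_bins

    copy_numbers = (
        [int(rng.choice(GAIN_COPY_NUMBERS)) for _ in range(config.gain_count)]
        + [1] * config.het_loss_count
        + [0] * config.hom_loss_count
    )
    rng.shuffle(copy_numbers)

    lengths_bins = []
    for _ in range(config.n_regions):
        if config.length_levels is not None:
            length = int(rng.choice(config.length_levels))
        else:
            length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        lengths_bins.append(max(1, length // bs))

    if sum(lengths_bins) + config.n_regions - 1 > n_bins:
        raise RuntimeError(
            "could not place all truth regions disjointly; "
            "genome too short for the requested configuration"
        )
    placed: list[tuple[int, int]] = []  # (start_bin, end_bin), half-open
    max_attempts = 10_000 * config.n_regions
    attempts = 0
    order = np.argsort(lengths_bins)[::-1]  # longest first eases packing
    starts_bins = [0] * config.n_regions
    for idx in order:
        lb = lengths_bins[idx]
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "could not place all truth regions disjointly; "
                    "genome too short for the requested configuration"
                )
            if n_bins - lb <= 0:
                raise RuntimeError("region longer than the simulated genome")
            s = int(rng.integers(0, n_bins - lb + 1))
            # require a >=1-bin normal gap to every placed region
            if all(s + lb + 1 <= ps or ps + pl + 1 <= s for ps, pl in
                   ((p[0], p[1] - p[0]) for p in placed)):
                placed.append((s, s + lb))
                starts_bins[idx] = s
                break

    regions = [
        TruthRegion(
            chrom=config.chrom,
            start=starts_bins[i] * bs,
            end=(starts_bins[i] + lengths_bins[i]) * bs,
            copy_number=copy_numbers[i],
        )
        for i in range(config.n_regions)
    ]
    regions.sort(key=lambda r: r.start)
    return regions


def default_gc_profile(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-bin GC fractions in [0.3, 0.6].

    A long-wavelength sinusoid plus window-smoothed Gaussian noise, clipped —
    a stand-in for the slowly varying isochore structure of a real
    chromosome.
    """
    i = np.arange(n_bins)
    base = 0.45 + 0.10 * np.sin(2.0 * np.pi * i / max(n_bins / 8, 50))
    noise = rng.normal(0.0, 0.05, n_bins)
    win = min(51, max(3, n_bins // 10 * 2 + 1))
    kernel = np.ones(win) / win
    smooth = np.convolve(noise, kernel, mode="same")
    return np.clip(base + smooth, 0.3, 0.6)


def gc_depth_response(gc: np.ndarray) -> np.ndarray:
    """Multiplicative GC bias on expected depth: quadratic, peaked at 45% GC.

    Depth drops by ~16% at the extremes of the simulated GC range, a
    magnitude typical of PCR-amplified short-read libraries.
    """
    gc = np.asarray(gc, dtype=float)
    return 1.0 - 7.0 * (gc - 0.45) ** 2


def _draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.maximum(np.asarray(mu, dtype=float), 0.0)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    counts = np.zeros(len(mu), dtype=np.int64)
    pos = mu > 0
    p = r / (r + mu[pos])
    counts[pos] = rng.negative_binomial(r, p)
    return counts


def simulate_pair(config: SimConfig, seed=None) -> SimResult:
    """Draw one matched tumor/normal pair of per-bin count tables.

    The normal sample fluctuates around the diploid baseline modulated by
    the GC response; the tumor shares the GC modulation and is additionally
    scaled by :func:`expected_depth_factor` inside each truth region.
    Identical seeds give byte-identical outputs.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    truth = plan_truth_regions(config, rng)
    n_bins = config.n_bins
    bs = config.bin_size

    if config.gc_profile is not None:
        gc = np.asarray(config.gc_profile, dtype=float)
        if len(gc) != n_bins:
            raise ValueError("gc_profile length must equal the number of bins")
    else:
        gc = default_gc_profile(n_bins, rng)

    mu_normal = config.baseline_depth * gc_depth_response(gc)
    factor = np.ones(n_bins)
    for region in truth:
        b0, b1 = region.start // bs, region.end // bs
        factor[b0:b1] = expected_depth_factor(region.copy_number, config.purity)
    mu_tumor = mu_normal * factor

    normal_counts = _draw_counts(mu_normal, config.depth_noise, rng)
    tumor_counts = _draw_counts(mu_tumor, config.depth_noise, rng)

    starts = np.arange(n_bins, dtype=np.int64) * bs

    def table(counts):
        return pd.DataFrame(
            {
                "chrom": config.chrom,
                "bin_start": starts,
                "bin_end": starts + bs,
                "count": counts,
            }
        )

    return SimResult(table(tumor_counts), table(normal_counts), truth, gc)


def profile_from_table(table: pd.DataFrame, gc: np.ndarray, bin_size: int) -> BinProfile:
    """Convenience: wrap a simulated count table into a :class:`BinProfile`."""
    from .preprocess import bin_and_mask

    return bin_and_mask(table, bin_size=bin_size, gc=gc)


# ---------------------------------------------------------------------------
# I/O


def write_truth_bed(regions, path) -> None:
    """BED3+2 truth file: chrom, start, end, copy_number, type."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.copy_number}\t{r.type}\n")


def read_truth_bed(path) -> list[TruthRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, cn, typ = line.rstrip("\n").split("\t")[:5]
            regions.append(
                TruthRegion(chrom=chrom, start=int(start), end=int(end),
                            copy_number=int(cn), type=typ)
            )
    return regions


def write_reference_fasta(gc: np.ndarray, bin_size: int, path, chrom: str = "chr21",
                          seed: int = 0, line_width: int = 70) -> None:
    """Write a synthetic reference whose per-bin GC matches ``gc`` exactly.

    Each bin receives round(gc * bin_size) G/C bases (split between G and C)
    at shuffled positions; useful for exercising the FASTA-based binning
    path against simulated count tables.
    """
    rng = np.random.default_rng(seed)
    chunks = []
    for g in np.asarray(gc, dtype=float):
        n_gc = int(round(g * bin_size))
        bases = np.empty(bin_size, dtype="S1")
        half_gc = n_gc // 2
        half_at = (bin_size - n_gc) // 2
        bases[:half_gc] = b"G"
        bases[half_gc:n_gc] = b"C"
        bases[n_gc : n_gc + half_at] = b"A"
        bases[n_gc + half_at :] = b"T"
        rng.shuffle(bases)
        chunks.append(bases.tobytes().decode("ascii"))
    seq = "".join(chunks)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), line_width):
            fh.write(seq[i : i + line_width] + "\n")
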