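"""Assessment procedures: permutation specificity, nucleosome spacing, and
dinucleotide signature.

Three complementary checks of a call set, none of which requires a labelled
truth standard:

* **Permutation specificity** - reads are permuted uniformly within 1 kb
  blocks, destroying positioning while conserving local coverage; calls that
  survive are counted as false positives against a candidate universe of
  disjoint 30 bp central bins.
* **Inter-nucleosome spacing** - downstream of highly expressed TSSs
  (RPKM > 10), call centers are given integer nucleosome indices (not
  necessarily consecutive, to tolerate missed calls) and a per-gene linear
  fit of position against index estimates the spacing; ~180 bp is the
  expected value at active promoters.
* **Dinucleotide signature** - well-positioned nucleosome cores are GC-
  enriched and AA/TT-depleted; the difference D of the two center
  frequencies, pooled over sense and antisense sequences (dyad two-fold
  symmetry), is reported with a 95% confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .caller import CallSet, NucleosomeCall, call_nucleosomes
from .model import GammaHyper, UniformPrior
from .preprocess import BinnedTrack
from .reads_io import ReadCenters

logger = logging.getLogger("nucleofinder")

PERMUTATION_WINDOW = 1000
RPKM_MIN = 10.0
SPACING_GRID = (120, 250)
CANDIDATE_BIN = 30


@dataclass
class SpecificityReport:
    """False positives surviving read permutation versus the candidate universe."""

    calls_after: int
    candidate_regions: int
    true_negatives: int
    specificity: float
    calls_before: int | None = None


@dataclass
class SpacingEstimate:
    mean_spacing: float
    sd_spacing: float
    n_genes: int
    n_skipped: int = 0


@dataclass
class DinucleotideProfile:
    """Positional AA/TT and GC dinucleotide frequencies around call centers."""

    f_aatt: np.ndarray
    f_gc: np.ndarray
    D: float
    ci_low: float
    ci_high: float
    n: int
    m: int
    se: float
    dropped: int = 0


def permute_reads(
    centers: ReadCenters,
    window: int = PERMUTATION_WINDOW,
    seed: int | np.random.Generator = 0,
) -> ReadCenters:
    """Reassign each center a uniform position within its window-bp block.

    Per-block counts are conserved exactly; the output is sorted and
    reproducible under a fixed seed.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = centers.positions
    if pos.size == 0:
        return ReadCenters(centers.chrom, pos.copy(), centers.chrom_length)
    block_start = (pos // window) * window
    block_end = np.minimum(block_start + window, centers.chrom_length)
    new = block_start + np.floor(rng.random(pos.size) * (block_end - block_start)).astype(np.int64)
    return ReadCenters(centers.chrom, np.sort(new), centers.chrom_length)


def compute_specificity(
    calls_after_perm: int,
    total_candidate_regions: int,
    calls_before: int | None = None,
) -> SpecificityReport:
    """Specificity = TN / (TN + FP) with FP = calls surviving permutation.

    The candidate universe is the number of disjoint 30 bp central bins,
    i.e. chromosome length / 30 summed over chromosomes.
    """
    if total_candidate_regions <= 0:
        raise ValueError("candidate region count must be positive")
    if calls_after_perm > total_candidate_regions:
        raise ValueError("more false positives than candidate regions")
    tn = total_candidate_regions - calls_after_perm
    return SpecificityReport(
        calls_after=calls_after_perm,
        candidate_regions=total_candidate_regions,
        true_negatives=tn,
        specificity=tn / (tn + calls_after_perm),
        calls_before=calls_before,
    )


def permutation_specificity(
    signal_centers: Mapping[str, ReadCenters],
    control_centers: Mapping[str, ReadCenters] | None = None,
    window: int = PERMUTATION_WINDOW,
    seed: int = 0,
    **call_kwargs,
) -> SpecificityReport:
    """Run the caller before and after within-block read permutation.

    The after-permutation run reuses the hyperparameters and lambda_max
    fitted on the observed data: the null holds the fitted model constant
    and permutes only the reads, so the comparison measures positioning
    rather than a re-fit of the background to the permuted track.
    """
    before, params = call_nucleosomes(signal_centers, control_centers, **call_kwargs)
    fitted = {
        chrom: (GammaHyper(rec["alpha"], rec["beta"], chrom), UniformPrior(float(rec["lambda_max"])))
        for chrom, rec in params.items()
        if not rec.get("skipped")
    }
    rng = np.random.default_rng(seed)
    permuted = {
        chrom: permute_reads(signal_centers[chrom], window=window, seed=rng)
        for chrom in sorted(signal_centers)
    }
    after, _ = call_nucleosomes(permuted, control_centers, priors=fitted, **call_kwargs)
    candidates = sum(rc.chrom_length // CANDIDATE_BIN for rc in signal_centers.values())
    return compute_specificity(len(after), candidates, calls_before=len(before))


def average_profile(
    calls: Sequence[NucleosomeCall],
    track: BinnedTrack,
    flank: int = 100,
) -> np.ndarray:
    """Mean 10 bp-binned read counts along call-centered windows.

    ``track`` must be binned at 10 bp; the output covers the 150 bp call
    window plus ``flank`` bp each side.  Calls truncated by chromosome edges
    are dropped (count logged).
    """
    if track.bin_size != 10:
        raise ValueError("average_profile expects a 10 bp-binned track")
    if flank % 10 != 0:
        raise ValueError("flank must be a multiple of 10")
    n_bins = (150 + 2 * flank) // 10
    acc = np.zeros(n_bins, dtype=float)
    used = 0
    dropped = 0
    for call in calls:
        if call.chrom != track.chrom:
            continue
        center = call.center_start + (call.center_end - call.center_start) // 2
        w_start = center - 75 - flank
        i0 = w_start // 10
        if i0 < 0 or i0 + n_bins > track.n_bins:
            dropped += 1
            continue
        if w_start % 10 != 0:
            raise ValueError("call window does not align with the 10 bp grid")
        acc += track.counts[i0:i0 + n_bins]
        used += 1
    if used == 0:
        raise ValueError("no usable calls for the average profile")
    if dropped:
        logger.info("average_profile: dropped %d edge-truncated calls", dropped)
    return acc / used


def _fit_gene_spacing(
    dists: np.ndarray,
    d_min: int,
    d_max: int,
) -> float | None:
    """Optimal-numbering spacing for one gene's TSS-oriented call centers.

    For each candidate spacing d, centers get integer indices round(c/d)
    (required distinct); an OLS fit of position against index scores d by
    its residual sum of squares, and the best fit's slope is the spacing.
    Equal-RSS ties prefer the larger d (the more parsimonious numbering).
    """
    best: tuple[float, float] | None = None  # (rss, slope)
    for d in range(d_min, d_max + 1):
        k = np.floor(dists / d + 0.5).astype(np.int64)  # round half away from zero
        if np.unique(k).size < k.size:
            continue
        kc = k - k.mean()
        denom = float(kc @ kc)
        if denom == 0.0:
            continue
        cc = dists - dists.mean()
        slope = float(kc @ cc) / denom
        rss = float(cc @ cc) - slope * slope * denom
        if best is None or rss <= best[0] + 1e-9:
            best = (rss, slope)
    return None if best is None else best[1]


def estimate_spacing(
    calls: Sequence[NucleosomeCall],
    tss: Iterable[tuple[str, int, str, float]],
    rpkm_min: float = RPKM_MIN,
    window: int = 1000,
    d_grid: tuple[int, int] = SPACING_GRID,
) -> SpacingEstimate:
    """Mean/SD inter-nucleosome distance downstream of active TSSs.

    ``tss`` yields (chrom, position, strand, rpkm); genes with
    rpkm <= rpkm_min or fewer than 2 calls in their downstream 1 kb window
    are skipped (counted).  Distances are strand-oriented, so the estimate
    is invariant to gene strand.
    """
    by_chrom: dict[str, np.ndarray] = {}
    for call in calls:
        center = call.center_start + (call.center_end - call.center_start) // 2
        by_chrom.setdefault(call.chrom, []).append(center)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}

    spacings: list[float] = []
    skipped = 0
    for chrom, pos, strand, rpkm in tss:
        if rpkm <= rpkm_min:
            continue
        centers = by_chrom.get(chrom)
        if centers is None:
            skipped += 1
            continue
        if strand == "+":
            inside = centers[(centers > pos) & (centers <= pos + window)]
            dists = inside - pos
        elif strand == "-":
            inside = centers[(centers >= pos - window) & (centers < pos)]
            dists = pos - inside[::-1]
        else:
            raise ValueError(f"unknown strand symbol {strand!r}")
        if dists.size < 2:
            skipped += 1
            continue
        slope = _fit_gene_spacing(np.sort(dists).astype(float), d_grid[0], d_grid[1])
        if slope is None:
            skipped += 1
            continue
        spacings.append(slope)
    if not spacings:
        raise ValueError("no gene passed the expression and call-count filters")
    arr = np.asarray(spacings)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SpacingEstimate(float(arr.mean()), sd, arr.size, skipped)


def read_tss(path) -> list[tuple[str, int, str, float]]:
    """Parse a BED6 TSS list whose score column carries RPKM."""
    entries: list[tuple[str, int, str, float]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, _end, _name, score, strand = fields[:6]
            entries.append((chrom, int(start), strand, float(score)))
    return entries


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def dinucleotide_profile(
    calls: Sequence[NucleosomeCall],
    genome: Mapping[str, str],
    span: int = 150,
    include_ta: bool = False,
) -> DinucleotideProfile:
    """AA/TT and GC dinucleotide frequencies along call-centered windows.

    Each call contributes its span-bp sequence and the reverse complement
    (nucleosome dyad two-fold symmetry).  D is the mean over the central
    30 bp dinucleotide positions of f_GC - f_AA/TT; its 95% CI has
    half-width sqrt(chi2_{1,0.95}) * SE, with SE estimated from the
    between-call variance of the per-call central difference.  Positions
    with non-ACGT bases are excluded from the denominators.
    """
    if span % 2 != 0 or span < 32:
        raise ValueError("span must be an even number >= 32")
    half = span // 2
    seqs: list[str] = []
    dropped = 0
    for call in calls:
        center = call.center_start + (call.center_end - call.center_start) // 2
        record = genome[call.chrom]
        s, e = center - half, center + half
        if s < 0 or e > len(record):
            dropped += 1
            continue
        seqs.append(str(record[s:e]).upper())
    n = len(seqs)
    if n == 0:
        raise ValueError("no call lies fully inside the genome sequence")
    if dropped:
        logger.info("dinucleotide_profile: dropped %d calls near contig edges", dropped)

    codes = _CODE[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)].reshape(n, span)
    both = np.stack([codes, _COMP[codes][:, ::-1]], axis=1)  # (n, 2 strands, span)
    first, second = both[..., :-1], both[..., 1:]
    valid = (first < 4) & (second < 4)
    gc = (first == 2) & (second == 1)
    aatt = ((first == 0) & (second == 0)) | ((first == 3) & (second == 3))
    if include_ta:
        aatt |= (first == 3) & (second == 0)

    denom = valid.sum(axis=(0, 1)).astype(float)
    with np.errstate(invalid="ignore"):
        f_gc = np.where(denom > 0, gc.sum(axis=(0, 1)) / denom, np.nan)
        f_aatt = np.where(denom > 0, aatt.sum(axis=(0, 1)) / denom, np.nan)

    # dinucleotides with both bases inside the central 30 bp
    central = slice(half - 15, half + 14)
    m = half + 14 - (half - 15)
    v_valid = valid[:, :, central].sum(axis=(1, 2)).astype(float)
    if np.any(v_valid == 0):
        raise ValueError("a call has no valid central dinucleotide")
    d_per_call = (gc[:, :, central].sum(axis=(1, 2)) - aatt[:, :, central].sum(axis=(1, 2))) / v_valid
    D = float(d_per_call.mean())
    se = float(d_per_call.std(ddof=1) / math.sqrt(n)) if n > 1 else float("inf")
    hw = math.sqrt(stats.chi2.ppf(0.95, df=1)) * se
    return DinucleotideProfile(
        f_aatt=f_aatt, f_gc=f_gc, D=D, ci_low=D - hw, ci_high=D + hw,
        n=n, m=m, se=se, dropped=dropped,
    )
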