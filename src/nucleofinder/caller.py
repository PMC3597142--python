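"""Sliding five-bin scan and nucleosome call emission.

Each chromosome is processed independently: its corrected track supplies
both the method-of-moments gamma hyperparameters and lambda_max (the
chromosome's maximum corrected bin count).  Every 150 bp window (5 bins,
stride 1 bin) is scored under the eight models; windows where the
positioned-nucleosome model M1 strictly wins become calls scored by
log BF(M1:M0).  Overlapping candidates are resolved greedily by score so
kept calls have pairwise disjoint central 30 bp bins.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.special as sc

from .model import (
    MODEL_IDS,
    MODEL_STATES,
    GammaHyper,
    UniformPrior,
    UniformTable,
    _gamma_core,
    estimate_gamma_hyperparams,
    precompute_uniform_table,
)
from .preprocess import BinnedTrack, bin_counts, subtract_control
from .reads_io import ReadCenters

logger = logging.getLogger("nucleofinder")

WINDOW_BINS = 5
CENTER_BIN = 2


@dataclass(frozen=True)
class NucleosomeCall:
    """A detected well-positioned nucleosome (0-based half-open intervals)."""

    chrom: str
    start: int
    end: int
    center_start: int
    center_end: int
    log_bayes_factor: float
    winner_margin: float


#: calls are carried as plain lists sorted by (chrom, start)
CallSet = list


def scan_chromosome(
    track: BinnedTrack,
    hyper: GammaHyper,
    prior: UniformPrior,
    step_bins: int = 1,
    skip_zero_windows: bool = True,
    table: UniformTable | None = None,
) -> CallSet:
    """Score every five-bin window of one chromosome; return unresolved calls.

    All-zero windows are skipped by default (the null model wins there
    trivially); disable ``skip_zero_windows`` to force exhaustive evaluation.
    """
    if step_bins < 1:
        raise ValueError("step_bins must be >= 1")
    c = np.asarray(track.counts, dtype=np.int64)
    if c.size < WINDOW_BINS:
        return []
    n_win = c.size - WINDOW_BINS + 1
    S1 = c[0:n_win] + c[1:n_win + 1]
    S2 = c[2:n_win + 2]
    S3 = c[3:n_win + 3] + c[4:n_win + 4]
    s_max = int(max(S1.max(), S2.max(), S3.max()))
    if table is None:
        table = precompute_uniform_table(prior, s_max)
    grid = np.arange(s_max + 1)
    g1 = _gamma_core(1, grid, hyper)
    g2 = _gamma_core(2, grid, hyper)
    u1 = table.core_array(1, grid)
    u2 = table.core_array(2, grid)

    seg_bg = (g2[S1], g1[S2], g2[S3])
    seg_en = (u2[S1], u1[S2], u2[S3])
    L = np.empty((len(MODEL_IDS), n_win))
    for j, mid in enumerate(MODEL_IDS):
        states = MODEL_STATES[mid]
        L[j] = sum(seg_en[k] if states[k] == "en" else seg_bg[k] for k in range(3))

    l1 = L[1]
    best_other = np.maximum.reduce([L[j] for j in range(len(MODEL_IDS)) if j != 1])
    is_call = l1 > best_other
    if skip_zero_windows:
        is_call &= (S1 + S2 + S3) > 0
    idx = np.nonzero(is_call)[0]
    if step_bins > 1:
        idx = idx[idx % step_bins == 0]

    bf = l1 - L[0]
    margin = l1 - best_other
    b, off = track.bin_size, track.offset
    calls = [
        NucleosomeCall(
            chrom=track.chrom,
            start=off + b * int(i),
            end=off + b * (int(i) + WINDOW_BINS),
            center_start=off + b * (int(i) + CENTER_BIN),
            center_end=off + b * (int(i) + CENTER_BIN + 1),
            log_bayes_factor=float(bf[i]),
            winner_margin=float(margin[i]),
        )
        for i in idx
    ]
    return calls


def resolve_overlaps(calls: Iterable[NucleosomeCall]) -> CallSet:
    """Greedy selection in descending score with disjoint central bins.

    A call is kept iff its central 30 bp bin does not overlap the central bin
    of any already-kept call; ties in score break to the leftmost start.
    """
    order = sorted(calls, key=lambda c: (-c.log_bayes_factor, c.chrom, c.start))
    kept_starts: dict[str, list[int]] = {}
    kept_ends: dict[str, list[int]] = {}
    kept: list[NucleosomeCall] = []
    for call in order:
        starts = kept_starts.setdefault(call.chrom, [])
        ends = kept_ends.setdefault(call.chrom, [])
        i = bisect.bisect_left(starts, call.center_end)
        # neighbor to the left is the only candidate overlap
        if i > 0 and ends[i - 1] > call.center_start:
            continue
        starts.insert(i, call.center_start)
        ends.insert(i, call.center_end)
        kept.append(call)
    kept.sort(key=lambda c: (c.chrom, c.start))
    return kept


def call_nucleosomes(
    signal_centers: Mapping[str, ReadCenters],
    control_centers: Mapping[str, ReadCenters] | None = None,
    bin_size: int = 30,
    control_scale: float = 1.0,
    offset_sweep: bool = False,
    step_bins: int = 1,
    skip_zero_windows: bool = True,
    priors: Mapping[str, tuple[GammaHyper, UniformPrior]] | None = None,
) -> tuple[CallSet, dict]:
    """Full per-chromosome pipeline: bin, correct, fit priors, scan, resolve.

    Returns the resolved calls and a per-chromosome parameter record
    (hyperparameters, lambda_max, window and call counts) suitable for a
    JSON sidecar.  ``offset_sweep`` additionally scans the five 6 bp phases
    of the 30 bp grid (off by default).  ``priors`` fixes the per-chromosome
    (GammaHyper, UniformPrior) pair instead of estimating it from the track
    (used by the permutation-specificity null, which holds the fitted model
    constant while the data are permuted).
    """
    all_calls: list[NucleosomeCall] = []
    params: dict = {}
    offsets = tuple(range(0, bin_size, max(1, bin_size // 5))) if offset_sweep else (0,)
    for chrom in sorted(signal_centers):
        sig_centers = signal_centers[chrom]
        ctl_centers = control_centers.get(chrom) if control_centers else None
        chrom_calls = 0
        for offset in offsets:
            sig = bin_counts(sig_centers, bin_size, offset=offset)
            if ctl_centers is not None:
                ctl = bin_counts(ctl_centers, bin_size, chrom_length=sig.chrom_length, offset=offset)
                corrected = subtract_control(sig, ctl, control_scale)
            else:
                corrected = sig
            if priors is not None and chrom in priors:
                hyper, prior = priors[chrom]
                lam_max = prior.lambda_max
            else:
                lam_max = int(corrected.counts.max()) if corrected.n_bins else 0
                if lam_max == 0:
                    logger.info("%s (offset %d): no corrected signal, skipped", chrom, offset)
                    if offset == 0:
                        params[chrom] = {"skipped": True, "lambda_max": 0}
                    continue
                hyper = estimate_gamma_hyperparams(corrected)
                prior = UniformPrior(float(lam_max))
            calls = scan_chromosome(
                corrected, hyper, prior,
                step_bins=step_bins, skip_zero_windows=skip_zero_windows,
            )
            chrom_calls += len(calls)
            all_calls.extend(calls)
            if offset == 0:
                params[chrom] = {
                    "alpha": hyper.alpha,
                    "beta": hyper.beta,
                    "lambda_max": lam_max,
                    "n_windows": max(corrected.n_bins - WINDOW_BINS + 1, 0),
                }
        if chrom in params:
            params[chrom]["n_raw_calls"] = chrom_calls
        logger.info("%s: %d raw calls", chrom, chrom_calls)
    resolved = resolve_overlaps(all_calls)
    for chrom in params:
        params[chrom]["n_calls"] = sum(1 for c in resolved if c.chrom == chrom)
    return resolved, params


def write_calls(calls: Sequence[NucleosomeCall], path) -> None:
    """Write resolved calls as BED6 over the central 30 bp bins.

    Score is the log Bayes factor rounded to 3 decimals; the full 150 bp
    window is recoverable as the central bin padded by 60 bp each side.
    """
    with open(path, "w") as fh:
        fh.write("# nucleofinder calls: chrom, center_start, center_end, name, logBF(M1:M0), strand\n")
        ordered = sorted(calls, key=lambda c: (c.chrom, c.start))
        for i, call in enumerate(ordered, start=1):
            fh.write(
                f"{call.chrom}\t{call.center_start}\t{call.center_end}"
                f"\tnuc{i}\t{call.log_bayes_factor:.3f}\t.\n"
            )


def read_calls(path) -> CallSet:
    """Parse a calls BED file written by :func:`write_calls`."""
    calls: list[NucleosomeCall] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, cs, ce, _name, score, _strand = line.rstrip("\n").split("\t")[:6]
            cs_i, ce_i = int(cs), int(ce)
            pad = 2 * (ce_i - cs_i)
            calls.append(
                NucleosomeCall(
                    chrom=chrom,
                    start=cs_i - pad,
                    end=ce_i + pad,
                    center_start=cs_i,
                    center_end=ce_i,
                    log_bayes_factor=float(score),
                    winner_margin=float("nan"),
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls
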