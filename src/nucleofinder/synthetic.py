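"""Synthetic MNase-Seq-like data with known truth.

The generator emulates the population picture behind phased nucleosomes:
reads from a well-positioned nucleosome scatter normally around its center
(phasing_sd), delocalized nucleosomes and other noise contribute uniform
background, and the control sample shares the background read pool so that
control subtraction is exercised meaningfully.  Center positions are
back-transformed to 5'-end read coordinates on random strands by inverting
the +75 bp shift, so synthetic reads flow through the same pipeline as real
ones.  A companion genome generator plants a GC-dinucleotide excess (and
AA/TT depletion) at nucleosome cores with a closed-form expected signature,
and a spacing generator emits per-gene phased call arrays with dropout.

Planted centers sit mid-bin on the 30 bp grid by default, so stated
recovery rates measure detector sensitivity rather than grid phase (the
caller's offset sweep exists for phase effects).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .caller import NucleosomeCall
from .reads_io import ReadArrays

logger = logging.getLogger("nucleofinder")


@dataclass
class SimulationConfig:
    """Study conditions for the read/genome simulators.

    Rates are per bp; reads_per_nucleosome is the Poisson mean of reads a
    planted nucleosome emits.  With the defaults the array of 100 phased
    nucleosomes at 180 bp spacing tiles most of a ~19 kb chromosome, which
    mirrors chromatin's near-complete nucleosome tiling.
    """

    chrom: str = "chrS"
    n_nucleosomes: int = 100
    spacing: int = 180
    phasing_sd: float = 15.0
    reads_per_nucleosome: float = 50.0
    background_rate: float = 0.02
    control_depth: float | None = None
    at_bias_strength: float = 0.0
    gc_core_effect: float = 0.2
    margin: int = 500
    bin_size: int = 30
    read_length: int = 25
    shift: int = 75
    seed: int = 0
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.phasing_sd < 0:
            raise ValueError("spacing must be positive and phasing_sd non-negative")
        if min(self.reads_per_nucleosome, self.background_rate, self.at_bias_strength) < 0:
            raise ValueError("rates must be non-negative")
        if self.chrom_length is None:
            first = self.first_center
            self.chrom_length = first + (self.n_nucleosomes - 1) * self.spacing + self.margin
        if self.control_depth is None:
            # depth-matched control: naked-DNA libraries are conventionally
            # sequenced to the depth of the nucleosome sample
            self.control_depth = (
                self.background_rate
                + self.n_nucleosomes * self.reads_per_nucleosome / self.chrom_length
            )
        if self.control_depth < 0:
            raise ValueError("control_depth must be non-negative")

    @property
    def first_center(self) -> int:
        # snap the first planted center to the middle of a 30 bp bin
        raw = self.margin + self.spacing // 2
        return (raw // self.bin_size) * self.bin_size + self.bin_size // 2


@dataclass
class TruthSet:
    """Planted nucleosome centers and the generating parameters."""

    centers: np.ndarray
    config: SimulationConfig


def planted_centers(config: SimulationConfig) -> np.ndarray:
    centers = config.first_center + config.spacing * np.arange(config.n_nucleosomes, dtype=np.int64)
    if centers.size and centers[-1] >= config.chrom_length:
        raise ValueError("planted centers exceed chromosome length")
    return centers


def _centers_to_reads(
    centers: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ReadArrays:
    """Back-transform center coordinates to 5' read coordinates on random strands."""
    minus = rng.random(centers.size) < 0.5
    five_prime = np.where(minus, centers + config.shift, centers - config.shift)
    # keep reads whose 25 bp footprint lies inside the chromosome
    lo = np.where(minus, config.read_length - 1, 0)
    hi = np.where(minus, config.chrom_length - 1, config.chrom_length - config.read_length)
    keep = (five_prime >= lo) & (five_prime <= hi)
    dropped = int(centers.size - keep.sum())
    if dropped:
        logger.debug("simulate_reads: dropped %d boundary reads", dropped)
    return ReadArrays(config.chrom, five_prime[keep].astype(np.int64), minus[keep])


def simulate_reads(
    config: SimulationConfig,
    genome: str | None = None,
) -> tuple[ReadArrays, ReadArrays, TruthSet]:
    """Generate signal and control reads plus the planted truth.

    Signal: for each planted center, Poisson(reads_per_nucleosome) read
    centers at center + Normal(0, phasing_sd), plus uniform background.
    Control: the same background pool (topped up or thinned to
    control_depth), optionally position-weighted toward AT-rich genome
    positions by at_bias_strength.  Deterministic under config.seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    truth = planted_centers(config)

    per_nuc = rng.poisson(config.reads_per_nucleosome, size=truth.size)
    nuc_centers = np.repeat(truth, per_nuc).astype(float)
    if config.phasing_sd > 0:
        nuc_centers = nuc_centers + rng.normal(0.0, config.phasing_sd, size=nuc_centers.size)
    nuc_centers = np.rint(nuc_centers).astype(np.int64)

    n_bg = rng.poisson(config.background_rate * L)
    bg_pool = rng.integers(0, L, size=n_bg, dtype=np.int64)

    signal_centers = np.concatenate([nuc_centers, bg_pool])

    # control shares the background pool, then is adjusted to control_depth
    control_centers = bg_pool
    extra_rate = config.control_depth - config.background_rate
    if extra_rate > 0:
        extra = rng.integers(0, L, size=rng.poisson(extra_rate * L), dtype=np.int64)
        control_centers = np.concatenate([control_centers, extra])
    elif extra_rate < 0 and bg_pool.size:
        n_keep = min(bg_pool.size, rng.poisson(config.control_depth * L))
        control_centers = rng.choice(bg_pool, size=n_keep, replace=False)

    if config.at_bias_strength > 0 and genome is not None and control_centers.size:
        is_at = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
        is_at = (is_at == ord("A")) | (is_at == ord("T")) | (is_at == ord("a")) | (is_at == ord("t"))
        weights = 1.0 + config.at_bias_strength * is_at.astype(float)
        weights /= weights.sum()
        control_centers = rng.choice(L, size=control_centers.size, p=weights).astype(np.int64)

    signal = _centers_to_reads(signal_centers, config, rng)
    control = _centers_to_reads(control_centers, config, rng)
    return signal, control, TruthSet(truth, config)


#: half-width of the GC-boosted region planted around each core center
CORE_HALF_SPAN = 35


def simulate_genome(config: SimulationConfig) -> tuple[str, TruthSet]:
    """Random genome with GC-biased letters at planted nucleosome cores.

    Outside cores the four bases are equiprobable.  Within +/-35 bp of each
    planted center, G and C have probability (1 + d)/4 and A and T
    (1 - d)/4 each, with d = gc_core_effect; the expected central
    dinucleotide signature is then analytic (see
    :func:`expected_dinucleotide_d`).  Deterministic under config.seed.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    L = config.chrom_length
    truth = planted_centers(config)
    d = config.gc_core_effect
    if not 0 <= d < 1:
        raise ValueError("gc_core_effect must lie in [0, 1)")

    base_probs = np.full(4, 0.25)
    core_probs = np.array([(1 - d) / 4, (1 + d) / 4, (1 + d) / 4, (1 - d) / 4])  # A C G T
    codes = rng.choice(4, size=L, p=base_probs)
    if d > 0:
        for center in truth:
            s = max(int(center) - CORE_HALF_SPAN, 0)
            e = min(int(center) + CORE_HALF_SPAN, L)
            codes[s:e] = rng.choice(4, size=e - s, p=core_probs)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return seq, TruthSet(truth, config)


def expected_dinucleotide_d(gc_core_effect: float, include_ta: bool = False) -> float:
    """Analytic E[f_GC - f_AA/TT] inside a planted core.

    Letters are iid with P(G) = P(C) = (1+d)/4 and P(A) = P(T) = (1-d)/4,
    so f_GC has expectation ((1+d)/4)^2 and f_AA/TT 2((1-d)/4)^2 (3x with
    TA included).
    """
    d = gc_core_effect
    at_terms = 3.0 if include_ta else 2.0
    return ((1 + d) / 4) ** 2 - at_terms * ((1 - d) / 4) ** 2


def write_fasta(seq: str, path, chrom: str = "chrS", width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_reads_bed(reads: ReadArrays, path, read_length: int = 25) -> None:
    """Write reads as BED6; the 5' end is start for '+' and end-1 for '-'."""
    with open(path, "w") as fh:
        for i in range(len(reads)):
            fp = int(reads.five_prime[i])
            if reads.minus[i]:
                start, end, strand = fp - read_length + 1, fp + 1, "-"
            else:
                start, end, strand = fp, fp + read_length, "+"
            fh.write(f"{reads.chrom}\t{start}\t{end}\tr{i + 1}\t0\t{strand}\n")


def simulate_spacing_genes(
    n_genes: int = 500,
    spacing: float = 180.0,
    jitter_sd: float = 10.0,
    dropout: float = 0.2,
    nucleosomes_per_gene: int = 5,
    first_offset: float = 90.0,
    window: int = 1000,
    rpkm_low_fraction: float = 0.1,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[list[NucleosomeCall], list[tuple[str, int, str, float]]]:
    """Per-gene phased call arrays with jitter and random call dropout.

    Genes alternate strand; each passing gene has RPKM > 10 and nucleosome
    centers at first_offset + spacing*k + Normal(0, jitter_sd) downstream of
    its TSS, each dropped with probability ``dropout``.  A fraction of
    low-RPKM decoy genes with random centers checks the expression filter.
    Call centers are snapped to the 30 bp grid like real calls.
    """
    rng = np.random.default_rng(seed)
    gene_gap = window + int(nucleosomes_per_gene * spacing) + 1000
    calls: list[NucleosomeCall] = []
    tss: list[tuple[str, int, str, float]] = []
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        pos = gene_gap * (g + 1)
        low_rpkm = rng.random() < rpkm_low_fraction
        rpkm = float(rng.uniform(0.1, 9.0)) if low_rpkm else float(10.0 + rng.exponential(30.0))
        tss.append((chrom, pos, strand, rpkm))
        if low_rpkm:
            offsets = np.sort(rng.uniform(30, window - 30, size=nucleosomes_per_gene))
        else:
            offsets = first_offset + spacing * np.arange(nucleosomes_per_gene)
            offsets = offsets + rng.normal(0.0, jitter_sd, size=offsets.size)
            offsets = offsets[rng.random(offsets.size) >= dropout]
        for off in offsets:
            center = pos + off if strand == "+" else pos - off
            bin_idx = int(center) // 30
            cs, ce = bin_idx * 30, bin_idx * 30 + 30
            calls.append(
                NucleosomeCall(chrom, cs - 60, ce + 60, cs, ce,
                               log_bayes_factor=1.0, winner_margin=1.0)
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls, tss


def save_fixture_set(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Emit signal.bed, control.bed, genome.fa, truth.json and sizes.tsv."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    signal, control, _ = simulate_reads(config, genome=genome)
    paths = {
        "signal": str(out / "signal.bed"),
        "control": str(out / "control.bed"),
        "genome": str(out / "genome.fa"),
        "truth": str(out / "truth.json"),
        "chrom_sizes": str(out / "sizes.tsv"),
    }
    write_reads_bed(signal, paths["signal"], config.read_length)
    write_reads_bed(control, paths["control"], config.read_length)
    write_fasta(genome, paths["genome"], config.chrom)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"centers": truth.centers.tolist(), "config": dataclasses.asdict(truth.config)},
            fh, indent=1,
        )
    with open(paths["chrom_sizes"], "w") as fh:
        fh.write(f"{config.chrom}\t{config.chrom_length}\n")
    return paths
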