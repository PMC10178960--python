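"""F2 bulk-sequencing simulator.

Simulates an F2 population from a cross between two inbred parents in which
the maternal parent carries one recessive causal SNP among many neutral
parental SNPs, selects phenotype bulks, and samples short-read allele counts
at every SNP — emitting the same kind of allele-depth VCF a real
bulked-segregant sequencing experiment produces.

The recombination model is Haldane's: crossover counts are Poisson with mean
equal to the chromosome's genetic length in Morgans, breakpoint positions
are uniform, and there is no interference.  Phenotype is fully penetrant and
recessive: a plant shows the mutant phenotype iff it is homozygous for the
maternal allele at the causal locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .variant_io import BULKS, VariantSite, write_bulk_vcf


@dataclass
class CrossConfig:
    """Design of the simulated cross and sequencing experiment.

    Parameters
    ----------
    chrom_lengths
        Chromosome name -> length in bp.
    n_markers
        Number of neutral parental SNPs, placed uniformly at random across
        the genome (proportionally to chromosome length) unless explicit
        positions are supplied via ``marker_positions``.
    causal_locus
        (chromosome, 1-based position) of the recessive causal SNP; added
        on top of the neutral markers.  ``None`` simulates a fully null
        genome with no causal gene.
    n_f2
        Total F2 plants simulated (must comfortably exceed 4 x bulk_size so
        the recessive quarter can fill the mutant bulk).
    bulk_size
        Plants per progeny bulk (mutant O-bulk and normal N-bulk).
    parent_bulk_size
        Plants pooled per parental bulk (maternal MO and paternal PN).
    mean_depth
        Mean sequencing depth per site per bulk.  Depth is Poisson-drawn
        per site per bulk unless ``fixed_depth`` is True.
    fixed_depth
        Use ``mean_depth`` as an exact per-site depth instead of a Poisson
        mean.
    error_rate
        Per-read probability of reporting the wrong allele.
    recomb_rate
        Recombination rate in cM per Mb.
    seed
        Seed for the single RNG driving the whole simulation.
    """

    chrom_lengths: dict[str, int]
    n_markers: int = 1000
    causal_locus: tuple[str, int] | None = None
    n_f2: int = 800
    bulk_size: int = 152
    parent_bulk_size: int = 9
    mean_depth: float = 50.0
    fixed_depth: bool = False
    error_rate: float = 0.0
    recomb_rate: float = 4.0
    seed: int = 0
    marker_positions: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        if self.causal_locus is not None:
            chrom, pos = self.causal_locus
            if chrom not in self.chrom_lengths:
                raise ValueError(f"causal locus chromosome {chrom!r} unknown")
            if not 1 <= pos <= self.chrom_lengths[chrom]:
                raise ValueError(
                    f"causal locus {chrom}:{pos} outside chromosome length "
                    f"{self.chrom_lengths[chrom]}"
                )
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.recomb_rate <= 0:
            raise ValueError("recomb_rate must be > 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")


@dataclass
class Gamete:
    """A recombinant gamete: starting parental origin plus breakpoints.

    ``origin0`` is 1 if the gamete starts (at position 1) on the maternal
    haplotype, else 0.  ``breakpoints`` are the crossover positions in bp,
    sorted ascending; parental origin flips at each one.
    """

    origin0: int
    breakpoints: np.ndarray

    def origin_at(self, positions: np.ndarray) -> np.ndarray:
        """Maternal-origin indicator (0/1) at each queried bp position."""
        n_cross = np.searchsorted(self.breakpoints, positions, side="right")
        return (self.origin0 + n_cross) % 2


def simulate_gamete(chrom_length: int, recomb_rate: float, rng: np.random.Generator) -> Gamete:
    """Draw one recombinant gamete for a chromosome under the Haldane model.

    The genetic length is chrom_length(bp) * recomb_rate(cM/Mb) / 1e8
    Morgans; the crossover count is Poisson with that mean and breakpoints
    fall uniformly on the chromosome.
    """
    if chrom_length <= 0:
        raise ValueError(f"chrom_length must be > 0, got {chrom_length}")
    morgans = chrom_length * recomb_rate / 1e8
    n_cross = rng.poisson(morgans)
    breakpoints = np.sort(rng.uniform(0, chrom_length, size=n_cross))
    origin0 = int(rng.integers(0, 2))
    return Gamete(origin0=origin0, breakpoints=breakpoints)


def phenotype_of(dosage_at_causal: int) -> str:
    """Phenotype from the maternal-allele dosage at the causal marker.

    The mutant phenotype is recessive: only dosage 2 (homozygous for the
    maternal mutant allele) shows it.
    """
    if dosage_at_causal not in (0, 1, 2):
        raise ValueError(f"dosage must be 0, 1 or 2, got {dosage_at_causal}")
    return "Olr" if dosage_at_causal == 2 else "normal"


def place_markers(config: CrossConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Positions of all simulated SNPs per chromosome, causal locus included.

    Neutral markers are distributed over chromosomes proportionally to
    length and placed uniformly; positions are de-duplicated and sorted.
    """
    if config.marker_positions is not None:
        positions = {
            c: np.asarray(sorted(p), dtype=np.int64)
            for c, p in config.marker_positions.items()
        }
    else:
        chroms = list(config.chrom_lengths)
        lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
        counts = rng.multinomial(config.n_markers, lengths / lengths.sum())
        positions = {}
        for chrom, length, k in zip(chroms, lengths, counts):
            pos = np.unique(rng.integers(1, int(length) + 1, size=k))
            positions[chrom] = pos
    if config.causal_locus is not None:
        chrom, pos = config.causal_locus
        merged = np.unique(np.append(positions.get(chrom, np.empty(0, np.int64)), pos))
        positions[chrom] = merged.astype(np.int64)
    return positions


def simulate_population(
    config: CrossConfig,
    positions: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Simulate maternal-allele dosages for every F2 plant at every marker.

    Returns chrom -> int8 array of shape (n_f2, n_markers_on_chrom).  Each
    F2 plant receives two independent recombinant gametes (both parents of
    an F2 are the same heterozygous F1), so dosage = gamete1 + gamete2.
    """
    dosages: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        length = config.chrom_lengths[chrom]
        mat = np.empty((config.n_f2, len(pos)), dtype=np.int8)
        for i in range(config.n_f2):
            g1 = simulate_gamete(length, config.recomb_rate, rng)
            g2 = simulate_gamete(length, config.recomb_rate, rng)
            mat[i] = g1.origin_at(pos) + g2.origin_at(pos)
        dosages[chrom] = mat
    return dosages


def select_bulks(
    causal_dosage: np.ndarray,
    bulk_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the mutant-phenotype (O) and normal-phenotype (N) bulks.

    Plants are classified by phenotype from their causal-locus dosage and
    sampled without replacement within each class; a plant enters at most
    one bulk.  Raises ``ValueError`` naming the shortfall if either class
    is smaller than ``bulk_size``.
    """
    olr_idx = np.flatnonzero(causal_dosage == 2)
    normal_idx = np.flatnonzero(causal_dosage != 2)
    for name, idx in (("Olr", olr_idx), ("normal", normal_idx)):
        if len(idx) < bulk_size:
            raise ValueError(
                f"only {len(idx)} {name}-phenotype plants simulated; "
                f"bulk_size {bulk_size} requires at least {bulk_size} "
                f"(shortfall {bulk_size - len(idx)})"
            )
    o_bulk = rng.choice(olr_idx, size=bulk_size, replace=False)
    n_bulk = rng.choice(normal_idx, size=bulk_size, replace=False)
    return o_bulk, n_bulk


def sample_reads(
    true_freq: float | np.ndarray,
    depth: int | np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial short-read sampling of the maternal allele at one site.

    The observed maternal-read probability is
    ``true_freq * (1 - error_rate) + (1 - true_freq) * error_rate``;
    the paternal count is the remainder of the depth.
    """
    f = np.asarray(true_freq, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("true_freq must lie in [0, 1]")
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    maternal = rng.binomial(np.asarray(depth), p)
    return maternal, np.asarray(depth) - maternal


@dataclass
class SimulatedExperiment:
    """Everything one simulated sequencing experiment produced."""

    sites: list[VariantSite]
    truth: dict  # chrom, pos of the causal SNP (or None), marker roles
    config: CrossConfig
    o_bulk_freq: dict = field(default_factory=dict)  # (chrom,pos) -> true O-bulk freq
    n_bulk_freq: dict = field(default_factory=dict)


def simulate_experiment(config: CrossConfig) -> SimulatedExperiment:
    """Run the full simulation: cross, bulk selection, read sampling.

    Parental bulks are homozygous for their own allele at every parental
    SNP, so their true maternal-allele frequencies are 1 (MO) and 0 (PN);
    read error still perturbs their observed counts.
    """
    rng = np.random.default_rng(config.seed)
    positions = place_markers(config, rng)
    dosages = simulate_population(config, positions, rng)

    if config.causal_locus is not None:
        c_chrom, c_pos = config.causal_locus
        c_idx = int(np.searchsorted(positions[c_chrom], c_pos))
        causal_dosage = dosages[c_chrom][:, c_idx]
    else:
        # no causal gene: phenotype is independent of genotype
        causal_dosage = rng.integers(0, 2, size=config.n_f2) * 2
    o_bulk, n_bulk = select_bulks(causal_dosage, config.bulk_size, rng)

    sites: list[VariantSite] = []
    o_freqs: dict = {}
    n_freqs: dict = {}
    for chrom in sorted(positions):
        pos = positions[chrom]
        mat = dosages[chrom]
        f_o = mat[o_bulk].sum(axis=0) / (2.0 * config.bulk_size)
        f_n = mat[n_bulk].sum(axis=0) / (2.0 * config.bulk_size)
        freqs = {"MO": np.ones_like(f_o), "PN": np.zeros_like(f_o), "O": f_o, "N": f_n}
        if config.fixed_depth:
            depths = {b: np.full(len(pos), int(config.mean_depth)) for b in BULKS}
        else:
            depths = {b: rng.poisson(config.mean_depth, size=len(pos)) for b in BULKS}
        counts = {}
        for b in BULKS:
            m, p = sample_reads(freqs[b], depths[b], config.error_rate, rng)
            counts[b] = (m, p)
        for j, p_bp in enumerate(pos):
            site_counts = {
                # maternal allele is ALT: (ref_depth, alt_depth) = (paternal, maternal)
                b: (int(counts[b][1][j]), int(counts[b][0][j]))
                for b in BULKS
            }
            sites.append(
                VariantSite(chrom=chrom, pos=int(p_bp), ref="G", alt="A", counts=site_counts)
            )
            o_freqs[(chrom, int(p_bp))] = float(f_o[j])
            n_freqs[(chrom, int(p_bp))] = float(f_n[j])

    truth = {
        "causal": config.causal_locus,
        "positions": {c: positions[c].tolist() for c in positions},
    }
    return SimulatedExperiment(
        sites=sites, truth=truth, config=config, o_bulk_freq=o_freqs, n_bulk_freq=n_freqs
    )


def emit_bulk_vcf(
    experiment: SimulatedExperiment,
    vcf_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Write the simulated experiment as a VCF plus a truth sidecar TSV.

    The sidecar lists every marker with its role (``causal`` or
    ``neutral``); exactly one causal record is present when the simulation
    planted a causal locus.
    """
    write_bulk_vcf(experiment.sites, experiment.config.chrom_lengths, vcf_path)
    causal = experiment.truth["causal"]
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\trole\n")
        for site in experiment.sites:
            role = (
                "causal"
                if causal is not None and (site.chrom, site.pos) == tuple(causal)
                else "neutral"
            )
            fh.write(f"{site.chrom}\t{site.pos}\t{role}\n")


def read_truth(path: str | Path) -> tuple[tuple[str, int] | None, list[tuple[str, int]]]:
    """Read a truth sidecar; returns (causal locus or None, all markers)."""
    causal = None
    markers: list[tuple[str, int]] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, pos, role = line.rstrip("\n").split("\t")
            markers.append((chrom, int(pos)))
            if role == "causal":
                causal = (chrom, int(pos))
    return causal, markers
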