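"""Forward-in-time simulation of serial cohorts under drift and directional selection.

The generator emulates the sampling design the scan assumes: one closed
population genotyped at three time points — an unselected baseline (cohort I),
the same population after a first phase of directional selection (cohort II,
~20 generations by default), and after a second phase (cohort III). Selection
acts at chosen sweep loci through multiplicative viability fitness
(1 + s) per copy of the selected allele; all other loci drift. Recombination
is uniform per bp. Marker density defaults to one SNP per 50 kb, the density
of a 50K bovine array.

All randomness flows from a single seed through one numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HaplotypePanel, SnpMap

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SweepLocus:
    """A locus under directional selection for allele 1 (the 1-coded allele).

    ``phases`` selects when the locus is active: (1,), (2,) or (1, 2).
    ``start_freq`` is the selected allele's founder frequency — implanting a
    sweep means the favored allele starts rare (default 0.10, comparable to
    the baseline frequency of a haplotype later driven up by selection);
    None leaves the founder draw untouched.
    """

    chrom: int
    snp_index: int  # index within its chromosome
    s: float
    phases: tuple = (1, 2)
    start_freq: float | None = 0.10

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient s must be >= 0")
        if not set(self.phases) <= {1, 2}:
            raise ValueError("phases must be a subset of {1, 2}")
        if self.start_freq is not None and not 0 < self.start_freq < 1:
            raise ValueError("start_freq must be in (0, 1)")


@dataclass
class SimConfig:
    """Study-design parameters for the three-cohort simulation."""

    n_chrom: int = 3
    snps_per_chrom: int = 400
    chrom_length_bp: int = 20_000_000
    n_founder_haplotypes: int = 1000
    pop_size: int = 500  # diploids per generation
    generations_phase1: int = 20
    generations_phase2: int = 20
    sweep_loci: tuple = ()
    recomb_rate_per_bp: float = 1e-8  # 1 cM/Mb
    cohort_sizes: tuple = (100, 100, 100)
    effect_corr: float = -0.27
    seed: int = 0
    founder_freq_range: tuple = (0.05, 0.95)

    def __post_init__(self) -> None:
        for name in ("n_chrom", "snps_per_chrom", "chrom_length_bp",
                     "n_founder_haplotypes", "pop_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_founder_haplotypes % 2:
            raise ValueError("n_founder_haplotypes must be even")
        if self.generations_phase1 < 0 or self.generations_phase2 < 0:
            raise ValueError("generation counts must be >= 0")
        self.sweep_loci = tuple(
            sl if isinstance(sl, SweepLocus) else SweepLocus(*sl) for sl in self.sweep_loci
        )
        for sl in self.sweep_loci:
            if not (0 <= sl.chrom < self.n_chrom):
                raise ValueError(f"sweep chromosome {sl.chrom} out of range")
            if not (0 <= sl.snp_index < self.snps_per_chrom):
                raise ValueError(f"sweep SNP index {sl.snp_index} out of range")
        if len(self.cohort_sizes) != 3:
            raise ValueError("cohort_sizes must have three entries")
        if max(self.cohort_sizes) > self.pop_size:
            raise ValueError("cohort sizes cannot exceed pop_size")
        if abs(self.effect_corr) > 1:
            raise ValueError("|effect_corr| must be <= 1")

    def global_sweep_indices(self) -> np.ndarray:
        return np.array(
            [sl.chrom * self.snps_per_chrom + sl.snp_index for sl in self.sweep_loci],
            dtype=int,
        )


@dataclass
class SimResult:
    """Three cohorts over one SnpMap, their phased panels, and ground truth."""

    config: SimConfig
    snp_map: SnpMap
    cohorts: dict  # label -> GenotypeMatrix
    panels: dict  # label -> HaplotypePanel
    truth: pd.DataFrame  # columns: locus, chrom, snp_index, generation, freq
    effect_table: pd.DataFrame | None = None


def _random_map(config: SimConfig, rng: np.random.Generator) -> SnpMap:
    frames = []
    for c in range(config.n_chrom):
        pos = np.sort(
            rng.choice(
                np.arange(1, config.chrom_length_bp), size=config.snps_per_chrom, replace=False
            )
        )
        base_idx = rng.integers(0, 4, size=(config.snps_per_chrom, 2))
        # force two distinct bases, allele1 alphabetically lower
        base_idx[:, 1] = (base_idx[:, 0] + rng.integers(1, 4, size=config.snps_per_chrom)) % 4
        lo = np.minimum(base_idx[:, 0], base_idx[:, 1])
        hi = np.maximum(base_idx[:, 0], base_idx[:, 1])
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"snp{c + 1}_{j}" for j in range(config.snps_per_chrom)],
                    "chrom": c + 1,
                    "pos": pos,
                    "allele1": _BASES[lo],
                    "allele2": _BASES[hi],
                }
            )
        )
    return SnpMap(pd.concat(frames, ignore_index=True))


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None,
                      snp_map: SnpMap | None = None) -> HaplotypePanel:
    """Draw founder haplotypes with per-SNP frequencies uniform on a range.

    Sites are independent at founding (linkage builds up through finite-
    population mating); the founder frequency range (default [0.05, 0.95])
    mimics the common-variant ascertainment of SNP arrays.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if snp_map is None:
        snp_map = _random_map(config, rng)
    lo, hi = config.founder_freq_range
    n_snps = snp_map.n_snps
    freqs = rng.uniform(lo, hi, size=n_snps)
    for sl in config.sweep_loci:
        if sl.start_freq is not None:
            freqs[sl.chrom * config.snps_per_chrom + sl.snp_index] = sl.start_freq
    alleles = (rng.random((config.n_founder_haplotypes, n_snps)) < freqs).astype(np.uint8)
    ids = [f"founder_h{i}" for i in range(config.n_founder_haplotypes)]
    return HaplotypePanel(ids, alleles, snp_map)


def _recomb_prob(snp_map: SnpMap, rate_per_bp: float) -> np.ndarray:
    """Per-adjacent-interval crossover probability; chromosome breaks get 0.5."""
    pos = snp_map.pos.astype(float)
    chrom = snp_map.chrom
    r = np.minimum(np.diff(pos) * rate_per_bp, 0.5)
    r[chrom[:-1] != chrom[1:]] = 0.5  # free recombination across chromosomes
    return r


def _fitness(alleles: np.ndarray, sweep_idx: np.ndarray, s_vals: np.ndarray) -> np.ndarray:
    """Viability weight per diploid: prod over loci of (1+s)^(selected-allele dose)."""
    n_ind = alleles.shape[0] // 2
    if len(sweep_idx) == 0:
        return np.ones(n_ind)
    dose = alleles[0::2][:, sweep_idx].astype(float) + alleles[1::2][:, sweep_idx].astype(float)
    return np.prod((1.0 + s_vals) ** dose, axis=1)


def evolve(
    panel: HaplotypePanel,
    config: SimConfig,
    n_generations: int,
    rng: np.random.Generator,
    active_loci: tuple = (),
    track: list | None = None,
) -> HaplotypePanel:
    """Run Wright–Fisher random mating with recombination and viability selection.

    Each generation, ``pop_size`` diploid offspring are formed. Both parents
    of each offspring are drawn (with replacement) with probability
    proportional to their fitness; each transmits one recombinant gamete.
    When ``track`` is given, the selected-allele frequency at every sweep
    locus is appended once per generation (post-reproduction).
    """
    if panel.n_haplotypes == 0:
        raise ValueError("empty haplotype panel")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    active_loci = tuple(active_loci)
    sweep_idx = np.array(
        [sl.chrom * config.snps_per_chrom + sl.snp_index for sl in active_loci], dtype=int
    )
    s_vals = np.array([sl.s for sl in active_loci], dtype=float)

    alleles = panel.alleles
    n_snps = alleles.shape[1]
    r = _recomb_prob(panel.snp_map, config.recomb_rate_per_bp)
    N = config.pop_size

    for _ in range(n_generations):
        w = _fitness(alleles, sweep_idx, s_vals)
        p_parent = w / w.sum()
        n_parents = alleles.shape[0] // 2
        # two parents per offspring, one gamete each -> 2N gametes
        parents = rng.choice(n_parents, size=2 * N, p=p_parent)
        start = rng.integers(0, 2, size=2 * N, dtype=np.uint8)
        xo = rng.random((2 * N, n_snps - 1), dtype=np.float32) < r.astype(np.float32)
        # which parental haplotype each gamete copies at each SNP: start parity
        # XOR the cumulative crossover parity
        which = np.empty((2 * N, n_snps), dtype=bool)
        which[:, 0] = start
        np.logical_xor.accumulate(xo, axis=1, out=which[:, 1:])
        which[:, 1:] ^= start[:, None].astype(bool)
        hap_a = alleles[2 * parents]
        hap_b = alleles[2 * parents + 1]
        alleles = np.where(which, hap_b, hap_a)
        if track is not None and len(config.sweep_loci):
            track.append(alleles[:, config.global_sweep_indices()].mean(axis=0))

    ids = [f"h{i}" for i in range(alleles.shape[0])]
    return HaplotypePanel(ids, alleles, panel.snp_map)


def sample_cohorts(
    panels: dict,
    config: SimConfig,
    rng: np.random.Generator,
    truth: pd.DataFrame,
) -> SimResult:
    """Form diploid cohorts from the generation-0 / g1 / g1+g2 panels.

    Individuals are built by pairing haplotypes without replacement, so each
    retained phased panel is exactly consistent with its dosage matrix.
    """
    labels = ("I", "II", "III")
    cohorts: dict = {}
    out_panels: dict = {}
    for label, size in zip(labels, config.cohort_sizes):
        panel = panels[label]
        if 2 * size > panel.n_haplotypes:
            raise ValueError(
                f"cohort {label}: {size} diploids need {2 * size} haplotypes, "
                f"panel has {panel.n_haplotypes}"
            )
        pick = rng.choice(panel.n_haplotypes, size=2 * size, replace=False)
        alleles = panel.alleles[pick]
        sample_ids = [f"{label}_{i}" for i in range(size)]
        hap_ids = [f"{label}_{i}_{k}" for i in range(size) for k in (0, 1)]
        sub = HaplotypePanel(hap_ids, alleles, panel.snp_map)
        out_panels[label] = sub
        cohorts[label] = sub.to_genotypes(sample_ids)
    return SimResult(
        config=config,
        snp_map=panels["I"].snp_map,
        cohorts=cohorts,
        panels=out_panels,
        truth=truth,
    )


def simulate(config: SimConfig) -> SimResult:
    """Run the full three-cohort design and return cohorts, panels and truth."""
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    # burn-in population drawn from founders
    pick0 = rng.choice(founders.n_haplotypes, size=2 * config.pop_size, replace=True)
    pop = HaplotypePanel(
        [f"g0_h{i}" for i in range(2 * config.pop_size)],
        founders.alleles[pick0],
        founders.snp_map,
    )

    sweep_idx = config.global_sweep_indices()
    traj: list = []

    def record(panel, generation):
        if len(sweep_idx):
            freqs = panel.alleles[:, sweep_idx].mean(axis=0)
            for k, sl in enumerate(config.sweep_loci):
                traj.append((k, sl.chrom, sl.snp_index, generation, float(freqs[k])))

    record(pop, 0)
    panel_I = pop

    track1: list = []
    active1 = tuple(sl for sl in config.sweep_loci if 1 in sl.phases)
    panel_II = evolve(pop, config, config.generations_phase1, rng, active1, track=track1)
    for g, freqs in enumerate(track1, start=1):
        for k, sl in enumerate(config.sweep_loci):
            traj.append((k, sl.chrom, sl.snp_index, g, float(freqs[k])))

    track2: list = []
    active2 = tuple(sl for sl in config.sweep_loci if 2 in sl.phases)
    panel_III = evolve(panel_II, config, config.generations_phase2, rng, active2, track=track2)
    for g, freqs in enumerate(track2, start=config.generations_phase1 + 1):
        for k, sl in enumerate(config.sweep_loci):
            traj.append((k, sl.chrom, sl.snp_index, g, float(freqs[k])))

    truth = pd.DataFrame(
        traj, columns=["locus", "chrom", "snp_index", "generation", "freq"]
    )
    result = sample_cohorts({"I": panel_I, "II": panel_II, "III": panel_III}, config, rng, truth)

    sweep_intervals = truth_sweep_intervals(result, flank_bp=1_000_000)
    result.effect_table = simulate_effect_table(
        result.snp_map,
        sweep_intervals,
        config.effect_corr,
        rng=rng,
    )
    return result


def truth_sweep_intervals(result: SimResult, flank_bp: int = 1_000_000) -> list[tuple]:
    """Half-open intervals around each sweep locus (for conditioning analyses)."""
    cfg = result.config
    out = []
    for k, sl in enumerate(cfg.sweep_loci):
        gidx = sl.chrom * cfg.snps_per_chrom + sl.snp_index
        pos = int(result.snp_map.pos[gidx])
        chrom = result.snp_map.chrom[gidx]
        out.append((chrom, max(0, pos - flank_bp), pos + flank_bp, f"sweep{k}"))
    return out


def simulate_effect_table(
    snp_map: SnpMap,
    signature_intervals: list[tuple] | None,
    effect_corr: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    inside_corr: float | None = None,
    traits: tuple = ("milk_yield", "fertility"),
) -> pd.DataFrame:
    """Draw a bivariate-normal per-SNP effect table with a target correlation.

    Genome-wide effects have correlation ``effect_corr``; SNPs whose position
    falls inside any of ``signature_intervals`` (chrom, start, end[, name],
    half-open bp) optionally receive a different (typically more negative)
    correlation ``inside_corr``, emulating an antagonistic-pleiotropy contrast
    between swept regions and the genomic background.
    """
    if abs(effect_corr) > 1:
        raise ValueError("|effect_corr| must be <= 1")
    if inside_corr is not None and abs(inside_corr) > 1:
        raise ValueError("|inside_corr| must be <= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = snp_map.n_snps

    def draw(rho: float, size: int) -> np.ndarray:
        z = rng.standard_normal((size, 2))
        y = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho * rho)) * z[:, 1]
        return np.column_stack([z[:, 0], y])

    effects = draw(effect_corr, n)
    if inside_corr is not None and signature_intervals:
        inside = snp_mask_from_intervals(snp_map, signature_intervals)
        k = int(inside.sum())
        if k:
            effects[inside] = draw(inside_corr, k)
    return pd.DataFrame(
        effects, columns=list(traits), index=pd.Index(snp_map.snp_ids, name="snp_id")
    )


def snp_mask_from_intervals(snp_map: SnpMap, intervals: list[tuple]) -> np.ndarray:
    """Boolean per-SNP mask: position inside any (chrom, start, end, ...) interval."""
    mask = np.zeros(snp_map.n_snps, dtype=bool)
    chrom = snp_map.chrom
    pos = snp_map.pos
    for iv in intervals:
        c, start, end = iv[0], iv[1], iv[2]
        mask |= (chrom == c) & (pos >= start) & (pos < end)
    return mask


# ---------------------------------------------------------------------------
# Text export of a full simulation
# ---------------------------------------------------------------------------


def export_simresult(result: SimResult, outdir) -> None:
    """Write cohorts (ped/map + phased VCF), truth and effects as plain text."""
    from pathlib import Path

    from .genio import write_effect_table, write_ped_map, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, matrix in result.cohorts.items():
        write_ped_map(matrix, outdir / f"cohort_{label}.ped", outdir / f"cohort_{label}.map")
        write_vcf(outdir / f"cohort_{label}.vcf", result.snp_map, panel=result.panels[label])
    result.truth.to_csv(outdir / "truth_trajectories.tsv", sep="\t", index=False)
    if result.effect_table is not None:
        write_effect_table(outdir / "effect_table.tsv", result.effect_table)
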