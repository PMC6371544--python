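"""Parameter-recovery experiments: can the scan find what the simulator implants?

These are the package's end-to-end checks, run over replicate simulations:

* sweep recovery — a strong implanted sweep (s = 0.5, diploid population 500,
  40 generations) on a 100 Mb chromosome at 50 kb marker density should be
  overlapped by a called Z_AFD signature at some window size in nearly every
  replicate; the selected core haplotype should gain frequency across the
  cohorts, and the modal core haplotype at the sweep locus should gain EHH
  decay distance relative to the unselected baseline;
* neutral false positives — without sweeps, signatures appear at a low rate
  that decreases as the call threshold rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ehhscan import CoreSpec, ehh_profile
from .freqstats import afd, group_frequencies
from .genio import GenotypeMatrix, GroupAssignment
from .simcohort import SimConfig, SimResult, SweepLocus, simulate
from .zscan import build_windows, call_signatures, zscore_scan

RECOVERY_WINDOWS_BP = (500_000, 1_000_000, 2_000_000, 3_000_000)


def recovery_config(seed: int, s: float = 0.5) -> SimConfig:
    """One 100 Mb chromosome at 50 kb density with a central implanted sweep."""
    return SimConfig(
        n_chrom=1,
        snps_per_chrom=2000,
        chrom_length_bp=100_000_000,
        pop_size=500,
        n_founder_haplotypes=1000,
        generations_phase1=20,
        generations_phase2=20,
        cohort_sizes=(100, 100, 100),
        sweep_loci=(SweepLocus(0, 1000, s),) if s > 0 else (),
        seed=seed,
    )


def combined_matrix(result: SimResult) -> tuple[GenotypeMatrix, GroupAssignment]:
    """Stack the three cohorts into one matrix with a group assignment."""
    labels = list(result.cohorts)
    dosage = np.vstack([result.cohorts[l].dosage for l in labels])
    samples: list = []
    mapping: dict = {}
    for l in labels:
        for s in result.cohorts[l].samples:
            samples.append(s)
            mapping[s] = l
    return GenotypeMatrix(samples, dosage, result.snp_map), GroupAssignment(mapping, unions={})


@dataclass
class RecoveryReplicate:
    hit: bool
    n_signatures: int
    peak_z: float
    core_freq: dict  # cohort -> selected-core frequency
    decay_bp: dict  # cohort -> total EHH decay of the cohort's modal core


@dataclass
class RecoveryResult:
    replicates: list

    @property
    def recovery_rate(self) -> float:
        return float(np.mean([r.hit for r in self.replicates]))

    def mean_core_freq(self, label) -> float:
        return float(np.mean([r.core_freq[label] for r in self.replicates]))

    def mean_decay_bp(self, label) -> float:
        vals = [r.decay_bp[label] for r in self.replicates]
        return float(np.nanmean(vals))

    def median_decay_bp(self, label) -> float:
        vals = [r.decay_bp[label] for r in self.replicates]
        return float(np.nanmedian(vals))


def _selected_core(result: SimResult, gidx: int, half: int = 2) -> CoreSpec:
    """The most common core haplotype among selected-allele carriers in cohort III."""
    panel = result.panels["III"]
    a, b = gidx - half, gidx + half
    sel = panel.alleles[:, gidx] == 1
    block = panel.alleles[sel, a : b + 1]
    haps, counts = np.unique(block, axis=0, return_counts=True)
    h = tuple(int(x) for x in haps[np.argmax(counts)])
    chrom = result.snp_map.chrom[gidx]
    return CoreSpec(chrom, a, b, h)


def _modal_core(panel, gidx: int, half: int = 2) -> CoreSpec:
    """The most common core haplotype at a locus over a whole cohort panel.

    Decay comparisons across cohorts use each cohort's own modal core: it
    always has many carriers, so its EHH is a population measurement rather
    than a relatedness measurement among a handful of rare-core carriers.
    """
    a, b = gidx - half, gidx + half
    block = panel.alleles[:, a : b + 1]
    haps, counts = np.unique(block, axis=0, return_counts=True)
    h = tuple(int(x) for x in haps[np.argmax(counts)])
    return CoreSpec(panel.snp_map.chrom[gidx], a, b, h)


def run_sweep_recovery(
    n_replicates: int,
    seed: int,
    s: float = 0.5,
    call_thresh: float = 3.0,
    extend_thresh: float = 2.0,
    windows_bp: tuple = RECOVERY_WINDOWS_BP,
    ehh_threshold: float = 0.6,
) -> RecoveryResult:
    """Simulate, scan and measure sweep recovery over independent replicates.

    A replicate is a hit when any called Z_AFD signature (any window size)
    overlaps the implanted sweep SNP's position.
    """
    base = np.random.SeedSequence(seed).generate_state(n_replicates, dtype=np.uint32)
    reps = []
    for rep_seed in base:
        cfg = recovery_config(int(rep_seed) % (2**31), s=s)
        result = simulate(cfg)
        matrix, groups = combined_matrix(result)
        freqs = group_frequencies(matrix, groups, labels=["I", "II", "III"])
        track = afd(freqs, "I", "III")
        gidx = cfg.global_sweep_indices()[0]
        sweep_pos = int(result.snp_map.pos[gidx])
        hit = False
        n_sigs = 0
        peak = 0.0
        for w in windows_bp:
            zt = zscore_scan(track, build_windows(result.snp_map, "distance", w))
            sigs = call_signatures(zt, call_thresh, extend_thresh)
            n_sigs += len(sigs)
            peak = max(peak, float(np.nanmax(zt.z)))
            if any(sg.start_bp <= sweep_pos <= sg.end_bp for sg in sigs):
                hit = True
        # frequency trajectory of the selected core (cohort III's swept
        # haplotype); decay of each cohort's own modal core at the locus,
        # whose many carriers make EHH a stable population measurement
        core = _selected_core(result, gidx)
        core_freq = {}
        decay = {}
        for label, panel in result.panels.items():
            match = (
                panel.alleles[:, core.start : core.end + 1]
                == np.asarray(core.haplotype, dtype=np.uint8)
            ).all(axis=1)
            core_freq[label] = float(match.mean())
            prof = ehh_profile(panel, _modal_core(result.panels[label], gidx),
                               ehh_threshold, full=False)
            decay[label] = float(prof.total_decay_bp)
        reps.append(RecoveryReplicate(hit, n_sigs, peak, core_freq, decay))
    return RecoveryResult(reps)


def run_neutral_false_positives(
    n_replicates: int,
    seed: int,
    call_thresholds: tuple = (2.5, 3.0, 3.5),
    window_bp: int = 1_000_000,
) -> dict:
    """Mean called-signature count per neutral genome at rising call thresholds."""
    base = np.random.SeedSequence(seed).generate_state(n_replicates, dtype=np.uint32)
    counts = {t: 0 for t in call_thresholds}
    for rep_seed in base:
        cfg = SimConfig(
            n_chrom=3,
            snps_per_chrom=400,
            chrom_length_bp=20_000_000,
            pop_size=200,
            n_founder_haplotypes=400,
            cohort_sizes=(80, 80, 80),
            sweep_loci=(),
            seed=int(rep_seed) % (2**31),
        )
        result = simulate(cfg)
        matrix, groups = combined_matrix(result)
        freqs = group_frequencies(matrix, groups, labels=["I", "II", "III"])
        track = afd(freqs, "I", "III")
        zt = zscore_scan(track, build_windows(result.snp_map, "distance", window_bp))
        for t in call_thresholds:
            counts[t] += len(call_signatures(zt, call_thresh=t, extend_thresh=2.0))
    return {t: c / n_replicates for t, c in counts.items()}
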