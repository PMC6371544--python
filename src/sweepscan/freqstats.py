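"""Per-group allele frequencies and single-SNP differentiation statistics.

For each cohort the frequency ``p`` of allele1 is computed from non-missing
genotypes (complete-case denominators), together with the expected
heterozygosity ``2p(1-p)``. Two cohorts are compared per SNP by

* AFD — the absolute allele frequency difference ``|p_A - p_B|`` (symmetric),
* HD  — the signed expected-heterozygosity difference ``het_A - het_B``
  (antisymmetric; first-listed group minus second).

A random-AFD calibration splits one cohort into two subsets with identical
selection history; the largest AFD observed between them bounds what drift
and sampling alone produce, and its rounded value is the recommended
threshold for calling a single-SNP frequency change non-random. Direction
consistency further filters for SNPs whose frequency moved the same way in
both selection phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, GroupAssignment, SnpMap


@dataclass
class FrequencyTable:
    """Per-SNP allele1 frequency, allele count used, and expected het per group."""

    snp_map: SnpMap
    groups: list
    p: np.ndarray  # (n_groups, n_snps), NaN where undefined
    n_obs: np.ndarray  # (n_groups, n_snps) alleles counted

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)

    @property
    def het(self) -> np.ndarray:
        """Expected heterozygosity 2p(1-p) per group per SNP."""
        return 2.0 * self.p * (1.0 - self.p)

    def _gi(self, group) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in frequency table") from None

    def freq(self, group) -> np.ndarray:
        return self.p[self._gi(group)]

    def group_het(self, group) -> np.ndarray:
        return self.het[self._gi(group)]

    @classmethod
    def from_frequencies(cls, snp_map: SnpMap, freqs: dict, n_obs: int = 0) -> "FrequencyTable":
        """Build directly from known frequencies (e.g. published per-group values)."""
        groups = list(freqs)
        p = np.array([np.asarray(freqs[g], dtype=float) for g in groups])
        n = np.full_like(p, n_obs, dtype=int)
        return cls(snp_map, groups, p, n)

    def to_frame(self) -> pd.DataFrame:
        out = self.snp_map.frame[["snp_id", "chrom", "pos"]].copy()
        for gi, g in enumerate(self.groups):
            out[f"p_{g}"] = self.p[gi]
            out[f"het_{g}"] = self.het[gi]
            out[f"n_{g}"] = self.n_obs[gi]
        return out


@dataclass
class SiteStatTrack:
    """Per-SNP comparison statistic S_i between two groups (AFD or HD)."""

    kind: str  # "AFD" | "HD"
    comparison: tuple  # (group_A, group_B)
    values: np.ndarray  # NaN = flagged missing
    snp_map: SnpMap

    def __post_init__(self) -> None:
        if self.kind not in ("AFD", "HD"):
            raise ValueError("kind must be 'AFD' or 'HD'")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.snp_map.n_snps:
            raise ValueError("track length does not match SnpMap")

    def to_frame(self) -> pd.DataFrame:
        out = self.snp_map.frame[["snp_id", "chrom", "pos"]].copy()
        out[self.kind] = self.values
        return out


def group_frequencies(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    labels: list | None = None,
    haploid_samples: set | None = None,
) -> FrequencyTable:
    """Count allele1 frequencies per group with complete-case denominators.

    ``haploid_samples`` (e.g. males on the X chromosome) contribute one
    allele per non-missing call, counting dosage >= 1 as one copy of allele1.
    """
    if labels is None:
        labels = sorted(set(groups.mapping.values()))
    haploid_samples = haploid_samples or set()
    p = np.full((len(labels), matrix.snp_map.n_snps), np.nan)
    n_obs = np.zeros((len(labels), matrix.snp_map.n_snps), dtype=int)
    for gi, label in enumerate(labels):
        idx = groups.indices(label, matrix)
        dos = matrix.dosage[idx].astype(float)
        dos[dos == MISSING] = np.nan
        is_hap = np.array([matrix.samples[i] in haploid_samples for i in idx])
        ploidy = np.where(is_hap, 1.0, 2.0)[:, None] * ~np.isnan(dos).astype(bool)
        counts = np.where(is_hap[:, None], np.minimum(dos, 1.0), dos)
        denom = np.where(np.isnan(dos), 0.0, ploidy).sum(axis=0)
        num = np.nansum(counts, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[gi] = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
        n_obs[gi] = denom.astype(int)
    return FrequencyTable(matrix.snp_map, list(labels), p, n_obs)


def afd(freqs: FrequencyTable, group_a, group_b) -> SiteStatTrack:
    """Absolute allele frequency difference |p_A - p_B| per SNP."""
    values = np.abs(freqs.freq(group_a) - freqs.freq(group_b))
    return SiteStatTrack("AFD", (group_a, group_b), values, freqs.snp_map)


def hd(freqs: FrequencyTable, group_a, group_b) -> SiteStatTrack:
    """Signed expected-heterozygosity difference het_A - het_B per SNP."""
    values = freqs.group_het(group_a) - freqs.group_het(group_b)
    return SiteStatTrack("HD", (group_a, group_b), values, freqs.snp_map)


def afd_filter(freqs: FrequencyTable, group_a, group_b, min_afd: float) -> np.ndarray:
    """Mask of SNPs with AFD >= min_afd (inclusive threshold)."""
    if not 0 <= min_afd <= 1:
        raise ValueError("min_afd must be in [0, 1]")
    track = afd(freqs, group_a, group_b).values
    return ~np.isnan(track) & (track >= min_afd)


def afd_fraction(track: SiteStatTrack, thresholds) -> pd.DataFrame:
    """Count and fraction of SNPs with AFD >= t for each threshold t."""
    v = track.values[~np.isnan(track.values)]
    rows = [
        (t, int((v >= t).sum()), (v >= t).sum() / len(v) if len(v) else np.nan)
        for t in thresholds
    ]
    return pd.DataFrame(rows, columns=["threshold", "count", "fraction"])


@dataclass
class RandomAfdReport:
    """Empirical null distribution of AFD between same-history subsets."""

    distribution: np.ndarray
    max_afd: float
    recommended_threshold: float
    subset_sizes: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"random_afd": self.distribution})


def calibrate_random_afd(
    matrix: GenotypeMatrix,
    subset_a: list,
    subset_b: list,
) -> RandomAfdReport:
    """AFD distribution between two disjoint subsets of one cohort.

    Both subsets share the selection history, so their AFD is pure sampling
    noise; the recommended threshold is the maximum rounded to 0.01.
    """
    set_a, set_b = set(subset_a), set(subset_b)
    if not set_a or not set_b:
        raise ValueError("both subsets must be non-empty")
    if set_a & set_b:
        raise ValueError("subsets must be disjoint")
    groups = GroupAssignment(
        {**{s: "a" for s in subset_a}, **{s: "b" for s in subset_b}}, unions={}
    )
    sub_idx = matrix.sample_index(list(subset_a) + list(subset_b))
    sub = GenotypeMatrix(
        [matrix.samples[i] for i in sub_idx], matrix.dosage[sub_idx], matrix.snp_map
    )
    freqs = group_frequencies(sub, groups, labels=["a", "b"])
    dist = afd(freqs, "a", "b").values
    dist = dist[~np.isnan(dist)]
    max_afd = float(dist.max())
    return RandomAfdReport(
        distribution=dist,
        max_afd=max_afd,
        recommended_threshold=round(max_afd, 2),
        subset_sizes=(len(set_a), len(set_b)),
    )


@dataclass
class DirectionSummary:
    n_total: int
    n_kept: int

    @property
    def fraction(self) -> float:
        return self.n_kept / self.n_total if self.n_total else float("nan")


def direction_consistent(
    freqs: FrequencyTable,
    group_i,
    group_ii,
    group_iii,
    min_afd: float,
) -> tuple[np.ndarray, DirectionSummary]:
    """SNPs whose frequency moved the same way in both phases with total AFD >= min_afd.

    Keeps SNPs with sign(p_II - p_I) == sign(p_III - p_II) != 0 and
    |p_III - p_I| >= min_afd. Ties (zero change in either phase) are treated
    as inconsistent.
    """
    p1 = freqs.freq(group_i)
    p2 = freqs.freq(group_ii)
    p3 = freqs.freq(group_iii)
    d1 = np.sign(p2 - p1)
    d2 = np.sign(p3 - p2)
    with np.errstate(invalid="ignore"):
        mask = (d1 == d2) & (d1 != 0) & (np.abs(p3 - p1) >= min_afd)
    mask &= ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3))
    return mask, DirectionSummary(n_total=len(mask), n_kept=int(mask.sum()))
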