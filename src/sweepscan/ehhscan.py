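"""Extended haplotype homozygosity (EHH) around core haplotypes.

EHH at a flanking SNP x is the probability that two haplotypes drawn at
random (without replacement) from the carriers of a core haplotype are
identical at every SNP from the core out to x:

    EHH(x) = sum_g C(e_g, 2) / C(c, 2)

where the c carriers split into groups of identical extended haplotypes of
sizes e_g. EHH equals 1 at the core and is non-increasing with distance,
since extending the interval can only refine the grouping. A long span over
which EHH stays above a threshold (0.6 by default) in the selected cohort
but not the baseline cohort is the haplotype-based evidence of a sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import HaplotypePanel, SnpMap


@dataclass(frozen=True)
class CoreSpec:
    """A contiguous core SNP range [start, end] (global indices) and its haplotype."""

    chrom: object
    start: int  # global SNP index, inclusive
    end: int  # global SNP index, inclusive
    haplotype: tuple  # allele codes (0/1) over the core SNPs

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("core end < start")
        if len(self.haplotype) != self.end - self.start + 1:
            raise ValueError("core haplotype length does not match SNP range")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def _validate_core(panel: HaplotypePanel, core: CoreSpec) -> None:
    chrom = panel.snp_map.chrom
    if core.start < 0 or core.end >= panel.snp_map.n_snps:
        raise ValueError("core SNP range outside the map")
    if not (chrom[core.start : core.end + 1] == core.chrom).all():
        raise ValueError("core SNP range crosses a chromosome boundary")


def carriers(panel: HaplotypePanel, core: CoreSpec) -> np.ndarray:
    """Indices of haplotypes matching the core haplotype exactly."""
    _validate_core(panel, core)
    block = panel.alleles[:, core.start : core.end + 1]
    return np.flatnonzero((block == np.asarray(core.haplotype, dtype=np.uint8)).all(axis=1))


def _homozygosity(group_sizes: np.ndarray, c: int) -> float:
    return float((group_sizes * (group_sizes - 1)).sum() / (c * (c - 1)))


def ehh_at(panel: HaplotypePanel, core: CoreSpec, target: int) -> float:
    """EHH between the core edge and a target SNP (global index), inclusive."""
    carr = carriers(panel, core)
    c = len(carr)
    if c < 2:
        raise ValueError("EHH undefined: fewer than 2 core-haplotype carriers")
    if target >= core.start and target <= core.end:
        return 1.0
    if target > core.end:
        cols = slice(core.end + 1, target + 1)
    else:
        cols = slice(target, core.start)
    ext = panel.alleles[carr, cols]
    _, counts = np.unique(ext, axis=0, return_counts=True)
    return _homozygosity(counts, c)


@dataclass
class EhhProfile:
    """EHH at every flanking SNP plus decay distances at a threshold."""

    core: CoreSpec
    carrier_count: int
    core_frequency: float
    threshold: float
    snp_index: np.ndarray  # global SNP indices, ascending, includes the core SNPs
    ehh: np.ndarray  # EHH per SNP in snp_index
    left_decay_bp: int
    right_decay_bp: int
    snp_map: SnpMap

    @property
    def total_decay_bp(self) -> int:
        """Left + right decay plus the core span itself."""
        core_span = int(self.snp_map.pos[self.core.end] - self.snp_map.pos[self.core.start])
        return self.left_decay_bp + self.right_decay_bp + core_span

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_map.snp_ids[self.snp_index],
                "pos": self.snp_map.pos[self.snp_index],
                "EHH": self.ehh,
            }
        )


def _directional_ehh(
    panel: HaplotypePanel, carr: np.ndarray, start_col: int, stop_col: int, step: int,
    stop_below: float = 0.0,
) -> np.ndarray:
    """EHH at each SNP walking from the core edge outward (incremental grouping).

    Group labels refine as each SNP is added, which makes monotone
    non-increase structural. With ``stop_below`` > 0 the walk ends after the
    first value strictly below it (EHH can only shrink further out), so scans
    that only need decay distances avoid walking whole chromosomes.
    """
    c = len(carr)
    denom = c * (c - 1)
    labels = np.zeros(c, dtype=np.int64)
    out = []
    for col in range(start_col, stop_col, step):
        a = panel.alleles[carr, col].astype(np.int64)
        labels = labels * 2 + a
        _, labels = np.unique(labels, return_inverse=True)
        counts = np.bincount(labels)
        v = float((counts * (counts - 1)).sum() / denom)
        out.append(v)
        if v < stop_below:
            break
    return np.array(out)


def ehh_profile(
    panel: HaplotypePanel, core: CoreSpec, threshold: float = 0.6,
    full: bool = True,
) -> EhhProfile:
    """EHH profile around the core plus decay distances at the threshold.

    The decay distance per direction is the bp span from the core edge to the
    last *consecutive* SNP with EHH >= threshold (the first drop below the
    threshold terminates the span; no interpolation). With ``full=True`` the
    profile covers the whole chromosome; otherwise the walk stops one SNP
    past the threshold crossing, which is all decay distances need.
    """
    carr = carriers(panel, core)
    c = len(carr)
    if c < 2:
        raise ValueError("EHH undefined: fewer than 2 core-haplotype carriers")
    sl = panel.snp_map.chrom_slices()[core.chrom]
    pos = panel.snp_map.pos
    stop_below = 0.0 if full else threshold

    right = _directional_ehh(panel, carr, core.end + 1, sl.stop, 1, stop_below)
    left = _directional_ehh(panel, carr, core.start - 1, sl.start - 1, -1, stop_below)

    def decay(vals: np.ndarray, edge_idx: int, step: int) -> int:
        span = 0
        for k, v in enumerate(vals):
            if v < threshold:
                break
            span = abs(int(pos[edge_idx + step * (k + 1)]) - int(pos[edge_idx]))
        return span

    right_decay = decay(right, core.end, 1)
    left_decay = decay(left, core.start, -1)

    idx = np.arange(core.start - len(left), core.end + 1 + len(right))
    ehh_vals = np.concatenate(
        [left[::-1], np.ones(core.size), right]
    )
    return EhhProfile(
        core=core,
        carrier_count=c,
        core_frequency=c / panel.n_haplotypes,
        threshold=threshold,
        snp_index=idx,
        ehh=ehh_vals,
        left_decay_bp=left_decay,
        right_decay_bp=right_decay,
        snp_map=panel.snp_map,
    )


def core_haplotype_frequencies(
    panels: dict, core: CoreSpec
) -> pd.DataFrame:
    """Frequency of every distinct core haplotype per cohort.

    Rows are haplotype strings (allele1/allele2 letters from the map), one
    column per cohort, sorted descending by the last cohort's frequency.
    """
    labels = list(panels)
    any_panel = panels[labels[0]]
    _validate_core(any_panel, core)
    a1 = any_panel.snp_map.frame["allele1"].to_numpy()[core.start : core.end + 1]
    a2 = any_panel.snp_map.frame["allele2"].to_numpy()[core.start : core.end + 1]

    rows: dict = {}
    for label in labels:
        block = panels[label].alleles[:, core.start : core.end + 1]
        haps, counts = np.unique(block, axis=0, return_counts=True)
        n = block.shape[0]
        for h, cnt in zip(haps, counts):
            name = "".join(a2[k] if h[k] else a1[k] for k in range(len(h)))
            rows.setdefault(name, {})[label] = cnt / n
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df.reindex(columns=labels)
    df.index.name = "haplotype"
    return df.sort_values(labels[-1], ascending=False)


@dataclass
class CoreScanSummary:
    """Counts of long-EHH regions per decay-distance cut, after deduplication."""

    cuts_bp: tuple
    region_counts: dict  # cut -> merged region count
    regions: dict  # cut -> list of (chrom, start_bp, end_bp)


def scan_cores(
    panel: HaplotypePanel,
    core_size_snps: int = 5,
    threshold: float = 0.6,
    min_core_freq: float = 0.05,
    cuts_bp: tuple = (1_000_000, 1_500_000),
) -> tuple[list[EhhProfile], CoreScanSummary]:
    """Slide cores of ``core_size_snps`` across the panel and profile each.

    Every core haplotype with frequency >= ``min_core_freq`` is profiled.
    For each decay cut, cores whose best haplotype spans >= the cut are
    deduplicated into maximal regions (union of their EHH spans) before
    counting, so the counts are regions, not cores.
    """
    if core_size_snps < 1:
        raise ValueError("core_size_snps must be >= 1")
    snp_map = panel.snp_map
    pos = snp_map.pos
    profiles: list[EhhProfile] = []
    n_hap = panel.n_haplotypes
    for chrom, sl in snp_map.chrom_slices().items():
        for a in range(sl.start, sl.stop - core_size_snps + 1):
            b = a + core_size_snps - 1
            block = panel.alleles[:, a : b + 1]
            haps, counts = np.unique(block, axis=0, return_counts=True)
            for h, cnt in zip(haps, counts):
                if cnt / n_hap < min_core_freq or cnt < 2:
                    continue
                prof = ehh_profile(
                    panel, CoreSpec(chrom, a, b, tuple(int(x) for x in h)),
                    threshold, full=False,
                )
                profiles.append(prof)
    # per core position, keep the longest span among its haplotypes
    best_by_core: dict = {}
    for prof in profiles:
        key = (prof.core.chrom, prof.core.start)
        if key not in best_by_core or prof.total_decay_bp > best_by_core[key].total_decay_bp:
            best_by_core[key] = prof
    region_counts = {}
    regions_out = {}
    for cut in cuts_bp:
        spans = []
        for prof in best_by_core.values():
            if prof.total_decay_bp >= cut:
                start_bp = int(pos[prof.core.start]) - prof.left_decay_bp
                end_bp = int(pos[prof.core.end]) + prof.right_decay_bp
                spans.append((prof.core.chrom, start_bp, end_bp))
        merged = _merge_spans(spans)
        region_counts[cut] = len(merged)
        regions_out[cut] = merged
    return profiles, CoreScanSummary(tuple(cuts_bp), region_counts, regions_out)


def _merge_spans(spans: list[tuple]) -> list[tuple]:
    spans = sorted(spans, key=lambda t: (str(t[0]), t[1], t[2]))
    out: list[list] = []
    for chrom, s, e in spans:
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([chrom, s, e])
    return [tuple(x) for x in out]


def profiles_to_frame(profiles: list[EhhProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        a1 = p.snp_map.frame["allele1"].to_numpy()[p.core.start : p.core.end + 1]
        a2 = p.snp_map.frame["allele2"].to_numpy()[p.core.start : p.core.end + 1]
        hap = "".join(
            a2[k] if p.core.haplotype[k] else a1[k] for k in range(p.core.size)
        )
        rows.append(
            {
                "chrom": p.core.chrom,
                "core_start_bp": int(p.snp_map.pos[p.core.start]),
                "core_end_bp": int(p.snp_map.pos[p.core.end]),
                "haplotype": hap,
                "frequency": p.core_frequency,
                "left_decay_bp": p.left_decay_bp,
                "right_decay_bp": p.right_decay_bp,
                "total_decay_bp": p.total_decay_bp,
            }
        )
    return pd.DataFrame(rows)


def bifurcation_text(panel: HaplotypePanel, core: CoreSpec, n_snps: int = 5) -> str:
    """Nested parenthesized counts of haplotype splits right of the core.

    A plain-text stand-in for a bifurcation diagram: each level adds one SNP
    and shows how the carrier group splits, e.g. ``(12 -> 0:(8 -> ...), 1:(4))``.
    """
    carr = carriers(panel, core)
    sl = panel.snp_map.chrom_slices()[core.chrom]
    stop = min(core.end + 1 + n_snps, sl.stop)

    def rec(rows: np.ndarray, col: int) -> str:
        if col >= stop or len(rows) == 0:
            return f"({len(rows)})"
        a = panel.alleles[rows, col]
        parts = []
        for allele in (0, 1):
            sub = rows[a == allele]
            if len(sub):
                parts.append(f"{allele}:{rec(sub, col + 1)}")
        return f"({len(rows)} -> " + ", ".join(parts) + ")"

    return rec(carr, core.end + 1)
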