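"""Long-range scan: sliding-window means, per-chromosome Z-scores, signature calls.

The long-range statistic for SNP j is the mean of the single-SNP statistic
S_i (AFD or HD) over all markers i in j's window,

    X_j = sum_{i=l_j..u_j} S_i / (u_j - l_j + 1),

standardized per chromosome,

    Z_j = (X_j - mean(X)) / sd(X),

so that chromosomes with different baseline differentiation are comparable.
Windows slide one SNP at a time (every SNP is a window center). Interior
windows are symmetric — (size-1)/2 markers each side in fixed-count mode,
size/2 bp each side in fixed-distance mode — and edge windows truncate to
whatever markers the chromosome offers, so SNPs near chromosome ends use
unequal flank counts rather than being dropped.

A selection signature is a region whose Z reaches the call threshold
(default 3) with a contiguous extension at the extend threshold (default 2)
on both sides of the peak. Z_AFD is one-sided high (AFD is non-negative;
only excess differentiation is evidence of selection); Z_HD is two-sided
with the sign reported, since selection can lower or raise local
heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqstats import SiteStatTrack
from .genio import SnpMap

DEFAULT_WINDOWS_BP = (500_000, 1_000_000, 2_000_000, 3_000_000)


@dataclass
class WindowSpec:
    """Per-SNP window bounds [l_j, u_j] (global indices, inclusive)."""

    mode: str  # "count" | "distance"
    size: int  # SNP count (odd) or bp span
    lower: np.ndarray
    upper: np.ndarray
    snp_map: SnpMap

    def label(self) -> str:
        if self.mode == "count":
            return f"{self.size}snp"
        return f"{self.size / 1e6:g}Mb"


def build_windows(snp_map: SnpMap, mode: str, size: int) -> WindowSpec:
    """Window bounds per SNP; windows never cross a chromosome boundary."""
    n = snp_map.n_snps
    lower = np.zeros(n, dtype=int)
    upper = np.zeros(n, dtype=int)
    if mode == "count":
        if size < 1 or size % 2 == 0:
            raise ValueError("count-mode window size must be odd and >= 1")
        half = (size - 1) // 2
    elif mode == "distance":
        if size <= 0:
            raise ValueError("distance-mode window size must be positive")
    else:
        raise ValueError("mode must be 'count' or 'distance'")

    for chrom, sl in snp_map.chrom_slices().items():
        start, stop = sl.start, sl.stop
        if start == stop:
            raise ValueError(f"chromosome {chrom!r} has no SNPs")
        idx = np.arange(start, stop)
        if mode == "count":
            lower[sl] = np.maximum(idx - half, start)
            upper[sl] = np.minimum(idx + half, stop - 1)
        else:
            pos = snp_map.pos[sl].astype(np.int64)
            half_bp = size / 2
            lower[sl] = start + np.searchsorted(pos, pos - half_bp, side="left")
            upper[sl] = start + np.searchsorted(pos, pos + half_bp, side="right") - 1
    return WindowSpec(mode, size, lower, upper, snp_map)


def longrange_mean(track: SiteStatTrack, windows: WindowSpec) -> np.ndarray:
    """X_j: mean of S_i over each window, skipping flagged-missing S_i.

    Computed with prefix sums (O(n)); windows whose statistics are all
    missing get NaN.
    """
    if windows.snp_map.n_snps != track.snp_map.n_snps:
        raise ValueError("track and windows built over different maps")
    s = track.values
    usable = ~np.isnan(s)
    vals = np.where(usable, s, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(usable)])
    num = csum[windows.upper + 1] - csum[windows.lower]
    cnt = ccnt[windows.upper + 1] - ccnt[windows.lower]
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    return x


@dataclass
class ZScoreTrack:
    """Windowed means X_j and per-chromosome standardized Z_j."""

    kind: str
    comparison: tuple
    windows: WindowSpec
    x: np.ndarray
    z: np.ndarray
    chrom_stats: dict  # chrom -> (mean, sd)
    snp_map: SnpMap

    def to_frame(self) -> pd.DataFrame:
        out = self.snp_map.frame[["snp_id", "chrom", "pos"]].copy()
        out["X"] = self.x
        out["Z"] = self.z
        return out

    def to_bedgraph(self, path) -> None:
        """4-column text: chrom, 0-based start, end, Z."""
        chrom = self.snp_map.chrom
        pos = self.snp_map.pos
        with open(path, "w") as fh:
            for j in range(self.snp_map.n_snps):
                if np.isnan(self.z[j]):
                    continue
                fh.write(f"{chrom[j]}\t{pos[j] - 1}\t{pos[j]}\t{self.z[j]:.6g}\n")


def standardize(
    x: np.ndarray, track: SiteStatTrack, windows: WindowSpec
) -> ZScoreTrack:
    """Z_j = (X_j - chromosome mean) / chromosome sample sd (ddof=1)."""
    snp_map = windows.snp_map
    z = np.full_like(x, np.nan, dtype=float)
    stats = {}
    for chrom, sl in snp_map.chrom_slices().items():
        xs = x[sl]
        ok = ~np.isnan(xs)
        if ok.sum() < 2:
            raise ValueError(f"chromosome {chrom!r}: need >= 2 usable window means")
        mean = float(xs[ok].mean())
        sd = float(xs[ok].std(ddof=1))
        # rolling sums leave O(eps) noise on a truly constant chromosome
        if sd <= 1e-12 * max(abs(mean), 1.0):
            stats[chrom] = (mean, 0.0)
            continue  # all-constant chromosome: Z undefined, left NaN
        stats[chrom] = (mean, sd)
        z[sl] = (xs - mean) / sd
    return ZScoreTrack(track.kind, track.comparison, windows, x, z, stats, snp_map)


def zscore_scan(track: SiteStatTrack, windows: WindowSpec) -> ZScoreTrack:
    """Convenience: windowed means followed by per-chromosome standardization."""
    return standardize(longrange_mean(track, windows), track, windows)


@dataclass
class SelectionSignature:
    """A called region: a Z peak >= call threshold extended at >= extend threshold."""

    chrom: object
    start_bp: int
    end_bp: int
    peak_bp: int
    peak_z: float
    kind: str  # "Z_AFD" | "Z_HD"
    sign: int  # +1 / -1 (HD); +1 for AFD
    comparison: tuple
    window_label: str
    n_snps: int

    def as_tuple(self):
        return (self.chrom, self.start_bp, self.end_bp)


def call_signatures(
    zt: ZScoreTrack,
    call_thresh: float = 3.0,
    extend_thresh: float = 2.0,
) -> list[SelectionSignature]:
    """Call signatures: maximal runs at the extend threshold containing a peak.

    For AFD, a run is consecutive SNPs with Z >= extend_thresh; for HD the run
    is additionally sign-consistent and uses |Z|. A run qualifies when it
    contains at least one SNP at the call threshold; the peak is its maximum
    (leftmost on ties). Flagged-missing Z breaks runs.
    """
    if call_thresh < extend_thresh:
        raise ValueError("call_thresh must be >= extend_thresh")
    two_sided = zt.kind == "HD"
    kind = f"Z_{zt.kind}"
    out: list[SelectionSignature] = []
    pos = zt.snp_map.pos
    for chrom, sl in zt.snp_map.chrom_slices().items():
        z = zt.z[sl]
        offset = sl.start
        score = np.abs(z) if two_sided else z
        with np.errstate(invalid="ignore"):
            qual = ~np.isnan(z) & (score >= extend_thresh)
        sign = np.sign(z)
        j = 0
        n = len(z)
        while j < n:
            if not qual[j]:
                j += 1
                continue
            k = j
            while k + 1 < n and qual[k + 1] and (not two_sided or sign[k + 1] == sign[j]):
                k += 1
            run = slice(j, k + 1)
            run_scores = score[run]
            if run_scores.max() >= call_thresh:
                peak_local = int(np.argmax(run_scores)) + j
                out.append(
                    SelectionSignature(
                        chrom=chrom,
                        start_bp=int(pos[offset + j]),
                        end_bp=int(pos[offset + k]),
                        peak_bp=int(pos[offset + peak_local]),
                        peak_z=float(z[peak_local]),
                        kind=kind,
                        sign=int(sign[peak_local]) if two_sided else 1,
                        comparison=zt.comparison,
                        window_label=zt.windows.label(),
                        n_snps=k - j + 1,
                    )
                )
            j = k + 1
    return out


@dataclass
class MergedRegion:
    """Union of overlapping signatures across window sizes (rule is a package choice)."""

    chrom: object
    start_bp: int
    end_bp: int
    best_peak_z: float
    best_peak_bp: int
    kinds: tuple
    window_labels: tuple
    n_merged: int


def merge_across_windows(signature_lists: list[list[SelectionSignature]]) -> list[MergedRegion]:
    """Merge signature intervals from several window sizes into maximal regions.

    Overlapping or abutting intervals on the same chromosome are unioned;
    each merged region records the contributing window labels, statistic
    kinds, and the strongest peak by |Z|.
    """
    sigs = [s for lst in signature_lists for s in lst]
    if not sigs:
        return []
    sigs.sort(key=lambda s: (str(s.chrom), s.start_bp, s.end_bp))
    merged: list[MergedRegion] = []
    cur: list[SelectionSignature] = []

    def flush(group):
        best = max(group, key=lambda s: abs(s.peak_z))
        merged.append(
            MergedRegion(
                chrom=group[0].chrom,
                start_bp=min(s.start_bp for s in group),
                end_bp=max(s.end_bp for s in group),
                best_peak_z=best.peak_z,
                best_peak_bp=best.peak_bp,
                kinds=tuple(sorted({s.kind for s in group})),
                window_labels=tuple(sorted({s.window_label for s in group})),
                n_merged=len(group),
            )
        )

    for s in sigs:
        if cur and s.chrom == cur[0].chrom and s.start_bp <= max(c.end_bp for c in cur):
            cur.append(s)
        else:
            if cur:
                flush(cur)
            cur = [s]
    flush(cur)
    return merged


def signatures_to_frame(sigs: list[SelectionSignature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "peak_bp": s.peak_bp,
                "peak_Z": s.peak_z,
                "stat": s.kind,
                "sign": s.sign,
                "window": s.window_label,
                "comparison": "-".join(map(str, s.comparison)),
                "n_snps": s.n_snps,
            }
            for s in sigs
        ]
    )
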