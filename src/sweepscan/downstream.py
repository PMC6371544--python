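"""Cohort structure and signature-conditioned downstream analyses.

Three analyses sit downstream of the scans:

* identity-by-state (IBS) distances between individuals and their classical
  (Torgerson) multidimensional scaling, which visualizes the serial drift of
  the cohorts through genotype space;
* Pearson correlations between per-SNP effects of two traits, restricted to
  SNP subsets (e.g. inside called signatures) with optional interval
  exclusions for known outlier regions;
* annotation of called signatures against gene intervals, labelling genes as
  contained or proximal within a configurable distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genio import MISSING, GenotypeMatrix, SnpMap
from .zscan import SelectionSignature


@dataclass
class DistanceMatrix:
    """Pairwise 1 - IBS distances; symmetric, zero diagonal, in [0, 1]."""

    samples: list
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


def ibs_distances(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Distance = 1 - mean over co-observed SNPs of (2 - |dosage difference|)/2.

    Identical genotypes share both alleles at every SNP (distance 0); opposite
    homozygotes share none (distance 1). Pairs with zero co-observed SNPs are
    an error, as is an all-missing sample.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("IBS distances need >= 2 samples")
    dos = matrix.dosage.astype(float)
    miss = dos == MISSING
    if miss.all(axis=1).any():
        bad = matrix.samples[int(np.flatnonzero(miss.all(axis=1))[0])]
        raise ValueError(f"sample {bad!r} has no called genotypes")
    dos[miss] = np.nan
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.abs(dos[i + 1 :] - dos[i])  # NaN where either missing
        co = ~np.isnan(diff)
        n_co = co.sum(axis=1)
        if (n_co == 0).any():
            j = int(np.flatnonzero(n_co == 0)[0]) + i + 1
            raise ValueError(
                f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} share no called SNPs"
            )
        ibs = np.nansum((2.0 - diff) / 2.0, axis=1) / n_co
        d[i, i + 1 :] = d[i + 1 :, i] = 1.0 - ibs
    return DistanceMatrix(list(matrix.samples), d)


@dataclass
class MdsResult:
    """Classical MDS coordinates, eigenvalue-ordered, deterministic signs."""

    samples: list
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # all positive eigenvalues kept, descending

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.samples, columns=cols)


def classical_mds(d: DistanceMatrix, k: int = 4) -> MdsResult:
    """Torgerson metric MDS: double-centered Gram eigendecomposition.

    Coordinates are sqrt(eigenvalue)-scaled eigenvectors of the top-k
    positive-eigenvalue axes; if fewer than k positive eigenvalues exist the
    result is truncated. Each axis is sign-fixed so its largest-magnitude
    loading is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dm = np.asarray(d.values, dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    for axis in range(k_eff):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return MdsResult(list(d.samples), coords, evals[:n_pos])


@dataclass
class CorrelationReport:
    """Pearson correlation between two effect vectors on a SNP subset."""

    label: str
    n_snps: int
    r: float
    p_value: float
    traits: tuple
    exclusions: tuple

    def to_dict(self) -> dict:
        return {
            "subset": self.label,
            "n_snps": self.n_snps,
            "r": self.r,
            "p_value": self.p_value,
            "traits": "/".join(self.traits),
            "n_exclusions": len(self.exclusions),
        }


def effect_correlation(
    effects: pd.DataFrame,
    snp_map: SnpMap,
    trait_a: str,
    trait_b: str,
    subset: np.ndarray | None = None,
    exclusions: list[tuple] | None = None,
    label: str = "all",
) -> CorrelationReport:
    """Pearson r between two traits' SNP effects over a masked SNP subset.

    ``subset`` is a boolean per-SNP mask over the map (None = all SNPs);
    ``exclusions`` are (chrom, start, end[, name]) half-open bp intervals
    whose SNPs are removed before correlating (e.g. a region with one extreme
    outlier effect that would dominate r).
    """
    eff = effects.reindex(snp_map.snp_ids)
    a = eff[trait_a].to_numpy(dtype=float)
    b = eff[trait_b].to_numpy(dtype=float)
    keep = np.ones(snp_map.n_snps, dtype=bool) if subset is None else np.asarray(subset, bool).copy()
    keep &= ~(np.isnan(a) | np.isnan(b))
    exclusions = list(exclusions or [])
    if exclusions:
        from .simcohort import snp_mask_from_intervals

        keep &= ~snp_mask_from_intervals(snp_map, exclusions)
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"subset {label!r}: need >= 3 SNPs after exclusions, got {n}")
    av, bv = a[keep], b[keep]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError(f"subset {label!r}: constant effect vector, r undefined")
    r, p = stats.pearsonr(av, bv)
    return CorrelationReport(label, n, float(r), float(p), (trait_a, trait_b), tuple(map(tuple, exclusions)))


@dataclass
class GeneHit:
    gene: str
    gene_chrom: object
    gene_start: int
    gene_end: int
    relation: str  # "contained" | "proximal"
    distance_bp: int


@dataclass
class AnnotatedSignature:
    signature: SelectionSignature
    hits: list


def annotate_signatures(
    signatures: list[SelectionSignature],
    genes: list[tuple],
    proximity_bp: int = 1_500_000,
) -> tuple[list[AnnotatedSignature], pd.DataFrame]:
    """Match gene intervals to signatures as contained or proximal.

    A gene overlapping the signature at all is "contained" with distance 0;
    otherwise a gene whose nearest edge lies within ``proximity_bp`` of a
    signature boundary is "proximal" with that gap as the distance. Gene
    intervals are 0-based half-open bp; signature bounds are SNP positions
    (1-based bp). Returns per-signature annotations plus a summary frame with
    one row per signature (gene counts and label).
    """
    out = []
    rows = []
    for sig in signatures:
        hits = []
        for g in genes:
            chrom, gstart, gend = g[0], g[1], g[2]
            name = g[3] if len(g) > 3 else f"{chrom}:{gstart}-{gend}"
            if chrom != sig.chrom:
                continue
            # signature in 0-based half-open for the overlap arithmetic
            s0, s1 = sig.start_bp - 1, sig.end_bp
            if gstart < s1 and gend > s0:
                hits.append(GeneHit(name, chrom, gstart, gend, "contained", 0))
                continue
            gap = gstart - s1 if gstart >= s1 else s0 - gend
            if 0 <= gap <= proximity_bp:
                hits.append(GeneHit(name, chrom, gstart, gend, "proximal", int(gap)))
        hits.sort(key=lambda h: (h.distance_bp, h.gene))
        out.append(AnnotatedSignature(sig, hits))
        rows.append(
            {
                "chrom": sig.chrom,
                "start_bp": sig.start_bp,
                "end_bp": sig.end_bp,
                "n_contained": sum(h.relation == "contained" for h in hits),
                "n_proximal": sum(h.relation == "proximal" for h in hits),
                "genes": ";".join(h.gene for h in hits),
                "label": (
                    "contained"
                    if any(h.relation == "contained" for h in hits)
                    else ("proximal" if hits else "none")
                ),
            }
        )
    return out, pd.DataFrame(rows)


def signatures_with_hits(annotated: list[AnnotatedSignature]) -> int:
    """How many signatures contain or are near at least one gene."""
    return sum(1 for a in annotated if a.hits)
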