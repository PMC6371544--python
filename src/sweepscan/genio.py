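"""Readers and writers for genotype, haplotype, map, group, effect and interval files.

All analysis modules share one canonical in-memory representation:

* :class:`SnpMap` — the marker map (SNP id, chromosome, bp position, two alleles),
  with ``allele1`` always the alphabetically lower base so that allele
  orientation is unambiguous across files and cohorts.
* :class:`GenotypeMatrix` — per-sample dosage of ``allele1`` in {0, 1, 2},
  ``-1`` for missing.
* :class:`HaplotypePanel` — phased haplotypes coded 0 (= ``allele1``) / 1
  (= ``allele2``), no missing values.

Internally every interval is 0-based half-open; external tables and reports
use 1-based bp positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

MAP_COLUMNS = ("snp_id", "chrom", "pos", "allele1", "allele2")


class GenioError(ValueError):
    """Malformed input file or inconsistent genotype containers."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpMap:
    """Marker map shared by all cohorts of one analysis.

    ``frame`` has columns snp_id, chrom, pos, allele1, allele2. SNPs are
    grouped by chromosome, and positions are strictly increasing within each
    chromosome. ``allele1`` is the alphabetically lower of the two bases
    whenever both are known (bases among A, C, G, T; '0' marks an allele
    never observed).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = set(MAP_COLUMNS) - set(self.frame.columns)
        if missing_cols:
            raise GenioError(f"SnpMap frame missing columns {sorted(missing_cols)}")
        object.__setattr__(self, "frame", self.frame.reset_index(drop=True))
        chrom = self.frame["chrom"].to_numpy()
        pos = self.frame["pos"].to_numpy()
        # chromosome blocks must be contiguous, positions strictly increasing inside
        seen: set = set()
        prev = None
        for c in chrom:
            if c != prev:
                if c in seen:
                    raise GenioError(f"chromosome {c!r} is not a contiguous block")
                seen.add(c)
                prev = c
        for c in seen:
            p = pos[chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise GenioError(f"positions not strictly increasing on chromosome {c!r}")

    @property
    def n_snps(self) -> int:
        return len(self.frame)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.frame["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in file order."""
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of global SNP indices."""
        out = {}
        chrom = self.frame["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out[chrom[start]] = slice(start, i)
                start = i
        return out

    def subset(self, index: np.ndarray) -> "SnpMap":
        return SnpMap(self.frame.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Dosage of allele1 per sample per SNP; -1 encodes a missing genotype."""

    samples: list
    dosage: np.ndarray  # int8 (n_samples, n_snps)
    snp_map: SnpMap

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise GenioError("dosage must be 2-D (samples x SNPs)")
        if self.dosage.shape != (len(self.samples), self.snp_map.n_snps):
            raise GenioError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {self.snp_map.n_snps} SNPs"
            )
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            raise GenioError("dosage values must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing genotypes."""
        return (self.dosage == MISSING).mean(axis=0)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise GenioError(f"unknown sample id {exc.args[0]!r}") from None


@dataclass
class HaplotypePanel:
    """Phased haplotypes: allele 0 = allele1, 1 = allele2; no missing values."""

    ids: list
    alleles: np.ndarray  # uint8 (n_haplotypes, n_snps)
    snp_map: SnpMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise GenioError("alleles must be 2-D (haplotypes x SNPs)")
        if self.alleles.shape != (len(self.ids), self.snp_map.n_snps):
            raise GenioError("panel shape does not match ids x SnpMap")
        if self.alleles.max(initial=0) > 1:
            raise GenioError("haplotype alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)

    def to_genotypes(self, sample_ids=None) -> GenotypeMatrix:
        """Pair consecutive haplotypes (2i, 2i+1) into diploid dosages of allele1."""
        if self.n_haplotypes % 2:
            raise GenioError("odd haplotype count cannot form diploids")
        n = self.n_haplotypes // 2
        # dosage of allele1 = number of 0-coded alleles
        dos = (2 - self.alleles[0::2].astype(np.int8) - self.alleles[1::2].astype(np.int8))
        if sample_ids is None:
            sample_ids = [f"ind{i}" for i in range(n)]
        return GenotypeMatrix(list(sample_ids), dos, self.snp_map)


class GroupAssignment:
    """Sample id -> cohort label, with union labels (III = IIIa + IIIb)."""

    DEFAULT_UNIONS = {"III": ("IIIa", "IIIb")}

    def __init__(self, mapping: dict, unions: dict | None = None) -> None:
        self.mapping = dict(mapping)
        self.unions = dict(unions) if unions is not None else dict(self.DEFAULT_UNIONS)
        self.labels = sorted(set(self.mapping.values()))

    def _expand(self, label) -> set:
        if label in self.unions:
            return set(self.unions[label])
        return {label}

    def sample_ids(self, label) -> list:
        wanted = self._expand(label)
        ids = [s for s, g in self.mapping.items() if g in wanted]
        if not ids:
            raise GenioError(f"group {label!r} has no samples")
        return ids

    def indices(self, label, matrix: GenotypeMatrix) -> np.ndarray:
        wanted = self._expand(label)
        idx = [i for i, s in enumerate(matrix.samples) if self.mapping.get(s) in wanted]
        if not idx:
            raise GenioError(f"group {label!r} has no samples in the matrix")
        return np.array(idx, dtype=int)

    @classmethod
    def from_tsv(cls, path) -> "GroupAssignment":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
        return cls(dict(zip(df["sample"], df["group"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.mapping), "group": list(self.mapping.values())}
        ).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Allele-orientation canonicalization
# ---------------------------------------------------------------------------


def canonicalize_orientation(
    snp_map: SnpMap,
    dosage: np.ndarray | None = None,
    haplotypes: np.ndarray | None = None,
):
    """Reorient every SNP so allele1 is the alphabetically lower base.

    Flipping swaps allele1/allele2 in the map, maps dosage d -> 2 - d
    (missing preserved) and haplotype code a -> 1 - a. Idempotent, and an
    involution when applied to an already-flipped input.

    Returns (snp_map, dosage, haplotypes) with None passed through.
    """
    a1 = snp_map.frame["allele1"].astype(str).to_numpy()
    a2 = snp_map.frame["allele2"].astype(str).to_numpy()
    # '0' (unobserved allele) never outranks a real base
    flip = (a2 != "0") & ((a1 == "0") | (a2 < a1))
    if not flip.any():
        return snp_map, dosage, haplotypes
    frame = snp_map.frame.copy()
    frame.loc[flip, ["allele1", "allele2"]] = frame.loc[flip, ["allele2", "allele1"]].to_numpy()
    new_map = SnpMap(frame)
    if dosage is not None:
        dosage = dosage.copy()
        cols = np.flatnonzero(flip)
        sub = dosage[:, cols]
        flipped = np.where(sub == MISSING, MISSING, 2 - sub)
        dosage[:, cols] = flipped
    if haplotypes is not None:
        haplotypes = haplotypes.copy()
        haplotypes[:, np.flatnonzero(flip)] ^= 1
    return new_map, dosage, haplotypes


# ---------------------------------------------------------------------------
# PLINK .ped/.map text
# ---------------------------------------------------------------------------


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, SnpMap]:
    """Read whitespace-delimited PLINK .ped/.map into dosage form.

    Alleles are recoded so allele1 is the alphabetically lower observed base;
    '0' allele codes are missing. A site with more than two distinct bases is
    an error naming the SNP; a ped row with the wrong column count is an
    error with its line number.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None, dtype=str, comment="#"
    )
    if map_df.shape[1] == 3:  # chrom, id, bp (genetic distance omitted)
        map_df.columns = ["chrom", "snp_id", "pos"]
    elif map_df.shape[1] >= 4:
        map_df = map_df.iloc[:, :4]
        map_df.columns = ["chrom", "snp_id", "cm", "pos"]
    else:
        raise GenioError(f"{map_path}: .map needs >= 3 columns")
    n_snps = len(map_df)

    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenioError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            rows.append(np.array(parts[6:], dtype="U8"))
    allele_calls = (
        np.stack(rows).reshape(len(samples), n_snps, 2)
        if rows
        else np.empty((0, n_snps, 2), dtype="U8")
    )

    allele1 = np.full(n_snps, "0", dtype="U8")
    allele2 = np.full(n_snps, "0", dtype="U8")
    dosage = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        calls = allele_calls[:, j, :]
        observed = sorted(set(calls.ravel()) - {"0"})
        if len(observed) > 2:
            raise GenioError(
                f"SNP {map_df['snp_id'].iloc[j]!r} has >2 alleles: {observed}"
            )
        if observed:
            allele1[j] = observed[0]
        if len(observed) == 2:
            allele2[j] = observed[1]
        if len(samples):
            miss = (calls == "0").any(axis=1)
            dos = (calls == allele1[j]).sum(axis=1).astype(np.int8)
            dosage[:, j] = np.where(miss, MISSING, dos)

    frame = pd.DataFrame(
        {
            "snp_id": map_df["snp_id"].to_numpy(),
            "chrom": map_df["chrom"].to_numpy(),
            "pos": map_df["pos"].astype(int).to_numpy(),
            "allele1": allele1,
            "allele2": allele2,
        }
    )
    snp_map = SnpMap(frame)
    snp_map, dosage, _ = canonicalize_orientation(snp_map, dosage=dosage)
    return GenotypeMatrix(samples, dosage, snp_map), snp_map


def write_ped_map(matrix: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a GenotypeMatrix as PLINK .ped/.map text (deterministic order)."""
    m = matrix.snp_map.frame
    with open(map_path, "w") as fh:
        for _, row in m.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")
    a1 = m["allele1"].to_numpy()
    a2 = m["allele2"].to_numpy()
    geno_strings = {
        2: lambda j: f"{a1[j]} {a1[j]}",
        1: lambda j: f"{a1[j]} {a2[j]}",
        0: lambda j: f"{a2[j]} {a2[j]}",
        MISSING: lambda j: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(matrix.samples):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            row = matrix.dosage[i]
            fields.extend(geno_strings[int(row[j])](j) for j in range(len(row)))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> tuple[GenotypeMatrix, SnpMap, HaplotypePanel | None]:
    """Read a VCF 4.x with GT into the canonical containers.

    Only biallelic SNPs are kept (multiallelic records are skipped with a
    logged count). REF/ALT are reoriented to the allele1 convention with
    dosages flipped as needed. A haplotype panel is returned only when every
    genotype is phased and non-missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    n_skipped = 0
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        records.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}", var.REF, var.ALT[0], gts))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not records:
        raise GenioError(f"{path}: no usable biallelic SNP records")

    n_snps = len(records)
    dosage = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    hap = np.zeros((2 * len(samples), n_snps), dtype=np.uint8)
    any_missing = False
    frame_rows = []
    for j, (chrom, pos, sid, ref, alt, gts) in enumerate(records):
        frame_rows.append((sid, chrom, pos, ref, alt))
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            phased = bool(g[-1])
            if a < 0 or b < 0:
                any_missing = True
                continue
            if not phased:
                all_phased = False
            # dosage of REF for now; orientation fixed below
            dosage[i, j] = int(a == 0) + int(b == 0)
            hap[2 * i, j] = a
            hap[2 * i + 1, j] = b

    frame = pd.DataFrame(frame_rows, columns=["snp_id", "chrom", "pos", "allele1", "allele2"])
    snp_map = SnpMap(frame)
    panel_ok = all_phased and not any_missing
    snp_map, dosage, hap = canonicalize_orientation(
        snp_map, dosage=dosage, haplotypes=hap if panel_ok else None
    )
    matrix = GenotypeMatrix(samples, dosage, snp_map)
    panel = None
    if panel_ok:
        hap_ids = [f"{s}_{k}" for s in samples for k in (0, 1)]
        panel = HaplotypePanel(hap_ids, hap, snp_map)
    return matrix, snp_map, panel


def write_vcf(path, snp_map: SnpMap, matrix: GenotypeMatrix | None = None,
              panel: HaplotypePanel | None = None) -> None:
    """Write a minimal VCF 4.2 (GT only); phased '|' separators for panels."""
    if (matrix is None) == (panel is None):
        raise GenioError("pass exactly one of matrix or panel")
    if panel is not None and panel.n_haplotypes % 2:
        raise GenioError("panel with odd haplotype count cannot be written as diploid VCF")
    if matrix is not None:
        sample_ids = [str(s) for s in matrix.samples]
    else:
        sample_ids = [f"ind{i}" for i in range(panel.n_haplotypes // 2)]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    m = snp_map.frame
    for j in range(snp_map.n_snps):
        ref, alt = m["allele1"].iloc[j], m["allele2"].iloc[j]
        if matrix is not None:
            # REF = allele1, so GT allele 0 counts toward dosage
            codes = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
            gts = [codes[int(d)] for d in matrix.dosage[:, j]]
        else:
            a = panel.alleles[:, j]
            gts = [f"{a[2*i]}|{a[2*i+1]}" for i in range(len(sample_ids))]
        lines.append(
            f"{m['chrom'].iloc[j]}\t{m['pos'].iloc[j]}\t{m['snp_id'].iloc[j]}"
            f"\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED intervals and effect tables
# ---------------------------------------------------------------------------


def read_bed_intervals(path) -> list[tuple]:
    """Read BED3+ into (chrom, start, end, name) tuples, 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise GenioError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise GenioError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"interval{lineno}"
            out.append((chrom, start, end, name))
    return out


def read_effect_table(path) -> pd.DataFrame:
    """TSV with header: snp_id then one column per named trait."""
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns or df.shape[1] < 2:
        raise GenioError(f"{path}: effect table needs snp_id + >=1 trait column")
    return df.set_index("snp_id")


def write_effect_table(path, effects: pd.DataFrame) -> None:
    effects.reset_index().to_csv(path, sep="\t", index=False)
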