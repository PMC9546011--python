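"""Diploid biallelic genotype matrices: VCF I/O, sample/locus filters, HWE exact test.

The central container is :class:`GenotypeMatrix`: samples x loci calls coded as
the number of alternative alleles (0/1/2) with ``-1`` for missing. Filters mirror
the standard reduced-representation (RAD-seq) dataset-construction steps: per-sample
call-rate, minor-allele-frequency, and physical thinning so that retained SNPs are
approximately unlinked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1


@dataclass
class LocusTable:
    """Per-locus metadata, parallel to the columns of a genotype matrix."""

    chrom: np.ndarray  # object/str array
    pos: np.ndarray  # int64, 1-based
    ref: np.ndarray
    alt: np.ndarray
    ancestral: np.ndarray | None = None  # optional ancestral base per locus

    def __len__(self) -> int:
        return len(self.pos)

    def take(self, idx) -> "LocusTable":
        anc = None if self.ancestral is None else self.ancestral[idx]
        return LocusTable(self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx], anc)

    def ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP calls in {0, 1, 2, -1(missing)} counting ALT alleles."""

    sample_ids: list[str]
    loci: LocusTable
    calls: np.ndarray  # (n_samples, n_loci) int8

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_samples={len(self.sample_ids)}, "
                f"n_loci={len(self.loci)})"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("calls must be 0, 1, 2 or -1 (missing)")
        if len(self.loci) and np.any(self.loci.pos <= 0):
            raise ValueError("positions must be positive")
        key = list(zip(self.loci.chrom.tolist(), self.loci.pos.tolist()))
        if len(set(key)) != len(key):
            raise ValueError("(chromosome, position) pairs must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix([self.sample_ids[i] for i in idx], self.loci, self.calls[idx])

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.sample_ids, self.loci.take(idx), self.calls[:, idx])

    def allele_freqs(self) -> np.ndarray:
        """ALT-allele frequency per locus over non-missing gene copies (NaN if none)."""
        obs = self.calls != MISSING
        alt = np.where(obs, self.calls, 0).sum(axis=0).astype(float)
        copies = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt / copies, np.nan)


@dataclass
class PopulationMap:
    """sample -> population label, with optional decimal-degree coordinates."""

    populations: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for s, (lat, lon) in self.coordinates.items():
            if not (-90 <= lat <= 90) or not (-180 <= lon <= 180):
                raise ValueError(f"coordinates out of range for sample {s!r}")

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.populations.items() if p == pop]

    def pops(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations.values():
            seen.setdefault(p)
        return list(seen)


def read_popmap(path) -> PopulationMap:
    """Read a 2- or 4-column TSV: sample, population[, latitude, longitude]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] not in (2, 4):
        raise ValueError(f"population map must have 2 or 4 columns, found {df.shape[1]}")
    pops = dict(zip(df[0], df[1]))
    coords = {}
    if df.shape[1] == 4:
        coords = {s: (float(a), float(b)) for s, a, b in zip(df[0], df[2], df[3])}
    return PopulationMap(pops, coords)


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, p in pm.populations.items():
            if s in pm.coordinates:
                lat, lon = pm.coordinates[s]
                fh.write(f"{s}\t{p}\t{lat}\t{lon}\n")
            else:
                fh.write(f"{s}\t{p}\n")


@dataclass
class FilterReport:
    """Record of one filtering step: what was removed and under which threshold."""

    name: str
    removed: list[str]
    threshold: float | int | None = None
    seed: int | None = None
    reasons: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "filter": self.name,
                "threshold": self.threshold,
                "seed": self.seed,
                "n_removed": len(self.removed),
                "removed": self.removed,
                "reasons": self.reasons,
            }
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("item\tfilter\treason\n")
            for item in self.removed:
                fh.write(f"{item}\t{self.name}\t{self.reasons.get(item, '')}\n")


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid GT calls for biallelic SNPs from a VCF.

    Multi-allelic and non-SNP records are skipped; missing genotypes (``./.``)
    map to -1. Raises if no biallelic SNP records remain.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            row[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(row)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    loci = LocusTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
    )
    return GenotypeMatrix(samples, loci, np.array(rows, dtype=np.int8).T)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields, re-readable by read_vcf."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.loci.chrom.tolist()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_loci):
            cells = "\t".join(_GT_STR[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{gm.loci.chrom[j]}\t{gm.loci.pos[j]}\t.\t{gm.loci.ref[j]}\t"
                f"{gm.loci.alt[j]}\t.\tPASS\t.\tGT\t{cells}\n"
            )


# ---------------------------------------------------------------------------
# Filters


def filter_individuals_by_call_rate(
    gm: GenotypeMatrix, min_rate: float = 0.75
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop samples genotyped at fewer than ``min_rate`` of loci (default 75%)."""
    if not (0.0 <= min_rate <= 1.0):
        raise ValueError("min_rate must be in [0, 1]")
    rates = (gm.calls != MISSING).mean(axis=1) if gm.n_loci else np.ones(gm.n_samples)
    keep = rates >= min_rate
    removed = [s for s, k in zip(gm.sample_ids, keep) if not k]
    report = FilterReport("call_rate", removed, threshold=min_rate)
    return gm.take_samples(np.flatnonzero(keep)), report


def filter_loci_by_maf(
    gm: GenotypeMatrix, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci whose sample minor-allele frequency is >= ``min_maf`` (inclusive).

    Frequencies are computed over observed gene copies only; all-missing loci are
    removed with reason "all-missing".
    """
    p = gm.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf  # NaN compares False -> all-missing removed
    ids = gm.loci.ids()
    removed = [ids[j] for j in np.flatnonzero(~keep)]
    reasons = {ids[j]: "all-missing" for j in np.flatnonzero(np.isnan(p))}
    report = FilterReport("maf", removed, threshold=min_maf, reasons=reasons)
    return gm.take_loci(np.flatnonzero(keep)), report


def thin_loci_by_distance(
    gm: GenotypeMatrix, min_bp: int = 10_000, seed: int = 0
) -> tuple[GenotypeMatrix, FilterReport]:
    """Random thinning so no two retained loci on a chromosome are < min_bp apart.

    Loci are visited in a seeded random permutation; a locus is accepted iff no
    previously accepted locus on the same chromosome lies within ``min_bp``.
    """
    if min_bp <= 0:
        raise ValueError("min_bp must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(gm.n_loci)
    accepted_by_chrom: dict[str, list[int]] = {}
    keep = np.zeros(gm.n_loci, dtype=bool)
    for j in order:
        chrom = gm.loci.chrom[j]
        pos = int(gm.loci.pos[j])
        placed = accepted_by_chrom.setdefault(chrom, [])
        if all(abs(pos - q) >= min_bp for q in placed):
            placed.append(pos)
            keep[j] = True
    ids = gm.loci.ids()
    removed = [ids[j] for j in np.flatnonzero(~keep)]
    report = FilterReport("thin", removed, threshold=min_bp, seed=seed)
    return gm.take_loci(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on one locus's genotype counts.

    Conditional on the observed allele counts, the probability of each possible
    heterozygote count h is

        P(h) = multinomial(n; n1, h, n2) * 2**h / C(2n, n_minor)

    and the p-value is the total probability of all configurations no more
    probable than the observed one. Computed in exact rational arithmetic, so
    ties between equally probable configurations are handled exactly.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n_hom_ref, n_het, n_hom_alt = counts
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype count must be non-zero")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    # possible heterozygote counts share the parity of n_minor
    denom = math.comb(2 * n, n_minor)

    def weight(h: int) -> int:
        n1 = (n_minor - h) // 2  # minor-allele homozygotes
        n2 = n - n1 - h
        return math.factorial(n) // (
            math.factorial(n1) * math.factorial(h) * math.factorial(n2)
        ) * 2**h

    h_obs = n_het
    w_obs = weight(h_obs)
    total = 0
    for h in range(n_minor % 2, n_minor + 1, 2):
        w = weight(h)
        if w <= w_obs:
            total += w
    p = Fraction(total, denom)
    return float(p)
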