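"""One- and two-population site-frequency spectra.

A :class:`JointSFS` holds real-valued counts of SNPs indexed by derived-allele
count in each population (shape ``(n1+1,)`` or ``(n1+1, n2+1)`` for gene-copy
sample sizes ``n``). The fixed corners (all-ancestral, all-derived) carry no
polymorphism information and are always masked. Spectra can be polarized from
an outgroup, hypergeometrically projected to smaller sample sizes, folded,
marginalized, and exchanged in the dadi text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class OutgroupAlleles:
    """(chromosome, position) -> outgroup base, used to assign ancestral states."""

    alleles: dict[tuple[str, int], str]

    def get(self, chrom: str, pos: int) -> str | None:
        return self.alleles.get((chrom, pos))


def read_outgroup(path) -> OutgroupAlleles:
    """Read a 3-column TSV: chromosome, 1-based position, outgroup base."""
    alleles: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, base = line.split()[:3]
            key = (chrom, int(pos))
            if key in alleles:
                raise ValueError(f"duplicate outgroup position {key}")
            alleles[key] = base
    return OutgroupAlleles(alleles)


def write_outgroup(og: OutgroupAlleles, path) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), base in og.alleles.items():
            fh.write(f"{chrom}\t{pos}\t{base}\n")


def _corner_mask(shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[(0,) * len(shape)] = True
    mask[tuple(s - 1 for s in shape)] = True
    return mask


@dataclass
class JointSFS:
    """Derived-allele-count spectrum for one or two populations."""

    counts: np.ndarray
    populations: list[str]
    polarized: bool = True
    mask: np.ndarray = field(default=None)  # True = excluded cell

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim not in (1, 2):
            raise ValueError("spectrum must be 1- or 2-dimensional")
        if len(self.populations) != self.counts.ndim:
            raise ValueError("one population label per dimension required")
        if np.any(self.counts[~np.isnan(self.counts)] < 0):
            raise ValueError("spectrum counts must be non-negative")
        corner = _corner_mask(self.counts.shape)
        self.mask = corner if self.mask is None else (np.asarray(self.mask, bool) | corner)

    @property
    def ndim(self) -> int:
        return self.counts.ndim

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.counts.shape)

    def unmasked(self) -> np.ndarray:
        return np.where(self.mask, 0.0, self.counts)

    def total(self) -> float:
        """Total SNP count over unmasked cells."""
        return float(np.nansum(self.unmasked()))

    def copy(self) -> "JointSFS":
        return JointSFS(self.counts.copy(), list(self.populations), self.polarized,
                        self.mask.copy())


@dataclass
class PolarizationReport:
    n_used: int
    n_missing_calls: int
    n_outgroup_absent: int
    n_outgroup_mismatch: int


def build_joint_sfs(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pops: list[str],
    outgroup: OutgroupAlleles,
    return_report: bool = False,
):
    """Polarized joint SFS from genotypes plus an outgroup allele table.

    A locus contributes one SNP iff (i) every focal sample is genotyped there and
    (ii) the outgroup base matches exactly one of the two alleles (that allele is
    taken as ancestral). Other loci are dropped and tallied in the report.
    """
    if not 1 <= len(pops) <= 2:
        raise ValueError("1 or 2 populations required")
    sample_idx = []
    for pop in pops:
        members = popmap.samples_in(pop)
        if not members:
            raise ValueError(f"population {pop!r} absent from population map")
        idx = [gm.sample_ids.index(s) for s in members if s in gm.sample_ids]
        if not idx:
            raise ValueError(f"no genotyped samples for population {pop!r}")
        sample_idx.append(np.array(idx))
    sizes = [2 * len(ix) for ix in sample_idx]
    counts = np.zeros([n + 1 for n in sizes])
    n_used = n_missing = n_absent = n_mismatch = 0
    for j in range(gm.n_loci):
        base = outgroup.get(gm.loci.chrom[j], int(gm.loci.pos[j]))
        if base is None:
            n_absent += 1
            continue
        ref, alt = gm.loci.ref[j], gm.loci.alt[j]
        if base == ref and base != alt:
            derived_of_call = lambda c: c  # ALT is derived
        elif base == alt and base != ref:
            derived_of_call = lambda c: 2 - c  # REF is derived
        else:
            n_mismatch += 1
            continue
        cell = []
        ok = True
        for ix in sample_idx:
            calls = gm.calls[ix, j]
            if np.any(calls == MISSING):
                ok = False
                break
            cell.append(int(sum(derived_of_call(int(c)) for c in calls)))
        if not ok:
            n_missing += 1
            continue
        counts[tuple(cell)] += 1
        n_used += 1
    sfs = JointSFS(counts, list(pops), polarized=True)
    if return_report:
        return sfs, PolarizationReport(n_used, n_missing, n_absent, n_mismatch)
    return sfs


# ---------------------------------------------------------------------------
# Projection / folding / marginalization


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """P[j, i] = P(j derived in a hypergeometric subsample of m | i of n)."""
    i = np.arange(n + 1)[None, :]
    j = np.arange(m + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = (
            _logcomb(i, j) + _logcomb(n - i, m - j) - _logcomb(n, m)
        )
    w = np.where(np.isneginf(logw), 0.0, np.exp(logw))
    return w


def _logcomb(n, k):
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    bad = (k < 0) | (k > n)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(bad, -np.inf, out)


def project(sfs: JointSFS, target_sizes) -> JointSFS:
    """Expectation-preserving hypergeometric projection to smaller sample sizes."""
    target_sizes = tuple(int(t) for t in np.atleast_1d(target_sizes))
    if len(target_sizes) != sfs.ndim:
        raise ValueError("one target size per dimension required")
    counts = sfs.counts.copy()
    for axis, (n, m) in enumerate(zip(sfs.sizes, target_sizes)):
        if m > n:
            raise ValueError(f"target size {m} exceeds source size {n}")
        if m < 2:
            raise ValueError("target sizes must be >= 2")
        if m == n:
            continue
        P = _projection_matrix(n, m)
        counts = np.moveaxis(np.tensordot(P, counts, axes=([1], [axis])), 0, axis)
    return JointSFS(counts, list(sfs.populations), sfs.polarized)


def fold(sfs: JointSFS) -> JointSFS:
    """Minor-allele representation: each cell summed with its complement.

    Cells whose total derived count exceeds half the total gene copies are
    masked; cells exactly on the midline keep half the doubled value so total
    mass is conserved. Folding an already-folded spectrum is a no-op.
    """
    if not sfs.polarized:
        return sfs.copy()
    rev = sfs.unmasked()[tuple(slice(None, None, -1) for _ in range(sfs.ndim))]
    folded = sfs.unmasked() + rev
    shape = folded.shape
    idx = np.indices(shape)
    d = sum(idx)  # total derived copies per cell
    ntot = sum(s - 1 for s in shape)
    below = 2 * d < ntot
    mid = 2 * d == ntot
    folded = np.where(mid, folded / 2.0, folded)
    folded = np.where(below | mid, folded, 0.0)
    mask = _corner_mask(shape) | ~(below | mid)
    return JointSFS(folded, list(sfs.populations), polarized=False, mask=mask)


def marginalize(sfs: JointSFS, pop: str) -> JointSFS:
    """1-D marginal spectrum of ``pop`` from a 2-D joint spectrum."""
    if sfs.ndim != 2:
        raise ValueError("marginalize requires a 2-dimensional spectrum")
    if pop not in sfs.populations:
        raise ValueError(f"population {pop!r} not in spectrum")
    keep_axis = sfs.populations.index(pop)
    counts = sfs.unmasked().sum(axis=1 - keep_axis)
    return JointSFS(counts, [pop], sfs.polarized)


# ---------------------------------------------------------------------------
# dadi text format


def write_dadi_sfs(sfs: JointSFS, path) -> None:
    """Write the dadi SFS exchange format (shape line, data line, mask line)."""
    shape = " ".join(str(s) for s in sfs.counts.shape)
    foldflag = "unfolded" if sfs.polarized else "folded"
    popline = " ".join(f'"{p}"' for p in sfs.populations)
    with open(path, "w") as fh:
        fh.write(f"{shape} {foldflag} {popline}\n")
        fh.write(" ".join(repr(float(x)) for x in sfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def read_dadi_sfs(path) -> JointSFS:
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    shape = []
    i = 0
    while i < len(header) and header[i].isdigit():
        shape.append(int(header[i]))
        i += 1
    if not shape:
        raise ValueError("dadi SFS header must start with the shape")
    rest = header[i:]
    polarized = True
    pops = []
    for tok in rest:
        if tok == "folded":
            polarized = False
        elif tok == "unfolded":
            polarized = True
        else:
            pops.append(tok.strip('"'))
    if not pops:
        pops = [f"pop{k}" for k in range(len(shape))]
    data = np.array([float(x) for x in lines[1].split()])
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"dadi SFS data length {data.size} does not match header shape {shape}"
        )
    counts = data.reshape(shape)
    mask = None
    if len(lines) > 2:
        mvals = np.array([int(x) for x in lines[2].split()], dtype=bool)
        if mvals.size != data.size:
            raise ValueError("mask line length does not match data")
        mask = mvals.reshape(shape)
    return JointSFS(counts, pops, polarized=polarized, mask=mask)
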