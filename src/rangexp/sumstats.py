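"""Diversity and differentiation statistics for range-expansion analyses.

Per-population diversity (pi, observed heterozygosity, het/hom ratio),
Tajima's D from a one-population SFS, multi-locus Weir-Cockerham F_ST with a
label-permutation significance test, the directionality index psi (mean
derived-frequency difference at shared polymorphisms, whose sign points along
an expansion), and Evanno's delta-K for choosing the number of clusters from
replicated admixture log-likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .sfs import JointSFS


class UndefinedStatistic(ValueError):
    """A statistic has no defined value for this input (e.g. S = 0, sd = 0)."""


# ---------------------------------------------------------------------------
# Diversity


@dataclass
class PopDiversity:
    population: str
    n_samples: int
    pi: float       # mean per-SNP pairwise diversity
    h_o: float      # mean observed heterozygosity per SNP
    het_hom: float  # mean within-sample het/hom locus ratio


def diversity(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population pi, H_O and Het/Hom averaged over SNP loci.

    Per locus with n genotyped diploids and ALT frequency p-hat,
    ``pi = (2n/(2n-1)) * 2*p*(1-p)`` (the unbiased per-SNP pairwise diversity);
    statistics are averaged over all loci in the matrix. Het/Hom is computed per
    sample over its genotyped loci and averaged within the population; samples
    with no homozygous locus are excluded from that mean.
    """
    rows = []
    for pop in popmap.pops():
        idx = [gm.sample_ids.index(s) for s in popmap.samples_in(pop) if s in gm.sample_ids]
        if not idx:
            continue
        calls = gm.calls[np.array(idx)]
        obs = calls != MISSING
        if not obs.any():
            raise ValueError(f"population {pop!r} has no non-missing calls")
        n = obs.sum(axis=0).astype(float)  # diploids with data per locus
        alt = np.where(obs, calls, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            corr = np.where(2 * n > 1, 2 * n / (2 * n - 1), np.nan)
            pi_l = corr * 2 * p * (1 - p)
            het_l = np.where(obs, calls == 1, 0).sum(axis=0) / n
        het_per_sample = (calls == 1).sum(axis=1).astype(float)
        hom_per_sample = ((calls == 0) | (calls == 2)).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(hom_per_sample > 0, het_per_sample / hom_per_sample, np.nan)
        het_hom = float(np.nanmean(ratio)) if np.isfinite(ratio).any() else float("nan")
        rows.append(
            PopDiversity(pop, len(idx), float(np.nanmean(pi_l)), float(np.nanmean(het_l)),
                         het_hom)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaD:
    d: float
    s: float
    n: int
    constants: dict[str, float] = field(default_factory=dict)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard normalization constants for a sample of n gene copies."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(sfs: JointSFS) -> TajimaD:
    """Tajima's D from a one-population spectrum (folded or unfolded).

    pi-hat = sum_i xi_i * i*(n-i) / C(n,2); theta_W = S / a1;
    D = (pi-hat - theta_W) / sqrt(e1*S + e2*S*(S-1)).
    The i*(n-i) weight is symmetric in i <-> n-i, so folded spectra give the
    same value. Raises :class:`UndefinedStatistic` when S = 0.
    """
    if sfs.ndim != 1:
        raise ValueError("tajimas_d requires a one-population spectrum")
    n = sfs.sizes[0]
    xi = sfs.unmasked()
    s = float(xi.sum())
    if s <= 0:
        raise UndefinedStatistic("no segregating sites: Tajima's D undefined")
    i = np.arange(n + 1)
    pi_hat = float((xi * i * (n - i)).sum() / math.comb(n, 2))
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    d = (pi_hat - s / k["a1"]) / math.sqrt(var)
    return TajimaD(d, s, n, k)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def _pop_calls(gm: GenotypeMatrix, popmap: PopulationMap, pops: list[str]) -> list[np.ndarray]:
    out = []
    for pop in pops:
        idx = [gm.sample_ids.index(s) for s in popmap.samples_in(pop) if s in gm.sample_ids]
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 genotyped samples")
        out.append(gm.calls[np.array(idx)])
    return out


def _wc_components(calls_by_pop: list[np.ndarray]):
    """Per-locus Weir-Cockerham (1984) variance components a, b, c for r demes."""
    r = len(calls_by_pop)
    n_i, p_i, h_i = [], [], []
    for calls in calls_by_pop:
        obs = calls != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, calls, 0).sum(axis=0) / (2 * n)
            h = np.where(obs, calls == 1, 0).sum(axis=0) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    ok = (n_i >= 2).all(axis=0)  # need >=2 genotyped diploids per deme per locus
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    return a, b, c, ok


def wc_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    min_maf: float = 0.05,
) -> float:
    """Multi-locus Weir-Cockerham theta between two populations.

    Loci are screened at pooled minor-allele frequency >= ``min_maf`` over the
    two focal populations, then theta = sum(a) / sum(a+b+c) across loci.
    """
    calls_by_pop = _pop_calls(gm, popmap, [pop_a, pop_b])
    pooled = np.vstack(calls_by_pop)
    obs = pooled != MISSING
    copies = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, pooled, 0).sum(axis=0) / copies
    maf = np.minimum(p, 1 - p)
    keep = maf >= min_maf
    calls_by_pop = [c[:, keep] for c in calls_by_pop]
    if calls_by_pop[0].shape[1] == 0:
        raise ValueError("no loci pass the MAF screen")
    theta = _theta_from_calls(calls_by_pop)
    if np.isnan(theta):
        raise ValueError("F_ST undefined: no locus with >= 2 genotyped samples per population")
    return theta


def _theta_from_calls(calls_by_pop: list[np.ndarray]) -> float:
    a, b, c, ok = _wc_components(calls_by_pop)
    num = np.nansum(np.where(ok, a, np.nan))
    den = np.nansum(np.where(ok, a + b + c, np.nan))
    if not ok.any() or den == 0:
        return float("nan")
    return float(num / den)


@dataclass
class FstResult:
    theta: float
    p_value: float
    n_perm: int
    seed: int


def fst_permutation_test(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    min_maf: float = 0.05,
) -> FstResult:
    """Permutation significance for theta: individuals reshuffled between the
    two populations (sizes preserved); p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    calls_by_pop = _pop_calls(gm, popmap, [pop_a, pop_b])
    pooled = np.vstack(calls_by_pop)
    obs = pooled != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, pooled, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
    keep = np.minimum(p, 1 - p) >= min_maf
    pooled = pooled[:, keep]
    n_a = calls_by_pop[0].shape[0]
    theta_obs = _theta_from_calls([pooled[:n_a], pooled[n_a:]])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        t = _theta_from_calls([pooled[perm[:n_a]], pooled[perm[n_a:]]])
        if not np.isnan(t) and t >= theta_obs:
            n_ge += 1
    p_value = (1 + n_ge) / (n_perm + 1)
    return FstResult(theta_obs, p_value, n_perm, seed)


# ---------------------------------------------------------------------------
# Directionality index psi


@dataclass
class PsiResult:
    pop_from: str
    pop_to: str
    psi: float
    n_sites: float  # SNP mass over shared-derived cells


def psi(sfs: JointSFS) -> PsiResult:
    """Directionality index for the ordered pair (populations[0] -> populations[1]).

    Over unmasked cells with the derived allele present in both populations
    (i >= 1 and j >= 1) and not fixed in both,
    ``psi = sum f_ij * (j/n - i/n) / sum f_ij`` with equal sample sizes n.
    Positive values indicate expansion from the first population toward the
    second (the colony carries higher derived frequencies at shared sites).
    """
    if sfs.ndim != 2:
        raise ValueError("psi requires a two-population spectrum")
    if not sfs.polarized:
        raise ValueError("psi requires a polarized spectrum")
    n1, n2 = sfs.sizes
    if n1 != n2:
        raise ValueError("psi requires equal sample sizes; project the spectrum first")
    n = n1
    f = sfs.unmasked()
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    use = (i >= 1) & (j >= 1) & ~((i == n) & (j == n)) & ~sfs.mask
    # math.fsum is exactly rounded regardless of summation order, which makes
    # psi(A,B) == -psi(B,A) bitwise exact on transposed spectra
    denom = math.fsum(f[use])
    if denom <= 0:
        raise UndefinedStatistic("no shared-derived sites: psi undefined")
    num = math.fsum((f * ((j - i) / n))[use])
    return PsiResult(sfs.populations[0], sfs.populations[1], num / denom, denom)


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(loglik_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno et al. delta-K from per-K replicate log-likelihoods.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)), for the
    interior K of a consecutive grid with >= 2 replicates each. Where the
    replicate sd is zero, delta-K is undefined and reported as such (not NaN
    from a division).
    """
    ks = sorted(loglik_by_k)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K grid must be consecutive")
    for k in ks:
        if len(loglik_by_k[k]) < 2:
            raise ValueError(f"K={k} needs >= 2 replicates")
    mean_l = {k: float(np.mean(loglik_by_k[k])) for k in ks}
    sd_l = {k: float(np.std(loglik_by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        defined = ks[0] < k < ks[-1] and sd_l[k] > 0
        dk = (
            abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1]) / sd_l[k]
            if defined
            else np.nan
        )
        rows.append(
            {"k": k, "mean_loglik": mean_l[k], "sd_loglik": sd_l[k],
             "delta_k": dk, "defined": defined}
        )
    return pd.DataFrame(rows)
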