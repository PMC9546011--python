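"""Joint-SFS demographic inference for a source -> island founding.

Four two-population models of an island colonization from a large continental
source are fitted to a polarized joint SFS by Poisson composite likelihood
(the standard Poisson random-field treatment of SFS cells), with the expected
spectrum computed by the Monte-Carlo structured-coalescent engine in
:mod:`rangexp.simulate`. Optimization uses a sequential step-down strategy:
each pass restarts bounded Nelder-Mead searches from an Akaike-weighted
average of the previous pass's endpoints, perturbed by a shrinking fold
factor. Common random numbers (a fixed genealogy seed per fit) keep the
likelihood surface smooth enough for direct search.

Model structures (deme 0 = source, deme 1 = founded island; time backward in
units of 2*N_ref generations, sizes relative to N_ref, s = fraction of the
source that founds the island):

* ``found_and_grow`` — constant ancestral source; founding at T_F with
  fraction s; both demes change size post-split (to nu_N, nu_H); constant
  bidirectional migration from the founding onward.
* ``three_epoch`` — two stepwise ancestral size changes (nu_A1 then nu_A2)
  before the founding; post-split size change in both demes; migration starts
  after a lag (a free fraction of T_F).
* ``two_epoch_admixture`` — founding and post-split growth, no continuous
  migration; a single admixture pulse (source -> island) at a free time.
* ``zhan`` — one ancestral size change before founding; post-split growth in
  the island only; constant migration.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .sfs import JointSFS
from .simulate import BIG_TIME, DemographicScenario, SizeEpoch, simulate_expected_sfs


@dataclass
class Param:
    name: str
    lo: float
    hi: float
    log: bool = True  # optimized and averaged on log10 scale
    kind: str = "other"  # size | time | fraction | migration | other


@dataclass
class DemModelSpec:
    name: str
    params: list[Param]
    growth: str = "exponential"  # post-founding curve form: exponential | logistic

    @property
    def k_free(self) -> int:
        """Free-parameter count for AIC: optimized parameters plus theta-hat."""
        return len(self.params) + 1

    def build(self, values: np.ndarray) -> DemographicScenario:
        p = dict(zip([q.name for q in self.params], values))
        return _BUILDERS[self.name](p, self.growth)

    def check_bounds(self, values) -> np.ndarray:
        return np.array(
            [min(max(v, q.lo), q.hi) for v, q in zip(values, self.params)]
        )


def _post_split(sc, deme, t_found, nu_recent, nu_old, growth):
    sc.set_size(deme, SizeEpoch(0.0, t_found, growth, nu_recent=nu_recent, nu_old=nu_old))


def _build_found_and_grow(p, growth):
    sc = DemographicScenario(2, deme_names=["N", "H"])
    tf = p["T_F"]
    sc.set_size(0, SizeEpoch(tf, BIG_TIME, "constant", 1.0))
    _post_split(sc, 0, tf, p["nu_N"], 1.0, growth)
    sc.set_size(1, SizeEpoch(tf, BIG_TIME, "constant", 1.0))
    _post_split(sc, 1, tf, p["nu_H"], p["s"] * 1.0, growth)
    sc.add_founding(tf, 0, 1)
    sc.set_migration(0.0, tf, 1, 0, p["m_NH"])  # forward N->H gene flow
    sc.set_migration(0.0, tf, 0, 1, p["m_HN"])
    return sc


def _build_three_epoch(p, growth):
    sc = DemographicScenario(2, deme_names=["N", "H"])
    tf = p["T_F"]
    t2 = tf + p["T_2"]
    t1 = t2 + p["T_1"]
    sc.set_size(0, SizeEpoch(t1, BIG_TIME, "constant", 1.0))
    sc.set_size(0, SizeEpoch(t2, t1, "constant", p["nu_A1"]))
    sc.set_size(0, SizeEpoch(tf, t2, "constant", p["nu_A2"]))
    _post_split(sc, 0, tf, p["nu_N"], p["nu_A2"], growth)
    sc.set_size(1, SizeEpoch(tf, BIG_TIME, "constant", 1.0))
    _post_split(sc, 1, tf, p["nu_H"], p["s"] * p["nu_A2"], growth)
    sc.add_founding(tf, 0, 1)
    mig_end = tf * (1.0 - p["lag_frac"])  # migration starts a lag after founding
    if mig_end > 0:
        sc.set_migration(0.0, mig_end, 1, 0, p["m_NH"])
        sc.set_migration(0.0, mig_end, 0, 1, p["m_HN"])
    return sc


def _build_two_epoch_admixture(p, growth):
    sc = DemographicScenario(2, deme_names=["N", "H"])
    tf = p["T_F"]
    sc.set_size(0, SizeEpoch(tf, BIG_TIME, "constant", 1.0))
    _post_split(sc, 0, tf, p["nu_N"], 1.0, growth)
    sc.set_size(1, SizeEpoch(tf, BIG_TIME, "constant", 1.0))
    _post_split(sc, 1, tf, p["nu_H"], p["s"] * 1.0, growth)
    sc.add_founding(tf, 0, 1)
    t_adm = p["adm_frac"] * tf
    if t_adm > 0:
        sc.add_pulse(t_adm, 0, 1, p["f"])  # source -> island pulse
    return sc


def _build_zhan(p, growth):
    sc = DemographicScenario(2, deme_names=["N", "H"])
    tf = p["T_F"]
    t1 = tf + p["T_1"]
    sc.set_size(0, SizeEpoch(t1, BIG_TIME, "constant", 1.0))
    sc.set_size(0, SizeEpoch(0.0, t1, "constant", p["nu_A1"]))
    sc.set_size(1, SizeEpoch(tf, BIG_TIME, "constant", 1.0))
    _post_split(sc, 1, tf, p["nu_H"], p["s"] * p["nu_A1"], growth)
    sc.add_founding(tf, 0, 1)
    sc.set_migration(0.0, tf, 1, 0, p["m_NH"])
    sc.set_migration(0.0, tf, 0, 1, p["m_HN"])
    return sc


_BUILDERS = {
    "found_and_grow": _build_found_and_grow,
    "three_epoch": _build_three_epoch,
    "two_epoch_admixture": _build_two_epoch_admixture,
    "zhan": _build_zhan,
}

_SIZE = dict(lo=1e-2, hi=1e2, log=True, kind="size")
_TIME = dict(lo=1e-3, hi=5.0, log=True, kind="time")
_MIG = dict(lo=1e-5, hi=5.0, log=True, kind="migration")
_FRAC = dict(lo=1e-3, hi=0.999, log=False, kind="fraction")


def model_spec(name: str, growth: str = "exponential") -> DemModelSpec:
    """Parameter table for one of the four candidate models."""
    if name == "found_and_grow":
        params = [
            Param("s", **_FRAC),
            Param("T_F", **_TIME),
            Param("nu_N", **_SIZE),
            Param("nu_H", **_SIZE),
            Param("m_NH", **_MIG),
            Param("m_HN", **_MIG),
        ]
    elif name == "three_epoch":
        params = [
            Param("nu_A1", **_SIZE),
            Param("nu_A2", **_SIZE),
            Param("T_1", **_TIME),
            Param("T_2", **_TIME),
            Param("s", **_FRAC),
            Param("T_F", **_TIME),
            Param("nu_N", **_SIZE),
            Param("nu_H", **_SIZE),
            Param("m_NH", **_MIG),
            Param("m_HN", **_MIG),
            Param("lag_frac", **_FRAC),
        ]
    elif name == "two_epoch_admixture":
        params = [
            Param("s", **_FRAC),
            Param("T_F", **_TIME),
            Param("nu_N", **_SIZE),
            Param("nu_H", **_SIZE),
            Param("adm_frac", **_FRAC),
            Param("f", **_FRAC),
        ]
    elif name == "zhan":
        params = [
            Param("nu_A1", **_SIZE),
            Param("T_1", **_TIME),
            Param("s", **_FRAC),
            Param("T_F", **_TIME),
            Param("nu_H", **_SIZE),
            Param("m_NH", **_MIG),
            Param("m_HN", **_MIG),
        ]
    else:
        raise ValueError(f"unknown model {name!r}")
    return DemModelSpec(name, params, growth)


MODEL_NAMES = list(_BUILDERS)


@dataclass
class EngineConfig:
    replicates: int = 5000
    seed: int = 7
    common_random_numbers: bool = True
    t_max: float = 1e4

    def __post_init__(self):
        if self.replicates < 100:
            raise ValueError("engine needs >= 100 genealogy replicates")


def expected_sfs(
    model: DemModelSpec, values: np.ndarray, sizes: tuple[int, int], engine: EngineConfig
) -> JointSFS:
    """Per-unit-theta expected joint SFS under the model at ``values``."""
    scenario = model.build(np.asarray(values, float))
    return simulate_expected_sfs(
        scenario,
        [(0, sizes[0]), (1, sizes[1])],
        n_reps=engine.replicates,
        seed=engine.seed,
        t_max=engine.t_max,
    )


def poisson_loglik(model_sfs: JointSFS, obs_sfs: JointSFS, eps: float = 1e-10):
    """Poisson composite log-likelihood and its analytic theta-hat scaling.

    theta-hat = sum(obs) / sum(model) over unmasked cells;
    logL = sum[obs*ln(theta*model) - theta*model - lnGamma(obs+1)].
    Model cells below ``eps`` where data exist are floored at ``eps``. With a
    Monte-Carlo expected spectrum, set eps to the engine's resolution
    (~0.5/replicates): cells the finite genealogy sample happened to miss then
    cost ln(eps') rather than an arbitrarily harsh penalty that would push
    optimization toward mass-smearing parameters.
    """
    if model_sfs.counts.shape != obs_sfs.counts.shape:
        raise ValueError("model and observed spectra have different shapes")
    mask = model_sfs.mask | obs_sfs.mask
    m = np.where(mask, 0.0, model_sfs.counts)
    o = np.where(mask, 0.0, obs_sfs.counts)
    m_sum = m.sum()
    if m_sum <= 0:
        raise ValueError("model spectrum has no mass on unmasked cells")
    theta = o.sum() / m_sum
    m = np.where(~mask & (m < eps) & (o > 0), eps, m)
    use = ~mask & (m > 0)
    lam = theta * m[use]
    ll = float((o[use] * np.log(lam) - lam - gammaln(o[use] + 1)).sum())
    # unmasked cells with zero model mass and zero data contribute 0
    return ll, float(theta)


def aic(loglik: float, k: int) -> float:
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * loglik + 2.0 * k


@dataclass
class FitResult:
    model: str
    params: np.ndarray
    theta: float
    loglik: float | None
    aic: float | None
    pass_index: int
    run_index: int
    runtime_s: float
    converged: bool
    timed_out: bool
    # exact optimizer coordinates (log10-transformed where applicable); a
    # continuation run restarted here re-evaluates to exactly this loglik
    # under common random numbers, which a parameter round-trip through
    # 10**log10(v) would not guarantee on a Monte-Carlo surface
    x_opt: np.ndarray | None = None

    def param_dict(self, spec: DemModelSpec) -> dict[str, float]:
        return dict(zip([p.name for p in spec.params], self.params))


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    delta = np.asarray(aics, float) - np.min(aics)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def akaike_weighted_start(results: list[FitResult], spec: DemModelSpec) -> np.ndarray:
    """Akaike-weighted average of completed runs' parameters (log scale where
    the parameter is log-scaled), clipped to bounds. Timed-out runs carry no
    likelihood and are excluded."""
    done = [r for r in results if not r.timed_out and r.aic is not None]
    if not done:
        raise ValueError("all runs timed out; no parameters to weight")
    w = akaike_weights(np.array([r.aic for r in done]))
    mat = np.array([r.params for r in done])
    start = np.empty(mat.shape[1])
    for j, p in enumerate(spec.params):
        if p.log:
            start[j] = 10 ** float(w @ np.log10(mat[:, j]))
        else:
            start[j] = float(w @ mat[:, j])
    return spec.check_bounds(start)


@dataclass
class OptimizerConfig:
    passes: int = 4
    runs_per_pass: int = 30
    perturb_folds: tuple = (3.0, 2.0, 2.0, 1.0)
    timeout_s: float = 60.0
    method: str = "powell"  # direct-search method: powell | nelder-mead
    maxiter: int = 4  # direction-set sweeps (Powell) or simplex iterations (NM)
    elite_maxiter: int = 8  # deeper budget for the best-so-far continuation run
    screen_multiple: int = 5  # pass-1 candidate draws per retained start
    seed: int = 0

    def __post_init__(self):
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.timeout_s <= 0:
            raise ValueError("timeout must be positive")
        if len(self.perturb_folds) < self.passes:
            raise ValueError("need a perturbation fold per pass")
        if self.method not in ("powell", "nelder-mead"):
            raise ValueError("method must be 'powell' or 'nelder-mead'")


class _RunTimeout(Exception):
    pass


def _transform(values, spec):
    return np.array(
        [math.log10(v) if p.log else v for v, p in zip(values, spec.params)]
    )


def _untransform(x, spec):
    return np.array([10**xi if p.log else xi for xi, p in zip(x, spec.params)])


def _diversified_top(cands_x: np.ndarray, scores: np.ndarray, n_keep: int,
                     tlo: np.ndarray, thi: np.ndarray, min_sep: float = 0.12):
    """Greedy best-first selection with a minimum normalized L-inf separation,
    so multi-start searches begin in distinct likelihood basins."""
    span = np.maximum(thi - tlo, 1e-12)
    order = np.argsort(scores)
    chosen: list[int] = []
    for i in order:
        if not np.isfinite(scores[i]):
            continue
        if all(
            np.max(np.abs(cands_x[i] - cands_x[j]) / span) >= min_sep for j in chosen
        ):
            chosen.append(i)
        if len(chosen) == n_keep:
            return chosen
    # relax the separation if too few distinct candidates
    for i in order:
        if np.isfinite(scores[i]) and i not in chosen:
            chosen.append(i)
        if len(chosen) == n_keep:
            break
    return chosen


def fit_model(
    obs_sfs: JointSFS,
    spec: DemModelSpec,
    optimizer: OptimizerConfig | None = None,
    engine: EngineConfig | None = None,
) -> list[FitResult]:
    """Sequential step-down fit; returns every run from every pass.

    Pass 1 draws Sobol quasi-random starting candidates across the bounded
    (log10-transformed where applicable) parameter space, screens each with a
    single likelihood evaluation, and launches bounded direct searches
    (Powell by default) from the best-scoring mutually distant candidates.
    Each later pass perturbs the Akaike-weighted average of the previous
    pass's completed runs by that pass's fold factor; its first run instead
    continues from the best run so far with a deeper iteration budget, so the
    best AIC never degrades across passes under common random numbers. Every
    run carries a wall-clock timeout; timed-out runs are returned flagged and
    excluded from the weighting.
    """
    from scipy.stats import qmc

    optimizer = optimizer or OptimizerConfig()
    engine = engine or EngineConfig()
    if obs_sfs.ndim != 2:
        raise ValueError("observed spectrum must be two-dimensional")
    sizes = obs_sfs.sizes
    rng = np.random.default_rng(optimizer.seed)
    lo = np.array([p.lo for p in spec.params])
    hi = np.array([p.hi for p in spec.params])
    tlo = _transform(lo, spec)
    thi = _transform(hi, spec)

    eps = 0.5 / engine.replicates  # MC resolution floor for empty model cells

    def neg_ll(x):
        values = spec.check_bounds(_untransform(x, spec))
        if _time.monotonic() - run_t0 > optimizer.timeout_s:
            raise _RunTimeout
        try:
            model_sfs = expected_sfs(spec, values, sizes, engine)
        except RuntimeError:
            return 1e12  # non-coalescing corner of parameter space
        ll, _ = poisson_loglik(model_sfs, obs_sfs, eps=eps)
        return -ll

    def local_search_fn(fun, x0, maxiter):
        if optimizer.method == "powell":
            return minimize(
                fun, x0, method="Powell", bounds=list(zip(tlo, thi)),
                options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 0.05},
            )
        return minimize(
            fun, x0, method="Nelder-Mead", bounds=list(zip(tlo, thi)),
            options={"maxiter": maxiter, "xatol": 2e-3, "fatol": 0.1},
        )

    results: list[FitResult] = []
    for pass_i in range(optimizer.passes):
        fold = optimizer.perturb_folds[pass_i]
        deep = [False] * optimizer.runs_per_pass
        if pass_i == 0:
            n_cand = optimizer.screen_multiple * optimizer.runs_per_pass
            sobol = qmc.Sobol(d=len(spec.params), scramble=True,
                              seed=int(rng.integers(2**31 - 1)))
            n_draw = 2 ** int(np.ceil(np.log2(max(n_cand, 2))))
            cands_x = tlo + sobol.random(n_draw)[:n_cand] * (thi - tlo)
            run_t0 = _time.monotonic()
            scores = np.full(n_cand, np.inf)
            for ci in range(n_cand):
                try:
                    scores[ci] = neg_ll(cands_x[ci])
                except _RunTimeout:
                    break
            keep = _diversified_top(cands_x, scores, optimizer.runs_per_pass, tlo, thi)
            starts = [cands_x[i] for i in keep]
        else:
            prev = [r for r in results if r.pass_index == pass_i - 1]
            base = akaike_weighted_start(prev, spec)
            done = [r for r in results if not r.timed_out and r.aic is not None]
            best = min(done, key=lambda r: r.aic)
            # restart at the exact optimizer coordinates: under common random
            # numbers the first evaluation then reproduces best.loglik exactly
            starts = [best.x_opt if best.x_opt is not None
                      else _transform(best.params, spec)]
            deep[0] = True
            for _ in range(len(starts), optimizer.runs_per_pass):
                factors = fold ** rng.uniform(-1.0, 1.0, size=len(base))
                starts.append(_transform(spec.check_bounds(base * factors), spec))
        for run_i, x0 in enumerate(starts):
            run_t0 = _time.monotonic()
            timed_out = False
            converged = False
            # bounded scalar line searches on a Monte-Carlo surface can end a
            # run at a point worse than its start; remember the starting
            # evaluation so the run never reports a regression (picking the
            # overall argmin instead would select lucky noise minima at
            # arbitrary probe points)
            first = {"f": None, "x": None}

            def tracked(x, _first=first):
                f = neg_ll(x)
                if _first["f"] is None:
                    _first["f"] = f
                    _first["x"] = np.array(x, float)
                return f

            f_best = np.inf
            try:
                res = local_search_fn(
                    tracked,
                    np.asarray(x0, float),
                    optimizer.elite_maxiter if deep[run_i] else optimizer.maxiter,
                )
                converged = bool(res.success)
                if first["f"] is not None and res.fun > first["f"]:
                    x_best, f_best = first["x"], first["f"]
                else:
                    x_best, f_best = np.asarray(res.x, float), float(res.fun)
            except _RunTimeout:
                timed_out = True
            runtime = _time.monotonic() - run_t0
            if timed_out or f_best >= 1e12:
                results.append(
                    FitResult(spec.name,
                              spec.check_bounds(_untransform(np.asarray(x0), spec)),
                              np.nan, None, None,
                              pass_i, run_i, runtime, False, True)
                )
                continue
            values = spec.check_bounds(_untransform(x_best, spec))
            model_sfs = expected_sfs(spec, values, sizes, engine)
            _, theta = poisson_loglik(model_sfs, obs_sfs, eps=eps)
            ll = -float(f_best)
            results.append(
                FitResult(spec.name, values, theta, ll, aic(ll, spec.k_free),
                          pass_i, run_i, runtime, converged, False,
                          x_opt=x_best)
            )
        if not any(not r.timed_out for r in results):
            raise RuntimeError("every optimizer run timed out")
    return results


def best_fit(results: list[FitResult]) -> FitResult:
    done = [r for r in results if not r.timed_out and r.aic is not None]
    if not done:
        raise ValueError("no completed runs")
    return min(done, key=lambda r: r.aic)


def results_table(results: list[FitResult], spec: DemModelSpec):
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "model": r.model, "pass": r.pass_index, "run": r.run_index,
            "loglik": r.loglik, "aic": r.aic, "theta": r.theta,
            "runtime_s": r.runtime_s, "converged": r.converged,
            "timed_out": r.timed_out,
        }
        row.update(r.param_dict(spec))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Physical units


@dataclass
class UnitScaling:
    """Conversion from coalescent to physical units.

    mu: per-base per-generation mutation rate; generation_time_years: years per
    generation; length_bp: effective number of sequenced bases L behind the
    spectrum (total post-quality-filter bases scaled by the fraction of called
    SNPs that reached the final spectrum).
    """

    mu: float = 8.4e-9
    generation_time_years: float = 0.3
    length_bp: float = 1e6

    def __post_init__(self):
        if self.mu <= 0 or self.generation_time_years <= 0 or self.length_bp <= 0:
            raise ValueError("all scaling inputs must be positive")


def convert_units(fit: FitResult, spec: DemModelSpec, scaling: UnitScaling) -> dict:
    """Physical-unit report: N_ref = theta / (4*mu*L); sizes nu*N_ref
    individuals; times T*2*N_ref generations (and years); migration as both
    the scaled rate and the fraction replaced per generation m/(2*N_ref)."""
    if not fit.theta > 0:
        raise ValueError("fit has no positive theta scaling")
    n_ref = fit.theta / (4.0 * scaling.mu * scaling.length_bp)
    out = {"N_ref": n_ref, "theta": fit.theta, "model": fit.model}
    for p, v in zip(spec.params, fit.params):
        if p.kind == "size":
            out[f"{p.name}_individuals"] = v * n_ref
        elif p.kind == "time":
            gens = v * 2.0 * n_ref
            out[f"{p.name}_generations"] = gens
            out[f"{p.name}_years"] = gens * scaling.generation_time_years
        elif p.kind == "migration":
            out[f"{p.name}_scaled"] = v
            out[f"{p.name}_frac_per_gen"] = v / (2.0 * n_ref)
        else:
            out[p.name] = v
    return out
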