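"""Multi-deme coalescent scenarios and synthetic serial-founder datasets.

A :class:`DemographicScenario` describes demes with piecewise size curves
(constant / exponential / logistic), founding divergences, pulse admixtures and
continuous migration, all in coalescent scaling (sizes relative to N_ref, time
backward in units of 2*N_ref generations, backward lineage-migration rates per
unit time). It compiles to flat arrays consumed by the numba kernels in
:mod:`rangexp._kernel`.

Two products come out of a scenario: expected branch-length spectra (the engine
behind demographic inference) and complete synthetic datasets (genotypes with
known ancestral states, population map, coordinates) with the serial
founder-effect structure the downstream statistics assume: strong bottlenecks
at each colonization, post-founding growth, and low migration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .genotypes import GenotypeMatrix, LocusTable, PopulationMap
from .sfs import JointSFS, OutgroupAlleles

BIG_TIME = _kernel.BIG_TIME


@dataclass
class SizeEpoch:
    """One deme's size over backward-time interval [t_start, t_end).

    ``nu_recent`` applies at t_start (closer to the present), ``nu_old`` at
    t_end. Exponential curves interpolate log-linearly; logistic curves grow
    forward in time from nu_old toward carrying capacity nu_recent, with the
    rate set so 99% of the logistic transition completes within the epoch.
    """

    t_start: float
    t_end: float
    form: str = "constant"  # constant | exponential | logistic
    nu_recent: float = 1.0
    nu_old: float | None = None

    def __post_init__(self):
        if self.nu_recent <= 0 or (self.nu_old is not None and self.nu_old <= 0):
            raise ValueError("deme sizes must be positive")
        if self.form != "constant" and self.t_end >= BIG_TIME * 0.5:
            raise ValueError("the oldest epoch must have constant size")
        if self.form != "constant" and self.nu_old is None:
            raise ValueError("non-constant epochs need nu_old")

    def nu_at(self, t: float) -> float:
        if self.form == "constant":
            return self.nu_recent
        dur = self.t_end - self.t_start
        if self.form == "exponential":
            x = (t - self.t_start) / dur
            return self.nu_recent * (self.nu_old / self.nu_recent) ** x
        k, x0, r = self._logistic_params()
        ert = math.exp(r * (self.t_end - t))
        return k * x0 * ert / (1.0 - x0 + x0 * ert)

    def _logistic_params(self):
        """(K, x0, r): carrying capacity, start fraction at the old end, rate."""
        k = self.nu_recent
        x0 = self.nu_old / k
        dur = self.t_end - self.t_start
        xt = 0.99 if x0 < 1.0 else 1.01
        if abs(x0 - 1.0) < 1e-12 or abs(x0 - xt) < 1e-12:
            return k, x0, 0.0
        r = math.log(xt * (1.0 - x0) / (x0 * (1.0 - xt))) / dur
        return k, x0, max(r, 0.0)


@dataclass
class FoundingEvent:
    time: float
    source: int
    target: int


@dataclass
class PulseEvent:
    time: float
    source: int  # forward-time origin of the migrants
    target: int  # forward-time recipient; backward, its lineages jump to source
    fraction: float

    def __post_init__(self):
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("pulse fraction must be in (0, 1)")


@dataclass
class MigrationSpec:
    """Backward lineage migration: a lineage in ``in_deme`` jumps to ``to_deme``
    at ``rate`` per 2*N_ref generations while t in [t_start, t_end). Forward in
    time this is gene flow from ``to_deme`` into ``in_deme`` scaled as
    2*N_ref*(fraction of in_deme replaced per generation)."""

    t_start: float
    t_end: float
    in_deme: int
    to_deme: int
    rate: float


@dataclass
class DemographicScenario:
    n_demes: int
    deme_names: list[str] = None
    size_epochs: list[SizeEpoch] = field(default_factory=list)  # paired with deme ids
    size_deme: list[int] = field(default_factory=list)
    foundings: list[FoundingEvent] = field(default_factory=list)
    pulses: list[PulseEvent] = field(default_factory=list)
    migrations: list[MigrationSpec] = field(default_factory=list)
    coordinates: list[tuple[float, float]] = None  # per deme (lat, lon)

    def __post_init__(self):
        if self.deme_names is None:
            self.deme_names = [chr(ord("A") + i) for i in range(self.n_demes)]

    # -- builder API ------------------------------------------------------
    def set_size(self, deme: int, epoch: SizeEpoch) -> "DemographicScenario":
        self.size_epochs.append(epoch)
        self.size_deme.append(deme)
        return self

    def add_founding(self, time: float, source: int, target: int) -> "DemographicScenario":
        if time <= 0:
            raise ValueError("founding time must be positive")
        self.foundings.append(FoundingEvent(time, source, target))
        return self

    def add_pulse(self, time, source, target, fraction) -> "DemographicScenario":
        self.pulses.append(PulseEvent(time, source, target, fraction))
        return self

    def set_migration(self, t_start, t_end, in_deme, to_deme, rate) -> "DemographicScenario":
        if rate < 0:
            raise ValueError("migration rates must be >= 0")
        if rate > 0:
            self.migrations.append(MigrationSpec(t_start, t_end, in_deme, to_deme, rate))
        return self

    # -- validation / compilation -----------------------------------------
    def _deme_curve(self, deme: int, t: float) -> SizeEpoch | None:
        for ep, d in zip(self.size_epochs, self.size_deme):
            if d == deme and ep.t_start <= t < ep.t_end:
                return ep
        return None

    def validate(self) -> None:
        # every deme except the root must trace to a single root via foundings
        target_of = {}
        for f in self.foundings:
            if f.target in target_of:
                raise ValueError(f"deme {f.target} founded twice")
            target_of[f.target] = f.source
        roots = [d for d in range(self.n_demes) if d not in target_of]
        if len(roots) != 1:
            raise ValueError(f"scenario must have exactly one root deme, found {roots}")
        times = sorted(f.time for f in self.foundings)
        if len(set(times)) != len(times):
            raise ValueError("founding times must be distinct")

    def compile(self):
        """Flatten to the arrays expected by the numba kernels."""
        self.validate()
        boundaries = {0.0}
        for f in self.foundings:
            boundaries.add(f.time)
        for p in self.pulses:
            boundaries.add(p.time)
        for m in self.migrations:
            boundaries.add(m.t_start)
            if m.t_end < BIG_TIME * 0.5:
                boundaries.add(m.t_end)
        for ep in self.size_epochs:
            boundaries.add(ep.t_start)
            if ep.t_end < BIG_TIME * 0.5:
                boundaries.add(ep.t_end)
        bounds = sorted(boundaries) + [BIG_TIME]
        n_e = len(bounds) - 1
        epoch_times = np.array(bounds)
        size_form = np.zeros((n_e, self.n_demes), dtype=np.int8)
        size_p = np.zeros((n_e, self.n_demes, 3))
        mig = np.zeros((n_e, self.n_demes, self.n_demes))
        for e in range(n_e):
            ta, tb = bounds[e], bounds[e + 1]
            tmid = ta if tb >= BIG_TIME * 0.5 else 0.5 * (ta + tb)
            for d in range(self.n_demes):
                ep = self._deme_curve(d, tmid)
                if ep is None:
                    size_form[e, d] = 0
                    size_p[e, d, 0] = 1.0  # default: reference size
                    continue
                if ep.form == "constant":
                    size_form[e, d] = 0
                    size_p[e, d, 0] = ep.nu_recent
                elif ep.form == "exponential":
                    size_form[e, d] = 1
                    nur = ep.nu_at(ta)
                    nuo = ep.nu_at(tb)
                    lg = math.log(nuo / nur)
                    size_p[e, d, 0] = nur
                    size_p[e, d, 1] = lg
                    size_p[e, d, 2] = abs(lg) / (tb - ta)
                else:
                    size_form[e, d] = 2
                    k, _, r = ep._logistic_params()
                    size_p[e, d, 0] = k
                    size_p[e, d, 1] = ep.nu_at(tb) / k  # x at this slice's old end
                    size_p[e, d, 2] = r
            for m in self.migrations:
                if m.t_start <= tmid < m.t_end:
                    mig[e, m.in_deme, m.to_deme] += m.rate
        mig_out = mig.sum(axis=2)
        events = [(f.time, _kernel.EV_FOUNDING, f.source, f.target, 0.0) for f in self.foundings]
        events += [(p.time, _kernel.EV_PULSE, p.source, p.target, p.fraction) for p in self.pulses]
        events.sort()
        ev_bidx = np.array([bounds.index(t) for t, *_ in events] or [0], dtype=np.int32)
        ev_kind = np.array([k for _, k, *_ in events] or [0], dtype=np.int8)
        ev_src = np.array([s for _, _, s, _, _ in events] or [0], dtype=np.int32)
        ev_dst = np.array([d for _, _, _, d, _ in events] or [0], dtype=np.int32)
        ev_frac = np.array([f for *_, f in events] or [0.0])
        if not events:
            ev_bidx = np.array([-1], dtype=np.int32)  # never matched
        return (epoch_times, size_form, size_p, mig, mig_out,
                ev_bidx, ev_kind, ev_src, ev_dst, ev_frac)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_demes": self.n_demes,
                "deme_names": self.deme_names,
                "size_epochs": [
                    {"deme": d, **{k: v for k, v in ep.__dict__.items()}}
                    for ep, d in zip(self.size_epochs, self.size_deme)
                ],
                "foundings": [f.__dict__ for f in self.foundings],
                "pulses": [p.__dict__ for p in self.pulses],
                "migrations": [m.__dict__ for m in self.migrations],
                "coordinates": self.coordinates,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Expected spectra


class NonCoalescingError(RuntimeError):
    """The scenario failed to coalesce the sample within the time cap."""


def simulate_expected_sfs(
    scenario: DemographicScenario,
    sample_sizes: dict[int, int] | list[tuple[int, int]],
    n_reps: int = 5000,
    seed: int = 0,
    t_max: float = 1e4,
    return_se: bool = False,
):
    """Monte-Carlo expected SFS per unit theta (theta = 4*N_ref*mu*L).

    ``sample_sizes`` maps sampled deme -> gene copies (1 or 2 demes; the order
    given defines the spectrum axes). Cell (i, j) is the expected number of
    SNPs with i derived copies in the first population and j in the second,
    per unit theta. With ``return_se`` the per-cell Monte-Carlo standard error
    (on the same scale) is returned alongside.
    """
    items = list(sample_sizes.items()) if isinstance(sample_sizes, dict) else list(sample_sizes)
    if not 1 <= len(items) <= 2:
        raise ValueError("sample 1 or 2 demes")
    arrays = scenario.compile()
    sample_demes = np.concatenate(
        [np.full(n, d, dtype=np.int32) for d, n in items]
    )
    leaf_pop = np.concatenate(
        [np.full(n, ax, dtype=np.int32) for ax, (d, n) in enumerate(items)]
    )
    n0 = items[0][1]
    n1 = items[1][1] if len(items) == 2 else 0
    mean, meansq, fails = _kernel.expected_sfs_kernel(
        *arrays, sample_demes, leaf_pop, n0, n1, n_reps, seed, t_max
    )
    if fails > n_reps // 2:
        raise NonCoalescingError(
            f"{fails}/{n_reps} genealogies failed to coalesce within t_max={t_max}"
        )
    n_ok = n_reps - fails
    counts = mean / 2.0
    if len(items) == 1:
        counts = counts[:, 0]
    pops = [scenario.deme_names[d] for d, _ in items]
    sfs = JointSFS(counts, pops, polarized=True)
    if not return_se:
        return sfs
    var = np.maximum(meansq - mean**2, 0.0)
    se = np.sqrt(var / n_ok) / 2.0
    if len(items) == 1:
        se = se[:, 0]
    return sfs, se


# ---------------------------------------------------------------------------
# Full synthetic datasets


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    outgroup: OutgroupAlleles
    true_derived_counts: np.ndarray  # per retained locus, per sampled deme
    scenario: DemographicScenario
    seed: int


_BASES = np.array(list("ACGT"))


def simulate_dataset(
    scenario: DemographicScenario,
    samples_per_deme: dict[int, int],
    n_loci: int = 500,
    theta: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    one_snp_per_locus: bool = True,
    locus_spacing_bp: int = 20_000,
    t_max: float = 1e4,
) -> SyntheticDataset:
    """Genotypes + outgroup + population map under a coalescent scenario.

    Each locus is an independent genealogy (free recombination between loci,
    none within); mutations fall as a Poisson process on branches under the
    infinite-sites model with per-locus scaled rate ``theta``; by default one
    SNP per polymorphic locus is retained (RAD-like sparse loci). Gene copies
    are paired consecutively into diploids. The outgroup table records the true
    ancestral base at every retained SNP; REF/ALT polarity is randomized so
    polarization is actually exercised downstream.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    items = sorted(samples_per_deme.items())
    demes = [d for d, _ in items]
    n_dip = sum(n for _, n in items)
    n_copies = 2 * n_dip
    arrays = scenario.compile()
    sample_demes = np.concatenate(
        [np.full(2 * n, d, dtype=np.int32) for d, n in items]
    ).astype(np.int32)
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    total = 2 * n_copies - 1
    children = np.empty((total, 2), dtype=np.int32)
    node_birth = np.empty(total)
    node_death = np.empty(total)
    lin_node = np.empty(n_copies, dtype=np.int32)
    lin_deme = np.empty(n_copies, dtype=np.int32)
    deme_count = np.empty(scenario.n_demes, dtype=np.int64)

    _kernel.seed_kernel(kernel_seed)  # numba RNG state is separate from NumPy's
    chroms, poss, refs, alts, anc_bases, rows, true_counts = [], [], [], [], [], [], []
    members = np.zeros((total, n_copies), dtype=bool)
    deme_of_copy = sample_demes
    for locus in range(n_loci):
        ok = _kernel.sim_genealogy(
            *arrays, sample_demes, t_max,
            children, node_birth, node_death, lin_node, lin_deme, deme_count,
        )
        if ok == 0:
            raise NonCoalescingError(f"locus {locus}: no coalescence within t_max={t_max}")
        lengths = node_death - node_birth
        total_len = lengths.sum()
        n_mut = rng.poisson(theta / 2.0 * total_len)
        if n_mut == 0:
            continue
        mut_nodes = rng.choice(total, size=n_mut, p=lengths / total_len)
        if one_snp_per_locus:
            mut_nodes = mut_nodes[[rng.integers(0, n_mut)]]
        members[:n_copies] = np.eye(n_copies, dtype=bool)
        for v in range(n_copies, total):
            members[v] = members[children[v, 0]] | members[children[v, 1]]
        for snp_i, v in enumerate(mut_nodes):
            derived = members[v]
            anc, der = rng.choice(4, size=2, replace=False)
            anc_base, der_base = _BASES[anc], _BASES[der]
            if rng.random() < 0.5:
                ref, alt = anc_base, der_base
                alt_copies = derived
            else:
                ref, alt = der_base, anc_base
                alt_copies = ~derived
            calls = alt_copies.reshape(n_dip, 2).sum(axis=1).astype(np.int8)
            chroms.append(f"scaffold_{locus + 1}")
            poss.append((snp_i + 1) * locus_spacing_bp)
            refs.append(ref)
            alts.append(alt)
            anc_bases.append(anc_base)
            rows.append(calls)
            true_counts.append(
                [int(derived[deme_of_copy == d].sum()) for d in demes]
            )
    if not rows:
        raise ValueError("no polymorphic loci simulated (theta too small?)")
    calls = np.array(rows, dtype=np.int8).T
    if missing_rate > 0:
        miss = rng.random(calls.shape) < missing_rate
        calls = np.where(miss, np.int8(-1), calls)
    loci = LocusTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.array(anc_bases, dtype=object),
    )
    sample_ids = []
    pops = {}
    coords = {}
    for d, n in items:
        name = scenario.deme_names[d]
        for i in range(n):
            sid = f"{name}_{i}"
            sample_ids.append(sid)
            pops[sid] = name
            if scenario.coordinates is not None:
                coords[sid] = scenario.coordinates[d]
    gm = GenotypeMatrix(sample_ids, loci, calls)
    outgroup = OutgroupAlleles(
        {(c, int(p)): a for c, p, a in zip(chroms, poss, anc_bases)}
    )
    return SyntheticDataset(
        gm, PopulationMap(pops, coords), outgroup,
        np.array(true_counts, dtype=np.int64), scenario, seed,
    )


# ---------------------------------------------------------------------------
# Presets


def serial_founder_preset(
    n_demes: int,
    founder_fraction: float = 0.1,
    interval: float = 0.25,
    growth_form: str = "exponential",
    migration: float = 0.0,
    nu_final: float = 0.3,
    deme_spacing_deg: float = 15.0,
) -> DemographicScenario:
    """Chain colonization A -> B -> C -> ...: each deme founded from its
    predecessor with a ``founder_fraction`` bottleneck, then growing to
    ``nu_final`` by the present. Founding times are ``interval`` apart, the
    most recent colonization ``interval`` ago. Demes are laid out west-to-east
    on the equator for IBD testing.
    """
    if n_demes < 2:
        raise ValueError("need >= 2 demes")
    if not 0.0 < founder_fraction < 1.0:
        raise ValueError("founder_fraction must be in (0, 1)")
    sc = DemographicScenario(n_demes)
    sc.coordinates = [(0.0, -30.0 + deme_spacing_deg * i) for i in range(n_demes)]
    sc.set_size(0, SizeEpoch(0.0, BIG_TIME, "constant", 1.0))
    for i in range(1, n_demes):
        t_found = (n_demes - i) * interval
        sc.add_founding(t_found, i - 1, i)
        sc.set_size(
            i,
            SizeEpoch(0.0, t_found, growth_form, nu_recent=nu_final,
                      nu_old=founder_fraction),
        )
        sc.set_size(i, SizeEpoch(t_found, BIG_TIME, "constant", 1.0))
        if migration > 0:
            sc.set_migration(0.0, t_found, i, i - 1, migration)
            sc.set_migration(0.0, t_found, i - 1, i, migration)
    return sc


def stepping_stone_preset(
    n_demes: int,
    migration: float = 1.0,
    split_time: float = 4.0,
    deme_size: float = 0.5,
    deme_spacing_deg: float = 15.0,
) -> DemographicScenario:
    """Linear stepping-stone: demes split simultaneously from deme 0 long ago
    and exchange migrants only with immediate neighbours — the classic
    isolation-by-distance generator."""
    if n_demes < 2:
        raise ValueError("need >= 2 demes")
    sc = DemographicScenario(n_demes)
    sc.coordinates = [(0.0, -30.0 + deme_spacing_deg * i) for i in range(n_demes)]
    sc.set_size(0, SizeEpoch(0.0, BIG_TIME, "constant", 1.0))
    for i in range(1, n_demes):
        t = split_time + 1e-6 * i  # distinct founding times
        sc.add_founding(t, 0, i)
        sc.set_size(i, SizeEpoch(0.0, t, "constant", deme_size))
        sc.set_size(i, SizeEpoch(t, BIG_TIME, "constant", 1.0))
    for i in range(n_demes - 1):
        t = split_time
        sc.set_migration(0.0, t, i, i + 1, migration)
        sc.set_migration(0.0, t, i + 1, i, migration)
    return sc
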