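"""Config-driven pipeline chaining simulate -> filter -> sfs -> stats -> ibd -> fit.

One YAML config and one master seed determine every output; per-stage seeds are
derived by a stable hash of the stage name so inserting a stage never shifts
another stage's random stream. Each run writes a manifest recording inputs,
thresholds actually applied, seeds and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import demography, simulate, spatial, sumstats
from .genotypes import (GenotypeMatrix, filter_individuals_by_call_rate,
                        filter_loci_by_maf, hwe_exact_test, read_popmap, read_vcf,
                        thin_loci_by_distance, write_popmap, write_vcf)
from .sfs import (build_joint_sfs, marginalize, project, read_outgroup,
                  write_dadi_sfs, write_outgroup)

STAGES = ("simulate", "filter", "sfs", "stats", "ibd", "fit")


def stage_seed(master_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class ScenarioConfig:
    preset: str = "serial_founder"
    n_demes: int = 3
    founder_fraction: float = 0.01
    interval: float = 0.1
    migration: float = 0.0
    growth_form: str = "exponential"
    samples_per_deme: int = 8
    n_loci: int = 400
    theta: float = 1.0
    missing_rate: float = 0.0


@dataclass
class InputConfig:
    vcf: str | None = None
    popmap: str | None = None
    outgroup: str | None = None
    scenario: ScenarioConfig | None = None


@dataclass
class FilterConfig:
    call_rate: float = 0.75
    maf: float = 0.05
    thin_bp: int = 10_000


@dataclass
class SfsConfig:
    pops: list[str] | None = None  # default: first two populations
    projection: list[int] = field(default_factory=lambda: [10, 10])


@dataclass
class StatsConfig:
    diversity: bool = True
    tajima: bool = True
    fst: bool = True
    psi: bool = True
    hwe: bool = True
    n_perm: int = 1000


@dataclass
class IbdConfig:
    enabled: bool = True
    distance: str = "edwards"  # edwards | ibs
    n_perm: int = 999


@dataclass
class FitConfig:
    enabled: bool = False
    models: list[str] = field(default_factory=lambda: ["found_and_grow"])
    growth: str = "exponential"
    passes: int = 2
    runs_per_pass: int = 6
    replicates: int = 1000
    timeout_s: float = 60.0
    maxiter: int = 4  # direction-set sweeps per Powell run
    projection: list[int] = field(default_factory=lambda: [20, 10])


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "rangexp_out"
    input: InputConfig = field(default_factory=InputConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    sfs: SfsConfig = field(default_factory=SfsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    ibd: IbdConfig = field(default_factory=IbdConfig)
    fit: FitConfig = field(default_factory=FitConfig)


_SECTIONS = {
    "input": (InputConfig, {"scenario": ScenarioConfig}),
    "filters": (FilterConfig, {}),
    "sfs": (SfsConfig, {}),
    "stats": (StatsConfig, {}),
    "ibd": (IbdConfig, {}),
    "fit": (FitConfig, {}),
}


def _build_section(cls, sub, data, path):
    known = cls.__dataclass_fields__
    kwargs = {}
    for key, val in data.items():
        if key not in known:
            raise ValueError(f"unknown config key {path}.{key}")
        if key in sub and isinstance(val, dict):
            val = _build_section(sub[key], {}, val, f"{path}.{key}")
        kwargs[key] = val
    return cls(**kwargs)


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse + validate a YAML pipeline config, filling documented defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(path_or_dict)
    kwargs = {}
    for key, val in data.items():
        if key in ("seed", "output_dir"):
            kwargs[key] = val
        elif key in _SECTIONS:
            cls, sub = _SECTIONS[key]
            kwargs[key] = _build_section(cls, sub, val or {}, key)
        else:
            raise ValueError(f"unknown config key {key}")
    cfg = PipelineConfig(**kwargs)
    if not 0 <= cfg.filters.call_rate <= 1:
        raise ValueError("filters.call_rate must be in [0, 1]")
    if not 0 <= cfg.filters.maf <= 0.5:
        raise ValueError("filters.maf must be in [0, 0.5]")
    if cfg.filters.thin_bp <= 0:
        raise ValueError("filters.thin_bp must be positive")
    for m in cfg.fit.models:
        if m not in demography.MODEL_NAMES:
            raise ValueError(f"fit.models: unknown model {m!r}")
    for f in ("vcf", "popmap", "outgroup"):
        p = getattr(cfg.input, f)
        if p is not None and not Path(p).exists():
            raise ValueError(f"input.{f}: path {p!r} does not exist")
    return cfg


def config_to_yaml(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=False)


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages; returns the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "config": asdict(cfg)}
    gm = popmap = outgroup = None

    if "simulate" in stages and cfg.input.scenario is not None:
        sc_cfg = cfg.input.scenario
        seed = stage_seed(cfg.seed, "simulate")
        if sc_cfg.preset == "serial_founder":
            scenario = simulate.serial_founder_preset(
                sc_cfg.n_demes,
                founder_fraction=sc_cfg.founder_fraction,
                interval=sc_cfg.interval,
                migration=sc_cfg.migration,
                growth_form=sc_cfg.growth_form,
            )
        elif sc_cfg.preset == "stepping_stone":
            scenario = simulate.stepping_stone_preset(
                sc_cfg.n_demes, migration=max(sc_cfg.migration, 1.0)
            )
        else:
            raise ValueError(f"unknown scenario preset {sc_cfg.preset!r}")
        ds = simulate.simulate_dataset(
            scenario,
            {d: sc_cfg.samples_per_deme for d in range(sc_cfg.n_demes)},
            n_loci=sc_cfg.n_loci,
            theta=sc_cfg.theta,
            missing_rate=sc_cfg.missing_rate,
            seed=seed,
        )
        gm, popmap, outgroup = ds.genotypes, ds.popmap, ds.outgroup
        write_vcf(gm, out / "simulated.vcf")
        write_popmap(popmap, out / "popmap.tsv")
        write_outgroup(outgroup, out / "outgroup.tsv")
        (out / "scenario.json").write_text(scenario.to_json())
        manifest["stages"]["simulate"] = {
            "seed": seed, "n_samples": gm.n_samples, "n_loci": gm.n_loci,
        }

    if gm is None:
        if cfg.input.vcf is None:
            raise ValueError("no input VCF and no simulate stage")
        gm = read_vcf(cfg.input.vcf)
        popmap = read_popmap(cfg.input.popmap) if cfg.input.popmap else None
        outgroup = read_outgroup(cfg.input.outgroup) if cfg.input.outgroup else None

    if "filter" in stages:
        seed = stage_seed(cfg.seed, "filter")
        n0_samples, n0_loci = gm.n_samples, gm.n_loci
        gm, rep_cr = filter_individuals_by_call_rate(gm, cfg.filters.call_rate)
        gm, rep_maf = filter_loci_by_maf(gm, cfg.filters.maf)
        gm, rep_thin = thin_loci_by_distance(gm, cfg.filters.thin_bp, seed=seed)
        write_vcf(gm, out / "filtered.vcf")
        with open(out / "filter_report.json", "w") as fh:
            for rep in (rep_cr, rep_maf, rep_thin):
                fh.write(rep.to_json() + "\n")
        manifest["stages"]["filter"] = {
            "seed": seed,
            "call_rate": cfg.filters.call_rate, "maf": cfg.filters.maf,
            "thin_bp": cfg.filters.thin_bp,
            "samples_in": n0_samples, "samples_out": gm.n_samples,
            "loci_in": n0_loci, "loci_out": gm.n_loci,
        }

    pops = cfg.sfs.pops or (popmap.pops()[:2] if popmap else [])
    joint = None
    if "sfs" in stages and popmap is not None and outgroup is not None and len(pops) == 2:
        joint = build_joint_sfs(gm, popmap, pops, outgroup)
        proj = project(joint, cfg.sfs.projection)
        write_dadi_sfs(joint, out / "joint_sfs.txt")
        write_dadi_sfs(proj, out / "joint_sfs_projected.txt")
        manifest["stages"]["sfs"] = {
            "pops": pops, "projection": cfg.sfs.projection,
            "n_snps": joint.total(),
        }

    if "stats" in stages and popmap is not None:
        seed = stage_seed(cfg.seed, "stats")
        st: dict = {"seed": seed}
        if cfg.stats.diversity:
            div = sumstats.diversity(gm, popmap)
            div.to_csv(out / "diversity.tsv", sep="\t", index=False)
            st["diversity"] = div.to_dict("records")
        if cfg.stats.hwe:
            n_sig = 0
            for j in range(gm.n_loci):
                col = gm.calls[:, j]
                counts = [int((col == g).sum()) for g in (0, 1, 2)]
                if sum(counts) and hwe_exact_test(*counts) < 1e-6:
                    n_sig += 1
            st["hwe_p_below_1e-6"] = n_sig
        if cfg.stats.tajima and joint is not None:
            st["tajimas_d"] = {}
            for pop in pops:
                try:
                    st["tajimas_d"][pop] = sumstats.tajimas_d(marginalize(joint, pop)).d
                except sumstats.UndefinedStatistic:
                    st["tajimas_d"][pop] = None
        if cfg.stats.fst and popmap is not None and len(popmap.pops()) >= 2:
            st["fst"] = {}
            plist = popmap.pops()
            for i in range(len(plist)):
                for j in range(i + 1, len(plist)):
                    try:
                        r = sumstats.fst_permutation_test(
                            gm, popmap, plist[i], plist[j],
                            n_perm=cfg.stats.n_perm, seed=seed,
                        )
                        st["fst"][f"{plist[i]}~{plist[j]}"] = {
                            "theta": r.theta, "p": r.p_value,
                        }
                    except ValueError:
                        st["fst"][f"{plist[i]}~{plist[j]}"] = None
        if cfg.stats.psi and joint is not None:
            eq = project(joint, [min(joint.sizes)] * 2)
            try:
                pr = sumstats.psi(eq)
                st["psi"] = {f"{pr.pop_from}->{pr.pop_to}": pr.psi}
            except sumstats.UndefinedStatistic:
                st["psi"] = None
        with open(out / "stats.json", "w") as fh:
            json.dump(st, fh, indent=2, default=float)
        manifest["stages"]["stats"] = st

    if "ibd" in stages and cfg.ibd.enabled and popmap is not None and popmap.coordinates:
        seed = stage_seed(cfg.seed, "ibd")
        dist_fn = spatial.edwards_distance if cfg.ibd.distance == "edwards" else spatial.ibs_distance
        gen = dist_fn(gm)
        geo = spatial.geographic_distance(popmap, gm.sample_ids)
        res = spatial.mantel_test(gen, geo, n_perm=cfg.ibd.n_perm, seed=seed)
        tree = spatial.neighbor_joining(spatial.ibs_distance(gm))
        spatial.write_newick(tree, out / "nj_tree.nwk")
        manifest["stages"]["ibd"] = {
            "seed": seed, "distance": cfg.ibd.distance,
            "mantel_r": res.r, "mantel_p": res.p_value, "n_perm": res.n_perm,
        }

    if "fit" in stages and cfg.fit.enabled and joint is not None:
        seed = stage_seed(cfg.seed, "fit")
        obs = project(joint, cfg.fit.projection)
        engine = demography.EngineConfig(replicates=cfg.fit.replicates, seed=seed)
        opt = demography.OptimizerConfig(
            passes=cfg.fit.passes, runs_per_pass=cfg.fit.runs_per_pass,
            perturb_folds=tuple([3.0, 2.0, 2.0, 1.0][: cfg.fit.passes]),
            timeout_s=cfg.fit.timeout_s, maxiter=cfg.fit.maxiter, seed=seed,
        )
        fit_summary = {}
        for name in cfg.fit.models:
            spec = demography.model_spec(name, cfg.fit.growth)
            results = demography.fit_model(obs, spec, opt, engine)
            demography.results_table(results, spec).to_csv(
                out / f"fit_{name}.tsv", sep="\t", index=False
            )
            best = demography.best_fit(results)
            fit_summary[name] = {
                "aic": best.aic, "loglik": best.loglik, "theta": best.theta,
                "params": best.param_dict(spec),
            }
        with open(out / "fit_summary.json", "w") as fh:
            json.dump(fit_summary, fh, indent=2, default=float)
        manifest["stages"]["fit"] = {"seed": seed, "models": fit_summary}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
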