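"""End-to-end synthetic workflows with a single config and seed.

Three drivers reproduce the full analysis chain on generated data:

* :func:`run_table1_analogue` — simulate, build GRMs under both
  standardization modes, and fit the bivariate GREML with and without PC
  covariates, reporting r_g / h^2 estimates with SEs and the Wald test of
  r_g = 1 next to the simulation truth.
* :func:`run_table2_analogue` — stratify SNPs into frequency-and-LD-matched
  low/high groups on F_ST (or LDCV), fit the two-component bivariate
  GREML, and test the difference in r_g between groups.
* :func:`run_fig1_analogue` — split-sample GWAS, two-round clumping to
  sentinels, winner's-curse-free re-estimation, r_b with jackknife SE, a
  same-population negative control, and a GREML fit at the sentinels.

One global seed fans out to fixed per-stage child streams, so any stage can
be re-run in isolation and identical config + seed gives identical reports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import grm as grm_mod
from . import greml as greml_mod
from . import stratify as strat_mod
from . import sumstats as ss_mod
from .rg_diff import ComponentMoments, rg_difference_report
from .simulate import PopulationModel, TraitArchitecture, simulate_dataset

__all__ = ["RunConfig", "run_table1_analogue", "run_table2_analogue", "run_fig1_analogue", "run_all"]

_STAGES = ("simulate", "stratify", "sumstats", "fig1_simulate")


@dataclass
class SimulateConfig:
    n_pop1: int = 2000
    n_pop2: int = 2000
    m: int = 5000
    fst_target: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.5
    m_causal: int = 1000
    rg_true: float = 0.7
    h2_pop1: float = 0.5
    h2_pop2: float = 0.4


@dataclass
class GremlConfig:
    n_pcs: int = 20
    max_iter: int = 100
    tol: float = 1e-4
    start: str = "he"


@dataclass
class StratifyConfig:
    metric: str = "fst"
    n_freq_bins: int = 125
    n_ld_bins: int = 4
    window_kb: float = 1000.0
    estimator: str = "hudson"


@dataclass
class SumstatsConfig:
    # sparser architecture than the GREML preset: the sentinel-SNP analysis
    # needs individually detectable loci at desk-scale n
    m_causal: int = 100
    h2_pop1: float = 0.6
    h2_pop2: float = 0.6
    discovery_fraction: float = 0.5
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    window_kb: float = 1000.0
    window2_kb: float = 10_000.0


@dataclass
class RunConfig:
    """All module parameters, namespaced per stage, plus the global seed."""

    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    greml: GremlConfig = field(default_factory=GremlConfig)
    stratify: StratifyConfig = field(default_factory=StratifyConfig)
    sumstats: SumstatsConfig = field(default_factory=SumstatsConfig)
    seed: int = 1
    outdir: Optional[str] = None
    verbosity: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in ("simulate", "greml", "stratify", "sumstats"):
                sub_cls = {"simulate": SimulateConfig, "greml": GremlConfig,
                           "stratify": StratifyConfig, "sumstats": SumstatsConfig}[f.name]
                sub_known = {sf.name for sf in dataclasses.fields(sub_cls)}
                sub_unknown = set(v) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown config keys under {f.name}: {sorted(sub_unknown)}")
                if "ancestral_maf_range" in v:
                    v["ancestral_maf_range"] = tuple(v["ancestral_maf_range"])
                kwargs[f.name] = sub_cls(**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed).spawn(len(_STAGES))[_STAGES.index(stage)]


def _simulate_polymorphic(model: PopulationModel, arch: TraitArchitecture):
    """Simulate and drop SNPs fixed within either sampled population."""
    dataset, y = simulate_dataset(model, arch)
    keep = grm_mod.polymorphic_index(dataset)
    if len(keep) < dataset.n_snps:
        dataset = dataset.subset_snps(keep)
    return dataset, y


def _population_model(cfg: RunConfig, seed: int) -> PopulationModel:
    s = cfg.simulate
    return PopulationModel(
        n_pop1=s.n_pop1, n_pop2=s.n_pop2, m=s.m, fst_target=s.fst_target,
        ancestral_maf_range=s.ancestral_maf_range, ld_block_size=s.ld_block_size,
        ld_rho=s.ld_rho, seed=seed,
    )


def _stack(dataset, y, grms, covariates=None):
    """Order samples population-1-first and build the stacked model pieces."""
    pops = dataset.sample_table["population"].to_numpy()
    order = np.argsort(pops, kind="stable")
    n1 = int((pops == 1).sum())
    cols = [np.r_[np.ones(n1), np.zeros(len(y) - n1)],
            np.r_[np.zeros(n1), np.ones(len(y) - n1)]]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.extend(cov[order].T)
    x = np.column_stack(cols)
    grms = [a[np.ix_(order, order)] for a in grms]
    return greml_mod.BivariateModel(
        y=np.asarray(y, float)[order], X=x, grms=grms, n1=n1
    ), order


def run_table1_analogue(config: RunConfig) -> dict:
    """Whole-panel bivariate GREML under both GRM modes, with/without PCs."""
    seed = int(config.stage_seed("simulate").generate_state(1)[0] % 2**31)
    model = _population_model(config, seed)
    s = config.simulate
    arch = TraitArchitecture(m_causal=s.m_causal, rg_true=s.rg_true,
                             h2_pop1=s.h2_pop1, h2_pop2=s.h2_pop2)
    dataset, y = _simulate_polymorphic(model, arch)
    report: dict = {
        "n_pop1": s.n_pop1, "n_pop2": s.n_pop2, "m": s.m,
        "rg_true": s.rg_true, "h2_pop1_true": s.h2_pop1, "h2_pop2_true": s.h2_pop2,
    }
    opts = dict(max_iter=config.greml.max_iter, tol=config.greml.tol,
                start=config.greml.start)
    for mode in ("specific", "average"):
        g = grm_mod.compute_grm(dataset, mode=mode)
        k = min(config.greml.n_pcs, g.n - 4)
        pcs = grm_mod.compute_pcs(g, k)
        for with_pcs in (True, False):
            modelb, _ = _stack(dataset, y, [g.matrix], pcs if with_pcs else None)
            fit = greml_mod.reml_fit(modelb, **opts)
            d = greml_mod.derive_rg(fit)
            tag = f"{mode}_{'pcs' if with_pcs else 'nopcs'}"
            chi, p = (np.nan, np.nan)
            if d["defined"] and d["rg_se"] > 0:
                chi, p = greml_mod.wald_test(d["rg"], d["rg_se"], 1.0)
            report[tag] = {
                "rg": d["rg"], "rg_se": d["rg_se"],
                "rg_minus_truth": d["rg"] - s.rg_true,
                "h2_pop1": d["h2_pop1"], "h2_pop1_se": d["h2_pop1_se"],
                "h2_pop2": d["h2_pop2"], "h2_pop2_se": d["h2_pop2_se"],
                "p_rg_eq_1": p, "logL": fit.logL, "iterations": fit.iterations,
                "converged": fit.converged,
            }
    _emit(config, "table1", report)
    return report


def run_table2_analogue(config: RunConfig) -> dict:
    """Stratified two-component GREML and the r_g difference test."""
    seed = int(config.stage_seed("simulate").generate_state(1)[0] % 2**31)
    split_seed = int(config.stage_seed("stratify").generate_state(1)[0] % 2**31)
    model = _population_model(config, seed)
    s = config.simulate
    arch = TraitArchitecture(m_causal=s.m_causal, rg_true=s.rg_true,
                             h2_pop1=s.h2_pop1, h2_pop2=s.h2_pop2)
    dataset, y = _simulate_polymorphic(model, arch)
    sc = config.stratify
    strata = strat_mod.build_strata(
        dataset, metric=sc.metric, n_freq_bins=sc.n_freq_bins,
        n_ld_bins=sc.n_ld_bins, window_kb=sc.window_kb,
        estimator=sc.estimator, seed=split_seed,
    )
    gspec = grm_mod.compute_grm(dataset, mode="specific")
    k = min(config.greml.n_pcs, gspec.n - 10)
    pcs = grm_mod.compute_pcs(gspec, k)
    fit = strat_mod.two_component_fit(
        dataset, strata, y, covariates=pcs,
        max_iter=config.greml.max_iter, tol=config.greml.tol, start=config.greml.start,
    )
    names = ["Vg1_1", "Vg2_1", "C_1", "Vg1_2", "Vg2_2", "C_2"]
    moments = ComponentMoments(np.array([fit[n] for n in names]), fit.subcov(names))
    report = rg_difference_report(moments)
    t = strata.table
    balance = {}
    for pop in (1, 2):
        maf = np.minimum(t[f"freq{pop}"], 1 - t[f"freq{pop}"])
        ld = t[f"ld{pop}"]
        low, high = t["group"] == "low", t["group"] == "high"
        balance[f"maf{pop}_diff_in_sd"] = float(
            (maf[low].mean() - maf[high].mean()) / maf.std(ddof=1)
        )
        balance[f"ld{pop}_diff_in_sd"] = float(
            (ld[low].mean() - ld[high].mean()) / ld.std(ddof=1)
        )
    report.update({
        "metric": sc.metric,
        "n_low": int((t["group"] == "low").sum()),
        "n_high": int((t["group"] == "high").sum()),
        "mean_metric_low": float(t.loc[t["group"] == "low", sc.metric].mean()),
        "mean_metric_high": float(t.loc[t["group"] == "high", sc.metric].mean()),
        "rg_true": s.rg_true,
        "converged": fit.converged,
        "balance": balance,
    })
    _emit(config, "table2", report)
    return report


def run_fig1_analogue(config: RunConfig) -> dict:
    """Sentinel-SNP effect correlation r_b with negative control and a
    GREML fit restricted to the sentinel SNPs."""
    seed = int(config.stage_seed("fig1_simulate").generate_state(1)[0] % 2**31)
    split_ss = config.stage_seed("sumstats")
    model = _population_model(config, seed)
    f = config.sumstats
    arch = TraitArchitecture(m_causal=f.m_causal, rg_true=config.simulate.rg_true,
                             h2_pop1=f.h2_pop1, h2_pop2=f.h2_pop2)
    dataset, y = _simulate_polymorphic(model, arch)
    rng = np.random.default_rng(split_ss)

    # population 1: disjoint discovery / re-estimation halves
    ss_d, ss_e, idx_d, idx_e = ss_mod.split_sample_reestimate(
        dataset, y, f.discovery_fraction, rng, population=1
    )
    sent = ss_mod.clump_two_round(
        ss_d, dataset, p_threshold=f.p_threshold, r2_threshold=f.r2_threshold,
        window_kb=f.window_kb, window2_kb=f.window2_kb, sample_index=idx_d,
    )
    report: dict = {"n_sentinels": len(sent), "rg_true": config.simulate.rg_true}
    if len(sent) < 10:
        report["error"] = "fewer than 10 sentinels survived clumping"
        _emit(config, "fig1", report)
        return report

    # cross-population r_b: re-estimated effects in pop-1 half B vs pop 2
    idx_p2 = np.where(dataset.population_mask(2))[0]
    ss_p2 = ss_mod.gwas_scan(dataset, y, sample_index=idx_p2)
    rb, rb_se = ss_mod.rb_estimate(ss_e, ss_p2, sent.sentinels)
    report.update({"rb_cross": rb, "rb_cross_se": rb_se})

    # negative control: two disjoint quarters of population 1
    half = rng.permutation(idx_e)
    qa, qb = np.sort(half[: len(half) // 2]), np.sort(half[len(half) // 2:])
    ss_qa = ss_mod.gwas_scan(dataset, y, sample_index=qa)
    ss_qb = ss_mod.gwas_scan(dataset, y, sample_index=qb)
    try:
        nc, nc_se = ss_mod.negative_control(ss_qa, ss_qb, sent.sentinels)
        report.update({"rb_negative_control": nc, "rb_negative_control_se": nc_se})
    except ValueError as e:
        report["rb_negative_control_error"] = str(e)

    # GREML restricted to the sentinel SNPs (both populations, whole sample)
    sent_idx = dataset.snp_table.index[dataset.snp_table["snp"].isin(sent.sentinels)].to_numpy()
    if len(sent_idx) >= 2:
        sub = dataset.subset_snps(sent_idx)
        g = grm_mod.compute_grm(sub, mode="specific")
        modelb, _ = _stack(sub, y, [g.matrix])
        fit = greml_mod.reml_fit(modelb, max_iter=config.greml.max_iter,
                                 tol=config.greml.tol, start=config.greml.start)
        d = greml_mod.derive_rg(fit)
        report.update({
            "rg_greml_sentinels": d["rg"], "rg_greml_sentinels_se": d["rg_se"],
        })
    scatter = []
    ai, bi = ss_e.set_index("SNP"), ss_p2.set_index("SNP")
    for sid in sent.sentinels:
        scatter.append((sid, float(ai.loc[sid, "b"]), float(ai.loc[sid, "se"]),
                        float(bi.loc[sid, "b"]), float(bi.loc[sid, "se"])))
    report["scatter"] = scatter
    _emit(config, "fig1", report)
    return report


def run_all(config: RunConfig) -> dict:
    return {
        "table1": run_table1_analogue(config),
        "table2": run_table2_analogue(config),
        "fig1": run_fig1_analogue(config),
    }


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, object]]:
    items: list[tuple[str, object]] = []
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            items.extend(_flatten(v, key + "."))
        elif k == "scatter":
            continue
        else:
            items.append((key, v))
    return items


def _emit(config: RunConfig, name: str, report: dict) -> None:
    if config.outdir is None:
        return
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    with open(out / f"{name}.kv", "w") as fh:
        for k, v in _flatten(report):
            fh.write(f"{k}\t{v}\n")
    if "scatter" in report:
        with open(out / f"{name}_scatter.tsv", "w") as fh:
            fh.write("snp\tb_a\tse_a\tb_b\tse_b\n")
            for row in report["scatter"]:
                fh.write("\t".join(str(x) for x in row) + "\n")
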