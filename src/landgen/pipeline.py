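"""End-to-end landscape-genetics analysis driven by one flat config.

Stage order mirrors a standard microsatellite landscape-genetics study:
diversity summaries and Hardy-Weinberg tests, hierarchical F-statistics over
three nestings (populations; mountain-range/population;
environment/population), null-allele-corrected pairwise FST, the three
predictor distance matrices, reciprocal causal modeling, and spatial mixed
models of diversity against temperature.  Every number that appears in the
human-readable tables is also written to one machine-readable JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distances import (DistanceMatrix, environment_matrix, geographic_matrix,
                        least_cost_matrix, linearize_fst)
from .genotypes import (GenotypeTable, SiteTable, read_genepop, read_long_csv,
                        read_site_table, validate)
from .mantel import ReciprocalCausalModel
from .popgen import diversity_summary, hierarchical_f, hwe_test_mc, pairwise_fst
from .raster import read_esri_ascii
from .spatial import SpatialLM, lrt, morans_i

__all__ = ["RunConfig", "StageError", "run_pipeline", "published_dataset_check"]

log = logging.getLogger("landgen.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Flat, human-editable run configuration (YAML on disk)."""

    genotypes: str
    sites: str
    raster: str | None = None
    out_dir: str = "landgen_out"
    elevation_threshold_m: float = 1280.0
    n_perm: int = 9999
    bootstrap_b: int = 1000
    hwe_iter: int = 2000
    seed: int = 0
    fst_correction: str = "ena"
    log_geographic: bool = True
    hypotheses: list[str] = field(
        default_factory=lambda: ["IBD", "IBR", "IBE-tmax", "IBE-tmin"])
    responses: list[str] = field(default_factory=lambda: ["Ho", "He", "A", "Fis", "PA"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)),
                              encoding="utf-8")


def _load_genotypes(path: str) -> GenotypeTable:
    p = Path(path)
    if p.suffix.lower() == ".csv":
        return read_long_csv(p)
    return read_genepop(p)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write tables + ``results.json`` to ``cfg.out_dir``.

    Returns the results dictionary.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    results: dict = {"version": __version__, "seed": cfg.seed,
                     "config": dataclasses.asdict(cfg)}

    @_stage("genotype_io")
    def load_inputs():
        gt = _load_genotypes(cfg.genotypes)
        sites = read_site_table(cfg.sites)
        if set(gt.population_ids()) != set(sites.populations):
            # Genepop names populations after the last individual of each POP
            # block; when those ids do not match the site table but the block
            # count does, adopt the site names in block order
            if len(gt.population_ids()) != len(sites.populations):
                raise ValueError(
                    f"{len(gt.population_ids())} genotype populations vs "
                    f"{len(sites.populations)} sites; cannot reconcile"
                )
            mapping = dict(zip(gt.population_ids(), sites.populations))
            log.info("renaming Genepop populations to site ids: %s", mapping)
            gt.populations = [mapping[p] for p in gt.populations]
        sites = sites.reindex(gt.population_ids())
        gt.hierarchy = sites.hierarchy()
        return gt, sites

    gt, sites = load_inputs()
    results["validation"] = {
        "missingness": validate(gt).missingness.to_dict(),
        "sample_sizes": validate(gt).sample_sizes.to_dict(),
        "monomorphic_loci": validate(gt).monomorphic_loci,
    }

    @_stage("diversity")
    def diversity():
        ds = diversity_summary(gt)
        hwe = {pop: hwe_test_mc(gt, pop, n_iter=cfg.hwe_iter,
                                seed=int(rng.integers(2 ** 31)))
               for pop in gt.population_ids()}
        table = ds.table.copy()
        table["P_HWE"] = pd.Series(hwe)
        table.to_csv(out / "diversity.tsv", sep="\t", float_format="%.4f")
        return ds, table

    ds, div_table = diversity()
    results["diversity"] = json.loads(div_table.to_json(orient="index"))

    @_stage("hierarchical_f")
    def hierarchical():
        nestings = {"populations": None}
        mt = {p: h[0] for p, h in gt.hierarchy.items() if h[0]}
        env = {p: h[1] for p, h in gt.hierarchy.items() if h[1]}
        if len(set(mt.values())) > 1 and len(mt) == len(gt.population_ids()):
            nestings["mountain/population"] = ("Mt", mt)
        if len(set(env.values())) > 1 and len(env) == len(gt.population_ids()):
            nestings["environment/population"] = ("Env", env)
        res = {}
        for name, spec_ in nestings.items():
            if spec_ is None:
                hf = hierarchical_f(gt, B=cfg.bootstrap_b,
                                    seed=int(rng.integers(2 ** 31)))
            else:
                gname, groups = spec_
                hf = hierarchical_f(gt, groups=groups, group_name=gname,
                                    B=cfg.bootstrap_b,
                                    seed=int(rng.integers(2 ** 31)))
            hf.write_tsv(out / f"hierarchical_f_{name.replace('/', '_')}.tsv")
            res[name] = {k: {"estimate": v, "ci": list(hf.ci.get(k, (None, None)))}
                         for k, v in hf.f.items()}
        return res

    results["hierarchical_f"] = hierarchical()

    @_stage("fst")
    def fst_stage():
        raw = pairwise_fst(gt, correction="none")
        ena = pairwise_fst(gt, correction=cfg.fst_correction) \
            if cfg.fst_correction != "none" else raw
        ena.write_phylip(out / "fst_ena.phy")
        raw.write_phylip(out / "fst_raw.phy")
        return raw, ena

    fst_raw, fst_ena = fst_stage()
    results["fst"] = {"raw": fst_raw.values.tolist(),
                      "ena": fst_ena.values.tolist(),
                      "labels": fst_raw.labels}

    @_stage("landscape_distances")
    def distances():
        G = linearize_fst(fst_ena.distance_matrix())
        hyp: dict[str, DistanceMatrix] = {}
        for label in cfg.hypotheses:
            if label == "IBD":
                hyp[label] = geographic_matrix(sites, log_transform=cfg.log_geographic)
            elif label == "IBR":
                if cfg.raster is None:
                    raise ValueError("IBR hypothesis requested but no raster given")
                raster = read_esri_ascii(cfg.raster)
                hyp[label] = least_cost_matrix(raster, sites,
                                               cfg.elevation_threshold_m)
            elif label.startswith("IBE-"):
                hyp[label] = environment_matrix(sites, label.split("-", 1)[1])
            else:
                raise ValueError(f"unknown hypothesis {label!r}")
            hyp[label].write_tsv(out / f"distance_{label}.tsv")
        G.write_tsv(out / "distance_genetic.tsv")
        return G, hyp

    G, hyp = distances()

    @_stage("mantel_rcm")
    def rcm():
        res = ReciprocalCausalModel(G, hyp).fit(
            n_perm=cfg.n_perm, seed=int(rng.integers(2 ** 31)))
        res.support_frame().to_csv(out / "rcm_support.tsv", sep="\t",
                                   float_format="%.3f")
        res.correlation_frame().to_csv(out / "rcm_correlations.tsv", sep="\t")
        return res

    rcm_res = rcm()
    results["rcm"] = rcm_res.to_dict()

    @_stage("spatial_model")
    def spatial():
        rows = []
        model_results = {}
        for resp in cfg.responses:
            if resp not in div_table.columns:
                continue
            y = div_table[resp].astype(float)
            null_fit = SpatialLM(y, sites).fit()
            fits = {}
            for cov in ("tmin", "tmax"):
                if cov not in sites.data.columns:
                    continue
                for quad in (False, True):
                    name = f"{resp} ~ {cov}{'^2' if quad else ''}"
                    fit = SpatialLM(y, sites, covariate=cov, quadratic=quad).fit()
                    fits[name] = fit
            n_tests = len(fits)
            best = None
            for name, fit in fits.items():
                stat, p_adj = lrt(fit, null_fit, n_tests=n_tests)
                beta_name = fit.params.index[-1]
                ci = fit.conf_int().loc[beta_name]
                rows.append(dict(model=name, p_bonferroni=p_adj,
                                 beta=fit.params[beta_name],
                                 ci_low=ci["low"], ci_high=ci["high"],
                                 lambda_=fit.lambda_, df=fit.df_model,
                                 mAIC=fit.aic))
                model_results[name] = dict(
                    p_bonferroni=p_adj, beta=float(fit.params[beta_name]),
                    ci=[float(ci["low"]), float(ci["high"])],
                    lambda_=float(fit.lambda_), mAIC=float(fit.aic))
                if p_adj < 0.05 and (best is None or fit.aic < best[1].aic):
                    best = (name, fit)
            rows.append(dict(model=f"{resp} ~ 1 (null)", p_bonferroni=np.nan,
                             beta=np.nan, ci_low=np.nan, ci_high=np.nan,
                             lambda_=null_fit.lambda_, df=null_fit.df_model,
                             mAIC=null_fit.aic))
            model_results[f"{resp} ~ 1"] = dict(mAIC=float(null_fit.aic),
                                               lambda_=float(null_fit.lambda_))
            target = best[1] if best else null_fit
            mi = morans_i(target.resid, sites)
            model_results[f"{resp} residual Moran I"] = dict(
                I=float(mi.I), expected=mi.expected, p=float(mi.p))
        pd.DataFrame(rows).to_csv(out / "spatial_models.tsv", sep="\t",
                                  index=False, float_format="%.5g")
        return model_results

    results["spatial_models"] = spatial()

    (out / "results.json").write_text(
        json.dumps(results, indent=2, default=float), encoding="utf-8")
    return results


def published_dataset_check(genepop_path: str | Path,
                            sites: SiteTable | None = None) -> dict:
    """Headline allele counts and hierarchical F for a deposited dataset.

    Intended for the full 180-individual, 8-locus, 9-population genotype
    download; computes the quantities a reader would compare with the
    published per-population and hierarchical summaries: total distinct
    alleles, mean alleles per locus, the per-population allele-count range,
    and the four hierarchical F-statistics.
    """
    gt = read_genepop(genepop_path)
    ds = diversity_summary(gt)
    all_alleles = {(row.locus, row.allele)
                   for row in ds.frequencies.itertuples()}
    per_locus = ds.frequencies.groupby("locus")["allele"].nunique()
    out = {
        "total_alleles": len(all_alleles),
        "mean_alleles_per_locus": float(per_locus.mean()),
        "max_population_na": int(ds.table["Na"].max()),
        "min_population_na": int(ds.table["Na"].min()),
    }
    hf = hierarchical_f(gt)
    out["F_Pop/T"] = hf.f["F_Pop/T"]
    out["F_Ind/Pop"] = hf.f["F_Ind/Pop"]
    if sites is not None:
        gt.hierarchy = sites.hierarchy()
        mt = {p: h[0] for p, h in gt.hierarchy.items()}
        hf_mt = hierarchical_f(gt, groups=mt, group_name="Mt")
        out["F_Mt/T"] = hf_mt.f["F_Mt/T"]
        out["F_Pop/Mt"] = hf_mt.f["F_Pop/Mt"]
    return out
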