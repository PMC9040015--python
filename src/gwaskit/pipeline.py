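"""One-command GWAS pipeline: convert -> GRM -> eigen (once) -> PCs ->
variance components -> association scans -> report.

The GRM eigendecomposition is computed exactly once per run and the same
object feeds PC derivation, REML estimation and the mixed-model scan; the
run manifest records the instrumented decomposition count so the contract
is checkable. Reruns with identical config and seed reproduce identical
result tables. A plotting failure never invalidates result tables already
written (stage isolation).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import assoc, genotype_io, popstruct, varcomp, viz

__all__ = ["RunConfig", "run", "parse_config_file"]

log = logging.getLogger("gwaskit")

_VALID_MODELS = ("glm", "mlm", "farmcpu")
_VALID_VC = ("brent", "emmax", "fastlmm", "he")


@dataclass
class RunConfig:
    genotype: str = ""                 # store dir or source file
    format: str = "store"              # store | vcf | plink_bed | hapmap | numeric
    pheno: str = ""
    covar: Optional[str] = None
    trait: Optional[str] = None
    npc: int = 5
    varcomp_method: str = "brent"
    models: Sequence[str] = ("glm", "mlm")
    n_workers: int = 1
    out_dir: str = "gwaskit_out"
    seed: int = 0
    plots: bool = True
    grm_denominator: str = "vanraden2"
    numeric_map: Optional[str] = None
    farmcpu_max_loop: int = 10

    def validate(self):
        if self.npc < 0:
            raise ValueError("npc must be >= 0")
        bad = set(self.models) - set(_VALID_MODELS)
        if bad:
            raise ValueError(f"unknown models {sorted(bad)}")
        if self.varcomp_method not in _VALID_VC:
            raise ValueError(f"unknown varcomp method {self.varcomp_method!r}")


def parse_config_file(path) -> dict:
    """Flat key = value config; keys mirror RunConfig fields."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "models":
            out[key] = tuple(v.strip() for v in val.split(","))
        elif key in ("npc", "n_workers", "seed", "farmcpu_max_loop"):
            out[key] = int(val)
        elif key == "plots":
            out[key] = val.lower() in ("1", "true", "yes")
        else:
            out[key] = val
    return out


class _Stage:
    def __init__(self, name, manifest):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.time()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.time() - self.t0
        self.manifest["stages"][self.name] = {"seconds": round(dt, 3),
                                              "ok": exc_type is None}
        if exc_type is None:
            log.info("stage %s: done (%.2fs)", self.name, dt)
        else:
            log.error("stage %s: FAILED (%s)", self.name, exc)
            if exc is not None:
                exc.args = (f"[stage {self.name}] {exc}",) + tuple(exc.args[1:])
        return False


def run(config: RunConfig) -> dict:
    """Execute the standard pipeline; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    manifest = {
        "config": {**asdict(config), "models": list(config.models)},
        "versions": {"gwaskit": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    eig_before = popstruct.eigen_decomposition_count()
    try:
        with _Stage("convert", manifest):
            if config.format == "store":
                store = genotype_io.GenotypeStore(config.genotype)
            else:
                kwargs = {}
                if config.format == "numeric" and config.numeric_map:
                    kwargs["map_path"] = config.numeric_map
                store = genotype_io.convert(config.genotype, config.format,
                                            out / "store", **kwargs)
            log.info("store: %d markers x %d samples", *store.shape)

        with _Stage("align", manifest):
            pheno = genotype_io.load_phenotype(config.pheno)
            covar_df = genotype_io.load_phenotype(config.covar) if config.covar else None
            trait = config.trait or pheno.columns[1]
            aligned = genotype_io.align_samples(store, pheno, covar_df, trait)
            log.info("aligned %d samples (%d dropped for missing values)",
                     len(aligned.y), aligned.n_dropped_missing)

        with _Stage("grm", manifest):
            grm = popstruct.compute_grm(store, aligned.sample_index,
                                        denominator=config.grm_denominator)
            popstruct.write_grm(grm, out / "grm.txt")

        with _Stage("eigen", manifest):
            eig = popstruct.eigen_grm(grm)

        covariates = aligned.covariates
        if config.npc > 0:
            with _Stage("pca", manifest):
                pcs = popstruct.compute_pcs(eig, config.npc)
                pc_df = pd.DataFrame(pcs, columns=[f"PC{i+1}" for i in range(config.npc)])
                pc_df.insert(0, "sample_id", aligned.sample_ids)
                pc_df.to_csv(out / "pcs.tsv", sep="\t", index=False)
                covariates = pcs if covariates is None \
                    else np.column_stack([covariates, pcs])
        else:
            pcs = None

        need_vc = "mlm" in config.models or True  # varcomp always reported
        vc = None
        if need_vc:
            with _Stage("varcomp", manifest):
                n = len(aligned.y)
                X = np.ones((n, 1)) if covariates is None \
                    else np.column_stack([np.ones(n), covariates])
                if config.varcomp_method == "brent":
                    vc = varcomp.reml_brent(aligned.y, X, eig)
                elif config.varcomp_method == "emmax":
                    vc = varcomp.reml_emmax(aligned.y, X, eig)
                elif config.varcomp_method == "fastlmm":
                    vc = varcomp.reml_fastlmm(aligned.y, X, store=store,
                                              sample_index=aligned.sample_index)
                else:
                    vc = varcomp.he_regression(aligned.y, grm, X)
                report = (f"method\t{vc.method}\nsigma_g2\t{vc.sigma_g2:.6g}\n"
                          f"sigma_e2\t{vc.sigma_e2:.6g}\nh2\t{vc.h2:.6g}\n"
                          f"loglik\t{vc.loglik if vc.loglik is not None else 'NA'}\n")
                (out / "varcomp.txt").write_text(report)
                log.info("variance components: h2=%.4f (%s)", vc.h2, vc.method)
                manifest["varcomp"] = {"h2": vc.h2, "sigma_g2": vc.sigma_g2,
                                       "sigma_e2": vc.sigma_e2, "method": vc.method}

        result_files = {}
        for model in config.models:
            with _Stage(f"assoc_{model}", manifest):
                if model == "glm":
                    res = assoc.glm_scan(aligned.y, store, covariates,
                                         aligned.sample_index,
                                         n_workers=config.n_workers)
                elif model == "mlm":
                    if vc.method == "he":
                        vc_mlm = varcomp.reml_brent(
                            aligned.y,
                            np.column_stack([np.ones(len(aligned.y)), covariates])
                            if covariates is not None else np.ones((len(aligned.y), 1)),
                            eig)
                    else:
                        vc_mlm = vc
                    res = assoc.mlm_scan(aligned.y, store, covariates, eig,
                                         vc_mlm, aligned.sample_index,
                                         n_workers=config.n_workers)
                else:
                    res, info = assoc.farmcpu_scan(
                        aligned.y, store, covariates, aligned.sample_index,
                        max_loop=config.farmcpu_max_loop,
                        n_workers=config.n_workers)
                    manifest["farmcpu"] = info
                path = out / f"{trait}.{model}.assoc.txt"
                assoc.write_results(res, path)
                result_files[model] = str(path)
        manifest["results"] = result_files

        if config.plots:
            plots_dir = out / "plots"
            plots_dir.mkdir(exist_ok=True)
            for model, path in result_files.items():
                try:
                    with _Stage(f"plot_{model}", manifest):
                        res = pd.read_csv(path, sep="\t")
                        viz.manhattan(res, viz.PlotSpec(
                            out=str(plots_dir / f"{trait}.{model}.manhattan.png")))
                        viz.qq(res, viz.PlotSpec(
                            out=str(plots_dir / f"{trait}.{model}.qq.png")))
                except Exception:   # stage isolation: plots never void results
                    log.exception("plotting failed for %s", model)
            try:
                with _Stage("plot_misc", manifest):
                    viz.marker_density(store.markers, 1e6, viz.PlotSpec(
                        out=str(plots_dir / "marker_density.png")))
                    viz.pheno_dist(pheno[[pheno.columns[0], trait]], viz.PlotSpec(
                        out=str(plots_dir / "pheno_dist.png")))
                    if pcs is not None and config.npc >= 2:
                        viz.pca_plot(pcs, None, viz.PlotSpec(
                            out=str(plots_dir / "pca.png")))
            except Exception:
                log.exception("misc plotting failed")

        manifest["eigen_decompositions"] = (
            popstruct.eigen_decomposition_count() - eig_before)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return manifest
    finally:
        log.removeHandler(fh)
        fh.close()
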