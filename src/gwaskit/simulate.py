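"""Synthetic genotypes, population structure, relatedness and phenotypes.

The generator produces the data shapes a GWAS engine must survive:

* unstructured cohorts — Hardy-Weinberg sampling at frequencies drawn
  uniformly from the configured MAF range;
* discrete population structure — subpopulation allele frequencies drift
  from the ancestral frequency under the Balding-Nichols model,
  p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F), with divergence F;
* cryptic relatedness — samples grouped into full-sib families whose
  genotypes are drawn by Mendelian transmission from simulated parents;
* phenotypes with known truth — a configurable number of QTNs with
  normal or equal-variance effects, environmental noise rescaled so the
  realized heritability matches the target exactly.

Everything is driven by an explicit seed; there is no hidden global
randomness.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import GenotypeStore, StoreWriter

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_polygenic_from_eigen",
    "subpop_labels",
    "family_labels",
]


@dataclass
class SimConfig:
    """Configuration for one simulated cohort.

    ``fst`` is the Balding-Nichols divergence between subpopulations
    (0 = panmictic); ``family_size`` > 1 groups samples into full-sib
    families of that size; ``effect_dist`` is "normal" (iid N(0,1) allelic
    effects) or "equal" (each QTN scaled to contribute equal genetic
    variance, random sign).
    """

    n_samples: int = 1000
    n_markers: int = 10_000
    seed: int = 0
    maf_range: tuple = (0.05, 0.5)
    n_subpop: int = 1
    fst: float = 0.0
    family_size: int = 1
    n_chrom: int = 10
    chrom_length: int = 100_000_000
    n_qtn: int = 0
    h2: float = 0.5
    effect_dist: str = "normal"
    min_qtn_spacing: int = 2_000_000

    def validate(self):
        if self.n_samples < 2 or self.n_markers < 1:
            raise ValueError("need >= 2 samples and >= 1 marker")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_qtn > 0 and not (0 <= self.h2 <= 1):
            raise ValueError("h2 must be in [0, 1]")
        if self.n_qtn > self.n_markers:
            raise ValueError("more QTNs than markers")
        if self.fst < 0 or self.fst >= 1:
            raise ValueError("fst must be in [0, 1)")
        if self.effect_dist not in ("normal", "equal"):
            raise ValueError(f"unknown effect distribution {self.effect_dist!r}")


def subpop_labels(cfg: SimConfig) -> np.ndarray:
    """Subpopulation index per sample (contiguous, balanced blocks)."""
    return np.minimum(
        np.arange(cfg.n_samples) * cfg.n_subpop // cfg.n_samples,
        cfg.n_subpop - 1,
    )


def family_labels(cfg: SimConfig) -> np.ndarray:
    """Family index per sample (contiguous blocks of ``family_size``)."""
    if cfg.family_size <= 1:
        return np.arange(cfg.n_samples)
    return np.arange(cfg.n_samples) // cfg.family_size


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(cfg.n_chrom, cfg.n_markers // cfg.n_chrom)
    per[: cfg.n_markers % cfg.n_chrom] += 1
    recs = []
    i = 0
    for c, k in enumerate(per, start=1):
        pos = np.sort(rng.integers(1, cfg.chrom_length, size=k))
        for pp in pos:
            recs.append({"snp_id": f"snp{i}", "chrom": str(c), "pos": int(pp),
                         "allele_major": "A", "allele_minor": "B"})
            i += 1
    return pd.DataFrame(recs)


def simulate_genotypes(cfg: SimConfig, out_path=None,
                       block_size: int = 2048) -> GenotypeStore:
    """Write a simulated genotype store; reproducible under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if out_path is None:
        out_path = tempfile.mkdtemp(prefix="gwaskit_sim_")
    pops = subpop_labels(cfg)
    fams = family_labels(cfg)
    n_fam = int(fams.max()) + 1
    fam_pop = pops[np.searchsorted(fams, np.arange(n_fam))]
    map_df = _marker_map(cfg, rng)
    writer = StoreWriter(out_path, [f"s{i}" for i in range(cfg.n_samples)],
                         dtype="uint8")
    for start in range(0, cfg.n_markers, block_size):
        stop = min(start + block_size, cfg.n_markers)
        b = stop - start
        p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=b)
        if cfg.n_subpop > 1 and cfg.fst > 0:
            F = cfg.fst
            a = p_anc * (1 - F) / F
            bb = (1 - p_anc) * (1 - F) / F
            p_pop = rng.beta(a[:, None], bb[:, None],
                             size=(b, cfg.n_subpop))
        else:
            p_pop = np.repeat(p_anc[:, None], cfg.n_subpop, axis=1)
        if cfg.family_size <= 1:
            P = p_pop[:, pops]                       # b x n
            X = rng.binomial(2, P).astype(np.float64)
        else:
            Pf = p_pop[:, fam_pop]                   # b x n_fam
            parents = rng.binomial(2, Pf[:, :, None], size=(b, n_fam, 2))
            size = cfg.family_size
            t1 = rng.random((b, n_fam, size)) < parents[:, :, [0]] / 2.0
            t2 = rng.random((b, n_fam, size)) < parents[:, :, [1]] / 2.0
            X = (t1.astype(np.float64) + t2).reshape(b, n_fam * size)
            X = X[:, : cfg.n_samples]
        writer.append(X, map_df.iloc[start:stop].to_dict("records"))
    return writer.finalize({"sim_seed": cfg.seed})


def _pick_qtns(cfg: SimConfig, markers: pd.DataFrame,
               rng: np.random.Generator) -> np.ndarray:
    maf = markers["maf"].to_numpy()
    cand = np.flatnonzero(np.isfinite(maf) & (maf >= 0.05))
    if len(cand) < cfg.n_qtn:
        cand = np.flatnonzero(np.isfinite(maf) & (maf > 0))
    if len(cand) < cfg.n_qtn:
        raise ValueError("not enough polymorphic markers for requested QTNs")
    rng.shuffle(cand)
    chosen = []
    chroms = markers["chrom"].to_numpy()
    poss = markers["pos"].to_numpy()
    for i in cand:
        ok = all(
            chroms[i] != chroms[j] or abs(int(poss[i]) - int(poss[j])) >= cfg.min_qtn_spacing
            for j in chosen
        )
        if ok:
            chosen.append(int(i))
        if len(chosen) == cfg.n_qtn:
            break
    if len(chosen) < cfg.n_qtn:
        raise ValueError("cannot place QTNs with the requested spacing")
    return np.sort(np.array(chosen))


def simulate_phenotype(store: GenotypeStore, cfg: SimConfig,
                       seed: Optional[int] = None, trait: str = "trait1",
                       polygenic: bool = False):
    """Simulate a phenotype with known QTN truth from an existing store.

    The environmental noise is rescaled against the empirical genetic
    variance so the realized h^2 (var of genetic values / var of y) equals
    the target exactly. ``polygenic=True`` treats every marker as a QTN
    with equal-variance effects — the mixed model's own generative model,
    used for structured-null calibration.

    Returns ``(pheno, truth)`` where ``truth`` holds the QTN table, the
    effects and the realized h^2.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    n = store.n_samples
    if polygenic:
        qtn_idx = np.flatnonzero(store.markers["maf"].to_numpy() > 0)
        effect_dist = "equal"
    else:
        qtn_idx = _pick_qtns(cfg, store.markers, rng) if cfg.n_qtn > 0 else np.array([], dtype=int)
        effect_dist = cfg.effect_dist
    g = np.zeros(n)
    effects = np.zeros(len(qtn_idx))
    if len(qtn_idx) and cfg.h2 > 0:
        block = store.dosage_block(0, store.n_markers)[qtn_idx] \
            if len(qtn_idx) > store.n_markers // 2 else \
            np.array([store.dosage_row(int(i)) for i in qtn_idx])
        block = np.nan_to_num(block, nan=0.0)
        X = block - block.mean(axis=1, keepdims=True)
        if effect_dist == "equal":
            sd = X.std(axis=1)
            sd[sd == 0] = 1.0
            effects = rng.choice([-1.0, 1.0], size=len(qtn_idx)) / sd
        else:
            effects = rng.standard_normal(len(qtn_idx))
        g = effects @ X
    var_g = float(g.var())
    if cfg.h2 >= 1.0 and var_g > 0:
        y = g.copy()
    elif cfg.h2 <= 0 or var_g == 0:
        e = rng.standard_normal(n)
        y = (e - e.mean()) / e.std()
        var_g = 0.0
    else:
        gc = g - g.mean()
        e = rng.standard_normal(n)
        e = e - e.mean()
        e -= gc * (e @ gc) / (gc @ gc)   # orthogonalize: realized h2 exact
        e /= e.std()
        e *= np.sqrt(var_g * (1 - cfg.h2) / cfg.h2)
        y = g + e
    realized = var_g / float(y.var()) if y.var() > 0 else 0.0
    pheno = pd.DataFrame({"sample_id": store.samples, trait: y})
    truth = {
        "qtn": store.markers.iloc[qtn_idx][["snp_id", "chrom", "pos"]]
        .assign(effect=effects).reset_index(drop=True),
        "qtn_index": qtn_idx,
        "realized_h2": realized,
        "h2_target": cfg.h2,
    }
    return pheno, truth


def simulate_polygenic_from_eigen(eig, h2: float, seed: int) -> np.ndarray:
    """Phenotype whose genetic value is drawn from the GRM's own structure.

    g ~ N(0, K) via the eigendecomposition (g = U sqrt(lambda) z), with
    environmental noise orthogonalized and rescaled so the realized
    heritability equals ``h2`` exactly. This is the correctly specified
    generative model for GRM-based REML, used for parameter-recovery
    studies of the variance-component estimators.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1) for a polygenic draw")
    rng = np.random.default_rng(seed)
    n = eig.n
    g = eig.vectors @ (np.sqrt(eig.values) * rng.standard_normal(n))
    gc = g - g.mean()
    e = rng.standard_normal(n)
    e = e - e.mean()
    e -= gc * (e @ gc) / (gc @ gc)
    e /= e.std()
    e *= np.sqrt(gc.var() * (1 - h2) / h2)
    return g + e
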