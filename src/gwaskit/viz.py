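"""Publication plots for GWAS results: Manhattan, Q-Q, marker density,
phenotype distribution and PCA.

Every operation writes an image and returns ``(path, table)`` where the
table holds the exact plotted coordinates; tests assert on the table, not
on pixels. Result tables from other tools are accepted through a
column-mapping config (e.g. CHR/BP/P -> CHROM/POS/PVALUE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlotSpec",
    "manhattan",
    "qq",
    "marker_density",
    "pheno_dist",
    "pca_plot",
    "read_results",
    "genome_coordinates",
]

_DEFAULT_CYCLE = ("#4197d8", "#f8c120", "#413496", "#495226",
                  "#d60b6f", "#e66519", "#d581b7", "#83d3ad")

# common column dialects of other GWAS tools
_ALIASES = {"CHR": "CHROM", "BP": "POS", "P": "PVALUE", "RS": "SNP",
            "MARKER": "SNP", "BETA": "EFFECT"}


@dataclass
class PlotSpec:
    """Output and styling options shared by all plot operations."""

    out: str = "plot.png"
    fmt: str = "png"
    dpi: int = 150
    colors: Sequence[str] = _DEFAULT_CYCLE
    thresholds: Optional[Sequence[float]] = None   # p cut-offs
    highlights: Optional[dict] = None              # SNP id -> label
    layout: str = "rectangular-single"
    title: Optional[str] = None
    style: dict = field(default_factory=dict)      # pass-through rcParams

    def __post_init__(self):
        if self.thresholds:
            for t in self.thresholds:
                if not 0 < t < 1:
                    raise ValueError(f"threshold {t} outside (0, 1)")
        if self.layout not in ("rectangular-single", "rectangular-stacked",
                               "rectangular-overlaid", "circular"):
            raise ValueError(f"unknown layout {self.layout!r}")

    def path(self) -> Path:
        p = Path(self.out)
        if p.suffix.lstrip(".") != self.fmt:
            p = p.with_suffix("." + self.fmt)
        return p


def read_results(path_or_df, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Load a result table, renaming foreign column dialects to canonical names."""
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) \
        else pd.read_csv(path_or_df, sep=None, engine="python")
    ren = {}
    for c in df.columns:
        cu = str(c).upper()
        if column_map and c in column_map:
            ren[c] = column_map[c]
        elif cu in _ALIASES:
            ren[c] = _ALIASES[cu]
        elif cu in ("CHROM", "POS", "PVALUE", "SNP", "EFFECT", "SE", "N"):
            ren[c] = cu
    df = df.rename(columns=ren)
    return df


def _natural_chrom_order(chroms) -> list:
    def key(c):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)
    return sorted(set(map(str, chroms)), key=key)


def genome_coordinates(tables: Sequence[pd.DataFrame],
                       chrom_lengths: Optional[dict] = None,
                       gap_fraction: float = 0.01):
    """Cumulative genome coordinate for each chromosome.

    Returns ``(order, offsets, lengths, gap)``: chromosome order, the
    cumulative offset added to within-chromosome positions, per-chromosome
    lengths and the inter-chromosome gap (``gap_fraction`` of the total
    genome length).
    """
    chroms = pd.concat([t["CHROM"].astype(str) for t in tables])
    order = _natural_chrom_order(chroms)
    lengths = {}
    for c in order:
        mx = max(
            t.loc[t["CHROM"].astype(str) == c, "POS"].max() for t in tables
            if (t["CHROM"].astype(str) == c).any()
        )
        lengths[c] = float(chrom_lengths[c]) if chrom_lengths and c in chrom_lengths else float(mx)
    total = sum(lengths.values())
    gap = gap_fraction * total
    offsets = {}
    run = 0.0
    for c in order:
        offsets[c] = run
        run += lengths[c] + gap
    return order, offsets, lengths, gap


def _as_tables(results) -> list[pd.DataFrame]:
    if isinstance(results, pd.DataFrame):
        results = [results]
    out = []
    for t in results:
        t = read_results(t)
        if t.empty:
            raise ValueError("empty result table")
        missing = {"CHROM", "POS", "PVALUE"} - set(t.columns)
        if missing:
            raise ValueError(f"result table lacks columns {sorted(missing)}")
        if t["PVALUE"].isna().all():
            raise ValueError("all p-values missing")
        out.append(t)
    return out


def _place_labels(ax, pts, min_dx, dy):
    """Greedy vertical displacement so highlight labels do not overlap."""
    placed = []
    for x, y, label in sorted(pts):
        yy = y + dy
        for px, py in placed:
            if abs(x - px) < min_dx and abs(yy - py) < dy:
                yy = py + dy
        placed.append((x, yy))
        ax.annotate(label, (x, y), xytext=(x, yy), fontsize=7,
                    ha="center", arrowprops={"arrowstyle": "-", "lw": 0.5})


def manhattan(results, spec: PlotSpec, group_names: Optional[Sequence[str]] = None,
              chrom_lengths: Optional[dict] = None, density: bool = False,
              window_bp: float = 1e6):
    """Manhattan plot(s): -log10(p) against cumulative genome position.

    Multiple tables are drawn overlaid, stacked or as concentric circular
    tracks according to ``spec.layout``; chromosomes alternate colors,
    threshold lines are drawn at each cut-off and highlighted SNPs are
    labeled with greedy displacement. Returns ``(path, coords)`` with the
    plotted coordinate table.
    """
    tables = _as_tables(results)
    names = list(group_names) if group_names else [f"group{i + 1}" for i in range(len(tables))]
    order, offsets, lengths, gap = genome_coordinates(tables, chrom_lengths)
    m_total = max(len(t) for t in tables)
    thresholds = list(spec.thresholds) if spec.thresholds else [0.05 / m_total]

    frames = []
    for name, t in zip(names, tables):
        t = t.dropna(subset=["PVALUE"])
        chrom = t["CHROM"].astype(str).to_numpy()
        x = t["POS"].to_numpy(dtype=float) + np.array([offsets[c] for c in chrom])
        y = -np.log10(np.clip(t["PVALUE"].to_numpy(dtype=float), 1e-300, 1.0))
        frames.append(pd.DataFrame({
            "GROUP": name,
            "SNP": t["SNP"].to_numpy() if "SNP" in t else np.arange(len(t)),
            "CHROM": chrom, "POS": t["POS"].to_numpy(), "X": x, "Y": y,
        }))
    coords = pd.concat(frames, ignore_index=True)
    ymax = max(coords["Y"].max(), max(-np.log10(th) for th in thresholds)) * 1.08 + 0.2

    with plt.rc_context(spec.style):
        if spec.layout == "circular":
            fig, ax = plt.subplots(figsize=(7, 7),
                                   subplot_kw={"projection": "polar"})
            span = sum(lengths.values()) + gap * len(order)
            r0, band = 1.0, 0.8 / max(len(frames), 1)
            for gi, fr in enumerate(frames):
                theta = fr["X"] / span * 2 * np.pi
                ylo, yspan = r0 + gi * band, band * 0.9
                # each track's -log10(p) normalized to its own radial band
                ymx = max(fr["Y"].max(), 1e-9)
                r = ylo + fr["Y"] / ymx * yspan
                ci = [order.index(c) % len(spec.colors) for c in fr["CHROM"]]
                ax.scatter(theta, r, s=2,
                           c=[spec.colors[i] for i in ci], linewidths=0)
                for th in thresholds:
                    rt = ylo + (-np.log10(th)) / ymx * yspan
                    if rt <= ylo + yspan:
                        ax.plot(np.linspace(0, 2 * np.pi, 256),
                                np.full(256, rt), ls="--", lw=0.6, c="grey")
            ax.set_yticks([])
            ax.set_xticks([])
        elif spec.layout == "rectangular-stacked" and len(frames) > 1:
            fig, axes = plt.subplots(len(frames), 1, figsize=(9, 2.4 * len(frames)),
                                     sharex=True, squeeze=False)
            for ax_, fr, name in zip(axes[:, 0], frames, names):
                _draw_manhattan_axis(ax_, fr, order, spec, thresholds, ymax)
                ax_.set_ylabel(f"{name}\n" + r"$-\log_{10}(p)$")
            ax = axes[-1, 0]
        else:
            fig, ax = plt.subplots(figsize=(9, 3.2))
            for gi, (fr, name) in enumerate(zip(frames, names)):
                _draw_manhattan_axis(ax, fr, order, spec, thresholds, ymax,
                                     marker_index=gi, label=name)
            if len(frames) > 1:
                ax.legend(fontsize=7)
            ax.set_ylabel(r"$-\log_{10}(p)$")
        if spec.layout != "circular":
            ticks = [offsets[c] + lengths[c] / 2 for c in order]
            ax.set_xticks(ticks)
            ax.set_xticklabels(order, fontsize=7)
            ax.set_xlabel("chromosome")
            if density:
                _density_strip(ax, tables[0], offsets, window_bp, ymax)
        if spec.highlights:
            _apply_highlights(ax, coords, spec)
        if spec.title:
            fig.suptitle(spec.title)
        out = spec.path()
        fig.savefig(out, dpi=spec.dpi, bbox_inches="tight")
        plt.close(fig)
    coords.to_csv(str(out) + ".coords.tsv", sep="\t", index=False)
    return out, coords


def _draw_manhattan_axis(ax, fr, order, spec, thresholds, ymax,
                         marker_index=0, label=None):
    if label is not None and len(spec.colors) >= 2:
        # overlaid groups: one color per group, chromosome alternation dropped
        pass
    ci = [order.index(c) % 2 + 2 * (marker_index % 4) for c in fr["CHROM"]]
    colors = [spec.colors[i % len(spec.colors)] for i in ci]
    ax.scatter(fr["X"], fr["Y"], s=3, c=colors, linewidths=0, label=label)
    for th in thresholds:
        ax.axhline(-np.log10(th), ls="--", lw=0.7, c="grey")
    ax.set_ylim(0, ymax)


def _density_strip(ax, table, offsets, window_bp, ymax):
    t = table
    chrom = t["CHROM"].astype(str).to_numpy()
    x = t["POS"].to_numpy(dtype=float) + np.array([offsets[c] for c in chrom])
    bins = np.arange(x.min(), x.max() + window_bp, window_bp)
    counts, edges = np.histogram(x, bins=bins)
    norm = counts / max(counts.max(), 1)
    cmap = plt.get_cmap("viridis")
    for c, lo, hi in zip(norm, edges[:-1], edges[1:]):
        ax.axvspan(lo, hi, ymin=0.0, ymax=0.03, color=cmap(c), lw=0)


def _apply_highlights(ax, coords, spec):
    pts = []
    unresolved = []
    for snp, label in spec.highlights.items():
        hit = coords[coords["SNP"].astype(str) == str(snp)]
        if hit.empty:
            unresolved.append(snp)
            continue
        row = hit.iloc[0]
        pts.append((row["X"], row["Y"], label or str(snp)))
    if unresolved:
        warnings.warn(f"highlight SNPs not found in results: {unresolved}")
    if pts:
        xr = ax.get_xlim()
        _place_labels(ax, pts, min_dx=(xr[1] - xr[0]) * 0.02,
                      dy=(ax.get_ylim()[1]) * 0.05)


def qq(results, spec: PlotSpec, group_names: Optional[Sequence[str]] = None):
    """Q-Q plot of observed vs expected -log10(p) with a 95% null band.

    Expected quantiles are -log10((i - 0.5)/N) for ranked p-values; the
    shaded envelope is the beta order-statistic band under the uniform
    null. Returns ``(path, coords)``.
    """
    tables = _as_tables(results)
    names = list(group_names) if group_names else [f"group{i + 1}" for i in range(len(tables))]
    frames = []
    for name, t in zip(names, tables):
        p = np.sort(t["PVALUE"].dropna().to_numpy(dtype=float))
        N = len(p)
        i = np.arange(1, N + 1)
        exp = -np.log10((i - 0.5) / N)
        obs = -np.log10(np.clip(p, 1e-300, 1.0))
        frames.append(pd.DataFrame({"GROUP": name, "EXPECTED": exp[::-1],
                                    "OBSERVED": obs[::-1]}))
    coords = pd.concat(frames, ignore_index=True)
    with plt.rc_context(spec.style):
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
        Nmax = max(len(f) for f in frames)
        i = np.arange(1, Nmax + 1)
        exp = -np.log10((i - 0.5) / Nmax)
        lo = -np.log10(stats.beta.ppf(0.975, i, Nmax - i + 1))
        hi = -np.log10(stats.beta.ppf(0.025, i, Nmax - i + 1))
        ax.fill_between(exp, lo, hi, color="lightgrey", alpha=0.6,
                        label="95% null band")
        lim = max(coords["EXPECTED"].max(), coords["OBSERVED"].max())
        ax.plot([0, lim], [0, lim], c="grey", lw=0.8)
        for gi, (fr, name) in enumerate(zip(frames, names)):
            ax.scatter(fr["EXPECTED"], fr["OBSERVED"], s=4,
                       c=spec.colors[gi % len(spec.colors)], linewidths=0,
                       label=name)
        ax.set_xlabel(r"expected $-\log_{10}(p)$")
        ax.set_ylabel(r"observed $-\log_{10}(p)$")
        if len(frames) > 1 or True:
            ax.legend(fontsize=7)
        if spec.title:
            ax.set_title(spec.title)
        out = spec.path()
        fig.savefig(out, dpi=spec.dpi, bbox_inches="tight")
        plt.close(fig)
    coords.to_csv(str(out) + ".coords.tsv", sep="\t", index=False)
    return out, coords


def marker_density(markers: pd.DataFrame, window_bp: float, spec: PlotSpec,
                   chromosomes: Optional[Sequence[str]] = None):
    """Markers per genomic window, rendered as color-graded bars per chromosome.

    ``markers`` needs ``chrom`` and ``pos`` columns (canonical CHROM/POS also
    accepted). Chromosomes listed in ``chromosomes`` but absent from the map
    are rendered as zero-count tracks. Returns ``(path, counts)`` with
    columns CHROM, WIN_START, COUNT.
    """
    mk = markers.rename(columns={"CHROM": "chrom", "POS": "pos"})
    chroms = _natural_chrom_order(mk["chrom"]) if chromosomes is None \
        else [str(c) for c in chromosomes]
    recs = []
    for c in chroms:
        sub = mk[mk["chrom"].astype(str) == c]
        top = float(sub["pos"].max()) if len(sub) else window_bp
        edges = np.arange(0, top + window_bp, window_bp)
        if len(edges) < 2:
            edges = np.array([0.0, window_bp])
        counts, _ = np.histogram(sub["pos"].to_numpy(dtype=float) if len(sub) else [],
                                 bins=edges)
        for lo, cnt in zip(edges[:-1], counts):
            recs.append({"CHROM": c, "WIN_START": int(lo), "COUNT": int(cnt)})
    table = pd.DataFrame(recs)
    with plt.rc_context(spec.style):
        fig, ax = plt.subplots(figsize=(8, 0.4 * len(chroms) + 1))
        vmax = max(table["COUNT"].max(), 1)
        cmap = plt.get_cmap("turbo")
        for yi, c in enumerate(chroms):
            sub = table[table["CHROM"] == c]
            for _, row in sub.iterrows():
                ax.barh(yi, window_bp, left=row["WIN_START"], height=0.8,
                        color=cmap(row["COUNT"] / vmax), lw=0)
        ax.set_yticks(range(len(chroms)))
        ax.set_yticklabels(chroms, fontsize=7)
        ax.invert_yaxis()
        ax.set_xlabel("position (bp)")
        sm = plt.cm.ScalarMappable(cmap=cmap,
                                   norm=plt.Normalize(0, vmax))
        fig.colorbar(sm, ax=ax, label="markers / window")
        if spec.title:
            ax.set_title(spec.title)
        out = spec.path()
        fig.savefig(out, dpi=spec.dpi, bbox_inches="tight")
        plt.close(fig)
    table.to_csv(str(out) + ".coords.tsv", sep="\t", index=False)
    return out, table


def pheno_dist(pheno: pd.DataFrame, spec: PlotSpec):
    """Histogram + density curve per trait; returns ``(path, stats_table)``.

    A constant trait is rendered as a single bin with a warning.
    """
    traits = pheno.columns[1:]
    recs = []
    with plt.rc_context(spec.style):
        fig, axes = plt.subplots(1, len(traits), figsize=(4 * len(traits), 3.2),
                                 squeeze=False)
        for ax, tr in zip(axes[0], traits):
            vals = pheno[tr].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                raise ValueError(f"trait {tr!r} has no observations")
            if np.ptp(vals) == 0:
                warnings.warn(f"trait {tr!r} is constant; single-bin histogram")
                ax.hist(vals, bins=1, color=spec.colors[0])
                skw = 0.0
            else:
                ax.hist(vals, bins=30, density=True, color=spec.colors[0],
                        alpha=0.7)
                kde = stats.gaussian_kde(vals)
                xs = np.linspace(vals.min(), vals.max(), 200)
                ax.plot(xs, kde(xs), c=spec.colors[2 % len(spec.colors)])
                skw = float(stats.skew(vals))
            ax.set_title(str(tr), fontsize=9)
            recs.append({"TRAIT": tr, "N": len(vals), "MEAN": float(vals.mean()),
                         "SD": float(vals.std()), "SKEWNESS": skw})
        out = spec.path()
        fig.savefig(out, dpi=spec.dpi, bbox_inches="tight")
        plt.close(fig)
    table = pd.DataFrame(recs)
    table.to_csv(str(out) + ".coords.tsv", sep="\t", index=False)
    return out, table


def pca_plot(pcs: np.ndarray, labels=None, spec: PlotSpec = None, dims: int = 2):
    """PC scatter in 2-D (PC1 vs PC2) or 3-D (PC1-PC3), colored by group."""
    spec = spec or PlotSpec(out="pca.png")
    pcs = np.asarray(pcs, dtype=np.float64)
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if pcs.shape[1] < dims:
        raise ValueError(f"need >= {dims} PC columns, got {pcs.shape[1]}")
    labels = np.asarray(labels) if labels is not None else np.zeros(len(pcs), dtype=int)
    table = pd.DataFrame({f"PC{i + 1}": pcs[:, i] for i in range(dims)})
    table["GROUP"] = labels
    with plt.rc_context(spec.style):
        fig = plt.figure(figsize=(4.6, 4.2))
        ax = fig.add_subplot(111, projection="3d" if dims == 3 else None)
        for gi, g in enumerate(np.unique(labels)):
            mask = labels == g
            args = [pcs[mask, i] for i in range(dims)]
            ax.scatter(*args, s=8, label=str(g),
                       c=spec.colors[gi % len(spec.colors)])
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        if dims == 3:
            ax.set_zlabel("PC3")
        if len(np.unique(labels)) > 1:
            ax.legend(fontsize=7)
        if spec.title:
            ax.set_title(spec.title)
        out = spec.path()
        fig.savefig(out, dpi=spec.dpi, bbox_inches="tight")
        plt.close(fig)
    table.to_csv(str(out) + ".coords.tsv", sep="\t", index=False)
    return out, table
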