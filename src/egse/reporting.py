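"""Report data and rendering: heatmaps, method MDS, summary/bar plots, HTML.

Every display is split into a pure data operation (a join/sort/filter over the
score tables, easy to test) and a matplotlib renderer.  Colour semantics are
emitted as categorical keys (``up``/``down``/``neutral``/``highlight`` …)
rather than RGB so renderers can restyle; the default style maps up-regulated
to red, down-regulated to blue and neutral to purple.  The static HTML report
collects the ranked tables and plots per collection × contrast plus the
cross-contrast comparison.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import top_sets
from .gmt import CollectionIndex, get_set_by_name
from .linmod import GeneLevelStats, top_table
from .pipeline import AnalysisResult

__all__ = [
    "set_heatmap_data",
    "methods_mds",
    "summary_plot_data",
    "comparative_summary_plot_data",
    "bar_plot_data",
    "summary_heatmap_data",
    "generate_report",
    "report_from_tables",
    "ReportBundle",
]

_P_LIKE = {"p.value", "p.adj", "min.pvalue"}
_DIRECTION_KEY = {1: "up", -1: "down", 0: "neutral"}


# ---------------------------------------------------------------------------
# plot-data operations (pure)
# ---------------------------------------------------------------------------

def set_heatmap_data(gls: GeneLevelStats, index: CollectionIndex, set_name: str,
                     contrasts: list[str] | None = None,
                     fdr_cutoff: float = 0.05):
    """Genes × contrasts logFC matrix for one set, plus significance flags
    and the full per-gene top-table rows for the CSV side file.

    Rows are the set's genes present in the expression matrix (displayed by
    symbol when a symbols map was supplied); columns follow the contrast
    matrix order.  A gene is flagged significant when its FDR is at most
    ``fdr_cutoff`` in at least one of the selected contrasts.
    """
    gs = get_set_by_name(index, set_name)
    iset = next(s for s in index if s.name == set_name)
    if not iset.index:
        raise ValueError(f"set {set_name!r} has no expressed genes")
    contrasts = list(contrasts) if contrasts else list(gls.contrast_names)
    genes = [gls.gene_ids[i] for i in iset.index]
    mat = pd.DataFrame(
        {c: gls.logfc[iset.index, gls.contrast_column(c)] for c in contrasts},
        index=[gls.symbol_of(g) for g in genes])
    fdr = np.column_stack([gls.fdr[iset.index, gls.contrast_column(c)] for c in contrasts])
    flags = pd.Series((fdr <= fdr_cutoff).any(axis=1), index=mat.index)
    rows = []
    for c in contrasts:
        tt = top_table(gls, c)
        sub = tt[tt["FeatureID"].isin(genes)].copy()
        sub.insert(0, "Contrast", c)
        rows.append(sub)
    csv = pd.concat(rows, ignore_index=True)
    return mat, flags, csv


def methods_mds(ranks: pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the methods from their set rankings.

    Dissimilarity between two methods is one minus the Spearman correlation of
    their rank columns; the doubly-centred squared-distance matrix is
    eigen-decomposed and the top two axes scaled by the square roots of their
    eigenvalues.  Axis signs are fixed so the first method has non-negative
    coordinates.
    """
    if ranks.shape[1] < 3:
        raise ValueError("MDS needs at least three methods")
    rho = stats.spearmanr(ranks.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    D = 1.0 - rho
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for j in range(coords.shape[1]):
        if coords[0, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(coords, index=ranks.columns, columns=["dim1", "dim2"])


def _x_values(table: pd.DataFrame, x_axis: str) -> np.ndarray:
    vals = table[x_axis].to_numpy(dtype=float)
    if x_axis in _P_LIKE:
        return -np.log10(np.clip(vals, 1e-300, None))
    return vals


def summary_plot_data(table: pd.DataFrame, x_axis: str = "p.adj",
                      x_cutoff: float | None = None, variant: str = "directional",
                      sort_by: str | None = None, top_k: int = 10,
                      highlight_extra: int = 5,
                      set_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Bubble-plot data: x from the chosen score (−log10 for p-like axes),
    y the set's average absolute logFC.

    The directional variant sizes bubbles by the significance score and
    colours by regulation direction; the rank variant sizes by set cardinality
    (``set_sizes``) and colours by rank.  The top ``top_k`` sets under the
    active sort are flagged for labelling, plus up to ``highlight_extra`` sets
    among the collection's top 5 significance scores that fall outside the
    top ``top_k`` (given a distinct colour key).  ``x_cutoff`` keeps only sets
    at or below the cutoff on the raw axis scale.
    """
    if x_axis not in table.columns:
        raise KeyError(f"unknown x_axis {x_axis!r}")
    if variant not in ("directional", "rank"):
        raise ValueError(f"unknown variant {variant!r}")
    sort_by = sort_by or x_axis
    df = pd.DataFrame(index=table.index)
    df["x"] = _x_values(table, x_axis)
    df["y"] = table["avg.logfc"].to_numpy()
    if variant == "directional":
        df["size"] = table["significance"].to_numpy()
        df["colour"] = [_DIRECTION_KEY[int(d)] for d in table["direction"]]
    else:
        if set_sizes is None:
            raise ValueError("rank variant needs set_sizes")
        df["size"] = [set_sizes.get(name, 0) for name in table.index]
        df["colour"] = table[sort_by].rank(method="min").astype(int).astype(object)

    top = set(top_sets(table, sort_by, top_k).index)
    top_sig = set(top_sets(table, "significance", 5).index)
    highlight = sorted(top_sig - top)[:highlight_extra]
    df["label"] = [name in top or name in highlight for name in df.index]
    df.loc[df.index.isin(highlight), "colour"] = "highlight"
    if x_cutoff is not None:
        df = df[table[x_axis].to_numpy() <= x_cutoff]
    return df


def comparative_summary_plot_data(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Contrast-vs-contrast significance scatter with a joint-direction class.

    Inner join on set name; x and y are −log10 adjusted p-values in the two
    contrasts; the class separates sets moving the same way in both contrasts
    from those moving in opposite directions (the "opposite" class is the one
    traditionally drawn in purple).
    """
    common = table_a.index.intersection(table_b.index)
    if len(common) == 0:
        raise ValueError("the two tables share no gene sets")
    a = table_a.loc[common]
    b = table_b.loc[common]
    da = a["direction"].astype(int)
    db = b["direction"].astype(int)
    joint = np.where((da == 0) | (db == 0), "neutral",
                     np.where(da == db, np.where(da > 0, "both-up", "both-down"),
                              "opposite"))
    return pd.DataFrame({
        "x": -np.log10(np.clip(a["p.adj"].to_numpy(dtype=float), 1e-300, None)),
        "y": -np.log10(np.clip(b["p.adj"].to_numpy(dtype=float), 1e-300, None)),
        "class": joint,
    }, index=common)


def bar_plot_data(table: pd.DataFrame, n: int = 20, value: str = "p.adj",
                  sort_by: str = "p.adj") -> pd.DataFrame:
    """Top-``n`` bar data: value per set (−log10 for p-like scores) and a colour
    key from the regulation direction (up → red, down → blue, neutral → purple
    in the default style)."""
    if n <= 0:
        raise ValueError("n must be positive")
    top = top_sets(table, sort_by, n)
    vals = top[value].to_numpy(dtype=float)
    if value in _P_LIKE:
        vals = -np.log10(np.clip(vals, 1e-300, None))
    return pd.DataFrame({
        "value": vals,
        "colour": [_DIRECTION_KEY[int(d)] for d in top["direction"]],
    }, index=top.index)


def summary_heatmap_data(comparison: pd.DataFrame,
                         per_contrast: dict[str, pd.DataFrame],
                         n: int = 20, value: str = "avg.logfc.dir",
                         sort_by: str = "p.adj",
                         show_vals: str | None = None):
    """Top-``n`` comparison sets × contrasts matrix of a per-contrast score
    (default: the direction-consistent average logFC), optionally annotated
    with a second score."""
    if not per_contrast:
        raise ValueError("need at least one contrast table")
    sample = next(iter(per_contrast.values()))
    if value not in sample.columns:
        raise KeyError(f"unknown value key {value!r}")
    rows = top_sets(comparison, sort_by, n).index
    mat = pd.DataFrame(
        {c: t[value].reindex(rows) for c, t in per_contrast.items()})
    if show_vals is None:
        return mat
    if show_vals not in sample.columns:
        raise KeyError(f"unknown show_vals key {show_vals!r}")
    ann = pd.DataFrame({c: t[show_vals].reindex(rows) for c, t in per_contrast.items()})
    return mat, ann


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

_COLOURS = {"up": "#c0392b", "down": "#2e6da4", "neutral": "#8e44ad",
            "highlight": "#16a085"}


def _save(fig, stem: Path) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        path = stem.with_suffix(f".{ext}")
        fig.savefig(path, dpi=100, metadata={"Date": None} if ext == "svg" else None)
        paths.append(path)
    plt.close(fig)
    return paths


def render_summary_plot(df: pd.DataFrame, stem: Path, title: str = "") -> list[Path]:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    colours = [_COLOURS.get(c, "#777777") if isinstance(c, str) else "#777777"
               for c in df["colour"]]
    size = 10 + 2 * np.abs(df["size"].to_numpy(dtype=float))
    ax.scatter(df["x"], df["y"], s=size, c=colours, alpha=0.6, linewidths=0)
    for name, row in df[df["label"]].iterrows():
        ax.annotate(str(name), (row["x"], row["y"]), fontsize=5)
    ax.set_xlabel("-log10(p.adj)")
    ax.set_ylabel("avg. |logFC|")
    ax.set_title(title, fontsize=9)
    return _save(fig, stem)


def render_bar_plot(df: pd.DataFrame, stem: Path, title: str = "") -> list[Path]:
    fig, ax = plt.subplots(figsize=(6, 0.25 * len(df) + 1.5))
    colours = [_COLOURS.get(c, "#777777") for c in df["colour"]]
    ax.barh(np.arange(len(df))[::-1], df["value"], color=colours)
    ax.set_yticks(np.arange(len(df))[::-1])
    ax.set_yticklabels(df.index, fontsize=5)
    ax.set_xlabel("-log10(p.adj)")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    return _save(fig, stem)


def render_mds(coords: pd.DataFrame, stem: Path, title: str = "method MDS") -> list[Path]:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords["dim1"], coords["dim2"], c="#34495e")
    for name, row in coords.iterrows():
        ax.annotate(str(name), (row["dim1"], row["dim2"]), fontsize=7)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title, fontsize=9)
    return _save(fig, stem)


def render_heatmap(mat: pd.DataFrame, stem: Path, title: str = "") -> list[Path]:
    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * mat.shape[1], 0.6 + 0.22 * len(mat)))
    lim = float(np.nanmax(np.abs(mat.to_numpy()))) if mat.size else 1.0
    im = ax.imshow(mat.to_numpy(dtype=float), cmap="RdBu_r", vmin=-lim, vmax=lim,
                   aspect="auto")
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(mat.columns, fontsize=6, rotation=45, ha="right")
    ax.set_yticks(range(len(mat)))
    ax.set_yticklabels(mat.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="avg.logfc.dir")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    return _save(fig, stem)


# ---------------------------------------------------------------------------
# HTML report
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    out_dir: Path
    index_page: Path
    tables: list[Path] = field(default_factory=list)
    plots: list[Path] = field(default_factory=list)
    set_csvs: list[Path] = field(default_factory=list)


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #ccc;padding:2px 6px;font-size:12px}}</style></head>
<body><h1>{title}</h1>
{params}
{sections}
</body></html>
"""


def _table_html(df: pd.DataFrame, n: int) -> str:
    return df.head(n).to_html(float_format=lambda v: f"{v:.3g}", border=0)


def generate_report(result: AnalysisResult, out_dir: str | Path,
                    number: int = 20, title: str = "Ensemble gene set analysis") -> ReportBundle:
    """Assemble the static HTML report: ranked tables, plots and an index page.

    Layout: ``index.html`` at the top, ranked tables under ``ranked-sets/``,
    images (PNG and SVG) under ``plots/``, per-set heatmap CSVs under
    ``sets/``.  No network resources are referenced; regeneration from the
    same result is byte-stable for the TSV/CSV outputs.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create report directory {out_dir}: {err}") from err
    (out_dir / "plots").mkdir(exist_ok=True)
    (out_dir / "sets").mkdir(exist_ok=True)
    tables = result.write_tables(out_dir / "ranked-sets")

    plots: list[Path] = []
    set_csvs: list[Path] = []
    sections = []
    sort_by = result.config.sort_by
    for label, ci in result.collections.items():
        items = []
        for contrast in result.contrast_names + ["comparison"]:
            table = result.table(label, contrast)
            top = top_sets(table, sort_by, number)
            stem = out_dir / "plots" / f"{label}-{contrast}-summary"
            plots += render_summary_plot(summary_plot_data(table, sort_by=sort_by),
                                         stem, f"{label} / {contrast}")
            stem = out_dir / "plots" / f"{label}-{contrast}-bars"
            plots += render_bar_plot(bar_plot_data(table, n=min(number, len(table)),
                                                   sort_by=sort_by),
                                     stem, f"{label} / {contrast}")
            if contrast != "comparison":
                ranks = result.ranks(label, contrast)
                if ranks.shape[1] >= 3:
                    plots += render_mds(methods_mds(ranks),
                                        out_dir / "plots" / f"{label}-{contrast}-mds")
            rel_tsv = f"ranked-sets/{label}-{contrast}.tsv"
            links = " | ".join(
                f'<a href="plots/{label}-{contrast}-{kind}.png">{kind}</a>'
                for kind in (("summary", "bars", "mds") if contrast != "comparison"
                             else ("summary", "bars")))
            items.append(
                f"<h3>{html.escape(label)} — {html.escape(contrast)}</h3>"
                f'<p><a href="{rel_tsv}">ranked table (TSV)</a> | {links}</p>'
                + _table_html(top, number))
        # comparison heatmap + a CSV for the top set of the comparison
        per_contrast = {c: result.table(label, c) for c in result.contrast_names}
        if len(per_contrast) >= 1:
            mat = summary_heatmap_data(result.comparison[label], per_contrast,
                                       n=min(number, len(result.comparison[label])),
                                       sort_by=sort_by)
            plots += render_heatmap(mat, out_dir / "plots" / f"{label}-summary-heatmap",
                                    f"{label} comparison")
            top_name = str(mat.index[0]) if len(mat) else None
            if top_name is not None:
                _, _, csv = set_heatmap_data(result.gls, ci, top_name)
                csv_path = out_dir / "sets" / f"{label}-{top_name}-heatmap.csv"
                csv.to_csv(csv_path, index=False)
                set_csvs.append(csv_path)
        sections.append(f"<h2>Collection: {html.escape(label)}</h2>" + "".join(items))

    params = ("<h2>Analysis parameters</h2><pre>"
              + html.escape(result.summary()) + "</pre>")
    index_page = out_dir / "index.html"
    index_page.write_text(_PAGE.format(title=html.escape(title), params=params,
                                       sections="".join(sections)), encoding="utf-8")
    return ReportBundle(out_dir=out_dir, index_page=index_page, tables=tables,
                        plots=plots, set_csvs=set_csvs)


def report_from_tables(tables_dir: str | Path, out_dir: str | Path,
                       number: int = 20, sort_by: str = "p.adj") -> ReportBundle:
    """Rebuild the HTML index and plots from stored ranked tables only.

    Reads every ``<collection>-<contrast>.tsv`` under ``tables_dir`` (the
    collection label is taken up to the first dash) without rerunning any
    statistics; gene-level displays that need the expression data are skipped.
    """
    tables_dir = Path(tables_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "plots").mkdir(exist_ok=True)
    files = sorted(tables_dir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no ranked tables under {tables_dir}")
    plots: list[Path] = []
    sections = []
    for path in files:
        label, _, contrast = path.stem.partition("-")
        table = pd.read_csv(path, sep="\t", index_col=0)
        if "Rank" in table.columns:
            table = table.drop(columns="Rank")
        top = top_sets(table, sort_by, number)
        stem = out_dir / "plots" / f"{path.stem}-summary"
        plots += render_summary_plot(summary_plot_data(table, sort_by=sort_by),
                                     stem, path.stem)
        stem = out_dir / "plots" / f"{path.stem}-bars"
        plots += render_bar_plot(bar_plot_data(table, n=min(number, len(table)),
                                               sort_by=sort_by), stem, path.stem)
        sections.append(
            f"<h3>{html.escape(label)} — {html.escape(contrast)}</h3>"
            f'<p><a href="plots/{path.stem}-summary.png">summary</a> | '
            f'<a href="plots/{path.stem}-bars.png">bars</a></p>'
            + _table_html(top, number))
    index_page = out_dir / "index.html"
    index_page.write_text(
        _PAGE.format(title="Ensemble gene set analysis (regenerated)",
                     params="", sections="".join(sections)),
        encoding="utf-8")
    return ReportBundle(out_dir=out_dir, index_page=index_page,
                        tables=list(files), plots=plots)
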