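"""Screen-level exploration of the per-treatment profiles.

PCA embedding of the ten z-scored morphometric features into three
components, ATC D-level hit-class selection, nearest-neighbour compound
queries in profile space, the edema-vs-renal correlation check, and static
exports: ATC-sorted heat maps, parallel-coordinates data, and a
self-contained HTML report with the 3-D PCA scatter and a searchable
results table.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .morphometry import PARAM_NAMES
from .plate_io import CATEGORIES
from .scoring import (
    GROSS_COLUMNS,
    RATIO_COLUMNS,
    Z_COLUMNS,
    ScreenResultTable,
    gross_col,
    ratio_col,
    z_col,
)

__all__ = [
    "Embedding",
    "HitClass",
    "pca_embed",
    "select_hit_classes",
    "nearest_neighbors",
    "correlate_edema_renal",
    "export_views",
]

#: Line colour scale of the parallel-coordinates plots: magenta at 0%
#: normal kidneys (all abnormal) to green at 100% (all normal).
NORMAL_CMAP = LinearSegmentedColormap.from_list(
    "normal_ratio", ["#FF00FF", "#00CC00"]
)


@dataclass(frozen=True)
class Embedding:
    """A 3-D PCA embedding of the treatment profiles.

    ``coordinates`` has one row per embedded treatment (columns PC1..PC3);
    ``explained_variance`` holds the per-component variance fractions
    (non-increasing, summing to <= 1); ``loadings`` is features × components;
    ``excluded`` lists treatments dropped for missing quantitative data.
    """

    coordinates: pd.DataFrame
    explained_variance: np.ndarray
    loadings: pd.DataFrame
    excluded: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(ev < -1e-12) or np.any(ev > 1 + 1e-12):
            raise ValueError("explained-variance fractions must be in [0, 1]")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")
        if ev.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must sum to <= 1")


def pca_embed(
    z_matrix: pd.DataFrame,
    n_components: int = 3,
    feature_columns: Optional[Sequence[str]] = None,
) -> Embedding:
    """Embed the treatments × features matrix by PCA (SVD of the centred data).

    Rows with any missing feature are excluded and reported.  The matrix is
    column-centred but not re-scaled — the features are already
    variance-standardized by the upstream z-scoring.  Component signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    df = z_matrix.copy()
    if feature_columns is None:
        feature_columns = [c for c in Z_COLUMNS if c in df.columns] or [
            c for c in PARAM_NAMES if c in df.columns
        ]
    if not feature_columns:
        raise ValueError("no feature columns found for the embedding")
    if "treatment" in df.columns:
        index = df["treatment"].astype(str)
    else:
        index = df.index.astype(str)
    X = df[list(feature_columns)].astype(float)
    complete = X.notna().all(axis=1).to_numpy()
    excluded = tuple(index[~complete])
    X = X.loc[complete].to_numpy()
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} complete rows, have {X.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    components = pca.components_  # (n_components, n_features)
    for i in range(n_components):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            coords[:, i] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    coordinates = pd.DataFrame(
        coords, index=pd.Index(index[complete], name="treatment"), columns=comp_names
    )
    loadings = pd.DataFrame(
        components.T, index=list(feature_columns), columns=comp_names
    )
    return Embedding(
        coordinates=coordinates,
        explained_variance=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        excluded=excluded,
    )


@dataclass(frozen=True)
class HitClass:
    """An ATC D-level group passing the hit-selection cut-offs."""

    d_level: str
    members: int
    abnormal: int

    def __post_init__(self) -> None:
        if self.abnormal > self.members:
            raise ValueError("abnormal count exceeds member count")

    @property
    def abnormal_fraction(self) -> float:
        return self.abnormal / self.members


def select_hit_classes(
    table: ScreenResultTable,
    flags: pd.DataFrame,
    min_members: int = 4,
    min_fraction: float = 0.5,
) -> List[HitClass]:
    """Select ATC D-level classes enriched for renal phenotypes.

    Groups compounds (controls and the unassigned ``N/A`` pool excluded) by
    D-level and keeps classes with at least ``min_members`` compounds of
    which at least ``min_fraction`` are flagged abnormal, sorted by abnormal
    fraction then member count, both descending.
    """
    df = table.frame.merge(flags[["treatment", "abnormal"]], on="treatment")
    df = df[~df["is_control"] & (df["atc_d_level"] != "N/A")]
    out = []
    for d_level, grp in df.groupby("atc_d_level"):
        members = len(grp)
        abnormal = int(grp["abnormal"].sum())
        if members >= min_members and abnormal / members >= min_fraction:
            out.append(HitClass(d_level=d_level, members=members, abnormal=abnormal))
    out.sort(key=lambda h: (-h.abnormal_fraction, -h.members, h.d_level))
    return out


def nearest_neighbors(
    data: ScreenResultTable | Embedding | pd.DataFrame,
    query: str,
    k: int = 5,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """The ``k`` treatments nearest to ``query`` in profile space.

    ``data`` may be a result table (z-scored feature space), an
    :class:`Embedding` (PCA space) or a bare treatments × features frame.
    Distances are Euclidean by default (``metric="cosine"`` available); ties
    are broken by treatment ID.  The query itself is excluded.
    """
    if isinstance(data, Embedding):
        frame = data.coordinates.copy()
    elif isinstance(data, ScreenResultTable):
        frame = data.frame.set_index("treatment")[list(Z_COLUMNS)].dropna()
    else:
        frame = data.set_index("treatment") if "treatment" in data.columns else data
        frame = frame.astype(float).dropna()
    if query not in frame.index:
        raise KeyError(f"unknown query treatment {query!r}")
    if not 1 <= k < len(frame):
        raise ValueError(f"k must be in [1, {len(frame) - 1}]")
    X = frame.to_numpy(dtype=float)
    q = frame.loc[query].to_numpy(dtype=float)
    if metric == "euclidean":
        d = np.sqrt(((X - q) ** 2).sum(axis=1))
    elif metric == "cosine":
        qn = np.linalg.norm(q)
        xn = np.linalg.norm(X, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - (X @ q) / (xn * qn)
        d = np.nan_to_num(d, nan=1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    res = pd.DataFrame({"treatment": frame.index.astype(str), "distance": d})
    res = res[res["treatment"] != str(query)]
    res = res.sort_values(["distance", "treatment"], kind="mergesort")
    return res.head(k).reset_index(drop=True)


def correlate_edema_renal(table: ScreenResultTable) -> Tuple[float, int]:
    """Rank correlation between edema and renal abnormality across treatments.

    Edema ratio = mild + severe; renal abnormality = 1 − normal_kidney
    ratio.  Returns (Spearman rho, n); rho is NaN with a warning when either
    measure is constant.
    """
    df = table.frame
    edema = (df[gross_col("edema_mild")] + df[gross_col("edema_severe")]).astype(float)
    renal = 1.0 - df[ratio_col("normal_kidney")].astype(float)
    ok = edema.notna() & renal.notna()
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 treatments with both measures")
    e, r = edema[ok], renal[ok]
    if e.nunique() < 2 or r.nunique() < 2:
        warnings.warn("constant column: edema-renal correlation undefined")
        return float("nan"), n
    rho, _ = stats.spearmanr(e, r)
    return float(rho), n


# ---------------------------------------------------------------------------
# Static exports: heat maps, parallel coordinates, HTML report
# ---------------------------------------------------------------------------


def _heatmap(
    matrix: pd.DataFrame, path: Path, title: str, diverging: bool, clip: float = 3.0
) -> None:
    fig_h = max(2.0, 0.035 * len(matrix) + 1.2)
    fig, ax = plt.subplots(figsize=(6, fig_h))
    data = matrix.to_numpy(dtype=float)
    if diverging:
        im = ax.imshow(
            np.clip(data, -clip, clip), aspect="auto", cmap="RdBu_r",
            vmin=-clip, vmax=clip, interpolation="nearest",
        )
    else:
        im = ax.imshow(
            data, aspect="auto", cmap="viridis", vmin=0, vmax=1,
            interpolation="nearest",
        )
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _fig_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg")
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg") :]


def _parallel_coords_figure(df: pd.DataFrame, columns: Sequence[str], title: str):
    fig, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(len(columns))
    Y = df[list(columns)].to_numpy(dtype=float)
    shades = df["normal_ratio"].to_numpy(dtype=float) if "normal_ratio" in df else None
    for i in range(Y.shape[0]):
        color = NORMAL_CMAP(shades[i] if shades is not None else 0.5)
        ax.plot(x, Y[i], color=color, alpha=0.35, lw=0.7)
    ax.set_xticks(x)
    ax.set_xticklabels(columns, rotation=90, fontsize=7)
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    return fig


def _pca_scatter_figure(embedding: Embedding, normal_ratio: pd.Series):
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    coords = embedding.coordinates
    colors = [
        NORMAL_CMAP(normal_ratio.get(t, 0.5)) for t in coords.index
    ]
    ax.scatter(coords["PC1"], coords["PC2"], coords["PC3"], c=colors, s=10)
    ev = embedding.explained_variance * 100
    ax.set_xlabel(f"PC1 ({ev[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.0f}%)")
    ax.set_zlabel(f"PC3 ({ev[2]:.0f}%)")
    ax.set_title("PCA of z-scored morphometric profiles", fontsize=10)
    return fig


_REPORT_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Pronephros screen report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; font-size: 11px; }}
th, td {{ border: 1px solid #ccc; padding: 2px 6px; }}
input {{ margin: 1em 0; padding: 4px; width: 30em; }}
.fig {{ margin: 1em 0; }}
</style></head><body>
<h1>Pronephros screen report</h1>
<p>{n_treatments} treatments; first three principal components explain
{ev_pct:.1f}% of the profile variance.</p>
<div class="fig">{pca_svg}</div>
<div class="fig">{pc_quant_svg}</div>
<div class="fig">{pc_qual_svg}</div>
<h2>Results table</h2>
<input id="q" placeholder="filter rows (treatment, compound, ATC class)"
 onkeyup="f()"><br>
{table_html}
<script>
function f() {{
  var q = document.getElementById('q').value.toLowerCase();
  var rows = document.querySelectorAll('#results tbody tr');
  rows.forEach(function(r) {{
    r.style.display = r.textContent.toLowerCase().includes(q) ? '' : 'none';
  }});
}}
</script>
</body></html>
"""


def export_views(
    table: ScreenResultTable,
    embedding: Embedding,
    outdir,
    sort: str = "atc",
) -> Dict[str, Path]:
    """Write the static exploration bundle; returns the paths written.

    * ``heatmap_zscores.png`` — quantitative z-scores, symmetric diverging
      scale clipped at |z| = 3 for display (data unclipped in the CSVs);
    * ``heatmap_categories.png`` — qualitative ratios on a 0–1 scale;
      both sorted by ATC D-level so class members are contiguous;
    * ``parallel_coordinates.csv`` / ``.json`` — one line record per
      treatment with quantitative data, with the normal-kidney ratio that
      colours the lines (magenta 0% → green 100%);
    * ``embedding.csv`` — PCA coordinates and explained variance;
    * ``report.html`` — self-contained report: 3-D PCA scatter, parallel
      coordinates, searchable results table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = table.sorted_by_atc() if sort == "atc" else table.frame.copy()
    paths: Dict[str, Path] = {}

    zmat = df.set_index("treatment")[list(Z_COLUMNS)]
    paths["heatmap_zscores"] = outdir / "heatmap_zscores.png"
    _heatmap(zmat, paths["heatmap_zscores"],
             "z-scored fold changes (ATC-sorted)", diverging=True)
    qmat = df.set_index("treatment")[list(RATIO_COLUMNS)]
    paths["heatmap_categories"] = outdir / "heatmap_categories.png"
    _heatmap(qmat, paths["heatmap_categories"],
             "qualitative category ratios (ATC-sorted)", diverging=False)

    pc = df[~df["quantitative_missing"]].copy()
    pc["normal_ratio"] = pc[ratio_col("normal_kidney")].fillna(0.5)
    pc_cols = ["treatment", "compound_name", "atc_d_level", "normal_ratio"] + list(
        Z_COLUMNS
    ) + [c for c in RATIO_COLUMNS]
    paths["parallel_coordinates_csv"] = outdir / "parallel_coordinates.csv"
    pc[pc_cols].to_csv(paths["parallel_coordinates_csv"], index=False)
    paths["parallel_coordinates_json"] = outdir / "parallel_coordinates.json"
    paths["parallel_coordinates_json"].write_text(
        json.dumps(pc[pc_cols].to_dict(orient="records"), indent=1, default=float)
    )

    emb = embedding.coordinates.reset_index()
    paths["embedding_csv"] = outdir / "embedding.csv"
    emb.to_csv(paths["embedding_csv"], index=False)
    (outdir / "embedding_variance.json").write_text(
        json.dumps(
            {
                "explained_variance_fraction": [
                    float(v) for v in embedding.explained_variance
                ],
                "excluded_treatments": list(embedding.excluded),
            },
            indent=1,
        )
    )

    normal_ratio = df.set_index("treatment")[ratio_col("normal_kidney")].fillna(0.5)
    pca_svg = _fig_svg(_pca_scatter_figure(embedding, normal_ratio))
    quant_fig = _parallel_coords_figure(
        pc, list(Z_COLUMNS), "Quantitative profiles (z-scores)"
    )
    qual_fig = _parallel_coords_figure(
        pc, [c for c in RATIO_COLUMNS], "Qualitative category ratios"
    )
    table_cols = [
        "treatment", "compound_id", "compound_name", "atc_d_level", "day",
        "n_embryos", ratio_col("normal_kidney"),
    ] + list(Z_COLUMNS)
    table_html = df[table_cols].round(3).to_html(
        index=False, table_id="results", na_rep=""
    )
    html = _REPORT_TEMPLATE.format(
        n_treatments=len(df),
        ev_pct=100.0 * float(np.sum(embedding.explained_variance)),
        pca_svg=pca_svg,
        pc_quant_svg=_fig_svg(quant_fig),
        pc_qual_svg=_fig_svg(qual_fig),
        table_html=table_html,
    )
    paths["report_html"] = outdir / "report.html"
    paths["report_html"].write_text(html)
    return paths
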