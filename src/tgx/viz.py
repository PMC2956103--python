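"""Presentation of gene-set scores: radar chart, heat map, supervised network.

Radar charts plot absolute score values against a constant reference circle
(default 20), so a toxicologist can see at a glance which endpoints exceed
the "clearly perturbed" level.  Heat maps and supervised networks keep the
sign: red for up-regulation, blue for down-regulation, white for no change,
with symmetric limits at the global |score| maximum so colors are comparable
across gene sets.

All renderers are deterministic: fixed styling, no timestamps, fixed SVG
hash salt — identical inputs yield byte-identical files.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colors as mcolors
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .io import ScoreTable

log = logging.getLogger(__name__)

_SVG_OPTS = {"metadata": {"Date": None, "Creator": None}}


def _deterministic_style() -> None:
    plt.rcParams["svg.hashsalt"] = "tgx"
    plt.rcParams["svg.fonttype"] = "none"


@dataclass
class SupervisedNetworkSpec:
    """A curated pathway-relationship graph onto which scores are painted.

    The topology is an input (expert knowledge), never inferred from data.
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    edge_labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for a, b in self.edges:
            if a not in known or b not in known:
                raise ValidationError(f"edge ({a!r}, {b!r}) references an unknown node")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SupervisedNetworkSpec":
        """Load from a 2/3-column TSV: source, target, optional label."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: network spec needs >=2 columns (source, target)")
        edges = list(zip(df[0], df[1]))
        labels = {}
        if df.shape[1] >= 3:
            labels = {(a, b): l for a, b, l in zip(df[0], df[1], df[2]) if isinstance(l, str)}
        nodes = list(dict.fromkeys([n for e in edges for n in e]))
        return cls(nodes=nodes, edges=edges, edge_labels=labels)


def _score_column(scores: ScoreTable, condition: str) -> pd.Series:
    if condition not in scores.scores.columns:
        raise ValidationError(f"condition {condition!r} not in score table")
    return scores.scores[condition]


def radar_chart(scores: ScoreTable, condition: str, out_path: str | Path,
                reference_level: float = 20.0) -> Path:
    """Radar chart of |score| per gene set with a constant reference circle.

    One axis per gene set in collection order; SVG or PNG chosen by the
    output extension.
    """
    col = _score_column(scores, condition)
    if len(col) < 3:
        raise ValidationError(f"radar chart needs >=3 gene sets, got {len(col)}")
    _deterministic_style()
    values = col.abs().to_numpy()
    n = len(values)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    closed = np.concatenate([values, values[:1]])
    angles_closed = np.concatenate([angles, angles[:1]])

    fig, ax = plt.subplots(figsize=(8, 8), subplot_kw={"polar": True})
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    ax.plot(angles_closed, closed, color="red", linewidth=1.5)
    ax.fill(angles_closed, closed, color="red", alpha=0.15)
    ref = np.full(angles_closed.shape, reference_level)
    ax.plot(angles_closed, ref, color="blue", linewidth=1.0)
    ax.set_xticks(angles)
    ax.set_xticklabels(col.index, fontsize=6)
    upper = max(float(values.max()), reference_level) * 1.1
    ax.set_ylim(0, upper if upper > 0 else 1.0)
    ax.set_title(str(condition))
    out_path = Path(out_path)
    kwargs = _SVG_OPTS if out_path.suffix == ".svg" else {}
    fig.savefig(out_path, **kwargs)
    plt.close(fig)
    return out_path


def heat_map(scores: ScoreTable, out_path: str | Path,
             ordering: str = "input") -> Path:
    """Gene set x condition heat map on a diverging red/white/blue scale.

    Color limits are symmetric at the global |score| maximum, centered on
    zero.  ``ordering='cluster'`` reorders rows by average-linkage
    hierarchical clustering of Euclidean distances.
    """
    if scores.scores.empty:
        raise ValidationError("cannot draw a heat map of an empty score table")
    if ordering not in ("input", "cluster"):
        raise ValidationError(f"unknown ordering {ordering!r}")
    _deterministic_style()
    mat = scores.scores
    if ordering == "cluster" and mat.shape[0] > 2:
        order = leaves_list(average(pdist(mat.to_numpy(), metric="euclidean")))
        mat = mat.iloc[order]
    vmax = float(np.abs(mat.to_numpy()).max())
    if vmax == 0:
        vmax = 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * mat.shape[1] + 3), max(4, 0.14 * mat.shape[0] + 2))
    )
    im = ax.imshow(mat.to_numpy(), cmap="bwr", aspect="auto",
                   norm=mcolors.Normalize(vmin=-vmax, vmax=vmax))
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]))
    ax.set_yticklabels(mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"{scores.method} score")
    fig.tight_layout()
    out_path = Path(out_path)
    kwargs = _SVG_OPTS if out_path.suffix == ".svg" else {}
    fig.savefig(out_path, **kwargs)
    plt.close(fig)
    return out_path


def score_to_color(score: float, vmax: float) -> str:
    """Hex fill color for a signed score on the shared red/white/blue scale."""
    if vmax <= 0 or score == 0:
        return "#ffffff"
    cmap = plt.get_cmap("bwr")
    frac = 0.5 + 0.5 * max(-1.0, min(1.0, score / vmax))
    return mcolors.to_hex(cmap(frac))


def render_supervised_network(spec: SupervisedNetworkSpec, scores: ScoreTable,
                              condition: str, out_prefix: str | Path,
                              comments: list[str] | None = None) -> Path:
    """Paint one condition's scores onto a curated network; emit DOT (+image).

    Nodes absent from the score table get a neutral fill and a warning.  The
    image is rendered only when a Graphviz layout engine is on PATH;
    otherwise the DOT file alone is produced (logged).
    """
    col = _score_column(scores, condition)
    vmax = float(col.abs().max())
    lines = [f"// {c}" for c in comments or []]
    lines.append("graph supervised {")
    lines.append("  node [style=filled, shape=box, fontsize=10];")
    for node in spec.nodes:
        if node in col.index:
            color = score_to_color(float(col[node]), vmax)
        else:
            log.warning("supervised-network node %r has no score; neutral fill", node)
            color = "#ffffff"
        lines.append(f'  "{node}" [fillcolor="{color}"];')
    for a, b in spec.edges:
        label = spec.edge_labels.get((a, b), "")
        attr = f' [label="{label}"]' if label else ""
        lines.append(f'  "{a}" -- "{b}"{attr};')
    lines.append("}")
    out_prefix = Path(out_prefix)
    dot_path = out_prefix.with_suffix(".dot")
    dot_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    engine = shutil.which("dot")
    if engine:
        png_path = out_prefix.with_suffix(".png")
        subprocess.run([engine, "-Tpng", str(dot_path), "-o", str(png_path)], check=True)
    else:
        log.info("no Graphviz layout engine on PATH; DOT file only")
    return dot_path
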