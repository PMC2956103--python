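"""Gaussian-graphical-model partial-correlation networks over gene-set scores.

Conditions are observations; features are gene-set scores plus (optionally)
phenotype changing levels.  Because the feature count (~64) approaches the
condition count (~150), the sample correlation matrix is shrunk toward the
identity before inversion:

    S* = (1 - lambda) S + lambda I,   Omega = (S*)^-1,
    rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)

with the analytic Schafer–Strimmer estimate of lambda ("auto"): the ratio of
the summed estimated variances of the off-diagonal correlations to their
summed squares, clipped to [0, 1].  An edge between two features means they
remain correlated after conditioning on every other feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .io import PhenotypeTable, ScoreTable

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Condition x feature matrix, standardized, with per-feature kinds."""

    data: pd.DataFrame               # conditions x features, no missing values
    kinds: pd.Series                 # feature name -> 'gene_set' | 'phenotype'
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.isna().to_numpy().any():
            raise ValidationError("feature matrix contains missing values")
        if not self.data.columns.equals(self.kinds.index):
            raise ValidationError("kinds index must match feature columns")
        if self.standardized:
            mu = self.data.mean().to_numpy()
            var = self.data.var(ddof=1).to_numpy()
            if not (np.all(np.abs(mu) < 1e-10) and np.all(np.abs(var - 1) < 1e-10)):
                raise ValidationError("standardized matrix fails mean-0/variance-1 check")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]


@dataclass
class PartialCorrelationNetwork:
    """Symmetric partial-correlation matrix over named, typed nodes."""

    pcor: pd.DataFrame               # features x features, diag 1
    kinds: pd.Series
    shrinkage: float
    n_observations: int
    edges: pd.DataFrame | None = field(default=None)   # selected edge list

    def __post_init__(self) -> None:
        m = self.pcor.to_numpy()
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("partial-correlation matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValidationError("partial-correlation diagonal must be 1")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValidationError("partial correlations must lie in [-1, 1]")

    def node_names(self) -> list[str]:
        return list(self.pcor.index)


def assemble_features(scores: ScoreTable,
                      phenotypes: PhenotypeTable | None = None) -> FeatureMatrix:
    """Join score and phenotype blocks on conditions and standardize columns.

    Conditions are intersected between blocks; rows with any missing phenotype
    are dropped listwise (count logged); zero-variance columns are dropped
    with a warning since they carry no correlation information.
    """
    score_block = scores.scores.T  # conditions x sets
    blocks = [score_block]
    kinds = {name: "gene_set" for name in score_block.columns}
    if phenotypes is not None:
        pheno = phenotypes.table
        overlap = set(score_block.columns) & set(pheno.columns)
        if overlap:
            raise ValidationError(
                f"duplicate feature name(s) across score/phenotype blocks: {sorted(overlap)}"
            )
        shared = score_block.index.intersection(pheno.index)
        score_block = score_block.loc[shared]
        pheno = pheno.loc[shared]
        n_drop = int(pheno.isna().any(axis=1).sum())
        if n_drop:
            log.info("dropping %d condition(s) with missing phenotype values", n_drop)
        keep = ~pheno.isna().any(axis=1)
        blocks = [score_block.loc[keep], pheno.loc[keep]]
        kinds.update({name: "phenotype" for name in pheno.columns})
    data = pd.concat(blocks, axis=1)
    if data.shape[0] < 3:
        raise ValidationError(
            f"only {data.shape[0]} usable condition(s); need at least 3"
        )
    variances = data.var(ddof=1)
    constant = variances.index[variances.to_numpy() <= 0]
    if len(constant):
        log.warning("dropping zero-variance feature(s): %s", list(constant))
        data = data.drop(columns=constant)
        for name in constant:
            kinds.pop(name)
    data = (data - data.mean()) / data.std(ddof=1)
    kinds_series = pd.Series({c: kinds[c] for c in data.columns}, name="kind")
    kinds_series.index.name = "feature"
    return FeatureMatrix(data=data, kinds=kinds_series, standardized=True)


def shrinkage_intensity(data: pd.DataFrame | np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    lambda* = sum_{i<j} Var(r_ij) / sum_{i<j} r_ij^2, with Var(r_ij)
    estimated from the empirical variance of the products of standardized
    observations, clipped to [0, 1].
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n < 3:
        return 1.0
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = (xs.T @ xs) / (n - 1)
    iu = np.triu_indices(p, k=1)
    r_off = r[iu]
    denom = float(np.sum(r_off ** 2))
    if denom == 0:
        return 1.0
    # var of each r_ij via the empirical variance of w_k = x_ki * x_kj
    var_sum = 0.0
    factor = n / ((n - 1) ** 3)
    for i, j in zip(*iu):
        w = xs[:, i] * xs[:, j]
        var_sum += factor * float(np.sum((w - w.mean()) ** 2))
    lam = var_sum / denom
    return float(min(1.0, max(0.0, lam)))


def _pcor_from_correlation(corr: np.ndarray) -> np.ndarray:
    omega = np.linalg.inv(corr)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def estimate_pcor(features: FeatureMatrix,
                  shrinkage: float | str = "auto") -> PartialCorrelationNetwork:
    """Shrinkage-regularized partial correlations among all features."""
    if not features.standardized:
        raise ValidationError("estimate_pcor requires a standardized FeatureMatrix")
    x = features.data.to_numpy()
    n, p = x.shape
    if isinstance(shrinkage, str):
        if shrinkage != "auto":
            raise ValidationError(f"shrinkage must be a number in [0,1] or 'auto', got {shrinkage!r}")
        lam = shrinkage_intensity(x)
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValidationError(f"shrinkage must lie in [0, 1], got {lam}")
    corr = (x.T @ x) / (n - 1)
    np.fill_diagonal(corr, 1.0)
    shrunk = (1.0 - lam) * corr + lam * np.eye(p)
    cond = np.linalg.cond(shrunk)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            f"shrunken correlation matrix is numerically singular "
            f"(n={n}, p={p}, lambda={lam}); increase the shrinkage intensity"
        )
    rho = _pcor_from_correlation(shrunk)
    pcor = pd.DataFrame(rho, index=features.data.columns, columns=features.data.columns)
    return PartialCorrelationNetwork(pcor=pcor, kinds=features.kinds.copy(),
                                     shrinkage=lam, n_observations=n)


def _edge_frame(pcor: pd.DataFrame) -> pd.DataFrame:
    names = list(pcor.index)
    iu = np.triu_indices(len(names), k=1)
    rho = pcor.to_numpy()[iu]
    df = pd.DataFrame({
        "source": [names[i] for i in iu[0]],
        "target": [names[j] for j in iu[1]],
        "pcor": rho,
    })
    return df


def select_edges(network: PartialCorrelationNetwork,
                 rule: str = "abs_threshold",
                 threshold: float = 0.1,
                 k: int | None = None,
                 q: float = 0.05,
                 features: FeatureMatrix | None = None,
                 n_permutations: int = 200,
                 seed: int = 0) -> pd.DataFrame:
    """Select network edges by one of three rules.

    ``abs_threshold`` keeps |rho| >= threshold; ``top_k`` keeps the k largest
    |rho|; ``perm_fdr`` permutes each feature column independently
    ``n_permutations`` times, pools the permuted off-diagonal |rho| values as
    the null, and keeps edges whose plug-in empirical FDR is <= q (seeded,
    hence bit-reproducible).  Edges are returned sorted by |rho| descending,
    ties broken by node names for determinism.
    """
    all_edges = _edge_frame(network.pcor)
    all_edges["abs"] = all_edges["pcor"].abs()
    all_edges = all_edges.sort_values(
        ["abs", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)

    if rule == "abs_threshold":
        sel = all_edges[all_edges["abs"] >= threshold]
    elif rule == "top_k":
        p = network.pcor.shape[0]
        n_pairs = p * (p - 1) // 2
        if k is None or k < 0 or k > n_pairs:
            raise ValidationError(f"top_k requires 0 <= k <= {n_pairs}, got {k}")
        sel = all_edges.head(k)
    elif rule == "perm_fdr":
        if features is None:
            raise ValidationError("perm_fdr requires the FeatureMatrix used for estimation")
        rng = np.random.default_rng(seed)
        x = features.data.to_numpy()
        n, p = x.shape
        lam = network.shrinkage
        null_vals = []
        for _ in range(n_permutations):
            xp = np.column_stack([rng.permutation(x[:, j]) for j in range(p)])
            xp = (xp - xp.mean(axis=0)) / xp.std(axis=0, ddof=1)
            corr = (xp.T @ xp) / (n - 1)
            np.fill_diagonal(corr, 1.0)
            shrunk = (1.0 - lam) * corr + lam * np.eye(p)
            rho = _pcor_from_correlation(shrunk)
            null_vals.append(np.abs(rho[np.triu_indices(p, k=1)]))
        null = np.concatenate(null_vals)
        obs = all_edges["abs"].to_numpy()
        # plug-in FDR at each observed |rho|: (#null >= t / B) / (#obs >= t)
        n_obs_ge = np.arange(1, obs.size + 1)  # obs sorted descending
        sorted_null = np.sort(null)
        n_null_ge = null.size - np.searchsorted(sorted_null, obs, side="left")
        fdr = (n_null_ge / n_permutations) / n_obs_ge
        # enforce monotone (step-up) FDR
        fdr = np.minimum.accumulate(fdr[::-1])[::-1]
        sel = all_edges[fdr <= q]
    else:
        raise ValidationError(f"unknown edge-selection rule {rule!r}")
    return sel.drop(columns="abs").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

#: Edge colors by sign of the partial correlation (positive purple, negative
#: green, matching the convention of shrinkage-GGM toxicogenomics networks).
EDGE_COLORS = {1: "purple", -1: "green"}


def _to_graph(network: PartialCorrelationNetwork, edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for name in network.node_names():
        g.add_node(name, kind=str(network.kinds[name]))
    for row in edges.itertuples(index=False):
        sign = 1 if row.pcor >= 0 else -1
        g.add_edge(row.source, row.target, weight=float(row.pcor), sign=sign)
    return g


def export_network(network: PartialCorrelationNetwork, edges: pd.DataFrame,
                   path: str | Path, fmt: str = "graphml",
                   comments: list[str] | None = None) -> None:
    """Write the selected network as GraphML, DOT or a TSV edge list.

    GraphML carries node ``kind`` and edge ``weight``/``sign`` attributes and
    loads in Cytoscape; DOT encodes sign as edge color and |rho| as penwidth.
    """
    path = Path(path)
    if fmt == "graphml":
        g = _to_graph(network, edges)
        if comments:
            g.graph["provenance"] = "; ".join(comments)
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "dot":
        lines = [f"// {c}" for c in comments or []]
        lines.append("graph pcor_network {")
        lines.append('  node [style=filled, fillcolor=white];')
        for name in network.node_names():
            shape = "box" if network.kinds[name] == "phenotype" else "ellipse"
            lines.append(f'  "{name}" [shape={shape}];')
        for row in edges.itertuples(index=False):
            color = EDGE_COLORS[1 if row.pcor >= 0 else -1]
            width = 0.5 + 4.5 * min(abs(row.pcor), 1.0)
            lines.append(
                f'  "{row.source}" -- "{row.target}" '
                f'[color={color}, penwidth={width:.3f}, label="{row.pcor:.3f}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for c in comments or []:
                fh.write(f"# {c}\n")
            edges.to_csv(fh, sep="\t", index=False, float_format="%.17g",
                         lineterminator="\n")
    else:
        raise FormatError(f"unknown export format {fmt!r}; expected graphml, dot or tsv")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read back a TSV edge list written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"source": str, "target": str})
    required = {"source", "target", "pcor"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: edge list must have columns {sorted(required)}")
    return df
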