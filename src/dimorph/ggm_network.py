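"""Gaussian graphical model of the metabolite panel.

Edges are full-order partial correlations: the correlation between two
metabolites' log concentrations after adjusting for every other metabolite
in the panel plus the covariates (age, sex, BMI).  Covariate adjustment is
done by residualizing each column first; the partial correlations then come
from the inverse of the residual correlation matrix,

    r_ij = -P_ij / sqrt(P_ii * P_jj),   P = C^{-1}.

Retaining edges with |r| at or above a cutoff yields a sparse network whose
connected components of size >= 2 ("non-singleton groups") behave as
independently regulated sub-phenotypes of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

_COND_LIMIT = 1e10


def residualize(X: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Residuals of each column of X after OLS on the covariates (plus an
    intercept).  With no covariates, columns are just centered."""
    Xv = X.to_numpy(float)
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(Xv - Xv.mean(axis=0), index=X.index, columns=X.columns)
    C = np.column_stack(
        [np.ones(len(X)), covariates.reindex(X.index).to_numpy(float)]
    )
    if np.isnan(C).any():
        raise ValueError("covariates contain missing values")
    beta, *_ = np.linalg.lstsq(C, Xv, rcond=None)
    return pd.DataFrame(Xv - C @ beta, index=X.index, columns=X.columns)


def partial_correlation_matrix(
    X: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    ridge: float | None = None,
) -> pd.DataFrame:
    """Full-order partial correlations between all columns of X, adjusted
    for the covariates.

    Requires a complete matrix with more samples than columns + covariates.
    A (near-)singular residual correlation matrix raises; passing a small
    ``ridge`` adds ridge*I before inversion as a documented fallback for
    small-n use.
    """
    if X.isna().any().any():
        raise ValueError("X must be complete (impute first)")
    n, p = X.shape
    ncov = 0 if covariates is None else covariates.shape[1]
    if n <= p + ncov:
        raise ValueError(
            f"need n > n_metabolites + n_covariates ({n} <= {p} + {ncov})"
        )
    resid = residualize(X, covariates)
    corr = np.corrcoef(resid.to_numpy(float), rowvar=False)
    if ridge is not None:
        corr = corr + ridge * np.eye(p)
    if np.linalg.cond(corr) > _COND_LIMIT:
        raise ValueError(
            "residual correlation matrix is singular or near-singular; "
            "drop collinear metabolites or pass a small ridge"
        )
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2.0
    return pd.DataFrame(pcor, index=X.columns, columns=X.columns)


@dataclass
class GGM:
    """Partial-correlation network: nodes are metabolites, edges carry the
    partial correlation r, and edges exist iff |r| >= cutoff."""

    graph: nx.Graph
    cutoff: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def groups(self) -> list[set]:
        """Connected components over the retained edges (all sizes)."""
        return [set(c) for c in nx.connected_components(self.graph)]


def build_ggm(
    pcor: pd.DataFrame, cutoff: float, classes: pd.Series | None = None
) -> GGM:
    """Threshold the partial-correlation matrix into a network.

    Every metabolite becomes a node (isolated nodes are kept); an edge is
    present iff the absolute partial correlation is at or above the cutoff.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    graph = nx.Graph(cutoff=float(cutoff))
    for node in pcor.columns:
        attrs = {}
        if classes is not None and node in classes.index:
            attrs["compound_class"] = str(classes[node])
        graph.add_node(node, **attrs)
    cols = list(pcor.columns)
    vals = pcor.to_numpy(float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = vals[i, j]
            if abs(r) >= cutoff and r != 0.0:
                graph.add_edge(cols[i], cols[j], r=float(r))
    return GGM(graph=graph, cutoff=float(cutoff))


def nonsingleton_groups(ggm: GGM) -> tuple[int, list[set]]:
    """Connected components of size >= 2; singleton metabolites (no retained
    partial correlation) are not counted."""
    groups = [g for g in ggm.groups() if len(g) >= 2]
    return len(groups), groups


def cutoff_sweep(pcor: pd.DataFrame, cutoffs) -> pd.DataFrame:
    """Edge and non-singleton-group counts as a function of the |r| cutoff.

    ``edge_pct`` is the retained fraction of the p*(p-1)/2 unique pairs, in
    percent.  Edge counts are monotone non-increasing in the cutoff.
    """
    p = pcor.shape[0]
    n_pairs = p * (p - 1) // 2
    rows = []
    for c in cutoffs:
        ggm = build_ggm(pcor, c)
        n_groups, _ = nonsingleton_groups(ggm)
        rows.append(
            {
                "cutoff": float(c),
                "n_edges": ggm.n_edges,
                "edge_pct": 100.0 * ggm.n_edges / n_pairs if n_pairs else 0.0,
                "n_nonsingleton_groups": n_groups,
            }
        )
    return pd.DataFrame(rows)


def annotate_ggm(
    ggm: GGM,
    effects: pd.DataFrame | None,
    significance: float = 0.05 / 131,
) -> GGM:
    """Attach sex-effect annotations to the nodes.

    ``effects`` is indexed by metabolite with columns ``beta_sex`` and ``p``
    (e.g. from :func:`dimorph.sex_effects.sex_effect_table`).  Nodes missing
    from it get a neutral annotation (beta 0, p 1).  Nodes significant at
    ``significance`` carry ``significant=True`` and a star in ``label``.
    """
    for node in ggm.graph.nodes:
        if effects is not None and node in effects.index:
            beta = float(effects.loc[node, "beta_sex"])
            p = float(effects.loc[node, "p"])
        else:
            beta, p = 0.0, 1.0
        sig = p < significance
        ggm.graph.nodes[node].update(
            beta_sex=beta, p=p, significant=bool(sig),
            label=f"{node}*" if sig else str(node),
        )
    return ggm


def annotate_and_export(
    ggm: GGM,
    effects: pd.DataFrame | None,
    path,
    format: str = "graphml",
    significance: float = 0.05 / 131,
) -> Path:
    """Annotate nodes with sex-effect betas/p-values and write the network.

    Formats: ``graphml`` (default) or ``gml``.  The written file round-trips
    through :func:`read_ggm`.
    """
    annotate_ggm(ggm, effects, significance)
    path = Path(path)
    g = ggm.graph.copy()
    g.graph["cutoff"] = ggm.cutoff
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "gml":
        for _, attrs in g.nodes(data=True):  # GML has no boolean type
            attrs["significant"] = int(attrs.get("significant", False))
        nx.write_gml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'gml'")
    return path


def read_ggm(path, format: str = "graphml") -> GGM:
    """Re-read a network written by :func:`annotate_and_export`."""
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gml":
        g = nx.read_gml(path)
        for _, attrs in g.nodes(data=True):
            if "significant" in attrs:
                attrs["significant"] = bool(attrs["significant"])
    else:
        raise ValueError(f"unknown format {format!r}")
    cutoff = float(g.graph.get("cutoff", 0.0))
    return GGM(graph=g, cutoff=cutoff)
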