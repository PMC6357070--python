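"""Metabolome marker stage: PCA, OPLS-DA fitting, Q2 cross-validation,
VIP-based marker selection, and metabolic pathway analysis.

The discriminant tier of markers is every metabolite with VIP >= the cutoff
(default 1.0); the significant tier additionally requires a Welch t-test
below the p threshold (default 0.05). Pathway analysis combines
hypergeometric over-representation with a topological impact score — the
sum of relative betweenness centralities of hit metabolites in the
pathway's graph, in [0, 1] — in the style of topology-aware metabolite set
enrichment tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as sps
import networkx as nx
from sklearn.decomposition import PCA

from .datatypes import MarkerSet, MetaboliteTable, PathwayLibrary, ValidationError
from .enrich import overrepresentation
from .opls import OPLSDA, vip as _vip


def _xy(table: MetaboliteTable) -> tuple[np.ndarray, np.ndarray]:
    """Samples x metabolites matrix and -1/+1 class vector."""
    return table.values.to_numpy().T, table.y_pm1()


def pca(
    table: MetaboliteTable, n_components: int = 2, scale: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered (and autoscaled) PCA of the sample x metabolite matrix.

    Returns (scores, loadings, explained variance ratios); scores are
    samples x components, loadings metabolites x components.
    """
    X, _ = _xy(table)
    cap = min(X.shape[0] - 1, X.shape[1])
    if n_components > cap:
        raise ValidationError(f"n_components {n_components} exceeds rank bound {cap}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = table.values.index[np.argmax(sd == 0)]
            raise ValidationError(f"constant metabolite {bad!r} cannot be autoscaled")
        Xc = Xc / sd
    model = PCA(n_components=n_components, svd_solver="full").fit(Xc)
    scores = model.transform(Xc)
    return scores, model.components_.T, model.explained_variance_ratio_


def fit_opls_da(table: MetaboliteTable, n_orth: int = 1) -> OPLSDA:
    """Fit OPLS-DA on the autoscaled table with a -1/+1 class response."""
    X, y = _xy(table)
    return OPLSDA(n_orth=n_orth, scale=True).fit(X, y)


def q2_crossval(
    table: MetaboliteTable, n_orth: int = 1, folds: int = 7, seed: int = 0
) -> float:
    """Stratified k-fold Q2 = 1 - PRESS/TSS of the -1/+1 response.

    Each fold refits the full model (scaling, orthogonal filtering,
    predictive component) on the retained samples and predicts the held-out
    response. Folds are stratified by group so no fold loses a whole class.
    """
    X, y = _xy(table)
    n = y.size
    if folds < 2 or folds > n:
        raise ValidationError("folds must be in [2, n_samples]")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in (-1.0, 1.0):
        idx = np.flatnonzero(y == cls)
        if idx.size < folds and idx.size < 2:
            raise ValidationError("a class is too small to stratify")
        perm = rng.permutation(idx)
        fold_of[perm] = np.arange(perm.size) % folds
    press = 0.0
    for f in range(folds):
        test = fold_of == f
        if not test.any():
            continue
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValidationError(f"fold {f} leaves a single class in training")
        model = OPLSDA(n_orth=n_orth, scale=True).fit(X[train], y[train])
        press += float(np.sum((y[test] - model.predict(X[test])) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def vip_scores(model: OPLSDA, table: MetaboliteTable) -> pd.Series:
    """VIP per metabolite, indexed by metabolite name."""
    return pd.Series(_vip(model), index=table.values.index, name="vip")


def select_markers(
    model: OPLSDA,
    table: MetaboliteTable,
    vip_cut: float = 1.0,
    p_cut: float = 0.05,
) -> tuple[MarkerSet, pd.DataFrame]:
    """Two-tier metabolite marker selection.

    Discriminant tier: VIP >= vip_cut. Significant tier: discriminant AND
    Welch two-sample t-test p < p_cut on the concentrations. Direction of
    change (treatment vs reference group) is recorded from group means.

    Returns the MarkerSet (one entry per discriminant metabolite, tier set
    accordingly) and the per-metabolite detail frame
    ``metabolite, vip, p, direction, tier``.
    """
    vips = vip_scores(model, table)
    g1, g2 = table.group_labels
    v1 = table.values.loc[:, table.groups[table.groups == g1].index].to_numpy()
    v2 = table.values.loc[:, table.groups[table.groups == g2].index].to_numpy()
    p = sps.ttest_ind(v2, v1, axis=1, equal_var=False).pvalue
    direction = np.where(v2.mean(axis=1) >= v1.mean(axis=1), "up", "down")
    tier = np.where(
        vips.to_numpy() >= vip_cut,
        np.where(p < p_cut, "significant", "discriminant"),
        "none",
    )
    detail = pd.DataFrame(
        {
            "metabolite": table.values.index,
            "vip": vips.to_numpy(),
            "p": p,
            "direction": direction,
            "tier": tier,
        }
    )
    markers = MarkerSet()
    for _, row in detail[detail["tier"] != "none"].iterrows():
        markers.add(str(row["metabolite"]), "metabolome", str(row["direction"]), str(row["tier"]))
    return markers, detail


def pathway_impact(hits: set[str], graph: nx.Graph) -> float:
    """Sum of relative betweenness centralities of hit nodes in a pathway graph.

    Betweenness is normalized so the node values sum to at most 1 over the
    graph (each node's centrality divided by the total); an empty or
    centrality-free graph gives impact 0.
    """
    if graph.number_of_nodes() == 0:
        return 0.0
    bc = nx.betweenness_centrality(graph, normalized=True)
    total = sum(bc.values())
    if total == 0:
        return 0.0
    return float(sum(bc[n] for n in hits if n in bc) / total)


def pathway_analysis(
    markers: MarkerSet,
    library: PathwayLibrary,
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation + topological impact per pathway.

    Returns columns ``pathway, hits, size, p, q, impact`` sorted by p.
    Impact is 0 for pathways without a supplied graph.
    """
    hit_ids = markers.ids() & universe if len(markers) else set()
    df = overrepresentation(hit_ids, library, universe)
    impacts = []
    for name in df["pathway"]:
        g = library.graphs.get(name)
        impacts.append(pathway_impact(hit_ids, g) if g is not None else 0.0)
    df["impact"] = impacts
    return df
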