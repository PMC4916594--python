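"""Weighted transcript co-expression network: soft-threshold adjacency,
topological overlap, average-linkage module detection, hub extraction.

The network is unsigned: the connection strength between transcripts i and
j is a_ij = |cor(x_i, x_j)|^beta, with Pearson correlation across all
libraries and a soft-thresholding power beta (default 20). Pairwise
similarity is the topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_iu, TOM_ii = 1; 1 - TOM is the
clustering dissimilarity. Modules are branches of the average-linkage
dendrogram below ``cut_height`` with at least ``min_module_size`` leaves
(a static tree cut; smaller branches stay unassigned as "gray", label 0).
Hubs are the top-``n_hubs`` members of a module by intramodular
connectivity (sum of within-module adjacency), exported as a VisANT-style
edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "GRAY",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "intramodular_connectivity",
    "extract_hubs",
    "write_visant_edges",
    "module_class_composition",
]

#: module label of unassigned transcripts
GRAY = 0


@dataclass(frozen=True)
class NetworkParams:
    """beta: soft-thresholding power (integer >= 1, default 20);
    min_module_size: smallest branch kept as a module (default 60);
    cut_height: dendrogram cut level on the 1 - TOM scale (default 0.995);
    n_hubs: hub transcripts exported per module (default 30)."""

    beta: int = 20
    min_module_size: int = 60
    cut_height: float = 0.995
    n_hubs: int = 30

    def __post_init__(self) -> None:
        if int(self.beta) != self.beta or self.beta < 1:
            raise ValueError("beta must be an integer >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.n_hubs < 1:
            raise ValueError("n_hubs must be >= 1")


def adjacency(expr_log: pd.DataFrame, params: NetworkParams | None = None) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |Pearson cor|^beta between
    transcript rows of a log-scale expression matrix (transcripts x samples).

    Zero-variance rows make the correlation undefined and must be removed
    beforehand; they raise a ValueError naming offenders.
    """
    params = params or NetworkParams()
    if expr_log.shape[1] < 3:
        raise ValueError("adjacency needs >= 3 samples per transcript")
    x = expr_log.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = expr_log.index[sd == 0].tolist()
        raise ValueError(f"zero-variance transcripts must be removed before adjacency: {bad[:5]}")
    cor = np.corrcoef(x)
    a = np.abs(np.clip(cor, -1.0, 1.0)) ** params.beta
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2  # enforce exact symmetry against fp noise
    return pd.DataFrame(a, index=expr_log.index, columns=expr_log.index)


def topological_overlap(adj: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unsigned TOM and its dissimilarity 1 - TOM.

    Vectorized: sum_{u != i,j} a_iu a_uj = (A @ A)_ij - 2 a_ij given a unit
    diagonal. Returns (tom, dissimilarity), both symmetric in [0, 1] with
    TOM diagonal 1.
    """
    a = adj.to_numpy(dtype=float)
    n = a.shape[0]
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    shared = a @ a - 2 * a  # (i,j) entry: sum over u != i,j of a_iu a_uj
    k = a.sum(axis=1) - 1.0
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    tom_df = pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom_df, 1.0 - tom_df


def detect_modules(
    dissim: pd.DataFrame,
    params: NetworkParams | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Average-linkage clustering of the TOM dissimilarity and a static
    tree cut: branches below ``cut_height`` with >= ``min_module_size``
    leaves become modules, everything else is gray (label 0). Module labels
    are 1, 2, ... in decreasing size order.

    Returns (assignments, scipy linkage matrix); assignments is indexed by
    transcript_id with a ``module`` column.
    """
    params = params or NetworkParams()
    d = dissim.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be square symmetric")
    n = d.shape[0]
    if n < params.min_module_size:
        logger.warning(
            "detect_modules: %d nodes < min_module_size %d; all gray", n, params.min_module_size
        )
        assignments = pd.DataFrame({"module": np.zeros(n, dtype=int)}, index=dissim.index)
        link = linkage(squareform(d, checks=False), method="average") if n > 1 else np.empty((0, 4))
        return assignments, link

    link = linkage(squareform((d + d.T) / 2, checks=False), method="average")
    raw = fcluster(link, t=params.cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= params.min_module_size].index
    # relabel kept clusters 1..k by decreasing size (ties: smaller raw label first)
    ordered = sorted(keep, key=lambda c: (-sizes[c], c))
    relabel = {c: i + 1 for i, c in enumerate(ordered)}
    labels = np.array([relabel.get(c, GRAY) for c in raw], dtype=int)
    assignments = pd.DataFrame({"module": labels}, index=dissim.index)
    return assignments, link


def intramodular_connectivity(adj: pd.DataFrame, modules: pd.DataFrame) -> pd.Series:
    """Sum of a node's adjacency to the other members of its own module
    (0 for gray nodes)."""
    labels = modules["module"].reindex(adj.index)
    kim = pd.Series(0.0, index=adj.index)
    for mod in labels.unique():
        if mod == GRAY:
            continue
        members = adj.index[(labels == mod).to_numpy()]
        sub = adj.loc[members, members].to_numpy(dtype=float)
        kim.loc[members] = sub.sum(axis=1) - 1.0  # exclude self (diagonal 1)
    return kim


def extract_hubs(
    adj: pd.DataFrame,
    modules: pd.DataFrame,
    params: NetworkParams | None = None,
    weights: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-``n_hubs`` members per module by intramodular connectivity, with
    a hub-hub edge list.

    ``weights`` (e.g. the TOM) supplies edge weights; defaults to the
    adjacency. Modules smaller than n_hubs return all members (warning).
    Returns (hubs, edges): hubs indexed by transcript_id with module,
    intramodular_connectivity and hub_rank (1 = most connected; ties broken
    by transcript id); edges has node1/node2/direction/method/weight rows
    in VisANT's column layout.
    """
    params = params or NetworkParams()
    labels = modules["module"].reindex(adj.index)
    if not (labels != GRAY).any():
        raise ValueError("extract_hubs: no non-gray module present")
    weights = adj if weights is None else weights
    kim = intramodular_connectivity(adj, modules)

    hub_rows = []
    edge_rows = []
    for mod in sorted(labels.unique()):
        if mod == GRAY:
            continue
        members = adj.index[(labels == mod).to_numpy()]
        if len(members) < params.n_hubs:
            logger.warning(
                "module %s has %d members < n_hubs %d; returning all",
                mod, len(members), params.n_hubs,
            )
        ranked = sorted(members, key=lambda t: (-kim[t], str(t)))[: params.n_hubs]
        for rank, tid in enumerate(ranked, start=1):
            hub_rows.append((tid, mod, kim[tid], rank))
        for i, t1 in enumerate(ranked):
            for t2 in ranked[i + 1:]:
                edge_rows.append((t1, t2, 0, "M1000", float(weights.loc[t1, t2])))

    hubs = pd.DataFrame(
        hub_rows, columns=["transcript_id", "module", "intramodular_connectivity", "hub_rank"]
    ).set_index("transcript_id")
    edges = pd.DataFrame(edge_rows, columns=["node1", "node2", "direction", "method", "weight"])
    return hubs, edges


def write_visant_edges(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a VisANT import file (tab-delimited, no header:
    node1, node2, direction flag, method tag, weight)."""
    edges.to_csv(path, sep="\t", index=False, header=False)


def module_class_composition(
    modules: pd.DataFrame,
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-module TSCT/TSNT counts, dominant tissue and purity.

    Dominant tissue is the modal ``specific_tissue`` among members with a
    call (ties broken lexicographically); purity is its share of the
    module's called members. Gray is reported as module 0.
    """
    if modules.empty:
        return pd.DataFrame(
            columns=["size", "n_TSCT", "n_TSNT", "dominant_tissue", "purity"]
        ).rename_axis("module")
    joined = modules.join(calls[["specific_tissue", "cls"]], how="left")
    rows = {}
    for mod, grp in joined.groupby("module"):
        called = grp[grp["specific_tissue"].notna()]
        if called.empty:
            dominant, purity = pd.NA, np.nan
        else:
            counts = called["specific_tissue"].value_counts().sort_index()
            dominant = counts.idxmax()
            purity = counts.max() / len(called)
        rows[mod] = {
            "size": len(grp),
            "n_TSCT": int((grp["cls"] == "TSCT").sum()),
            "n_TSNT": int((grp["cls"] == "TSNT").sum()),
            "dominant_tissue": dominant,
            "purity": purity,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("module")
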