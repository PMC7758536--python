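"""Network-based statistics: cluster-level correction on the connectome.

Mass-univariate edge tests are corrected by the network-based statistic:
edges exceeding an uncorrected one-sided p threshold are collected, their
connected components on the ROI node set form the observed clusters
(cluster size = edge count), and a permutation null of the maximal cluster
size is built by shuffling subject rows of the connectivity data against
the fixed design and re-running the identical model, contrast and
threshold.  The corrected p-value of an observed cluster of size ``k`` is

    p_corr = (1 + #{null max >= k}) / (1 + n_perm)

(the add-one convention, so p_corr is never below 1/(n_perm + 1)).  This
controls the family-wise error rate in the weak sense.  Row shuffling also
breaks covariate associations; Freedman-Lane residual permutation is
available for covariate-exact exchangeability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import EdgeStatMap, edge_index_pairs
from .glm import ContrastSpec, DesignMatrix, contrast_map, fit_edgewise

__all__ = [
    "NbsResult",
    "LobeSummary",
    "supra_threshold_edges",
    "connected_components_of_edges",
    "nbs_correct",
    "lobe_fraction_summary",
    "multi_threshold_report",
]

log = logging.getLogger(__name__)


@dataclass
class NbsResult:
    """Observed supra-threshold components and their permutation inference.

    ``components`` holds edge lists (arrays of (i, j) node pairs) sorted by
    decreasing size; ``sizes_k`` are edge counts; ``p_corrected`` aligns
    with ``components``.
    """

    components: list
    sizes_k: np.ndarray
    p_corrected: np.ndarray
    null_max_sizes: np.ndarray
    p_unc_threshold: float
    n_perm: int
    seed: int
    stat: EdgeStatMap | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list:
        return [comp for comp, p in zip(self.components, self.p_corrected) if p < alpha]

    @property
    def min_p_corrected(self) -> float:
        return float(self.p_corrected.min()) if self.p_corrected.size else 1.0


def supra_threshold_edges(stat: EdgeStatMap, p_unc: float) -> np.ndarray:
    """(i, j) pairs whose one-sided p is strictly below the threshold.

    Degenerate edges (NaN) never enter the set.
    """
    if not 0.0 < p_unc < 1.0:
        raise ValueError("p_unc must be inside (0, 1)")
    iu, ju = edge_index_pairs(stat.n_roi)
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(stat.p_unc) & (stat.p_unc < p_unc)
    return np.column_stack([iu[keep], ju[keep]])


def connected_components_of_edges(edges: np.ndarray, n_nodes: int) -> tuple[list, np.ndarray]:
    """Maximal connected components of an edge set; sizes are edge counts."""
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    if edges.size and edges.max() >= n_nodes:
        raise ValueError("edge endpoint outside the node set")
    g = nx.Graph()
    g.add_edges_from(map(tuple, edges))
    comps, sizes = [], []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comps.append(np.array(sorted((min(u, v), max(u, v)) for u, v in sub.edges())))
        sizes.append(sub.number_of_edges())
    order = np.argsort(sizes)[::-1]
    return [comps[k] for k in order], np.asarray(sizes, dtype=int)[order]


def _max_component_size(heads: np.ndarray, tails: np.ndarray) -> int:
    """Edge count of the largest connected component (union-find)."""
    if heads.size <= 1:
        return int(heads.size)
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    edge_count: dict[int, int] = {}
    for u, v in zip(heads.tolist(), tails.tolist()):
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru == rv:
            edge_count[ru] = edge_count.get(ru, 0) + 1
        else:
            parent[rv] = ru
            edge_count[ru] = edge_count.get(ru, 0) + edge_count.pop(rv, 0) + 1
    return max(edge_count.values())


def _t_threshold_maps(Yp: np.ndarray, design: DesignMatrix, pinv: np.ndarray,
                      c: np.ndarray, df: int, cvar: float, t_crit: float) -> np.ndarray:
    """Boolean supra-threshold masks for a batch of permuted Y stacks."""
    X = design.values
    B = np.matmul(pinv, Yp)  # (batch, p, m)
    resid = Yp - np.matmul(X, B)
    rss = np.einsum("bij,bij->bj", resid, resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.einsum("k,bkj->bj", c, B) / np.sqrt(rss / df * cvar)
    return np.nan_to_num(t, nan=-np.inf) > t_crit


def nbs_correct(
    Y: np.ndarray,
    design: DesignMatrix,
    contrast: ContrastSpec,
    p_unc: float = 0.005,
    n_perm: int = 5000,
    seed: int = 0,
    n_roi: int | None = None,
    permute: str = "rows",
) -> NbsResult:
    """Full NBS correction for one contrast (or association slope).

    ``permute='rows'`` shuffles subject rows of ``Y`` against the fixed
    design; ``permute='freedman_lane'`` permutes reduced-model residuals
    and adds back the nuisance fit, preserving covariate structure.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if permute not in ("rows", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {permute!r}")
    Y = np.asarray(Y, dtype=float)
    fit = fit_edgewise(Y, design, n_roi)
    stat = contrast_map(fit, contrast)
    alpha_floor = 1.0 / (n_perm + 1)
    if alpha_floor > 0.05:
        warnings.warn(f"n_perm={n_perm} cannot resolve p below {alpha_floor:.3f}")

    comps, sizes = connected_components_of_edges(supra_threshold_edges(stat, p_unc), stat.n_roi)

    c = contrast.for_design(design)
    pinv = np.linalg.pinv(design.values)
    cvar = float(c @ (pinv @ pinv.T) @ c)
    t_crit = float(stats.t.isf(p_unc, fit.df))
    iu, ju = edge_index_pairs(stat.n_roi)

    if permute == "freedman_lane":
        nuis = design.values[:, np.asarray(c) == 0]
        gamma = np.linalg.lstsq(nuis, Y, rcond=None)[0]
        fitted_nuis = nuis @ gamma
        resid_nuis = Y - fitted_nuis
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    batch = max(1, int(2e7 // max(Y.size, 1)))
    null_max = np.empty(n_perm, dtype=int)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_idx = np.array([rng.permutation(n) for _ in range(b)])
        if permute == "rows":
            Yp = Y[perm_idx]
        else:
            Yp = fitted_nuis[None, :, :] + resid_nuis[perm_idx]
        masks = _t_threshold_maps(Yp, design, pinv, c, fit.df, cvar, t_crit)
        for k in range(b):
            sel = masks[k]
            null_max[done + k] = _max_component_size(iu[sel], ju[sel])
        done += b

    p_corr = np.array([(1 + np.sum(null_max >= k)) / (1 + n_perm) for k in sizes])
    return NbsResult(comps, sizes, p_corr, null_max, p_unc, n_perm, seed, stat)


@dataclass
class LobeSummary:
    """Fractions (%) of a component's edges joining each lobe pair."""

    fractions: dict  # "LobeA-LobeB" -> percent, descending

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lobe_pair": list(self.fractions), "fraction_pct": list(self.fractions.values())}
        )


def lobe_fraction_summary(
    component: np.ndarray, lobe_assignment: dict, roi_labels: list[str]
) -> LobeSummary:
    """Tally a component's edges by the lobe pair they connect."""
    component = np.asarray(component, dtype=int).reshape(-1, 2)
    if component.size == 0:
        return LobeSummary({})
    counts: dict[str, int] = {}
    for i, j in component:
        try:
            li, lj = lobe_assignment[roi_labels[i]], lobe_assignment[roi_labels[j]]
        except KeyError as err:
            raise ValueError(f"ROI without lobe label: {err.args[0]}") from None
        pair = "-".join(sorted((li, lj)))
        counts[pair] = counts.get(pair, 0) + 1
    k = component.shape[0]
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return LobeSummary({pair: 100.0 * cnt / k for pair, cnt in items})


def multi_threshold_report(
    Y: np.ndarray,
    design: DesignMatrix,
    contrast: ContrastSpec,
    thresholds: tuple = (0.001, 0.005, 0.01, 0.05),
    n_perm: int = 5000,
    seed: int = 0,
    n_roi: int | None = None,
    directions: tuple = ("greater", "less"),
) -> pd.DataFrame:
    """Corrected p, cluster size and minimum |d| across initial thresholds.

    One row per (threshold, direction); the reported cluster is the most
    significant component at that setting, with the smallest absolute
    Cohen's d among its edges.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for direction in directions:
        spec = contrast if direction == "greater" else contrast.negated()
        for p_unc in thresholds:
            res = nbs_correct(Y, design, spec, p_unc, n_perm, seed, n_roi)
            if res.sizes_k.size:
                best = int(np.argmin(res.p_corrected))
                comp = res.components[best]
                iu, ju = edge_index_pairs(res.stat.n_roi)
                flat = {(i, j): k for k, (i, j) in enumerate(zip(iu, ju))}
                d_vals = np.array([res.stat.d[flat[(i, j)]] for i, j in comp])
                rows.append(
                    dict(contrast=spec.name, direction=direction, p_unc=p_unc,
                         p_corrected=res.p_corrected[best], k=int(res.sizes_k[best]),
                         min_abs_d=float(np.nanmin(np.abs(d_vals))),
                         significant=res.p_corrected[best] < 0.05,
                         trend=res.p_corrected[best] < 0.10)
                )
            else:
                rows.append(
                    dict(contrast=spec.name, direction=direction, p_unc=p_unc,
                         p_corrected=np.nan, k=0, min_abs_d=np.nan,
                         significant=False, trend=False)
                )
    return pd.DataFrame(rows)
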