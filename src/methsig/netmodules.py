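"""Correlation-network module detection over differentially methylated genes.

The network is built from unsigned soft-thresholded Pearson correlation,
a_ij = |PCC_ij|^beta, with the exponent chosen as the smallest candidate
whose connectivity distribution fits a scale-free law (R^2 of the
log10(k) vs log10(p(k)) regression at or above a target).  Pairwise
topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

measures shared network neighborhoods; 1 - TOM is the clustering
dissimilarity.  Modules are branches of the average-linkage dendrogram
cut at a height fraction, with branches below the minimum size merged
into their nearest branch (by average inter-branch dissimilarity) or set
aside as unassigned ("grey").  Surviving modules are relabeled by
decreasing size with the conventional color palette (turquoise largest,
then blue, brown, yellow, green, red, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError, ValidationError
from .preprocess import GeneMatrix

GREY = "grey"

#: Size-ordered module palette (largest module first).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)


@dataclass
class Network:
    """Soft-thresholded correlation network with topological overlap."""

    gene_ids: list
    beta_power: float
    adjacency: np.ndarray  # |PCC|^beta off-diagonal, unit diagonal
    tom: np.ndarray        # symmetric in [0, 1], unit diagonal


@dataclass
class PowerSelection:
    power: int
    achieved_r2: float
    met_target: bool
    table: pd.DataFrame  # per-candidate power and scale-free fit R^2


@dataclass
class ModuleAssignment:
    """Gene-to-color module map plus the dendrogram merge structure."""

    gene_ids: list
    colors: np.ndarray            # per-gene color, GREY = unassigned
    linkage_matrix: np.ndarray    # scipy merge structure
    module_sizes: dict            # color -> size, in palette (size) order

    @property
    def module_colors(self) -> list:
        return list(self.module_sizes)

    def genes_in(self, color: str) -> list:
        return [g for g, c in zip(self.gene_ids, self.colors) if c == color]


def _correlation(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValidationError("constant gene vectors: correlation undefined")
    corr = np.corrcoef(values)
    if not np.isfinite(corr).all():
        raise ValidationError("non-finite correlations")
    return corr


def scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution fit.

    Connectivities are grouped into equal-occupancy bins (stable counts
    per bin); the fitted relation is log10 density against log10 mean
    connectivity, where density is the bin's probability mass divided by
    its width — with equal-occupancy bins the raw per-bin frequency is
    constant by construction and carries no information, so the density
    correction is what makes the fit meaningful.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    n_bins = min(n_bins, k.size)
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 4:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        sel = idx == b
        width = edges[b + 1] - edges[b]
        if sel.sum() == 0 or width <= 0:
            continue
        # median is robust to the strong within-bin skew of low-degree bins
        xs.append(np.log10(np.median(k[sel])))
        ys.append(np.log10(sel.sum() / (k.size * width)))
    # a degree distribution spanning less than half a decade cannot
    # exhibit scale-free behavior, and a frequency that increases with
    # connectivity is the opposite of scale-free: report no fit
    if len(xs) < 3 or np.ptp(xs) < 0.5:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    if not np.isfinite(r) or r > 0:
        return 0.0
    return float(r * r)


#: Minimum best-candidate R^2 for the fit profile to be considered
#: informative at all; below this the argmax is numerical noise.
UNINFORMATIVE_R2 = 0.3

#: Conventional soft-threshold exponent for unsigned correlation
#: networks when the scale-free fit is uninformative.
DEFAULT_POWER = 10


def pick_power(g: GeneMatrix, candidates: Sequence[int] = tuple(range(1, 21)),
               fit_target: float = 0.8, n_bins: int = 10) -> PowerSelection:
    """Choose the smallest soft-threshold exponent reaching the
    scale-free fit target.

    When no candidate reaches the target, the candidate maximizing the
    fit is used instead (with a warning) — unless even the best fit is
    below ``UNINFORMATIVE_R2``, in which case the degree distribution
    carries no scale-free signal at any exponent (typical for small,
    strongly modular gene sets, where degrees concentrate on a few
    values) and the argmax would be numerical noise; the conventional
    unsigned-network default exponent is used then.
    """
    if g.n_genes < 3:
        raise ValidationError("need at least 3 genes to build a network")
    corr = np.abs(_correlation(g.values))
    np.fill_diagonal(corr, 0.0)
    rows = []
    chosen = None
    for beta in candidates:
        k = (corr ** beta).sum(axis=1)
        r2 = scale_free_r2(k, n_bins=n_bins)
        rows.append({"power": beta, "r_squared": r2, "mean_connectivity": float(k.mean())})
        if chosen is None and r2 >= fit_target:
            chosen = (beta, r2)
    table = pd.DataFrame(rows)
    if chosen is not None:
        return PowerSelection(int(chosen[0]), float(chosen[1]), True, table)
    best = table.loc[table["r_squared"].idxmax()]
    if best["r_squared"] >= UNINFORMATIVE_R2 or fit_target <= 0:
        warnings.warn(
            f"no candidate power reached scale-free fit R^2 >= {fit_target}; "
            f"using power {int(best['power'])} (R^2 = {best['r_squared']:.3f})"
        )
        return PowerSelection(int(best["power"]), float(best["r_squared"]), False, table)
    cand = sorted(int(c) for c in candidates)
    power = min(cand, key=lambda c: (abs(c - DEFAULT_POWER), c))
    warnings.warn(
        f"scale-free fit uninformative at every candidate power (best R^2 = "
        f"{best['r_squared']:.3f}); using the conventional unsigned-network "
        f"default power {power}"
    )
    return PowerSelection(power, float(best["r_squared"]), False, table)


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with the diagonal of ``a`` taken as zero; TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.isfinite(a).all():
        raise ValidationError("adjacency contains non-finite entries")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def tom_from_matrix(g: GeneMatrix, beta_power: float) -> Network:
    """Topological overlap of the soft-thresholded correlation network."""
    if g.n_genes < 3:
        raise ValidationError("need at least 3 genes to build a network")
    a = np.abs(_correlation(g.values)) ** beta_power
    np.fill_diagonal(a, 0.0)
    tom = tom_from_adjacency(a)
    adjacency = a.copy()
    np.fill_diagonal(adjacency, 1.0)
    return Network(list(g.gene_ids), float(beta_power), adjacency, tom)


def colors_for_sizes(sizes: Sequence[int]) -> list:
    """Palette labels for module sizes, largest first.

    Pure function of the size list: returns one color per input module,
    in the input order, such that the largest module is turquoise, the
    next blue, and so on.  Ties keep input order.
    """
    order = sorted(range(len(sizes)), key=lambda i: (-sizes[i], i))
    palette = list(MODULE_COLORS) + [f"module{i}" for i in range(len(sizes))]
    out = [None] * len(sizes)
    for rank, i in enumerate(order):
        out[i] = palette[rank]
    return out


def cut_modules(network: Network, min_module_size: int = 10,
                cut_height: float = 0.99) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a simplified dynamic cut.

    The dendrogram is cut at ``cut_height`` times its maximum merge
    height; branches smaller than ``min_module_size`` are merged into the
    nearest branch by average inter-branch dissimilarity when that
    dissimilarity stays within the cut, otherwise their genes go grey.
    """
    n = len(network.gene_ids)
    if min_module_size > n:
        raise ParameterError(f"min_module_size={min_module_size} exceeds {n} genes")
    if not 0 <= cut_height <= 1:
        raise ParameterError("cut_height must be a fraction in [0, 1]")
    d = 1.0 - network.tom
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    max_h = z[:, 2].max() if len(z) else 0.0
    h = cut_height * max_h
    flat = fcluster(z, t=h, criterion="distance")
    branches = {b: np.flatnonzero(flat == b) for b in np.unique(flat)}

    grey_idx: list = []
    while True:
        small = [(idx.size, b) for b, idx in branches.items() if idx.size < min_module_size]
        if not small or len(branches) == 0:
            break
        _, b = min(small)
        idx = branches.pop(b)
        best_b, best_d = None, np.inf
        for ob, oidx in branches.items():
            avg = d[np.ix_(idx, oidx)].mean()
            if avg < best_d:
                best_b, best_d = ob, avg
        if best_b is not None and best_d <= h:
            branches[best_b] = np.concatenate([branches[best_b], idx])
        else:
            grey_idx.extend(idx.tolist())

    # deterministic module order: size descending, then lowest member index
    mods = sorted(branches.values(), key=lambda ix: (-ix.size, ix.min()))
    palette = colors_for_sizes([ix.size for ix in mods])
    colors = np.full(n, GREY, dtype=object)
    sizes = {}
    for color, idx in zip(palette, mods):
        colors[idx] = color
        sizes[color] = int(idx.size)
    return ModuleAssignment(list(network.gene_ids), colors.astype(str), z, sizes)
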