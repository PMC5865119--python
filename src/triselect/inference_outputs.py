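"""Posterior predictions on the ecological triangle.

Turns a fitted habitat-use posterior into the quantities habitat
selection studies report: predicted use clouds and marginality vectors
for arbitrary availabilities, pairwise-site log-ratio significance maps
over a discretized simplex, representative-animal selection by Ward
clustering of availability compositions, and ternary figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.cluster.hierarchy import fcluster, linkage
from shapely.geometry import MultiPoint, Polygon

from .habitat_model import Posterior
from .simplex_core import (
    Composition,
    MarginalityVector,
    TRIANGLE_VERTICES,
    marginality,
    make_composition,
    ternary_coords,
)

#: classification thresholds for the posterior probability P(log-ratio > 0)
P_HI = 0.95
P_LO = 0.05

CLASS_LABELS = ("greater_in_A", "greater_in_B", "no_difference", "infeasible")


# ---------------------------------------------------------------------------
# Predicted use and marginality
# ---------------------------------------------------------------------------

def _site_index(post: Posterior, site: str) -> int:
    if post.form == "pooled":
        return 0
    try:
        return post.sites.index(site)
    except ValueError:
        raise KeyError(f"site {site!r} not in fitted posterior {post.sites}") from None


def _predict_probs(
    post: Posterior, site: str, d_arr: np.ndarray, eps: np.ndarray | None = None
) -> np.ndarray:
    """Use probabilities per draw per composition: (R, n_cells, 3)."""
    s = _site_index(post, site)
    X = np.column_stack([np.ones(len(d_arr)), d_arr[:, 0], d_arr[:, 1]])
    A = post.flat_a()[:, s]                             # (R, 2, 3)
    eta = np.einsum("rhj,cj->rch", A, X)                # (R, n_cells, 2)
    if eps is not None:
        eta = eta + eps[:, None, :]
    z = np.concatenate([eta, np.zeros_like(eta[..., :1])], axis=-1)
    z -= z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def predict_use(
    post: Posterior,
    site: str,
    d: Composition,
    include_eps: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Posterior sample of predicted use compositions, shape (R, 3).

    By default the predictions use the *mean* multinomial logit (eps = 0):
    the spread of the cloud reflects parameter uncertainty only.  With
    ``include_eps`` a fresh residual pair eps ~ N(0, sigma_r^2) is drawn
    per posterior draw, adding new-individual overdispersion.
    """
    eps = None
    if include_eps:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((post.n_total, 2)) * post.flat_sigma()[:, None]
    return _predict_probs(post, site, d.as_array()[None, :2], eps)[:, 0, :]


def predicted_marginality(
    post: Posterior,
    site: str,
    d: Composition,
    include_eps: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, MarginalityVector]:
    """Posterior sample of marginality deltas plus the mean marginality.

    The mean marginality connects the availability to the mean of the
    predicted use cloud (the circle-with-cross of a marginality figure).
    """
    cloud = predict_use(post, site, d, include_eps=include_eps, seed=seed)
    deltas = cloud - d.as_array()
    mean_used = make_composition(cloud.mean(axis=0), normalize=True)
    return deltas, marginality(d, mean_used)


# ---------------------------------------------------------------------------
# Ternary grid and log-ratio maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TernaryGrid:
    """All compositions on a barycentric lattice of the given step."""

    step: float = 0.01

    def __post_init__(self) -> None:
        m = round(1.0 / self.step)
        if abs(m * self.step - 1.0) > 1e-9 or m < 1:
            raise ValueError("step must divide 1 exactly")

    @property
    def resolution(self) -> int:
        return round(1.0 / self.step)

    @property
    def cells(self) -> np.ndarray:
        """(n_cells, 3) array of lattice compositions; n = C(m + 2, 2)."""
        m = self.resolution
        i, j = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
        keep = i + j <= m
        i, j = i[keep], j[keep]
        k = m - i - j
        return np.column_stack([i, j, k]) / m


@dataclass(frozen=True)
class LogRatioMap:
    """Posterior comparison of the use of one habitat between two sites."""

    site_a: str
    site_b: str
    habitat_index: int
    table: pd.DataFrame  # p_shrub, p_pole, p_cws, P_gt0, class

    def class_counts(self) -> pd.Series:
        return self.table["class"].value_counts()


def log_ratio_map(
    post: Posterior,
    s1: str,
    s2: str,
    h: int,
    grid: TernaryGrid | None = None,
    feasible: Callable[[np.ndarray], np.ndarray] | None = None,
    chunk: int = 512,
) -> LogRatioMap:
    """Map P(log(p_{s1,h} / p_{s2,h}) > 0) over home-range compositions.

    Cells with P above 0.95 are classed ``greater_in_A`` (the habitat is
    used more in ``s1``), below 0.05 ``greater_in_B``; cells outside the
    joint feasibility region are ``infeasible``.  Ties at exactly zero
    count 1/2.
    """
    if h not in (0, 1, 2):
        raise ValueError("habitat index must be 0 (shrub), 1 (pole) or 2 (cws)")
    grid = grid or TernaryGrid()
    cells = grid.cells
    ok = np.ones(len(cells), dtype=bool) if feasible is None else np.asarray(feasible(cells), dtype=bool)
    P = np.full(len(cells), np.nan)
    idx = np.nonzero(ok)[0]
    for start in range(0, len(idx), chunk):
        sel = idx[start:start + chunk]
        d_arr = cells[sel, :2]
        p1 = _predict_probs(post, s1, d_arr)[..., h]
        p2 = _predict_probs(post, s2, d_arr)[..., h]
        lr = np.log(p1) - np.log(p2)
        P[sel] = (lr > 0).mean(axis=0) + 0.5 * (lr == 0).mean(axis=0)
    cls = np.where(
        ~ok, "infeasible",
        np.where(P > P_HI, "greater_in_A", np.where(P < P_LO, "greater_in_B", "no_difference")),
    )
    table = pd.DataFrame(
        dict(p_shrub=cells[:, 0], p_pole=cells[:, 1], p_cws=cells[:, 2],
             P_gt0=P, **{"class": cls})
    )
    return LogRatioMap(site_a=s1, site_b=s2, habitat_index=h, table=table)


def joint_feasible_region(
    availabilities_s1: Sequence[Composition],
    availabilities_s2: Sequence[Composition],
    buffer: float = 1e-9,
) -> Callable[[np.ndarray], np.ndarray]:
    """Predicate for compositions available in *both* sites.

    The feasible region is the intersection of each site's convex hull of
    observed availability points in the ternary plane.  A degenerate hull
    (collinear availabilities) falls back to a minimally buffered segment.
    Returns a vectorized predicate over (n, 3) composition arrays.
    """
    def hull(avails: Sequence[Composition]):
        if len(avails) < 3:
            raise ValueError("need at least 3 availability compositions per site")
        pts = ternary_coords(np.array([a.as_array() for a in avails]))
        geom = MultiPoint([tuple(p) for p in pts]).convex_hull
        if not isinstance(geom, Polygon):
            geom = geom.buffer(buffer)
        return geom

    region = hull(availabilities_s1).intersection(hull(availabilities_s2))

    def predicate(compositions: np.ndarray) -> np.ndarray:
        arr = np.asarray(compositions, dtype=float)
        if region.is_empty:
            return np.zeros(len(arr), dtype=bool)
        xy = ternary_coords(arr)
        return shapely.intersects_xy(region, xy[:, 0], xy[:, 1])

    return predicate


# ---------------------------------------------------------------------------
# Representative animals
# ---------------------------------------------------------------------------

def select_representatives(
    availabilities: Mapping[str, Composition],
    k: int = 8,
    seed: int = 0,
) -> list[str]:
    """Pick one animal per availability cluster.

    Animals are clustered on Euclidean distance in the ternary plane with
    Ward's minimum-variance agglomeration, the tree is cut into ``k``
    groups, and one member is sampled uniformly per group.  Input order
    does not matter: animals are processed in sorted-id order.
    """
    ids = sorted(availabilities)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available animals")
    if k == len(ids):
        return list(ids)
    pts = ternary_coords(np.array([availabilities[i].as_array() for i in ids]))
    Z = linkage(pts, method="ward")
    groups = fcluster(Z, t=k, criterion="maxclust")
    rng = np.random.default_rng(seed)
    chosen = []
    for g in np.unique(groups):
        members = [ids[i] for i in np.nonzero(groups == g)[0]]
        chosen.append(members[rng.integers(len(members))])
    return chosen


# ---------------------------------------------------------------------------
# Export and figures
# ---------------------------------------------------------------------------

def write_log_ratio_map(m: LogRatioMap, path) -> None:
    m.table.to_csv(path, index=False)


def write_marginality_cloud(deltas: np.ndarray, d: Composition, path) -> None:
    cloud = d.as_array() + deltas
    pd.DataFrame(cloud, columns=["p_shrub", "p_pole", "p_cws"]).to_csv(path, index=False)


def ternary_axes(ax=None, labels=("shrub", "pole stage", "CWS")):
    """Bare ternary axes: the reference triangle with vertex labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.6))
    tri = np.vstack([TRIANGLE_VERTICES, TRIANGLE_VERTICES[:1]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    offsets = [(-0.02, -0.04), (0.02, -0.04), (0.0, 0.03)]
    for (x, y), lab, (dx, dy) in zip(TRIANGLE_VERTICES, labels, offsets):
        ax.text(x + dx, y + dy, lab, ha="center", va="center")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_marginality(vectors: Sequence[MarginalityVector], ax=None, **arrow_kw):
    """Marginality vectors as arrows on a ternary plot."""
    ax = ternary_axes(ax)
    kw = dict(head_width=0.01, length_includes_head=True, color="tab:blue")
    kw.update(arrow_kw)
    for m in vectors:
        pa = ternary_coords(m.available.as_array()[None])[0]
        pu = ternary_coords(m.used.as_array()[None])[0]
        ax.arrow(pa[0], pa[1], pu[0] - pa[0], pu[1] - pa[1], **kw)
    return ax


def plot_use_cloud(cloud: np.ndarray, d: Composition, ax=None):
    """Predicted-use cloud (grey dots), availability (open circle) and the
    mean use (crossed circle) on a ternary plot."""
    ax = ternary_axes(ax)
    xy = ternary_coords(cloud)
    ax.plot(xy[:, 0], xy[:, 1], ".", color="grey", alpha=0.1, ms=2)
    pa = ternary_coords(d.as_array()[None])[0]
    pm = xy.mean(axis=0)
    ax.plot(*pa, "o", mfc="white", mec="black")
    ax.plot(*pm, "o", mfc="white", mec="black")
    ax.plot(*pm, "+", color="black")
    return ax


def plot_log_ratio_map(m: LogRatioMap, ax=None):
    """Three-way classification of a log-ratio map on the triangle."""
    ax = ternary_axes(ax)
    colors = dict(
        greater_in_A="black", greater_in_B="lightgrey",
        no_difference="dimgrey", infeasible="white",
    )
    xy = ternary_coords(m.table[["p_shrub", "p_pole", "p_cws"]].to_numpy())
    for cls, color in colors.items():
        sel = (m.table["class"] == cls).to_numpy()
        if sel.any() and cls != "infeasible":
            ax.scatter(xy[sel, 0], xy[sel, 1], s=4, c=color, marker="s", lw=0)
    ax.set_title(f"{m.site_a} vs {m.site_b}")
    return ax
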