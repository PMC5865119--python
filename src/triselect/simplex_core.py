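"""Geometry and elementary selection metrics on the 3-part habitat simplex.

A home range composed of three habitat types (shrub, pole stage, coppice
with standards) is a point on the 2-simplex — the "ecological triangle".
This module provides the closed compositional arithmetic used everywhere
else: compositions, marginality vectors (used minus available), selection
ratios, and the bijection between barycentric and planar ternary
coordinates.

Habitat order is fixed as (shrub, pole, cws) throughout the package; the
reference habitat of the multinomial logit is cws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical habitat order: shrub (h=1), pole stage (h=2), coppice with
#: standards (h=3, the reference habitat of the use model)
HABITATS: tuple[str, str, str] = ("shrub", "pole", "cws")

#: absolute tolerance for compositional closure (components summing to 1)
CLOSURE_TOL = 1e-9

# Equilateral reference triangle with unit side, vertices counter-clockwise:
# shrub at the origin, pole at (1, 0), cws at the apex.
TRIANGLE_VERTICES = np.array(
    [[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]]
)


@dataclass(frozen=True)
class Composition:
    """A 3-part composition (proportions of shrub, pole, cws summing to 1)."""

    p_shrub: float
    p_pole: float
    p_cws: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("composition components must be finite")
        if np.any(arr < -CLOSURE_TOL) or np.any(arr > 1 + CLOSURE_TOL):
            raise ValueError(f"components must lie in [0, 1], got {arr}")
        if abs(arr.sum() - 1.0) > CLOSURE_TOL:
            raise ValueError(
                f"components must sum to 1 within {CLOSURE_TOL}, got sum {arr.sum()!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p_shrub, self.p_pole, self.p_cws], dtype=float)

    def __getitem__(self, i: int) -> float:
        return float(self.as_array()[i])


@dataclass(frozen=True)
class TernaryPoint:
    """Planar image of a composition in the fixed reference triangle."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class MarginalityVector:
    """Displacement on the simplex from available to used conditions.

    ``delta = used - available`` componentwise; its direction says which
    habitats are preferred (positive) or avoided (negative), its length
    measures selection strength.
    """

    available: Composition
    used: Composition

    @property
    def delta(self) -> np.ndarray:
        return self.used.as_array() - self.available.as_array()

    @property
    def length(self) -> float:
        """Selection strength as planar distance in the ternary embedding."""
        return marginality_length(self)

    @property
    def norm3(self) -> float:
        """Euclidean norm of the raw 3-vector delta (= length * sqrt(2))."""
        return float(np.linalg.norm(self.delta))


def make_composition(
    values: Sequence[float] | np.ndarray, normalize: bool = False
) -> Composition:
    """Build a :class:`Composition` from three non-negative values.

    With ``normalize=True`` the values are rescaled to sum to 1; otherwise
    they must already be closed within :data:`CLOSURE_TOL` (and are then
    renormalized silently to remove rounding slack).
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected 3 values, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"negative component in {arr}")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero composition is degenerate")
    if not normalize and abs(total - 1.0) > CLOSURE_TOL:
        raise ValueError(
            f"values sum to {total!r}, not 1; pass normalize=True to rescale"
        )
    arr = arr / total
    return Composition(*arr)


def marginality(available: Composition, used: Composition) -> MarginalityVector:
    """Marginality vector connecting available to used conditions."""
    return MarginalityVector(available=available, used=used)


def delta_proportions(
    available: Sequence[float] | np.ndarray, used: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Componentwise ``used - available`` on raw proportion vectors.

    Published compositions are often rounded (or occasionally inconsistent)
    so their components do not close to 1 exactly; this helper reproduces
    figure-caption arithmetic without enforcing closure.  For closed
    compositions it equals ``marginality(a, u).delta``.  Example: a range of
    (0.50, 0.30, 0.20) with printed use (0.40, 0.10, 0.60) gives
    (-0.10, -0.20, +0.40).
    """
    a = np.asarray(available, dtype=float)
    u = np.asarray(used, dtype=float)
    if a.shape != (3,) or u.shape != (3,):
        raise ValueError("expected two 3-part proportion vectors")
    return u - a


def marginality_length(m: MarginalityVector) -> float:
    """Length of the marginality vector in the planar ternary embedding.

    This matches distances measured on a drawn ternary plot; the raw
    3-vector norm differs by a constant factor sqrt(2) (constant because
    deltas are zero-sum).
    """
    pa = to_ternary(m.available).as_array()
    pu = to_ternary(m.used).as_array()
    return float(np.linalg.norm(pu - pa))


def selection_ratio(used: Composition, available: Composition) -> np.ndarray:
    """Per-habitat selection ratios ``w_h = u_h / a_h``.

    ``w_h > 1`` indicates preference, ``w_h < 1`` avoidance.  Habitats
    with zero availability have an undefined ratio and are returned as
    NaN rather than clamped — dividing by a vanishing availability is
    exactly the rare-habitat overemphasis this package's marginality
    metric avoids.
    """
    u = used.as_array()
    a = available.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(a > 0, u / np.where(a > 0, a, 1.0), np.nan)
    return w


def to_ternary(c: Composition) -> TernaryPoint:
    """Map a composition to its planar point (barycentric embedding)."""
    xy = c.as_array() @ TRIANGLE_VERTICES
    return TernaryPoint(float(xy[0]), float(xy[1]))


def from_ternary(t: TernaryPoint, tol: float = 1e-9) -> Composition:
    """Invert :func:`to_ternary`; errors if the point lies outside the triangle."""
    lam = barycentric_coords(np.array([[t.x, t.y]]))[0]
    if np.any(lam < -tol) or np.any(lam > 1 + tol):
        raise ValueError(f"point ({t.x}, {t.y}) lies outside the reference triangle")
    lam = np.clip(lam, 0.0, 1.0)
    lam = lam / lam.sum()
    return Composition(*lam)


def ternary_coords(compositions: np.ndarray) -> np.ndarray:
    """Vectorized planar coordinates for an (n, 3) array of compositions."""
    arr = np.asarray(compositions, dtype=float)
    return arr @ TRIANGLE_VERTICES


def barycentric_coords(xy: np.ndarray) -> np.ndarray:
    """Vectorized inverse of :func:`ternary_coords` for an (n, 2) array."""
    xy = np.asarray(xy, dtype=float)
    h = TRIANGLE_VERTICES[2, 1]  # apex height sqrt(3)/2
    lam_cws = xy[:, 1] / h
    lam_pole = xy[:, 0] - 0.5 * lam_cws
    lam_shrub = 1.0 - lam_pole - lam_cws
    return np.column_stack([lam_shrub, lam_pole, lam_cws])


def drop_category_renormalize(values: Sequence[float] | np.ndarray) -> Composition:
    """Remove the grassland share of a 4-part composition and re-close.

    Grassland typically makes up only a small fraction of forest home
    ranges, so availability is inferred on the remaining three types.
    ``values`` is ordered (grassland, shrub, pole, cws).
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"expected 4 values (grassland, shrub, pole, cws), got {arr.shape}")
    if np.any(arr < 0):
        raise ValueError(f"negative component in {arr}")
    rest = arr[1:]
    if rest.sum() <= 0:
        raise ValueError("grassland covers the whole composition; nothing to renormalize")
    return make_composition(rest, normalize=True)


# ---------------------------------------------------------------------------
# CSV interface: composition tables
# ---------------------------------------------------------------------------

COMPOSITION_COLUMNS = ["site", "animal_id", "role", "p_shrub", "p_pole", "p_cws"]


def read_composition_table(path) -> pd.DataFrame:
    """Read a composition table (site, animal_id, role, p_shrub, p_pole, p_cws)."""
    df = pd.read_csv(path, comment="#")
    missing = set(COMPOSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    bad = ~df["role"].isin(["available", "used"])
    if bad.any():
        raise ValueError(f"unknown role values: {df.loc[bad, 'role'].unique()}")
    for _, row in df.iterrows():
        make_composition([row.p_shrub, row.p_pole, row.p_cws])
    return df[COMPOSITION_COLUMNS]


def write_composition_table(df: pd.DataFrame, path) -> None:
    df[COMPOSITION_COLUMNS].to_csv(path, index=False)


def compositions_to_frame(
    comps: Iterable[tuple[str, str, str, Composition]]
) -> pd.DataFrame:
    """Build a composition table from (site, animal_id, role, composition) tuples."""
    rows = [
        dict(
            site=s, animal_id=a, role=r,
            p_shrub=c.p_shrub, p_pole=c.p_pole, p_cws=c.p_cws,
        )
        for s, a, r, c in comps
    ]
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)
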