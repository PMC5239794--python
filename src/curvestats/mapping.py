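"""Mapping constant-curvature contours among extracted edges.

An ordered pair of edge elements (A, B) is summarised by its pair geometry:
the centre distance d, the direction phi of B relative to A's orientation,
and the axial orientation difference theta, both wrapped to (-90, 90]. The
pair is *continuous* (cocircular in the tangent sense) when theta = 2 phi
up to a tolerance: the exterior-angle rule for two chords of a common
circle. Collinearity is the phi = theta = 0 special case.

A mapped contour is a chain of exactly four edge elements in which every
consecutive pair is continuous, consecutive spacings agree to within one
fifth, and the orientation step is constant in sign and magnitude to within
+-5 deg. The search is greedy and unguided: edges are seeded in
deterministic row-major order, chains are grown on both sides of the seed,
and accepted contours are marked so their members are removed from further
search. End elements of a mapped contour are edges one spacing beyond
either terminus that continue it (continuous pairing, forward half-plane);
their orientation is recorded relative to the terminal member and
sign-normalised so that positive means continuing the curvature direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._angles import wrap90, wrap180

__all__ = [
    "PairGeometry",
    "pair_geometry",
    "is_continuous",
    "find_contours",
    "extract_end_elements",
    "bin_contours",
    "ConstantCurvatureMapper",
    "LENGTH_BINS",
    "CURVATURE_CLASSES",
]

#: inter-element spacing (length) bins in pixels, printed edges
LENGTH_BINS = [(1, 8), (9, 17), (18, 24), (25, 33), (34, 42)]
CURVATURE_CLASSES = (0, 10, 20, 30, 40)
SPACING_RANGE_PX = (1.0, 42.0)
SPACING_TOL_FRAC = 0.2  # +- one fifth of the distance
DEFAULT_TOL_DEG = 5.0


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of an ordered edge pair: distance, direction, orientation step."""

    d: float
    phi: float
    theta: float

    @property
    def continuity_defect_deg(self) -> float:
        """|theta - 2 phi| wrapped to the axial range; 0 for cocircular pairs."""
        return abs(wrap90(self.theta - 2.0 * self.phi))


def pair_geometry(a, b) -> PairGeometry:
    """Pair geometry of edge elements ``a`` and ``b``.

    Each element needs attributes/keys ``x_px``, ``y_px``,
    ``orientation_deg``. phi is the direction of B from A measured against
    A's orientation axis, theta the orientation difference B - A; both are
    axial (wrapped to (-90, 90]).
    """
    ax, ay, ao = _xyo(a)
    bx, by, bo = _xyo(b)
    dx, dy = bx - ax, by - ay
    d = float(np.hypot(dx, dy))
    if d == 0.0:
        raise ValueError("coincident edge elements have no pair geometry")
    direction = np.degrees(np.arctan2(dy, dx))
    return PairGeometry(d=d, phi=float(wrap90(direction - ao)),
                        theta=float(wrap90(bo - ao)))


def _xyo(e) -> tuple[float, float, float]:
    if isinstance(e, (pd.Series, dict)):
        return float(e["x_px"]), float(e["y_px"]), float(e["orientation_deg"])
    return float(e.x_px), float(e.y_px), float(e.orientation_deg)


def is_continuous(g: PairGeometry, tol_deg: float = DEFAULT_TOL_DEG) -> bool:
    """True when the pair satisfies the exterior-angle rule theta = 2 phi."""
    return g.continuity_defect_deg <= tol_deg


# ---------------------------------------------------------------------------
# chain criteria


def _chain_spacings(x, y, order) -> np.ndarray:
    return np.hypot(np.diff(x[order]), np.diff(y[order]))


def _chain_steps(o, order) -> np.ndarray:
    return wrap90(np.diff(o[order]))


def _spacings_ok(sp: np.ndarray) -> bool:
    if (sp <= 0).any():
        return False
    for i in range(len(sp) - 1):
        if abs(sp[i + 1] - sp[i]) > SPACING_TOL_FRAC * min(sp[i], sp[i + 1]):
            return False
    return True


def _steps_ok(steps: np.ndarray, tol_deg: float) -> bool:
    m = steps.mean()
    if np.any(np.abs(steps - m) > tol_deg):
        return False
    # constant sign, with tolerance: no two steps on strictly opposite
    # sides of the +-tol band
    return not (steps.max() > tol_deg and steps.min() < -tol_deg)


def _valid_chain(x, y, o, order, tol_deg: float) -> bool:
    """All four mapping criteria for an ordered 4-chain."""
    if len(order) != 4:
        return False
    sp = _chain_spacings(x, y, order)
    if not _spacings_ok(sp):
        return False
    m = sp.mean()
    if not (SPACING_RANGE_PX[0] * (1 - SPACING_TOL_FRAC) <= m
            <= SPACING_RANGE_PX[1] * (1 + SPACING_TOL_FRAC)):
        return False
    for i in range(3):
        a, b = order[i], order[i + 1]
        direction = np.degrees(np.arctan2(y[b] - y[a], x[b] - x[a]))
        phi = wrap90(direction - o[a])
        theta = wrap90(o[b] - o[a])
        if abs(wrap90(theta - 2.0 * phi)) > tol_deg:
            return False
    return _steps_ok(_chain_steps(o, order), tol_deg)


# ---------------------------------------------------------------------------
# greedy unguided search


def find_contours(
    edges: pd.DataFrame,
    spacing_range_px: tuple[float, float] = SPACING_RANGE_PX,
    tol_deg: float = DEFAULT_TOL_DEG,
    remove_members: bool = True,
) -> pd.DataFrame:
    """Greedy unguided search for 4-element constant-curvature chains.

    Edges are seeded in row-major order (by y, then x). For each seed,
    candidate spacings are taken from the distances of continuous
    neighbours within ``spacing_range_px`` (+- one fifth); chains grow on
    both sides of the seed, at each growth step taking the candidate that
    minimises the continuity defect |theta - 2 phi| (ties broken toward the
    smaller spacing deviation). A completed chain is accepted only if it
    passes all four criteria, then marked: with ``remove_members`` (the
    default) its members leave the candidate pool entirely, otherwise they
    only stop seeding new chains.

    Returns one row per contour: ``contour_id``, ``members`` (index tuple
    into ``edges``), ``step_deg`` (signed mean orientation step),
    ``spacing_px`` (mean spacing), plus the member coordinate arrays.
    """
    n = len(edges)
    out_cols = ["contour_id", "members", "step_deg", "spacing_px",
                "member_x", "member_y", "member_orient"]
    if n < 4:
        return pd.DataFrame(columns=out_cols)

    x = edges["x_px"].to_numpy(float)
    y = edges["y_px"].to_numpy(float)
    o = edges["orientation_deg"].to_numpy(float)
    index = edges.index.to_numpy()

    # deterministic seed order: strongest edges first when an energy column
    # is available (the most reliable structure anchors the search), else
    # row-major by pixel position; ties always break row-major
    if "peak_energy" in edges:
        e = edges["peak_energy"].to_numpy(float)
        seed_order = np.lexsort((x, y, -e))
    else:
        seed_order = np.lexsort((x, y))
    in_pool = np.ones(n, dtype=bool)
    seeded = np.zeros(n, dtype=bool)
    results = []

    lo = spacing_range_px[0] * (1 - SPACING_TOL_FRAC)
    hi = spacing_range_px[1] * (1 + SPACING_TOL_FRAC)

    def geometry_from(i: int, pool: np.ndarray):
        dx, dy = x[pool] - x[i], y[pool] - y[i]
        d = np.hypot(dx, dy)
        direction = np.degrees(np.arctan2(dy, dx))
        phi = wrap90(direction - o[i])
        theta = wrap90(o[pool] - o[i])
        defect = np.abs(wrap90(theta - 2.0 * phi))
        return d, defect

    def grow(chain: list[int], pool_mask: np.ndarray) -> list[int] | None:
        """Extend alternately at tail and head until 4 members or stuck."""
        while len(chain) < 4:
            best = None  # (defect, spacing_dev, side, j)
            for side in ("tail", "head"):
                term = chain[-1] if side == "tail" else chain[0]
                prev = chain[-2] if side == "tail" else chain[1]
                sp_ref = float(np.hypot(x[term] - x[prev], y[term] - y[prev]))
                cand = np.nonzero(pool_mask)[0]
                cand = cand[~np.isin(cand, chain)]
                if cand.size == 0:
                    continue
                d, defect = geometry_from(term, cand)
                ok = (np.abs(d - sp_ref) <= SPACING_TOL_FRAC * np.minimum(d, sp_ref)) \
                    & (defect <= tol_deg) & (d > 0)
                for j, dj, defj in zip(cand[ok], d[ok], defect[ok]):
                    # step consistency with the existing chain
                    trial = chain + [j] if side == "tail" else [j] + chain
                    if not _steps_ok(_chain_steps(o, trial), tol_deg):
                        continue
                    key = (defj, abs(dj - sp_ref), 0 if side == "tail" else 1, j)
                    if best is None or key < best[0]:
                        best = (key, side, j)
            if best is None:
                return None
            _, side, j = best
            if side == "tail":
                chain.append(j)
            else:
                chain.insert(0, j)
        return chain

    cid = 0
    for i in seed_order:
        if seeded[i] or not in_pool[i]:
            continue
        seeded[i] = True
        pool = np.nonzero(in_pool)[0]
        pool = pool[pool != i]
        if pool.size < 3:
            continue
        d, defect = geometry_from(i, pool)
        ok = (d >= lo) & (d <= hi) & (defect <= tol_deg)
        cand = pool[ok]
        if cand.size == 0:
            continue
        order = np.lexsort((d[ok], defect[ok]))
        accepted = None
        for j in cand[order]:
            chain = grow([i, int(j)], in_pool)
            if chain is not None and _valid_chain(x, y, o, chain, tol_deg):
                accepted = chain
                break
        if accepted is None:
            continue
        # canonical orientation: head precedes tail in row-major order
        if (y[accepted[0]], x[accepted[0]]) > (y[accepted[-1]], x[accepted[-1]]):
            accepted = accepted[::-1]
        sp = _chain_spacings(x, y, accepted)
        steps = _chain_steps(o, accepted)
        results.append(dict(
            contour_id=cid,
            members=tuple(index[k] for k in accepted),
            step_deg=float(steps.mean()),
            spacing_px=float(sp.mean()),
            member_x=tuple(x[k] for k in accepted),
            member_y=tuple(y[k] for k in accepted),
            member_orient=tuple(o[k] for k in accepted),
        ))
        cid += 1
        for k in accepted:
            seeded[k] = True
            if remove_members:
                in_pool[k] = False
    return pd.DataFrame(results, columns=out_cols)


# ---------------------------------------------------------------------------
# end elements


def _curvature_sign(step_deg: float) -> float:
    return 1.0 if step_deg >= 0 else -1.0


def extract_end_elements(
    contour: pd.Series | dict,
    edges: pd.DataFrame,
    tol_deg: float = DEFAULT_TOL_DEG,
) -> pd.DataFrame:
    """End elements continuing a mapped contour at either terminus.

    A candidate must lie one contour spacing (+- one fifth) from the
    terminal member, pair continuously with it, and sit in the forward
    half-plane: its direction from the terminal member within (-90, 90) deg
    of the outward contour direction. ``orientation_rel_deg`` is the
    candidate's orientation relative to the terminal member, multiplied by
    the local curvature sign so that positive always means continuing the
    curvature (at the head the traversal direction, hence the sign, flips).
    """
    xs = np.asarray(contour["member_x"], float)
    ys = np.asarray(contour["member_y"], float)
    os_ = np.asarray(contour["member_orient"], float)
    spacing = float(contour["spacing_px"])
    step = float(contour["step_deg"])
    members = set(contour["members"])

    ex = edges["x_px"].to_numpy(float)
    ey = edges["y_px"].to_numpy(float)
    eo = edges["orientation_deg"].to_numpy(float)
    not_member = ~edges.index.isin(list(members))

    records = []
    for end, ti, pi, sgn in (("tail", 3, 2, _curvature_sign(step)),
                             ("head", 0, 1, -_curvature_sign(step))):
        outward = np.degrees(np.arctan2(ys[ti] - ys[pi], xs[ti] - xs[pi]))
        dx, dy = ex - xs[ti], ey - ys[ti]
        d = np.hypot(dx, dy)
        with np.errstate(invalid="ignore"):
            direction = np.degrees(np.arctan2(dy, dx))
        sel = not_member & (d > 0) & (np.abs(d - spacing) <= SPACING_TOL_FRAC * np.minimum(d, spacing))
        sel &= np.abs(wrap180(direction - outward)) < 90.0
        phi = wrap90(direction - os_[ti])
        theta = wrap90(eo - os_[ti])
        sel &= np.abs(wrap90(theta - 2.0 * phi)) <= tol_deg
        rel = wrap90(eo - os_[ti]) * sgn
        for k in np.nonzero(sel)[0]:
            if abs(rel[k]) >= 90.0:
                continue
            records.append(dict(
                contour_id=contour["contour_id"], end=end,
                orientation_rel_deg=float(rel[k]),
                x_px=float(ex[k]), y_px=float(ey[k]),
                edge_index=int(edges.index[k]),
            ))
    return pd.DataFrame(records, columns=["contour_id", "end", "orientation_rel_deg",
                                          "x_px", "y_px", "edge_index"])


def extract_all_end_elements(contours: pd.DataFrame, edges: pd.DataFrame,
                             tol_deg: float = DEFAULT_TOL_DEG) -> pd.DataFrame:
    parts = [extract_end_elements(row, edges, tol_deg=tol_deg)
             for _, row in contours.iterrows()]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(columns=["contour_id", "end", "orientation_rel_deg",
                                     "x_px", "y_px", "edge_index"])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# binning


def length_bin_label(spacing_px: float) -> str:
    r = int(round(spacing_px))
    for lo, hi in LENGTH_BINS:
        if lo <= r <= hi:
            return f"{lo}-{hi}"
    return "unbinned"


def curvature_class(step_deg: float) -> float:
    """Nearest 10-deg curvature class of an (unsigned) orientation step."""
    c = int(round(abs(step_deg) / 10.0)) * 10
    return float(c) if c in CURVATURE_CLASSES else np.nan


def bin_contours(contours: pd.DataFrame) -> pd.DataFrame:
    """Counts per (curvature class, length bin); spacings outside 1-42 px
    fall into an 'unbinned' bucket."""
    labels = [f"{lo}-{hi}" for lo, hi in LENGTH_BINS] + ["unbinned"]
    table = pd.DataFrame(0, index=list(CURVATURE_CLASSES), columns=labels)
    table.index.name = "curvature_class_deg"
    if len(contours) == 0:
        return table
    for _, row in contours.iterrows():
        cls = curvature_class(row["step_deg"])
        if np.isnan(cls):
            continue
        table.loc[int(cls), length_bin_label(row["spacing_px"])] += 1
    return table


class ConstantCurvatureMapper(BaseEstimator, TransformerMixin):
    """Transformer: edge table -> (contours, end-element records).

    ``transform`` returns the contour DataFrame of :func:`find_contours`
    with ``length_bin`` and ``curvature_class_deg`` columns added;
    ``end_elements_`` holds the end records of the last transform.
    """

    def __init__(self, spacing_range_px: tuple[float, float] = SPACING_RANGE_PX,
                 tol_deg: float = DEFAULT_TOL_DEG, remove_members: bool = True):
        self.spacing_range_px = spacing_range_px
        self.tol_deg = tol_deg
        self.remove_members = remove_members

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        contours = find_contours(X, spacing_range_px=self.spacing_range_px,
                                 tol_deg=self.tol_deg,
                                 remove_members=self.remove_members)
        if len(contours):
            contours["length_bin"] = contours["spacing_px"].map(length_bin_label)
            contours["curvature_class_deg"] = contours["step_deg"].map(curvature_class)
        else:
            contours["length_bin"] = pd.Series(dtype=object)
            contours["curvature_class_deg"] = pd.Series(dtype=float)
        self.end_elements_ = extract_all_end_elements(contours, X, tol_deg=self.tol_deg)
        return contours
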