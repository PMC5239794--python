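"""Contour-in-noise stimulus construction.

Stimuli are 8 x 8 deg fields of 256 Gabor micro-patterns whose positions
are constrained to a 16 x 16 grid of 0.5 deg cells: exactly one element
centroid per cell, which keeps local density uniform so that a target
contour is revealed only by the orientation relations of its elements.

A target contour is a train of elements whose central members turn by a
constant curvature angle per step (0-40 deg); the two end elements are
displaced from the terminal members in a direction theta_e relative to the
terminal orientation, and their own orientation equals that direction.
Positive theta_e is toward the curvature side ("clockwise to the angle of
curvature"); for a C-shaped contour all steps share one sign, for an
S-shaped contour the step sign flips once at the path midpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gabor import GaborParams, PX_PER_DEG, gabor_value
from ._angles import orientation_mod180

__all__ = [
    "ContourSpec",
    "StimulusField",
    "PlacementError",
    "build_contour_path",
    "place_contour_in_grid",
    "fill_noise_and_render",
    "enumerate_conditions",
    "make_stimulus",
]

FIELD_DEG = 8.0
GRID_N = 16
CELL_DEG = FIELD_DEG / GRID_N  # 0.5 deg
FIELD_PX = int(FIELD_DEG * PX_PER_DEG)  # 512
BACKGROUND_LEVEL = 128  # mid-gray, stands in for the 45 cd/m^2 background


class PlacementError(RuntimeError):
    """Raised when no rigid motion fits the contour into the grid."""


@dataclass(frozen=True)
class ContourSpec:
    """Geometry of a target contour.

    ``curvature_angle_deg`` is the per-step orientation change of the
    central elements; ``end_direction_deg`` (theta_e) is the direction of
    each end element relative to the adjacent terminal element's
    orientation, positive toward the curvature side. ``n_elements`` is 6
    (4 central + 2 ends) or 4 (central elements only, the no-end baseline).
    """

    n_elements: int = 6
    curvature_angle_deg: float = 0.0
    end_direction_deg: float = 0.0
    end_separation_deg: float = 0.5
    core_separation_deg: float = 0.5
    shape: str = "C"

    def __post_init__(self) -> None:
        if self.n_elements not in (4, 6):
            raise ValueError(f"n_elements must be 4 or 6, got {self.n_elements}")
        if self.shape not in ("C", "S"):
            raise ValueError(f"shape must be 'C' or 'S', got {self.shape!r}")
        if self.core_separation_deg <= 0:
            raise ValueError("core_separation_deg must be positive")
        if self.n_elements == 6 and self.end_separation_deg <= 0:
            raise ValueError("end_separation_deg must be positive")

    @property
    def n_core(self) -> int:
        return 4

    def core_steps(self) -> np.ndarray:
        """Signed orientation steps between the four central elements."""
        a = float(self.curvature_angle_deg)
        if self.shape == "C":
            return np.array([a, a, a])
        # S: sign flips once, between central elements 2 and 3 (the path midpoint)
        return np.array([a, -a, -a])


@dataclass
class StimulusField:
    """A rendered stimulus with its ground truth.

    ``elements`` holds one row per micro-pattern with columns
    (element, x_deg, y_deg, orientation_deg, is_contour, cell_row, cell_col).
    ``image`` is the 8-bit grayscale raster (None until rendered).
    """

    elements: pd.DataFrame
    spec: ContourSpec | None
    seed: int
    image: np.ndarray | None = None
    background_level: int = BACKGROUND_LEVEL
    n_clipped_px: int = 0
    cell_exemptions: list = field(default_factory=list)


def build_contour_path(spec: ContourSpec) -> pd.DataFrame:
    """Lay out the contour in a local coordinate frame.

    Returns a DataFrame with columns (x_deg, y_deg, orientation_deg,
    is_end), ordered head to tail. The first central element sits at the
    origin with orientation 0; consecutive central elements are separated
    by ``core_separation_deg`` along the bisector of their orientations, so
    every adjacent pair is cocircular (the orientation difference is twice
    the relative direction).
    """
    steps = spec.core_steps()
    orients = np.concatenate([[0.0], np.cumsum(steps)])
    pos = [np.zeros(2)]
    for i in range(spec.n_core - 1):
        direction = np.deg2rad(0.5 * (orients[i] + orients[i + 1]))
        pos.append(pos[-1] + spec.core_separation_deg * np.array([np.cos(direction), np.sin(direction)]))
    pos = np.asarray(pos)

    rows = [
        {"x_deg": p[0], "y_deg": p[1], "orientation_deg": orientation_mod180(o), "is_end": False}
        for p, o in zip(pos, orients)
    ]

    if spec.n_elements == 6:
        def _sign(s: float) -> float:
            return 1.0 if s >= 0 else -1.0

        # tail end: direction theta_e from the last element's orientation,
        # positive toward the side the contour is turning
        tail_dir = orients[-1] + _sign(steps[-1]) * spec.end_direction_deg
        tv = np.deg2rad(tail_dir)
        tail_pos = pos[-1] + spec.end_separation_deg * np.array([np.cos(tv), np.sin(tv)])
        # head end: mirrored — outward is the reversed first orientation and
        # the curvature side flips when the path is traversed backwards
        head_dir = orients[0] + 180.0 - _sign(steps[0]) * spec.end_direction_deg
        hv = np.deg2rad(head_dir)
        head_pos = pos[0] + spec.end_separation_deg * np.array([np.cos(hv), np.sin(hv)])
        rows = (
            [{"x_deg": head_pos[0], "y_deg": head_pos[1],
              "orientation_deg": orientation_mod180(head_dir), "is_end": True}]
            + rows
            + [{"x_deg": tail_pos[0], "y_deg": tail_pos[1],
                "orientation_deg": orientation_mod180(tail_dir), "is_end": True}]
        )

    return pd.DataFrame(rows)


def _cell_of(x_deg: np.ndarray, y_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    col = np.floor(x_deg / CELL_DEG).astype(int)
    row = np.floor(y_deg / CELL_DEG).astype(int)
    return row, col


def place_contour_in_grid(
    path: pd.DataFrame,
    rng_seed: int,
    max_attempts: int = 10_000,
    allow_end_exemption: bool = False,
) -> pd.DataFrame:
    """Apply a random rigid motion until each element lands in its own cell.

    The path is rotated uniformly about its centroid and translated to a
    uniform position; a placement is accepted when every element centroid
    falls inside the 8 x 8 deg field and every *non-end* element occupies a
    distinct grid cell. With ``allow_end_exemption`` (used for the large
    end-element separations of the two-shape experiment) end elements may
    share a cell with another element; the sharing cell is flagged in the
    returned frame so the displaced noise element can be dropped to
    conserve density.

    Deterministic for a given ``rng_seed``. Raises :class:`PlacementError`
    when the attempt budget is exhausted.
    """
    rng = np.random.default_rng(rng_seed)
    xy = path[["x_deg", "y_deg"]].to_numpy()
    centroid = xy.mean(axis=0)
    xy0 = xy - centroid
    is_end = path["is_end"].to_numpy() if "is_end" in path else np.zeros(len(path), bool)
    span = np.linalg.norm(xy0, axis=1).max()
    if span > np.hypot(FIELD_DEG, FIELD_DEG) / 2:
        raise PlacementError("contour cannot fit inside the field under any rigid motion")

    for _ in range(max_attempts):
        rot = rng.uniform(0.0, 360.0)
        th = np.deg2rad(rot)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = xy0 @ R.T
        center = rng.uniform(0.0, FIELD_DEG, size=2)
        placed = rotated + center
        if placed.min() < 0 or placed.max() >= FIELD_DEG:
            continue
        row, col = _cell_of(placed[:, 0], placed[:, 1])
        cells = list(zip(row, col))
        core_cells = [c for c, e in zip(cells, is_end) if not e]
        if len(set(core_cells)) != len(core_cells):
            continue
        shared = [c for c, e in zip(cells, is_end) if e and cells.count(c) > 1]
        if shared and not allow_end_exemption:
            continue
        out = path.copy()
        out["x_deg"] = placed[:, 0]
        out["y_deg"] = placed[:, 1]
        out["orientation_deg"] = orientation_mod180(path["orientation_deg"].to_numpy() + rot)
        out["cell_row"] = row
        out["cell_col"] = col
        out.attrs["shared_cells"] = shared
        out.attrs["rotation_deg"] = rot
        return out
    raise PlacementError(f"no valid placement found in {max_attempts} attempts")


def fill_noise_and_render(
    placed: pd.DataFrame,
    rng_seed: int,
    gabor: GaborParams | None = None,
    contrast: float = 1.0,
    render: bool = True,
    spec: ContourSpec | None = None,
) -> StimulusField:
    """Fill every empty grid cell with a random element and rasterise.

    Noise elements take a uniform orientation on [0, 180) and a uniform
    centroid within their cell. Patches are composited additively in
    contrast space on the mid-gray background and mapped to 8-bit; pixels
    forced outside the displayable range are clipped and counted.
    """
    rng = np.random.default_rng(rng_seed)
    gabor = gabor or GaborParams()

    rows = []
    occupied: set[tuple[int, int]] = set()
    shared = set(map(tuple, placed.attrs.get("shared_cells", [])))
    for _, r in placed.iterrows():
        rows.append(
            dict(x_deg=r.x_deg, y_deg=r.y_deg, orientation_deg=r.orientation_deg,
                 is_contour=True, cell_row=int(r.cell_row), cell_col=int(r.cell_col))
        )
        occupied.add((int(r.cell_row), int(r.cell_col)))
    for cr in range(GRID_N):
        for cc in range(GRID_N):
            if (cr, cc) in occupied:
                continue
            x = (cc + rng.uniform()) * CELL_DEG
            y = (cr + rng.uniform()) * CELL_DEG
            rows.append(
                dict(x_deg=x, y_deg=y, orientation_deg=rng.uniform(0.0, 180.0),
                     is_contour=False, cell_row=cr, cell_col=cc)
            )
    elements = pd.DataFrame(rows)
    elements.insert(0, "element", np.arange(len(elements)))

    fld = StimulusField(elements=elements, spec=spec, seed=rng_seed,
                        cell_exemptions=sorted(shared))
    if render:
        img = np.zeros((FIELD_PX, FIELD_PX))
        half = int(np.ceil(4 * gabor.sigma_px))
        for _, e in elements.iterrows():
            cx = e.x_deg * PX_PER_DEG
            cy = e.y_deg * PX_PER_DEG
            c0, r0 = int(round(cx)), int(round(cy))
            rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, FIELD_PX))
            cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, FIELD_PX))
            if rr.size == 0 or cc.size == 0:
                continue
            ys, xs = np.meshgrid(rr - cy, cc - cx, indexing="ij")
            img[np.ix_(rr, cc)] += contrast * gabor_value(gabor, e.orientation_deg, xs, ys)
        raw = BACKGROUND_LEVEL + 127.0 * img
        fld.n_clipped_px = int(np.count_nonzero((raw < 0) | (raw > 255)))
        fld.image = np.clip(np.rint(raw), 0, 255).astype(np.uint8)
    return fld


def enumerate_conditions(experiment: int) -> pd.DataFrame:
    """Tabulate the stimulus conditions of the two detection experiments.

    Experiment 1: 5 contour angles x 10 end directions = 50 conditions
    (25 repeats per condition per block, 1250 trials/block). The
    inter-element distance is 0.75 deg for the straight contour and
    0.5 deg otherwise. Experiment 2: contour angle fixed at 30 deg,
    5 end separations x {C, S} x {collinear 0, cocircular 30} = 20
    conditions plus two 4-element no-end baselines, flagged.
    """
    if experiment == 1:
        angles = [0, 10, 20, 30, 40]
        end_dirs = [-30, -20, -10, 0, 10, 20, 30, 40, 50, 60]
        rows = []
        for a in angles:
            sep = 0.75 if a == 0 else 0.5
            for e in end_dirs:
                rows.append(dict(experiment=1, contour_angle_deg=a, end_direction_deg=e,
                                 core_separation_deg=sep, end_separation_deg=sep,
                                 shape="C", n_elements=6, is_baseline=False,
                                 reps_per_block=25))
        return pd.DataFrame(rows)
    if experiment == 2:
        rows = []
        for sep in [0.5, 0.75, 1.0, 1.5, 2.0]:
            for shape in ["C", "S"]:
                for e in [0, 30]:
                    rows.append(dict(experiment=2, contour_angle_deg=30,
                                     end_direction_deg=e, core_separation_deg=0.5,
                                     end_separation_deg=sep, shape=shape,
                                     n_elements=6, is_baseline=False,
                                     reps_per_block=50))
        for shape in ["C", "S"]:
            rows.append(dict(experiment=2, contour_angle_deg=30, end_direction_deg=np.nan,
                             core_separation_deg=0.5, end_separation_deg=np.nan,
                             shape=shape, n_elements=4, is_baseline=True,
                             reps_per_block=50))
        return pd.DataFrame(rows)
    raise ValueError(f"experiment must be 1 or 2, got {experiment}")


def make_stimulus(spec: ContourSpec, seed: int, target_present: bool = True,
                  max_placement_retries: int = 10, **render_kw) -> StimulusField:
    """Convenience wrapper: path -> placement -> noise fill -> raster.

    On a placement failure the seed is re-derived (documented offset stream)
    up to ``max_placement_retries`` times. A target-absent field skips the
    contour entirely and contains 256 noise elements.
    """
    if not target_present:
        empty = pd.DataFrame(columns=["x_deg", "y_deg", "orientation_deg",
                                      "is_end", "cell_row", "cell_col"])
        return fill_noise_and_render(empty, rng_seed=seed, spec=spec, **render_kw)
    path = build_contour_path(spec)
    allow_ex = spec.n_elements == 6 and spec.end_separation_deg > CELL_DEG
    last_err: Exception | None = None
    for k in range(max_placement_retries):
        try:
            placed = place_contour_in_grid(path, rng_seed=seed + 1_000_003 * k,
                                           allow_end_exemption=allow_ex)
            return fill_noise_and_render(placed, rng_seed=seed, spec=spec, **render_kw)
        except PlacementError as err:  # retry with a fresh stream
            last_err = err
    raise PlacementError(f"placement failed after {max_placement_retries} seeds") from last_err


def save_stimulus(fld: StimulusField, out_dir: str | Path, stem: str) -> None:
    """Write the raster (PNG), ground truth (CSV) and spec sidecar (JSON)."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fld.image is not None:
        Image.fromarray(fld.image, mode="L").save(out / f"{stem}.png")
    fld.elements.to_csv(out / f"{stem}.csv", index=False)
    sidecar = {"seed": fld.seed, "spec": asdict(fld.spec) if fld.spec else None,
               "n_clipped_px": fld.n_clipped_px,
               "cell_exemptions": [list(c) for c in fld.cell_exemptions]}
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
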