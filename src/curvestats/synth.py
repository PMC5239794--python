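"""Synthetic image surrogates and simulated response tables.

This module generates every fixture the analysis pipeline needs without any
external corpus: grayscale images with *planted* chains of equally spaced,
constantly turning edge elements over configurable backgrounds, plus
simulated two-interval forced-choice response tables drawn from a known
tuning surface.

Planted elements are rendered by default as odd-symmetric (edge-polarity)
Gabor micro-edges: a local luminance step windowed by a Gaussian. An odd
element puts the band-pass zero crossing exactly at the element centre,
which is what a log-Gabor edge detector localises; an even ridge (a drawn
line segment) would put the crossings on its flanks instead. A
line-segment render style is available for qualitative use.

The default corpus emulates the qualitative structure of curved contours in
natural scenes: low-curvature chains outnumber high-curvature ones, and the
planted continuation (end) elements are concentrated at the curvature step,
i.e. they continue "clockwise" along the curvature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._angles import orientation_mod180, wrap90
from .edges import ANALYSIS_RADIUS_PX

__all__ = [
    "PlantedContourSpec",
    "CorpusManifest",
    "render_planted_image",
    "generate_corpus",
    "generate_responses",
    "default_manifest",
    "EXP1_SURFACE",
]

IMAGE_SIZE_PX = 480
ELEMENT_LAMBDA_PX = 10.0  # matched to the detector's 0.1 c/px peak
ELEMENT_SIGMA_PX = 2.0


@dataclass(frozen=True)
class PlantedContourSpec:
    """One planted constant-curvature chain.

    ``step_deg`` is the signed orientation change per element,
    ``end_offset_deg`` the orientation of the two planted continuation
    elements relative to the curvature direction (None plants no ends).
    ``start_xy`` is the first member's pixel position and
    ``start_orientation_deg`` its orientation.
    """

    step_deg: float
    spacing_px: float
    n_elements: int = 4
    start_xy: tuple[float, float] = (240.0, 240.0)
    start_orientation_deg: float = 0.0
    end_offset_deg: float | None = None
    contrast: float = 0.5
    style: str = "edge"  # "edge" (odd micro-edge) | "segment" (drawn line)

    def __post_init__(self) -> None:
        if self.n_elements < 4:
            raise ValueError("planted chains need at least 4 elements")
        if not 1.0 <= self.spacing_px <= 42.0:
            raise ValueError("spacing_px must lie in the mapped range 1-42 px")
        if self.style not in ("edge", "segment"):
            raise ValueError(f"unknown element style {self.style!r}")


@dataclass
class CorpusManifest:
    """Recipe for a reproducible synthetic corpus.

    ``class_counts`` gives planted chains per image per curvature class;
    the default decreases with curvature. ``end_offset`` may be the string
    'equal_step' (plant continuations at the curvature step) or a number in
    degrees. Backgrounds: 'uniform' | 'onef' (1/f noise) | 'distractors'.
    """

    n_images: int = 50
    class_counts: dict = field(default_factory=lambda: {0: 2, 10: 2, 20: 1, 30: 1, 40: 1})
    spacing_px: float = 20.0
    end_offset: str | float = "equal_step"
    end_offset_sd: float = 0.0     # per-chain Gaussian jitter of the offset
    background: str = "uniform"
    noise_sigma: float = 0.0       # contrast SD of the 1/f background
    distractor_density: float = 0.0  # elements per image for 'distractors'
    contrast: float = 0.5
    master_seed: int = 0


def planted_chain_truth(spec: PlantedContourSpec) -> pd.DataFrame:
    """Positions/orientations of a planted chain (members plus any ends).

    Members are chained cocircularly: each displacement direction bisects
    the adjacent orientations, so every consecutive pair satisfies the
    theta = 2 phi continuity rule exactly. Continuation elements are placed
    one spacing beyond each terminus so that their pairing with the
    terminal member is continuous and their orientation sits at
    ``end_offset_deg`` from the terminal orientation *toward the curvature
    direction* (the sign flips at the head, where outward traversal
    reverses the turn).
    """
    s = spec.step_deg
    orients = spec.start_orientation_deg + s * np.arange(spec.n_elements)
    pos = [np.array(spec.start_xy, dtype=float)]
    for i in range(spec.n_elements - 1):
        direction = np.deg2rad(orients[i] + s / 2.0)
        pos.append(pos[-1] + spec.spacing_px * np.array([np.cos(direction), np.sin(direction)]))
    pos = np.asarray(pos)
    rows = [dict(x_px=p[0], y_px=p[1], orientation_deg=orientation_mod180(o),
                 kind="member", element=i)
            for i, (p, o) in enumerate(zip(pos, orients))]

    if spec.end_offset_deg is not None:
        rho = float(spec.end_offset_deg)
        sgn_tail = 1.0 if s >= 0 else -1.0
        for end, ti, pi, sgn in (("tail", -1, -2, sgn_tail), ("head", 0, 1, -sgn_tail)):
            outward = np.degrees(np.arctan2(pos[ti][1] - pos[pi][1],
                                            pos[ti][0] - pos[pi][0]))
            e_or = orients[ti] + sgn * rho
            theta = wrap90(e_or - orients[ti])
            direction = orients[ti] + theta / 2.0
            # the continuity rule fixes the direction only mod 180; take the
            # branch pointing outward from the chain
            if np.cos(np.deg2rad(direction - outward)) < 0:
                direction += 180.0
            dv = np.deg2rad(direction)
            p = pos[ti] + spec.spacing_px * np.array([np.cos(dv), np.sin(dv)])
            rows.append(dict(x_px=p[0], y_px=p[1],
                             orientation_deg=orientation_mod180(e_or),
                             kind=f"end_{end}", element=-1))
    df = pd.DataFrame(rows)
    df["step_deg"] = s
    df["spacing_px"] = spec.spacing_px
    return df


def _render_element(img: np.ndarray, x: float, y: float, orientation_deg: float,
                    contrast: float, style: str,
                    sigma: float = ELEMENT_SIGMA_PX,
                    lam: float = ELEMENT_LAMBDA_PX) -> None:
    half = int(np.ceil(4 * sigma))
    r0, c0 = int(round(y)), int(round(x))
    rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, img.shape[0]))
    cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, img.shape[1]))
    if rr.size == 0 or cc.size == 0:
        return
    ys, xs = np.meshgrid(rr - y, cc - x, indexing="ij")
    th = np.deg2rad(orientation_deg)
    t = xs * np.cos(th) + ys * np.sin(th)      # along the element
    p = -xs * np.sin(th) + ys * np.cos(th)     # across the element
    env = np.exp(-(t**2 + p**2) / (2.0 * sigma**2))
    if style == "edge":
        patch = contrast * env * np.sin(2.0 * np.pi * p / lam)
    else:  # "segment": an even ridge
        patch = contrast * env
    img[np.ix_(rr, cc)] += patch


def _background(shape: tuple[int, int], kind: str, noise_sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    bg = np.full(shape, 0.5)
    if kind == "onef" and noise_sigma > 0:
        u = np.fft.fftfreq(shape[1])[None, :]
        v = np.fft.fftfreq(shape[0])[:, None]
        r = np.hypot(u, v)
        amp = np.zeros_like(r)
        amp[r > 0] = 1.0 / r[r > 0]
        phase = np.exp(2j * np.pi * rng.random(shape))
        noise = np.real(np.fft.ifft2(amp * phase))
        noise *= noise_sigma / noise.std()
        bg += noise
    return bg


def render_planted_image(
    specs: list[PlantedContourSpec],
    seed: int,
    size_px: int = IMAGE_SIZE_PX,
    background: str = "uniform",
    noise_sigma: float = 0.0,
    distractor_density: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render planted chains over a background.

    Returns ``(image, truth)``: a float image in [0, 1] and the ground
    truth listing every planted element (members and ends) with its
    contour id. Distractor elements with uniform random position and
    orientation are added for ``background='distractors'``. Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    img = _background((size_px, size_px), background, noise_sigma, rng)
    truths = []
    for k, spec in enumerate(specs):
        truth = planted_chain_truth(spec)
        r = np.hypot(truth["x_px"] - (size_px - 1) / 2.0,
                     truth["y_px"] - (size_px - 1) / 2.0)
        if (r > ANALYSIS_RADIUS_PX).any():
            raise ValueError(
                f"planted chain {k} leaves the {ANALYSIS_RADIUS_PX} px analysis radius")
        for _, e in truth.iterrows():
            _render_element(img, e.x_px, e.y_px, e.orientation_deg,
                            spec.contrast, spec.style)
        truth = truth.copy()
        truth.insert(0, "contour_id", k)
        truths.append(truth)
    n_distract = int(distractor_density) if background == "distractors" else 0
    for _ in range(n_distract):
        _render_element(img, rng.uniform(0, size_px), rng.uniform(0, size_px),
                        rng.uniform(0, 180.0), 0.5, "edge")
    truth_df = (pd.concat(truths, ignore_index=True) if truths
                else pd.DataFrame(columns=["contour_id", "x_px", "y_px",
                                           "orientation_deg", "kind", "element",
                                           "step_deg", "spacing_px"]))
    return np.clip(img, 0.0, 1.0), truth_df


def _place_chains(manifest: CorpusManifest, rng: np.random.Generator,
                  max_attempts: int = 200) -> list[PlantedContourSpec]:
    """Random non-overlapping placements for one image's chains."""
    size = IMAGE_SIZE_PX
    center = (size - 1) / 2.0
    specs: list[PlantedContourSpec] = []
    occupied: list[np.ndarray] = []
    min_clearance = 3.0 * manifest.spacing_px
    for cls, count in sorted(manifest.class_counts.items()):
        for _ in range(count):
            step = float(cls) * rng.choice([-1.0, 1.0])
            rho = float(abs(step) if manifest.end_offset == "equal_step"
                        else manifest.end_offset)
            if manifest.end_offset_sd > 0:
                rho = float(np.clip(rho + rng.normal(0.0, manifest.end_offset_sd),
                                    -85.0, 85.0))
            placed = None
            for _ in range(max_attempts):
                start = np.array([rng.uniform(center - 150, center + 150),
                                  rng.uniform(center - 150, center + 150)])
                spec = PlantedContourSpec(
                    step_deg=step, spacing_px=manifest.spacing_px,
                    start_xy=tuple(start),
                    start_orientation_deg=rng.uniform(0, 180.0),
                    end_offset_deg=rho, contrast=manifest.contrast)
                truth = planted_chain_truth(spec)
                pts = truth[["x_px", "y_px"]].to_numpy()
                r = np.hypot(pts[:, 0] - center, pts[:, 1] - center)
                if (r > ANALYSIS_RADIUS_PX - 10).any():
                    continue
                if occupied and min(
                    np.hypot(*(pts[:, None, :] - q[None, :, :]).transpose(2, 0, 1)).min()
                    for q in occupied
                ) < min_clearance:
                    continue
                placed = (spec, pts)
                break
            if placed is None:
                continue  # crowded image: skip this chain, keep going
            specs.append(placed[0])
            occupied.append(placed[1])
    return specs


def generate_corpus(
    manifest: CorpusManifest, out_dir: str | Path | None = None
) -> list[tuple[np.ndarray, pd.DataFrame]]:
    """Generate a corpus of planted images with ground truth.

    Bit-reproducible from the manifest's master seed. When ``out_dir`` is
    given, images are written as 8-bit PNG with CSV ground truth and the
    manifest as JSON.
    """
    out = []
    for i in range(manifest.n_images):
        seed = manifest.master_seed + i
        rng = np.random.default_rng((manifest.master_seed, 7919, i))
        specs = _place_chains(manifest, rng)
        img, truth = render_planted_image(
            specs, seed=seed, background=manifest.background,
            noise_sigma=manifest.noise_sigma,
            distractor_density=manifest.distractor_density)
        truth.insert(0, "image", i)
        out.append((img, truth))
    if out_dir is not None:
        from PIL import Image

        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for i, (img, truth) in enumerate(out):
            Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(
                out_path / f"img_{i:04d}.png")
            truth.to_csv(out_path / f"img_{i:04d}_truth.csv", index=False)
        (out_path / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return out


def default_manifest(**overrides) -> CorpusManifest:
    return CorpusManifest(**overrides)


#: tuning surface emulating the group-average detection results of the
#: six-element contour experiment: amplitude falls with curvature angle,
#: the best end direction sits slightly below the curvature angle, and the
#: tuning width is broad (~61 deg; flat at 40 deg where detection nears
#: chance).
EXP1_SURFACE = pd.DataFrame({
    "contour_angle_deg": [0, 10, 20, 30, 40],
    "A": [0.908, 0.834, 0.773, 0.687, 0.566],
    "M": [0.0, 8.054, 13.63, 23.618, 2.76],
    "SD": [61.0, 61.0, 61.0, 61.0, 92.0],
})


def generate_responses(
    experiment: int,
    n_trials: int = 200,
    seed: int = 0,
    surface: pd.DataFrame | None = None,
    n_observers: int = 1,
    out_dir: str | Path | None = None,
) -> list[pd.DataFrame]:
    """Simulated response tables for the two detection experiments.

    Experiment 1 samples the 50-condition grid from ``surface`` (defaults
    to :data:`EXP1_SURFACE`); experiment 2 samples its 20 conditions plus
    the two 4-element baselines from a plausible performance table
    (separation-dependent, shape x end-orientation crossover, baselines at
    chance). One table per observer.
    """
    from .stimulus import enumerate_conditions
    from .psychometrics import simulate_observer

    conditions = enumerate_conditions(experiment)
    tables = []
    for obs in range(n_observers):
        obs_seed = np.random.SeedSequence((seed, experiment, obs)).generate_state(1)[0]
        if experiment == 1:
            surf = surface if surface is not None else EXP1_SURFACE
            tbl = simulate_observer(surf, conditions, n_trials, int(obs_seed))
        else:
            cond = conditions.copy()
            cond["p_correct"] = [
                _exp2_probability(r) for _, r in cond.iterrows()]
            rng = np.random.default_rng(int(obs_seed))
            cond["n_trials"] = n_trials
            cond["n_correct"] = rng.binomial(n_trials, cond["p_correct"])
            cond["proportion"] = cond["n_correct"] / n_trials
            tbl = cond
        tbl = tbl.copy()
        tbl.insert(0, "observer", obs)
        tables.append(tbl)
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        for obs, tbl in enumerate(tables):
            tbl.to_csv(out_path / f"exp{experiment}_obs{obs}.csv", index=False)
    return tables


def _exp2_probability(row) -> float:
    """Plausible detection probability for a 30-deg contour condition.

    Performance decays with end-element separation toward the 4-element
    baseline (near chance); at small separations cocircular ends help the
    C shape and collinear ends help the S shape.
    """
    if bool(row.get("is_baseline", False)):
        return 0.55
    sep = float(row["end_separation_deg"])
    cocircular = float(row["end_direction_deg"]) == 30.0
    matched = (cocircular and row["shape"] == "C") or (not cocircular and row["shape"] == "S")
    top = 0.85 if matched else 0.70
    frac = (sep - 0.5) / 1.5  # 0 at the closest separation, 1 at the farthest
    return float(top - (top - 0.55) * min(max(frac, 0.0), 1.0))
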