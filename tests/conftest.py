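"""Shared fixtures and independent reference implementations.

The oracle here re-derives the contour-mapping criteria from first
principles (pairwise geometry recomputed inline, exhaustive enumeration of
ordered 4-tuples pruned only by the pairwise continuity predicate) so that
it stays independent of the greedy search it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def oracle_chains(df: pd.DataFrame, tol: float = 5.0) -> set[tuple[int, ...]]:
    """All ordered 4-tuples satisfying the four mapping criteria.

    Exhaustive (constraint-pruned) enumeration; returns canonical tuples
    (head before tail in row-major order).
    """
    x = df["x_px"].to_numpy(float)
    y = df["y_px"].to_numpy(float)
    o = df["orientation_deg"].to_numpy(float)
    n = len(df)
    dx = x[None, :] - x[:, None]
    dy = y[None, :] - y[:, None]
    d = np.hypot(dx, dy)
    direc = np.degrees(np.arctan2(dy, dx))
    phi = (direc - o[:, None] + 90.0) % 180.0 - 90.0
    th = (o[None, :] - o[:, None] + 90.0) % 180.0 - 90.0
    defect = np.abs((th - 2.0 * phi + 90.0) % 180.0 - 90.0)
    cont = (defect <= tol) & (d > 0)
    np.fill_diagonal(cont, False)
    adj = [np.nonzero(cont[i])[0] for i in range(n)]
    sols: set[tuple[int, ...]] = set()
    for a, b in np.argwhere(cont):
        for c in adj[b]:
            if c == a or abs(d[b, c] - d[a, b]) > min(d[a, b], d[b, c]) / 5:
                continue
            for e in adj[c]:
                if e in (a, b) or abs(d[c, e] - d[b, c]) > min(d[b, c], d[c, e]) / 5:
                    continue
                sp = np.array([d[a, b], d[b, c], d[c, e]])
                if not 0.8 <= sp.mean() <= 50.4:
                    continue
                st = np.array([th[a, b], th[b, c], th[c, e]])
                if np.any(np.abs(st - st.mean()) > tol):
                    continue
                if st.max() > tol and st.min() < -tol:
                    continue
                if (y[a], x[a]) <= (y[e], x[e]):
                    sols.add((int(a), int(b), int(c), int(e)))
                else:
                    sols.add((int(e), int(c), int(b), int(a)))
    return sols


def chain_coordinates(step_deg: float, spacing: float, n: int,
                      start=(0.0, 0.0), start_orient: float = 0.0) -> pd.DataFrame:
    """Exact cocircular chain laid out independently of the package.

    Element i has orientation start + i*step; the displacement from i to
    i+1 points along the bisector of the two orientations, so theta = 2 phi
    holds exactly for every consecutive pair.
    """
    orients = start_orient + step_deg * np.arange(n)
    pos = [np.asarray(start, float)]
    for i in range(n - 1):
        ang = np.deg2rad(orients[i] + step_deg / 2.0)
        pos.append(pos[-1] + spacing * np.array([np.cos(ang), np.sin(ang)]))
    pos = np.asarray(pos)
    return pd.DataFrame({"x_px": pos[:, 0], "y_px": pos[:, 1],
                         "orientation_deg": orients % 180.0})


def structured_edge_field(rng: np.random.Generator, n_chains: int = 3,
                          n_noise: int = 25, jitter: float = 1.0,
                          orient_jitter: float = 2.0) -> pd.DataFrame:
    """Edge field mixing jittered chains with uniform random distractors."""
    frames = []
    for _ in range(n_chains):
        step = float(rng.choice([0, 10, 20, 30, 40]) * rng.choice([-1, 1]))
        spacing = float(rng.uniform(8, 30))
        chain = chain_coordinates(step, spacing, 5,
                                  start=rng.uniform(30, 170, 2),
                                  start_orient=float(rng.uniform(0, 180)))
        chain["x_px"] += rng.normal(0, jitter, len(chain))
        chain["y_px"] += rng.normal(0, jitter, len(chain))
        chain["orientation_deg"] = (chain["orientation_deg"]
                                    + rng.normal(0, orient_jitter, len(chain))) % 180.0
        frames.append(chain)
    frames.append(pd.DataFrame({
        "x_px": rng.uniform(0, 200, n_noise),
        "y_px": rng.uniform(0, 200, n_noise),
        "orientation_deg": rng.uniform(0, 180, n_noise),
    }))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def planted_image():
    """One noise-free planted image with its ground truth (session cache)."""
    from curvestats.synth import PlantedContourSpec, render_planted_image

    spec = PlantedContourSpec(step_deg=20, spacing_px=20, start_xy=(200, 220),
                              start_orientation_deg=30, end_offset_deg=20)
    return render_planted_image([spec], seed=1)


@pytest.fixture(scope="session")
def planted_edges(planted_image):
    from curvestats.edges import detect_edges

    img, _ = planted_image
    return detect_edges(img)
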