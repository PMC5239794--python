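"""End-to-end orchestration with config, logging and provenance.

Two pipelines are provided. The image pipeline runs
synthesise (optional) -> prepare -> edge extraction -> contour mapping ->
statistics per image and merges the results; the psychophysics pipeline
runs condition enumeration -> simulated observers -> per-observer Gaussian
tuning fits -> group summary. Each run serialises its full configuration
and the library versions used into the output directory, and per-stage
counts are logged so silent failures are visible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edges import LogGaborEdgeDetector
from .mapping import ConstantCurvatureMapper
from .psychometrics import fit_tuning_by_angle
from .stats import summarize_corpus
from .synth import CorpusManifest, generate_corpus, generate_responses

__all__ = ["RunConfig", "run_image_pipeline", "run_psychophysics_pipeline"]

log = logging.getLogger("curvestats")

EXIT_OK, EXIT_VALIDATION, EXIT_COMPUTE = 0, 1, 2


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # image pipeline
    synth: dict = field(default_factory=dict)     # CorpusManifest overrides
    input_dir: str | None = None                  # read images instead of synth
    edges: dict = field(default_factory=dict)     # LogGaborEdgeDetector params
    mapping: dict = field(default_factory=dict)   # ConstantCurvatureMapper params
    make_plots: bool = False
    # psychophysics pipeline
    experiment: int = 1
    n_observers: int = 6
    n_trials: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        if self.experiment not in (1, 2):
            raise ValueError(f"experiment must be 1 or 2, got {self.experiment}")
        if self.n_trials <= 0 or self.n_observers < 0:
            raise ValueError("n_trials must be positive and n_observers >= 0")
        valid_manifest = set(CorpusManifest.__dataclass_fields__)
        unknown = set(self.synth) - valid_manifest
        if unknown:
            raise ValueError(f"unknown synth manifest keys: {sorted(unknown)}")


def _write_provenance(cfg: RunConfig, out: Path) -> None:
    import curvestats

    versions = {"curvestats": curvestats.__version__,
                "numpy": np.__version__, "pandas": pd.__version__}
    try:
        import scipy, skimage, sklearn  # noqa: E401

        versions.update(scipy=scipy.__version__, scikit_image=skimage.__version__,
                        scikit_learn=sklearn.__version__)
    except Exception:  # pragma: no cover
        pass
    (out / "run_manifest.json").write_text(
        json.dumps({"config": asdict(cfg), "versions": versions}, indent=2))


def _load_images(input_dir: str) -> list[tuple[np.ndarray, pd.DataFrame | None]]:
    from PIL import Image

    items = []
    for p in sorted(Path(input_dir).glob("*.png")):
        items.append((np.asarray(Image.open(p)), None))
    return items


def run_image_pipeline(cfg: RunConfig) -> dict:
    """Execute the full image-statistics pipeline; returns the summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_provenance(cfg, out)

    if cfg.input_dir is not None:
        corpus = _load_images(cfg.input_dir)
    else:
        manifest = CorpusManifest(master_seed=cfg.seed, **cfg.synth)
        corpus = generate_corpus(manifest)
        log.info("synthesised %d images", len(corpus))

    detector = LogGaborEdgeDetector(**cfg.edges).fit()
    mapper = ConstantCurvatureMapper(**cfg.mapping).fit()

    all_contours, all_ends = [], []
    for i, (img, _truth) in enumerate(corpus):
        try:
            edge_tbl = detector.transform(img)
            contours = mapper.transform(edge_tbl)
            ends = mapper.end_elements_
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"image {i}: edge/mapping stage failed") from err
        log.info("image %d: %d edges, %d contours, %d end records",
                 i, len(edge_tbl), len(contours), len(ends))
        if len(contours):
            contours = contours.copy()
            ends = ends.copy()
            contours["image"] = i
            contours["contour_id"] = contours["contour_id"].astype(str).radd(f"{i}_")
            ends["contour_id"] = ends["contour_id"].astype(str).radd(f"{i}_")
            all_contours.append(contours)
            all_ends.append(ends)

    contours = (pd.concat(all_contours, ignore_index=True) if all_contours
                else pd.DataFrame(columns=["contour_id", "step_deg", "spacing_px",
                                           "length_bin", "curvature_class_deg"]))
    ends = (pd.concat(all_ends, ignore_index=True) if all_ends
            else pd.DataFrame(columns=["contour_id", "end", "orientation_rel_deg"]))

    flat = contours.drop(columns=["members", "member_x", "member_y", "member_orient"],
                         errors="ignore")
    flat.to_csv(out / "contours.csv", index=False)
    ends.to_csv(out / "ends.csv", index=False)

    summary = summarize_corpus(contours, ends)
    summary["counts"].to_csv(out / "counts_by_curvature.csv")
    dist_frames = [d.to_frame() for d in summary["distributions"].values()]
    pd.concat(dist_frames, ignore_index=True).to_csv(out / "distributions.csv", index=False)
    fits = {int(k): v.to_dict() for k, v in summary["fits"].items()}
    blob = {"fits": fits,
            "trend": summary["trend"].to_dict() if summary["trend"] else None,
            "n_contours": int(len(contours)), "n_end_records": int(len(ends))}
    (out / "summary.json").write_text(json.dumps(blob, indent=2))

    if cfg.make_plots:
        _plot_summary(summary, out)
    return summary


def _plot_summary(summary: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    counts = summary["counts"]
    axes[0].bar(counts.index, counts.values, width=8)
    axes[0].set_xlabel("curvature angle (deg)")
    axes[0].set_ylabel("mapped contours")
    for cls, dist in summary["distributions"].items():
        axes[1].plot(dist.bin_centers_deg, dist.normalized_frequency,
                     marker="o", ms=3, label=f"{cls} deg")
    axes[1].set_xlabel("end-element orientation (deg)")
    axes[1].set_ylabel("normalised frequency")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=150)
    plt.close(fig)


def run_psychophysics_pipeline(cfg: RunConfig) -> dict:
    """Simulate observers on a condition grid and fit tuning per angle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_provenance(cfg, out)

    tables = generate_responses(cfg.experiment, n_trials=cfg.n_trials,
                                seed=cfg.seed, n_observers=cfg.n_observers)
    if not tables:
        log.warning("zero observers requested; writing empty summary")
        (out / "group_fits.csv").write_text("")
        return {"observer_fits": pd.DataFrame(), "group": pd.DataFrame()}

    responses = pd.concat(tables, ignore_index=True)
    responses.to_csv(out / "responses.csv", index=False)

    fits = []
    if cfg.experiment == 1:
        for obs, tbl in responses.groupby("observer"):
            f = fit_tuning_by_angle(tbl)
            f.insert(0, "observer", obs)
            fits.append(f)
        observer_fits = pd.concat(fits, ignore_index=True)
        # group means over clean fits only; degenerate (flat/diverged) fits
        # are counted, not averaged
        clean = observer_fits[~observer_fits["degenerate"]]
        group = clean.groupby("contour_angle_deg")[["A", "M", "SD", "r2"]].mean()
        group["n_degenerate"] = (observer_fits[observer_fits["degenerate"]]
                                 .groupby("contour_angle_deg").size())
        group["n_degenerate"] = group["n_degenerate"].fillna(0).astype(int)
        group = group.reindex(sorted(observer_fits["contour_angle_deg"].unique()))
        observer_fits.to_csv(out / "observer_fits.csv", index=False)
        group.to_csv(out / "group_fits.csv")
    else:
        observer_fits = pd.DataFrame()
        group = (responses[~responses["is_baseline"]]
                 .groupby(["shape", "end_direction_deg", "end_separation_deg"])
                 ["proportion"].mean().reset_index())
        group.to_csv(out / "group_means.csv", index=False)
    log.info("fitted %d observers (experiment %d)", cfg.n_observers, cfg.experiment)
    return {"observer_fits": observer_fits, "group": group}
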