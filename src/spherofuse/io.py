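"""File I/O, run configuration and the end-to-end pipeline driver.

The pipeline ties the modules into the complete workflow: detect microwells
in the first frame, select doublet candidates (all wells, a manual selection
file, or a trained classifier), track and segment each selected doublet,
extract the per-frame feature matrix, and fit the kinetic models.  All
tabular artifacts are CSV, images are multi-page grayscale TIFF, and the run
configuration is a YAML file whose saved copy reproduces a run bit-for-bit
given identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify, features, kinetics, microwell, segment
from .phantom import FrameStack

__all__ = ["RunConfig", "run_pipeline", "load_stack", "save_stack",
           "save_masks"]

log = logging.getLogger("spherofuse")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    input_path: str
    output_dir: str
    pixel_size: float = 1.6           # um / px
    frame_interval: float = 5.0       # minutes
    acquisition_delay_h: float = 1.0  # delay before the first frame (metadata)
    well_radius_range: tuple[float, float] = (50.0, 75.0)  # px
    selection: str = "all"            # all | manual | classifier
    manual_wells: str | None = None   # CSV with x,y columns
    classifier_model: str | None = None
    exclude_wells: str | None = None  # CSV of well ids to exclude
    min_area: int = 150
    search_margin: float = 20.0
    max_wells: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "well_radius_range" in data:
            data["well_radius_range"] = tuple(data["well_radius_range"])
        return cls(**data)

    def fingerprint(self) -> str:
        import hashlib
        blob = yaml.safe_dump(dataclasses.asdict(self)).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Image / table I/O
# ---------------------------------------------------------------------------

def load_stack(path: str | Path, pixel_size: float,
               frame_interval: float) -> FrameStack:
    """Load a multi-page TIFF (or a directory of per-frame images)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".tif", ".tiff", ".png"})
        if not files:
            raise FileNotFoundError(f"no frame images in {path}")
        frames = np.stack([tifffile.imread(f) if f.suffix.lower() != ".png"
                           else _read_png(f) for f in files])
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return FrameStack(frames.astype(float), pixel_size, frame_interval)


def _read_png(path: Path) -> np.ndarray:
    import imageio.v3 as iio
    img = iio.imread(path)
    return img if img.ndim == 2 else img.mean(axis=-1)


def save_stack(stack: FrameStack, path: str | Path) -> None:
    """Write frames as an 8-bit multi-page TIFF."""
    arr = np.clip(stack.frames, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, arr)


def save_masks(masks: list[np.ndarray], path: str | Path) -> None:
    """Write a binary mask sequence as a multi-page TIFF (0/255)."""
    arrs = [np.asarray(m, dtype=bool).astype(np.uint8) * 255 for m in masks]
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:  # pad to common shape
        h = max(s[0] for s in shapes)
        w = max(s[1] for s in shapes)
        arrs = [np.pad(a, ((0, h - a.shape[0]), (0, w - a.shape[1])))
                for a in arrs]
    tifffile.imwrite(path, np.stack(arrs))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _select_wells(wells: list[microwell.WellCircle], cfg: RunConfig,
                  frame0: np.ndarray) -> list[int]:
    """Indices of wells selected for fusion analysis."""
    if cfg.selection == "all":
        return list(range(len(wells)))
    if cfg.selection == "manual":
        if not cfg.manual_wells:
            raise ValueError("manual selection requires a manual_wells CSV")
        sel = pd.read_csv(cfg.manual_wells)
        picked = []
        for _, row in sel.iterrows():
            dists = [np.hypot(w.x - row["x"], w.y - row["y"]) for w in wells]
            picked.append(int(np.argmin(dists)))
        return sorted(set(picked))
    if cfg.selection == "classifier":
        if not cfg.classifier_model:
            raise ValueError("classifier selection requires a model path")
        import joblib
        model: classify.DoubletClassifier = joblib.load(cfg.classifier_model)
        picked = []
        for i, w in enumerate(wells):
            half = int(round(w.radius * 1.2))
            crop, (x0, y0) = segment._crop_with_origin(frame0, w.x, w.y, half)
            local = microwell.WellCircle(w.x - x0, w.y - y0, w.radius)
            vec = classify.well_features(crop, local, min_area=cfg.min_area)
            if model.predict(vec[None])[0] == 1:
                picked.append(i)
        return picked
    raise ValueError(f"unknown selection mode {cfg.selection!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full fusion-analysis workflow; returns the run report.

    Per-doublet failures mark the sample dropped and processing continues;
    missing inputs raise.  Artifacts written to ``output_dir``: the saved
    config, per-doublet feature CSVs and mask TIFFs, a track CSV, kinetic
    fits CSV and a JSON report.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    stack = load_stack(config.input_path, config.pixel_size,
                       config.frame_interval)
    wells = microwell.detect_microwells(stack[0], config.well_radius_range,
                                        max_wells=config.max_wells)
    log.info("detected %d microwells", len(wells))
    if not wells:
        raise RuntimeError("no microwells detected in the first frame")
    pd.DataFrame([{"well": i, "x": w.x, "y": w.y, "radius": w.radius,
                   "score": w.score} for i, w in enumerate(wells)]
                 ).to_csv(out / "wells.csv", index=False)
    selected = _select_wells(wells, config, stack[0])
    excluded: set[int] = set()
    if config.exclude_wells:
        excluded = set(pd.read_csv(config.exclude_wells)["well"].astype(int))
    report: dict = {"config_fingerprint": config.fingerprint(),
                    "n_wells": len(wells), "n_selected": len(selected),
                    "doublets": []}
    fits = []
    for i in selected:
        entry: dict = {"well": i}
        if i in excluded:
            entry["status"] = "excluded"
            report["doublets"].append(entry)
            continue
        try:
            res = segment.segment_sequence(
                stack, wells[i], min_area=config.min_area,
                search_margin=config.search_margin)
        except segment.EmptyWellError as exc:
            entry["status"] = f"empty_well: {exc}"
            report["doublets"].append(entry)
            continue
        recs = features.extract_timeseries(
            res.masks, res.rotations, pixel_size=config.pixel_size,
            frame_interval=config.frame_interval)
        df = features.records_to_frame(recs)
        df.to_csv(out / f"doublet_{i:03d}_features.csv", index=False)
        save_masks([m.binary_mask for m in res.masks],
                   out / f"doublet_{i:03d}_masks.tif")
        res.track.to_csv(out / f"doublet_{i:03d}_track.csv")
        entry["status"] = ("dropped" if res.drop_reason is not None
                           else "complete")
        entry["n_frames"] = res.n_frames
        if res.drop_reason is not None:
            entry["drop_frame"] = res.drop_frame
            entry["drop_reason"] = res.drop_reason.value
        valid = df["roundness"].notna()
        if valid.sum() >= 10:
            fit = kinetics.fit_exponential(df.loc[valid, "time"].to_numpy(),
                                           df.loc[valid, "roundness"].to_numpy())
            entry["fit"] = {"plateau": fit.plateau, "b": fit.b,
                            "tau": fit.tau, "rss": fit.rss,
                            "converged": fit.converged}
            fits.append({"well": i, **entry["fit"]})
            try:
                norm = kinetics.normalize_series(df)
                lin = kinetics.fit_linear_contact(
                    norm["time"].to_numpy(), norm["norm_contact"].to_numpy())
                entry["linear_fit"] = {"intercept": lin.intercept,
                                       "slope": lin.slope}
            except (kinetics.NormalizationError, ValueError):
                pass
        report["doublets"].append(entry)
    if fits:
        pd.DataFrame(fits).to_csv(out / "kinetic_fits.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
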