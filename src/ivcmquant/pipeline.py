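"""End-to-end pipeline: synthesize → rasterize → train → segment → quantify.

Stages communicate only through documented files under one run directory,
so the full run equals the composition of the CLI subcommands:

.. code-block:: text

    <run>/
      config.yaml, manifest.json
      data/      images/<subject>/<OS|OD>/<image>.tif, tracings/*.ndf,
                 cells/*.json, ground_truth.csv
      masks/     nerve/*.png (0/255), dc/*.png (class indices 0/1/2)
      models/    nerve.npz, dc.npz, lera.npz
      pred/      nerve/*.png, dc/*.png
      cnfl/      per_image.csv, per_participant.csv, selection.json
      dc/        per_image.csv, per_participant.csv
      evaluate/  cnfl_agreement.json, dc_agreement.json, bland_altman_cnfl.csv
      stats/     group_comparison.csv

The "manual" reference in the agreement stage is the analytic ground truth
carried by the synthetic annotations — the role the human grader's NeuronJ
and cell counts play for clinical data. Subjects are split by
subject-stratified folds; the agreement analysis uses only held-out
subjects.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .cnfl import (
    LengthRegressor,
    cnfl_image,
    cnfl_participant,
    predict_length,
    select_estimator,
    train_regressor,
)
from .dc import DCCounts, count_image, densities_participant
from .io import (
    MaskKind,
    SegmentationMask,
    parse_labelme,
    parse_ndf,
    rasterize_dc_mask,
    rasterize_nerve_mask,
    read_image,
    write_image,
    write_labelme,
    write_ndf,
)
from .metrics import agreement_report, bland_altman
from .segmentation import (
    ResUNetConfig,
    build_model,
    load_model,
    make_folds,
    predict_mask,
    save_model,
    train,
)
from .stats import benjamini_hochberg, t_test_equal_var
from .synth import DEFAULT_GROUP_SPECS, SynthParams, generate_cohort
from .units import image_area_mm2

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable description of a full run; a run is reproducible from
    this plus nothing else."""

    output_root: str = "run"
    image_shape: tuple[int, int] = (96, 96)
    n_subjects: tuple[int, int] = (6, 6)
    images_per_eye: int = 3
    line_width_px: int = 4
    held_out_fold: int = 0
    n_folds: int = 3
    estimator_policy: str = "auto"  # auto | algorithmic | regression
    nerve_model: ResUNetConfig = field(default_factory=lambda: ResUNetConfig(
        depth=3, base_channels=8, epochs=25, batch_size=4, learning_rate=3e-3))
    dc_model: ResUNetConfig = field(default_factory=lambda: ResUNetConfig(
        depth=3, base_channels=8, head="softmax3", loss="dice_plus_ce",
        epochs=25, batch_size=4, learning_rate=3e-3))
    regressor_epochs: int = 60
    seed: int = 0

    def to_yaml(self) -> str:
        doc = asdict(self)
        doc["image_shape"] = list(self.image_shape)
        doc["n_subjects"] = list(self.n_subjects)
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        doc = yaml.safe_load(text)
        for key in ("nerve_model", "dc_model"):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = ResUNetConfig(**doc[key])
        doc["image_shape"] = tuple(doc.get("image_shape", (96, 96)))
        doc["n_subjects"] = tuple(doc.get("n_subjects", (6, 6)))
        return cls(**doc)


def _mask_to_png(mask: SegmentationMask, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if mask.kind is MaskKind.NERVE_BINARY:
        Image.fromarray(mask.data * 255, mode="L").save(path)
    else:
        labels = np.argmax(mask.data, axis=0).astype(np.uint8)
        Image.fromarray(labels, mode="L").save(path)


def _png_to_mask(path: Path, kind: MaskKind) -> SegmentationMask:
    arr = np.asarray(Image.open(path))
    if kind is MaskKind.NERVE_BINARY:
        return SegmentationMask(kind, (arr > 0).astype(np.uint8))
    onehot = np.stack([(arr == c) for c in range(3)]).astype(np.uint8)
    return SegmentationMask(kind, onehot)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(config: PipelineConfig, run: Path) -> None:
    """Generate the cohort and write images + annotations + ground truth."""
    params = SynthParams(image_shape=config.image_shape)
    cohort = generate_cohort(
        DEFAULT_GROUP_SPECS, n_subjects=list(config.n_subjects),
        images_per_eye=config.images_per_eye, seed=config.seed, params=params,
    )
    rows = []
    for c in cohort:
        s = c.sample
        img_path = run / "data" / "images" / c.subject_id / c.eye.value / f"{s.image.image_id}.tif"
        write_image(s.image, img_path)
        (run / "data" / "tracings").mkdir(parents=True, exist_ok=True)
        (run / "data" / "cells").mkdir(parents=True, exist_ok=True)
        (run / "data" / "tracings" / f"{s.image.image_id}.ndf").write_text(write_ndf(s.tracing))
        (run / "data" / "cells" / f"{s.image.image_id}.json").write_text(write_labelme(s.annotation))
        rows.append({
            "image_id": s.image.image_id, "subject_id": c.subject_id,
            "eye": c.eye.value, "group": c.group,
            "true_length_mm": s.true_nerve_length_mm,
            "n_with": s.true_counts[0], "n_without": s.true_counts[1],
            "latent_cnfl_density": c.latent_cnfl_density,
            "latent_dc_with_density": c.latent_dc_with_density,
            "latent_dc_without_density": c.latent_dc_without_density,
        })
    pd.DataFrame(rows).to_csv(run / "data" / "ground_truth.csv", index=False)


def stage_rasterize(config: PipelineConfig, run: Path) -> None:
    """Rasterize NDF tracings and cell polygons into training masks."""
    gt = pd.read_csv(run / "data" / "ground_truth.csv")
    shape = tuple(config.image_shape)
    for image_id in gt["image_id"]:
        tracing = parse_ndf((run / "data" / "tracings" / f"{image_id}.ndf").read_text(),
                            image_shape=shape)
        _mask_to_png(rasterize_nerve_mask(tracing, config.line_width_px),
                     run / "masks" / "nerve" / f"{image_id}.png")
        annotation = parse_labelme((run / "data" / "cells" / f"{image_id}.json").read_text())
        _mask_to_png(rasterize_dc_mask(annotation),
                     run / "masks" / "dc" / f"{image_id}.png")


def _load_split(config: PipelineConfig, run: Path):
    gt = pd.read_csv(run / "data" / "ground_truth.csv")
    folds = make_folds(gt["subject_id"], k=config.n_folds, seed=config.seed)
    gt["fold"] = gt["subject_id"].map(folds)
    train_df = gt[gt["fold"] != config.held_out_fold]
    test_df = gt[gt["fold"] == config.held_out_fold]
    return gt, train_df, test_df


def _read_pixels(run: Path, row) -> np.ndarray:
    path = run / "data" / "images" / row.subject_id / row.eye / f"{row.image_id}.tif"
    return read_image(path).pixels


def stage_train(config: PipelineConfig, run: Path) -> None:
    """Train nerve + DC segmentation models and the length regressor."""
    _, train_df, _ = _load_split(config, run)
    nerve_pairs, dc_pairs, reg_pairs = [], [], []
    for row in train_df.itertuples():
        pixels = _read_pixels(run, row)
        nerve = _png_to_mask(run / "masks" / "nerve" / f"{row.image_id}.png",
                             MaskKind.NERVE_BINARY)
        dcm = _png_to_mask(run / "masks" / "dc" / f"{row.image_id}.png",
                           MaskKind.DC_ONEHOT)
        nerve_pairs.append((pixels, nerve.data))
        dc_pairs.append((pixels, dcm.data))
        reg_pairs.append((pixels, row.true_length_mm))

    nerve_cfg = replace(config.nerve_model, seed=config.seed)
    nerve_model = build_model(nerve_cfg)
    train(nerve_model, nerve_pairs, nerve_cfg)
    save_model(nerve_model, run / "models" / "nerve.npz")

    dc_cfg = replace(config.dc_model, seed=config.seed + 1)
    dc_model = build_model(dc_cfg)
    train(dc_model, dc_pairs, dc_cfg)
    save_model(dc_model, run / "models" / "dc.npz")

    reg_cfg = replace(config.nerve_model, seed=config.seed + 2,
                      epochs=config.regressor_epochs)
    regressor = LengthRegressor(reg_cfg)
    train_regressor(regressor, reg_pairs)
    state = regressor.state_arrays()
    np.savez_compressed(run / "models" / "lera.npz",
                        __config__=json.dumps(asdict(reg_cfg)), **state)


def _load_regressor(path: Path) -> LengthRegressor:
    with np.load(path, allow_pickle=False) as data:
        cfg = ResUNetConfig(**json.loads(str(data["__config__"])))
        model = LengthRegressor(cfg)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model


def stage_segment(config: PipelineConfig, run: Path) -> None:
    """Predict nerve and DC masks for every image."""
    gt = pd.read_csv(run / "data" / "ground_truth.csv")
    nerve_model = load_model(run / "models" / "nerve.npz")
    dc_model = load_model(run / "models" / "dc.npz")
    for row in gt.itertuples():
        pixels = _read_pixels(run, row)
        _mask_to_png(predict_mask(nerve_model, pixels),
                     run / "pred" / "nerve" / f"{row.image_id}.png")
        _mask_to_png(predict_mask(dc_model, pixels),
                     run / "pred" / "dc" / f"{row.image_id}.png")


def stage_cnfl(config: PipelineConfig, run: Path) -> None:
    """Per-image lengths (both estimators), selection, participant densities."""
    gt, _, test_df = _load_split(config, run)
    params = SynthParams(image_shape=config.image_shape)
    area = image_area_mm2(config.image_shape, params.pixel_pitch_um)
    regressor = _load_regressor(run / "models" / "lera.npz")
    rows = []
    for row in gt.itertuples():
        mask = _png_to_mask(run / "pred" / "nerve" / f"{row.image_id}.png",
                            MaskKind.NERVE_BINARY)
        alg = cnfl_image(mask, params.pixel_pitch_um, image_id=row.image_id,
                         line_width_px=config.line_width_px)
        reg = predict_length(regressor, _read_pixels(run, row), image_id=row.image_id)
        rows.append({"image_id": row.image_id, "subject_id": row.subject_id,
                     "length_mm_algorithmic": alg.length_mm,
                     "length_mm_regression": reg.length_mm,
                     "true_length_mm": row.true_length_mm,
                     "held_out": row.fold == config.held_out_fold})
    per_image = pd.DataFrame(rows)
    (run / "cnfl").mkdir(parents=True, exist_ok=True)
    per_image.to_csv(run / "cnfl" / "per_image.csv", index=False)

    held = per_image[per_image["held_out"]]
    if config.estimator_policy == "auto":
        selection = select_estimator(held["true_length_mm"],
                                     held["length_mm_algorithmic"],
                                     held["length_mm_regression"])
        chosen = selection.chosen
        (run / "cnfl" / "selection.json").write_text(json.dumps(asdict(selection), indent=2))
    else:
        chosen = config.estimator_policy
    col = f"length_mm_{chosen}"
    part_rows = []
    for subject_id, sub in per_image.groupby("subject_id"):
        agg = cnfl_participant(sub[col].tolist(), area, subject_id=subject_id)
        true_agg = cnfl_participant(sub["true_length_mm"].tolist(), area,
                                    subject_id=subject_id)
        part_rows.append({"subject_id": subject_id, "method": chosen,
                          "cnfl_density": agg.cnfl_density,
                          "cnfl_density_manual": true_agg.cnfl_density,
                          "held_out": bool(sub["held_out"].iloc[0])})
    pd.DataFrame(part_rows).to_csv(run / "cnfl" / "per_participant.csv", index=False)


def stage_dc(config: PipelineConfig, run: Path) -> None:
    """Per-image DC counts and participant densities from predicted masks."""
    gt, _, _ = _load_split(config, run)
    area = image_area_mm2(config.image_shape)
    rows = []
    for row in gt.itertuples():
        mask = _png_to_mask(run / "pred" / "dc" / f"{row.image_id}.png", MaskKind.DC_ONEHOT)
        counts = count_image(mask, image_id=row.image_id)
        rows.append({"image_id": row.image_id, "subject_id": row.subject_id,
                     "n_with": counts.n_with, "n_without": counts.n_without,
                     "true_n_with": row.n_with, "true_n_without": row.n_without,
                     "held_out": row.fold == config.held_out_fold})
    per_image = pd.DataFrame(rows)
    (run / "dc").mkdir(parents=True, exist_ok=True)
    per_image.to_csv(run / "dc" / "per_image.csv", index=False)
    part_rows = []
    for subject_id, sub in per_image.groupby("subject_id"):
        auto = densities_participant(
            [DCCounts(r.image_id, r.n_with, r.n_without) for r in sub.itertuples()],
            area, subject_id=subject_id)
        manual = densities_participant(
            [DCCounts(r.image_id, r.true_n_with, r.true_n_without) for r in sub.itertuples()],
            area, subject_id=subject_id)
        part_rows.append({
            "subject_id": subject_id,
            "density_with": auto.density_with, "density_without": auto.density_without,
            "density_total": auto.density_total,
            "density_with_manual": manual.density_with,
            "density_without_manual": manual.density_without,
            "density_total_manual": manual.density_total,
            "held_out": bool(sub["held_out"].iloc[0])})
    pd.DataFrame(part_rows).to_csv(run / "dc" / "per_participant.csv", index=False)


def _report_to_json(report) -> dict:
    doc = asdict(report)
    return doc


def stage_evaluate(config: PipelineConfig, run: Path) -> None:
    """Agreement (automated vs manual) on held-out subjects."""
    (run / "evaluate").mkdir(parents=True, exist_ok=True)
    cnfl_part = pd.read_csv(run / "cnfl" / "per_participant.csv")
    held = cnfl_part[cnfl_part["held_out"]]
    try:
        doc = _report_to_json(
            agreement_report(held["cnfl_density"], held["cnfl_density_manual"]))
    except ValueError:  # too few held-out subjects for ICC/Pearson
        bias, sd, lo, hi = bland_altman(held["cnfl_density"],
                                        held["cnfl_density_manual"])
        doc = {"bias": bias, "sd_diff": sd, "loa_low": lo, "loa_high": hi}
    (run / "evaluate" / "cnfl_agreement.json").write_text(json.dumps(doc, indent=2))
    ba = pd.DataFrame({
        "mean": (held["cnfl_density"] + held["cnfl_density_manual"]) / 2,
        "difference": held["cnfl_density"] - held["cnfl_density_manual"],
    })
    ba.to_csv(run / "evaluate" / "bland_altman_cnfl.csv", index=False)

    dc_part = pd.read_csv(run / "dc" / "per_participant.csv")
    held_dc = dc_part[dc_part["held_out"]]
    dc_doc = {}
    for cls in ("with", "without", "total"):
        auto = held_dc[f"density_{cls}"]
        manual = held_dc[f"density_{cls}_manual"]
        try:
            dc_doc[cls] = _report_to_json(agreement_report(auto, manual))
        except ValueError:  # degenerate (e.g. all-zero manual densities)
            bias, sd, lo, hi = bland_altman(auto, manual)
            dc_doc[cls] = {"bias": bias, "sd_diff": sd, "loa_low": lo, "loa_high": hi}
    (run / "evaluate" / "dc_agreement.json").write_text(json.dumps(dc_doc, indent=2))


def stage_stats(config: PipelineConfig, run: Path) -> None:
    """Two-group comparisons of per-participant densities, BH-adjusted."""
    gt = pd.read_csv(run / "data" / "ground_truth.csv")
    group_of = gt.drop_duplicates("subject_id").set_index("subject_id")["group"]
    cnfl_part = pd.read_csv(run / "cnfl" / "per_participant.csv").set_index("subject_id")
    dc_part = pd.read_csv(run / "dc" / "per_participant.csv").set_index("subject_id")
    groups = sorted(group_of.unique())
    rows = []
    measures = [("cnfl_density", cnfl_part), ("cnfl_density_manual", cnfl_part),
                ("density_with", dc_part), ("density_without", dc_part),
                ("density_total", dc_part)]
    for name, table in measures:
        g1 = table.loc[[s for s in table.index if group_of[s] == groups[0]], name]
        g2 = table.loc[[s for s in table.index if group_of[s] == groups[1]], name]
        cmp = t_test_equal_var(g1, g2)
        rows.append({"measure": name, **asdict(cmp)})
    out = pd.DataFrame(rows)
    dc_mask = out["measure"].str.startswith("density_")
    out.loc[dc_mask, "adjusted_p"] = benjamini_hochberg(out.loc[dc_mask, "p_value"].to_numpy())
    (run / "stats").mkdir(parents=True, exist_ok=True)
    out.to_csv(run / "stats" / "group_comparison.csv", index=False)


_STAGES = [
    ("synth", stage_synth),
    ("rasterize", stage_rasterize),
    ("train", stage_train),
    ("segment", stage_segment),
    ("cnfl", stage_cnfl),
    ("dc", stage_dc),
    ("evaluate", stage_evaluate),
    ("stats", stage_stats),
]


def run_pipeline(config: PipelineConfig, run_dir: str | Path | None = None) -> Path:
    """Execute every stage in order; returns the run directory.

    Writes ``manifest.json`` recording the config, seeds and per-stage wall
    times (timings are informational only — they are hardware-dependent and
    never part of any acceptance check). Any stage failure aborts the run
    with the stage name attached.
    """
    run = Path(run_dir if run_dir is not None else config.output_root)
    run.mkdir(parents=True, exist_ok=True)
    (run / "config.yaml").write_text(config.to_yaml())
    timings = {}
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            fn(config, run)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seconds": timings,
        "numpy": np.__version__,
    }
    (run / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run
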