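"""Batch pipeline: the eight analysis steps wired over a working directory.

Steps (each resumable, each a pure function of inputs + config + seed):

1. load        - list and validate the slide images in the input directory
2. preprocess  - convert TIFF/JPEG slides to 8-bit RGB PNG
3. segment     - tile each slide, classify patches, stitch a label mask
4. postprocess - bridge periderm gaps, drop spurious distal runs, close holes
5. qc          - write transition-zone inspection crops / apply a selection
6. phenotype   - measure per-root lengths, write the canonical CSVs
7. visualize   - per-slide boxplots of periderm length
8. save        - bundle the outputs into a destination directory

The working directory layout is ``<output_dir>/{preprocessed,masks,
postprocessed,qc,measurements,plots}``. A plain-text selection file
``selected_roots.txt`` in the output directory (lines ``slide_id,root_index``)
triggers the after-QC measurement tables.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, measurement, postprocess, qc
from .io_formats import MeasurementTable, ScaleConfig
from .model import ModelConfig, TrainConfig, TrainedModel, predict_slide, train
from .postprocess import PostprocessConfig
from .synthetic_data import make_patch_dataset
from .tiling import TilingConfig

logger = logging.getLogger(__name__)

STEPS = ("load", "preprocess", "segment", "postprocess", "qc", "phenotype", "visualize", "save")

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


class MissingPrerequisite(RuntimeError):
    """A pipeline step was invoked before the step it depends on."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    input_dir: str = "input"
    output_dir: str = "output"
    checkpoint: str | None = None
    seed: int = 0
    qc_margin: int = qc.DEFAULT_QC_MARGIN
    expected_n_roots: int | None = None
    tiling: TilingConfig = field(default_factory=TilingConfig)
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        for key in ("tiling", "scale", "postprocess", "model", "train"):
            payload[key] = dataclasses.asdict(getattr(self, key))
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        for key, typ in (
            ("tiling", TilingConfig),
            ("scale", ScaleConfig),
            ("postprocess", PostprocessConfig),
            ("model", ModelConfig),
            ("train", TrainConfig),
        ):
            if key in payload:
                sub = payload[key]
                for k, v in sub.items():  # YAML lists back to tuples
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                payload[key] = typ(**sub)
        return cls(**payload)

    # directory helpers -----------------------------------------------------
    def dir(self, name: str) -> Path:
        return Path(self.output_dir) / name

    @property
    def selection_file(self) -> Path:
        return Path(self.output_dir) / "selected_roots.txt"


def _slide_images(directory: Path) -> list[Path]:
    return sorted(p for p in directory.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)


# ---------------------------------------------------------------------------
# the steps
# ---------------------------------------------------------------------------

def step_load(config: PipelineConfig) -> list[Path]:
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise MissingPrerequisite(f"input directory {input_dir} does not exist")
    images = [p for p in _slide_images(input_dir) if not p.stem.endswith("_mask")]
    if not images:
        raise MissingPrerequisite(f"no slide images found in {input_dir}")
    for path in images:
        io_formats.read_image(path)  # validate that every slide decodes
    logger.info("loaded %d slide image(s)", len(images))
    return images


def step_preprocess(config: PipelineConfig) -> list[Path]:
    images = step_load(config)
    out = config.dir("preprocessed")
    out.mkdir(parents=True, exist_ok=True)
    return [io_formats.convert_to_png(p, out) for p in images]


def step_segment(config: PipelineConfig) -> list[Path]:
    pre = config.dir("preprocessed")
    if not pre.is_dir() or not _slide_images(pre):
        raise MissingPrerequisite("no preprocessed slides; run the preprocess step first")
    if config.checkpoint is None or not Path(config.checkpoint).exists():
        raise MissingPrerequisite(
            "segment requires a trained checkpoint; set 'checkpoint' in the config "
            "(train one with the train command)"
        )
    model = TrainedModel.load(config.checkpoint)
    mask_dir = config.dir("masks")
    out_paths = []
    for path in _slide_images(pre):
        image = io_formats.read_image(path)
        mask = predict_slide(model, image, config.tiling)
        out_paths.append(io_formats.write_mask_png(mask, mask_dir / f"{path.stem}.png"))
        logger.info("segmented %s: class px %s", path.stem, mask.class_pixel_counts())
    return out_paths


def step_postprocess(config: PipelineConfig) -> list[Path]:
    mask_dir = config.dir("masks")
    if not mask_dir.is_dir() or not _slide_images(mask_dir):
        raise MissingPrerequisite("no predicted masks; run the segment step first")
    out_dir = config.dir("postprocessed")
    out_paths = []
    for path in _slide_images(mask_dir):
        mask = io_formats.read_mask_png(path)
        cleaned, roots = postprocess.postprocess_slide(
            mask, config.postprocess, slide_id=path.stem,
            expected_n_roots=config.expected_n_roots,
        )
        out_paths.append(io_formats.write_mask_png(cleaned, out_dir / path.name))
        logger.info("postprocessed %s: %d root(s)", path.stem, len(roots))
    return out_paths


def step_qc(config: PipelineConfig) -> list[Path]:
    post_dir = config.dir("postprocessed")
    if not post_dir.is_dir() or not _slide_images(post_dir):
        raise MissingPrerequisite("no postprocessed masks; run the postprocess step first")
    pre_dir = config.dir("preprocessed")
    out = []
    for path in _slide_images(post_dir):
        mask = io_formats.read_mask_png(path)
        image = io_formats.read_image(pre_dir / path.name)
        roots = postprocess.extract_root_instances(
            mask, config.postprocess, slide_id=path.stem
        )
        out += qc.write_qc_images(image, mask, roots, config.dir("qc"), path.stem,
                                  margin=config.qc_margin)
    return out


def step_phenotype(config: PipelineConfig) -> list[Path]:
    post_dir = config.dir("postprocessed")
    if not post_dir.is_dir() or not _slide_images(post_dir):
        raise MissingPrerequisite("no postprocessed masks; run the postprocess step first")
    rows_peri, rows_root = [], []
    for path in _slide_images(post_dir):
        mask = io_formats.read_mask_png(path)
        roots = postprocess.extract_root_instances(mask, config.postprocess, slide_id=path.stem)
        for root in roots:
            m = measurement.measure_root(root, mask, config.scale)
            rows_peri.append((path.stem, root.root_id, m.periderm_length_px, m.periderm_length_um))
            rows_root.append((path.stem, root.root_id, m.whole_root_length_px, m.whole_root_length_um))
    meas_dir = config.dir("measurements")
    written = []
    tables = {}
    for quantity, rows in (("periderm_length", rows_peri), ("whole_root_length", rows_root)):
        for unit, col in (("pixels", 2), ("micrometers", 3)):
            df = pd.DataFrame(
                [(row[0], row[1], row[col]) for row in rows],
                columns=["slide_id", "root_index", "value"],
            )
            table = MeasurementTable(df, quantity=quantity, unit=unit)
            tables[(quantity, unit)] = table
            written.append(io_formats.write_measurements_csv(table, meas_dir))
    if config.selection_file.exists():
        selection = qc.SelectionList.read(config.selection_file)
        for unit in ("pixels", "micrometers"):
            filtered = qc.apply_selection(tables[("periderm_length", unit)], selection)
            written.append(io_formats.write_measurements_csv(filtered, meas_dir))
    logger.info("phenotype: measured %d root(s), wrote %d CSV file(s)",
                len(rows_peri), len(written))
    return written


def step_visualize(config: PipelineConfig) -> list[Path]:
    meas_dir = config.dir("measurements")
    src = meas_dir / "periderm_length_micrometers.csv"
    if not src.exists():
        raise MissingPrerequisite("no measurement CSVs; run the phenotype step first")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = io_formats.read_measurements_csv(src)
    plot_dir = config.dir("plots")
    plot_dir.mkdir(parents=True, exist_ok=True)
    out = []
    for slide, group in table.data.groupby("slide_id"):
        fig, ax = plt.subplots(figsize=(4, 5))
        ax.boxplot(group["value"], tick_labels=[str(slide)])
        ax.scatter(np.ones(len(group)), group["value"], color="k", zorder=3, s=12)
        ax.set_ylabel("periderm length (µm)")
        ax.set_title(f"{slide}: {len(group)} root(s)")
        path = plot_dir / f"{slide}_boxplot.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        out.append(path)
    return out


def step_save(config: PipelineConfig, destination: str | Path | None = None) -> Path:
    meas_dir = config.dir("measurements")
    if not meas_dir.is_dir():
        raise MissingPrerequisite("nothing to save; run the phenotype step first")
    dest = Path(destination) if destination else config.dir("bundle")
    dest.mkdir(parents=True, exist_ok=True)
    for sub in ("measurements", "plots", "qc", "postprocessed"):
        src = config.dir(sub)
        if src.is_dir():
            shutil.copytree(src, dest / sub, dirs_exist_ok=True)
    logger.info("saved outputs to %s", dest)
    return dest


_STEP_FUNCTIONS = {
    "load": step_load,
    "preprocess": step_preprocess,
    "segment": step_segment,
    "postprocess": step_postprocess,
    "qc": step_qc,
    "phenotype": step_phenotype,
    "visualize": step_visualize,
    "save": step_save,
}


def run_step(step: str, config: PipelineConfig):
    """Run one named pipeline step; raises MissingPrerequisite when out of order."""
    if step not in _STEP_FUNCTIONS:
        raise ValueError(f"unknown step {step!r}; valid steps: {STEPS}")
    return _STEP_FUNCTIONS[step](config)


def run_all(config: PipelineConfig) -> dict:
    """Run the eight steps in order and return a summary of counts."""
    for step in STEPS:
        logger.info("=== step: %s ===", step)
        run_step(step, config)
    table = io_formats.read_measurements_csv(
        config.dir("measurements") / "periderm_length_micrometers.csv"
    )
    summary = {
        "slides": int(table.data["slide_id"].nunique()),
        "roots_measured": int(len(table.data)),
        "roots_with_periderm": int((table.data["value"] > 0).sum()),
        "qc_applied": config.selection_file.exists(),
    }
    logger.info("run summary: %s", summary)
    return summary


# ---------------------------------------------------------------------------
# training entry point used by the CLI
# ---------------------------------------------------------------------------

def train_from_slides(
    slides, config: PipelineConfig, checkpoint_path: str | Path
) -> tuple[TrainedModel, "object"]:
    """Tile synthetic or annotated slides into patches and fit the segmenter."""
    patches, masks = make_patch_dataset(slides, patch_size=config.tiling.patch_size)
    logger.info("training on %d patch(es) of %d px", len(patches), config.tiling.patch_size)
    model, history = train(patches, masks, config.model, config.train,
                           checkpoint_path=checkpoint_path)
    history.to_csv(Path(checkpoint_path).with_suffix(".history.csv"))
    return model, history
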