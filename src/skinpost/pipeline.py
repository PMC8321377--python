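"""End-to-end postprocessing pipeline: threshold, classify, refine.

For a single SPM the pipeline (i) extracts the skin mask by tri-level Otsu
thresholding, (ii) computes the five region features, (iii) assigns one of
the eleven image classes, and (iv) applies the postprocessor that class
selects: morphological Set#1/2/3 on the Otsu mask, homogeneity refinement
on the SPM itself, or nothing for class H (no skin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ImageClass, Postprocessor, ThresholdSet, classify, postprocessor_for
from .features import FeatureVector, compute_features
from .homogeneity import HomogeneityParams, homogeneity_refine
from .io import find_images, read_spm, write_mask
from .morphology import MorphConfig, apply_set
from .otsu import otsu_three_class, skin_mask

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PostprocessResult", "post_process", "run_batch",
           "load_config", "save_config"]

_SET_FOR: dict[Postprocessor, int] = {
    Postprocessor.MORPH_SET1: 1,
    Postprocessor.MORPH_SET2: 2,
    Postprocessor.MORPH_SET3: 3,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all pipeline parameters.

    ``connectivity`` (4 or 8) applies to every labeling step.
    ``border_inclusive`` / ``otsu_high_strict`` expose the two comparison
    conventions (see :func:`skinpost.classify.classify` and
    :func:`skinpost.otsu.otsu_three_class`).  ``empty_mask_for_no_skin``
    makes class H return an all-false mask instead of the unrefined Otsu
    mask.
    """

    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    morph: MorphConfig = field(default_factory=MorphConfig)
    homogeneity: HomogeneityParams = field(default_factory=HomogeneityParams)
    connectivity: int = 8
    border_inclusive: bool = True
    otsu_high_strict: bool = True
    empty_mask_for_no_skin: bool = False

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def with_thresholds(self, thresholds: ThresholdSet) -> "PipelineConfig":
        kwargs = {k: getattr(self, k) for k in (
            "morph", "homogeneity", "connectivity", "border_inclusive",
            "otsu_high_strict", "empty_mask_for_no_skin")}
        return PipelineConfig(thresholds=thresholds, **kwargs)


@dataclass(frozen=True)
class PostprocessResult:
    """Output of :func:`post_process`, with intermediates kept for audit."""

    mask: np.ndarray
    image_class: ImageClass
    features: FeatureVector
    postprocessor: Postprocessor
    otsu_mask: np.ndarray


def post_process(spm: np.ndarray, config: PipelineConfig | None = None) -> PostprocessResult:
    """Run the full postprocessing pipeline on one SPM."""
    cfg = config or PipelineConfig()
    partition = otsu_three_class(spm, high_strict=cfg.otsu_high_strict)
    img = skin_mask(partition)
    feats = compute_features(img, cfg.connectivity)
    cls = classify(feats, cfg.thresholds, border_inclusive=cfg.border_inclusive)
    post = postprocessor_for(cls)

    if post is Postprocessor.NONE:
        mask = np.zeros_like(img) if cfg.empty_mask_for_no_skin else img.copy()
    elif post is Postprocessor.HOMOGENEITY:
        mask = homogeneity_refine(spm, cfg.homogeneity, cfg.connectivity)
    else:
        mask = apply_set(img, _SET_FOR[post], reference=img,
                         config=cfg.morph, connectivity=cfg.connectivity)
    return PostprocessResult(mask, cls, feats, post, img)


def run_batch(
    spm_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    pattern: str = "*.png",
) -> pd.DataFrame:
    """Postprocess every SPM in a directory and write one mask PNG per input.

    Returns the manifest (also written to ``out_dir/manifest.csv``) with one
    row per input file, in filename order: file, assigned class, selected
    postprocessor, skin pixel count, and a status flag.  Unreadable files
    are skipped with a warning and flagged in the manifest.

    Raises
    ------
    ValueError
        If the directory contains no matching files.
    """
    spm_dir = Path(spm_dir)
    out_dir = Path(out_dir)
    files = find_images(spm_dir, pattern)
    if not files:
        raise ValueError(f"no files matching {pattern!r} in {spm_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for path in files:
        try:
            spm = read_spm(path)
        except Exception as exc:  # noqa: BLE001 - flag and continue the batch
            logger.warning("skipping unreadable file %s: %s", path, exc)
            rows.append({"file": path.name, "image_class": "", "postprocessor": "",
                         "skin_pixels": -1, "status": "error"})
            continue
        result = post_process(spm, config)
        write_mask(result.mask, out_dir / path.name)
        rows.append({
            "file": path.name,
            "image_class": result.image_class.value,
            "postprocessor": result.postprocessor.value,
            "skin_pixels": int(result.mask.sum()),
            "status": "ok",
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a pipeline configuration to a single YAML file."""
    data = {
        "thresholds": config.thresholds.to_mapping(),
        "morph": asdict(config.morph),
        "homogeneity": asdict(config.homogeneity),
        "options": {
            "connectivity": config.connectivity,
            "border_inclusive": config.border_inclusive,
            "otsu_high_strict": config.otsu_high_strict,
            "empty_mask_for_no_skin": config.empty_mask_for_no_skin,
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML; omitted blocks use defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    thresholds = ThresholdSet.from_mapping(data.get("thresholds", {})) \
        if data.get("thresholds") else ThresholdSet()
    morph = MorphConfig(**data.get("morph", {}))
    homogeneity = HomogeneityParams(**data.get("homogeneity", {}))
    options = data.get("options", {})
    return PipelineConfig(thresholds=thresholds, morph=morph,
                          homogeneity=homogeneity, **options)
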