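"""Rule-based assignment of an image to one of eleven classes.

Each class describes a typical detection scenario (near foreground, far
face, group of people, background bleed-through, no skin, ...) and selects
one of four postprocessing routes: three morphological sequences or the
iterative region-homogeneity refinement.  The assignment is a fixed decision
tree over the five region features, with fourteen dimensionless thresholds.

Classes and their postprocessors:

=====  ============================  ==============
label  scenario                      postprocessor
=====  ============================  ==============
A      foreground near               morphology Set#1
B      foreground far                morphology Set#1
C      body parts near               morphology Set#1
D      body parts far                morphology Set#2
E      group near                    morphology Set#1
F      group far                     morphology Set#2
G      background detected as skin   morphology Set#3
H      no skin                       none
I      foreground near, one region   homogeneity
       dominating
K      body parts near, one region   homogeneity
       dominating
L      group near, one region        homogeneity
       dominating
=====  ============================  ==============
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from typing import Mapping, Sequence

from .features import FeatureVector

__all__ = [
    "ImageClass",
    "Postprocessor",
    "ThresholdSet",
    "classify",
    "postprocessor_for",
    "tune_thresholds",
]


class ImageClass(str, Enum):
    """The eleven admissible image classes (note: there is no J)."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"
    G = "G"
    H = "H"
    I = "I"  # noqa: E741 - the class label really is I
    K = "K"
    L = "L"


class Postprocessor(str, Enum):
    MORPH_SET1 = "morph_set1"
    MORPH_SET2 = "morph_set2"
    MORPH_SET3 = "morph_set3"
    HOMOGENEITY = "homogeneity"
    NONE = "none"


@dataclass(frozen=True)
class ThresholdSet:
    """The fourteen decision-tree thresholds.

    ``ts1``–``ts3`` cut on the skin ratio, ``tb1`` on the border skin ratio,
    ``(tl1, tl2)`` is the largest-region-ratio interval for single-region
    near-foreground images, and ``(tr1, tr2) ... (tr7, tr8)`` are the
    dominant-ratio intervals per component count.  Defaults are values
    learned on the training half of the ECU benchmark dataset.
    """

    ts1: float = 0.12
    ts2: float = 0.1685
    ts3: float = 0.1685
    tb1: float = 1.0
    tl1: float = 3.5e-6
    tl2: float = 86.3e-6
    tr1: float = 0.9967
    tr2: float = 0.9995
    tr3: float = 0.9730
    tr4: float = 0.9992
    tr5: float = 0.9701
    tr6: float = 0.9979
    tr7: float = 0.8736
    tr8: float = 0.9984

    def __post_init__(self) -> None:
        for lo, hi in (("tl1", "tl2"), ("tr1", "tr2"), ("tr3", "tr4"),
                       ("tr5", "tr6"), ("tr7", "tr8")):
            if getattr(self, lo) > getattr(self, hi):
                raise ValueError(f"{lo} must not exceed {hi}")

    def to_mapping(self) -> dict[str, float]:
        """Flat mapping keyed TS1..TR8, suitable for YAML/JSON serialization."""
        return {f.name.upper(): getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ThresholdSet":
        return cls(**{k.lower(): float(v) for k, v in mapping.items()})

    def replace(self, **kwargs: float) -> "ThresholdSet":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kwargs)
        return ThresholdSet(**vals)


_POSTPROCESSOR_BY_CLASS: dict[ImageClass, Postprocessor] = {
    ImageClass.A: Postprocessor.MORPH_SET1,
    ImageClass.B: Postprocessor.MORPH_SET1,
    ImageClass.C: Postprocessor.MORPH_SET1,
    ImageClass.D: Postprocessor.MORPH_SET2,
    ImageClass.E: Postprocessor.MORPH_SET1,
    ImageClass.F: Postprocessor.MORPH_SET2,
    ImageClass.G: Postprocessor.MORPH_SET3,
    ImageClass.H: Postprocessor.NONE,
    ImageClass.I: Postprocessor.HOMOGENEITY,
    ImageClass.K: Postprocessor.HOMOGENEITY,
    ImageClass.L: Postprocessor.HOMOGENEITY,
}


def classify(
    features: FeatureVector,
    thresholds: ThresholdSet | None = None,
    *,
    border_inclusive: bool = True,
) -> ImageClass:
    """Assign an image class from its feature vector.

    The tree first tests for background bleed-through (class G): a high skin
    ratio with few components whose border frame is saturated with skin.
    With the default ``tb1 = 1`` and BSR bounded by 1, the border test is
    taken as ``BSR >= tb1`` (``border_inclusive=True``); a strict ``>``
    comparison would make G unreachable and can be selected for sensitivity
    analysis.  Unless G fired, a high skin ratio (``SR > ts2``) routes
    through the per-component-count interval tests, and a low skin ratio
    (``SR < ts3``) splits into B/D/F by component count alone.  An image
    with no skin regions at all is class H, as is an image whose skin ratio
    falls in neither branch.
    """
    th = thresholds or ThresholdSet()
    sr = features.skin_ratio
    cc = features.component_count
    bsr = features.border_skin_ratio
    sr2 = features.dominant_ratio
    lrr = features.largest_region_ratio

    if cc == 0:
        return ImageClass.H

    cls = ImageClass.H
    if sr > th.ts1 and cc < 6:
        border_hit = bsr >= th.tb1 if border_inclusive else bsr > th.tb1
        if border_hit:
            cls = ImageClass.G

    if cls is not ImageClass.G and sr > th.ts2:
        if cc == 1:
            cls = ImageClass.I if th.tl1 <= lrr <= th.tl2 else ImageClass.A
        elif cc == 2:
            cls = ImageClass.I if th.tr1 <= sr2 <= th.tr2 else ImageClass.A
        elif cc == 3:
            cls = ImageClass.I if th.tr3 <= sr2 <= th.tr4 else ImageClass.A
        elif cc == 4:
            cls = ImageClass.K if th.tr5 <= sr2 <= th.tr6 else ImageClass.C
        elif cc == 5:
            cls = ImageClass.C
        elif cc in (6, 7):
            cls = ImageClass.L if th.tr7 <= sr2 <= th.tr8 else ImageClass.E
        else:
            cls = ImageClass.E

    if cls is not ImageClass.G and sr < th.ts3:
        if cc < 4:
            cls = ImageClass.B
        elif cc < 6:
            cls = ImageClass.D
        else:
            cls = ImageClass.F

    return cls


def postprocessor_for(image_class: ImageClass) -> Postprocessor:
    """The postprocessing route selected by an image class (see module table)."""
    return _POSTPROCESSOR_BY_CLASS[ImageClass(image_class)]


def tune_thresholds(
    training_pairs: Sequence[tuple],
    search_grid: Mapping[str, Sequence[float]],
    seed: int = 0,
    config=None,
) -> ThresholdSet:
    """Greedy coordinate-wise grid search for decision-tree thresholds.

    Starting from the default :class:`ThresholdSet`, each threshold named in
    ``search_grid`` (keys TS1..TR8, case-insensitive) is swept in declaration
    order over its candidate values, scoring each candidate by the pooled
    pixel F1 of the full pipeline over ``training_pairs`` (SPM, truth mask).
    A candidate replaces the incumbent only on a strict improvement, and
    sweeps repeat until a full pass changes nothing, so the result is
    deterministic given the inputs.  ``seed`` is accepted for interface
    stability; the search itself has no random component.

    Raises
    ------
    ValueError
        If ``training_pairs`` is empty or the grid names an unknown threshold.
    """
    from .evaluation import confusion_counts, pooled_f1
    from .pipeline import PipelineConfig, post_process

    del seed  # deterministic search
    if not training_pairs:
        raise ValueError("tune_thresholds requires at least one training pair")
    grid = {k.lower(): list(v) for k, v in search_grid.items()}
    valid_names = {f.name for f in fields(ThresholdSet)}
    unknown = set(grid) - valid_names
    if unknown:
        raise ValueError(f"unknown thresholds in grid: {sorted(unknown)}")
    for name, values in grid.items():
        if not values:
            raise ValueError(f"empty grid for {name}")

    base_config = config or PipelineConfig()

    def score(th: ThresholdSet) -> float:
        cfg = base_config.with_thresholds(th)
        counts = [
            confusion_counts(post_process(spm, cfg).mask, truth)
            for spm, truth in training_pairs
        ]
        return pooled_f1(counts)

    current = base_config.thresholds
    current_score = score(current)
    sweep_order = [f.name for f in fields(ThresholdSet) if f.name in grid]

    improved = True
    while improved:
        improved = False
        for name in sweep_order:
            for value in grid[name]:
                if value == getattr(current, name):
                    continue
                try:
                    candidate = current.replace(**{name: value})
                except ValueError:
                    continue  # candidate violates interval ordering
                cand_score = score(candidate)
                if cand_score > current_score:
                    current, current_score = candidate, cand_score
                    improved = True
    return current
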