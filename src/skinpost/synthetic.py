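"""Synthetic SPM / ground-truth generator for the eleven detection scenarios.

Real skin probability maps come from a segmentation network applied to
photographs; what the postprocessing pipeline actually consumes, though, is
region geometry: how much of the frame is skin, how many regions there are,
whether one region dominates, and whether the border is saturated.  The
generator therefore emulates each scenario with non-overlapping elliptical
blobs on a flat background — foreground blobs at a high mean score,
background at a low one, plus clipped Gaussian pixel noise.  Two artifact
types of real detectors can be added: a high-score border frame (background
bleed-through, the class-G situation) and isolated high-score speckle
pixels (false positives that the morphological sequences are designed to
remove).  Both artifacts go into the SPM only, never into the ground truth.

Generation is a pure function of the :class:`ScenarioSpec`, including its
seed, so every test and experiment is reproducible without stored fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .classify import ImageClass

__all__ = ["ScenarioSpec", "generate", "class_suite", "target_skin_fraction"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic SPM / ground-truth pair.

    ``blob_count`` includes the dominant blob when ``dominant_radius`` is
    set; the remaining blobs draw a radius uniformly from
    ``blob_radius_range`` and an axis-aspect from ``aspect_range``.
    ``fg_probability``/``bg_probability`` are mean SPM values on [0, 255]
    inside/outside the truth; ``noise_sd`` is the Gaussian pixel noise.
    ``border_bleed`` paints a ``border_width``-pixel high-score frame into
    the SPM; ``salt_count`` sprinkles isolated high-score pixels.  ``margin``
    is the minimum spacing kept between blobs and to the image edge.
    """

    name: str
    blob_count: int
    image_size: tuple[int, int] = (256, 256)
    blob_radius_range: tuple[int, int] = (10, 20)
    dominant_radius: int | None = None
    fg_probability: float = 230.0
    bg_probability: float = 10.0
    noise_sd: float = 5.0
    border_bleed: bool = False
    border_width: int = 4
    salt_count: int = 0
    aspect_range: tuple[float, float] = (0.95, 1.05)
    margin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blob_count < 0:
            raise ValueError("blob_count must be >= 0")
        if self.fg_probability <= self.bg_probability:
            raise ValueError("fg_probability must exceed bg_probability")
        if self.blob_radius_range[0] > self.blob_radius_range[1]:
            raise ValueError("blob_radius_range must be (min, max)")
        if self.dominant_radius is not None and self.blob_count < 1:
            raise ValueError("a dominant blob requires blob_count >= 1")


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def target_skin_fraction(spec: ScenarioSpec) -> float:
    """Expected ground-truth skin fraction implied by the blob geometry."""
    h, w = spec.image_size
    rmin, rmax = spec.blob_radius_range
    mean_r2 = (rmin * rmin + rmin * rmax + rmax * rmax) / 3.0  # E[r^2], r ~ U
    mean_aspect = sum(spec.aspect_range) / 2.0
    n_regular = spec.blob_count - (1 if spec.dominant_radius is not None else 0)
    area = n_regular * np.pi * mean_r2 * mean_aspect
    if spec.dominant_radius is not None:
        area += np.pi * spec.dominant_radius**2
    return float(area / (h * w))


def generate(spec: ScenarioSpec, max_tries: int = 400,
             max_restarts: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Generate one ``(spm, truth)`` pair from a scenario spec.

    Blobs are placed by rejection sampling with a spacing of ``margin``
    pixels so that regions stay disconnected under 8-neighborhood labeling.
    If a blob cannot be placed in ``max_tries`` attempts (an early blob
    blocked the layout), the whole layout is resampled, up to
    ``max_restarts`` times.

    Raises
    ------
    RuntimeError
        If no feasible layout is found within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    spacing = ndi.generate_binary_structure(2, 2)
    edge_margin = spec.margin + (spec.border_width + 2 if spec.border_bleed else 0)

    radii: list[tuple[float, float]] = []
    for i in range(spec.blob_count):
        if spec.dominant_radius is not None and i == 0:
            radii.append((float(spec.dominant_radius), float(spec.dominant_radius)))
        else:
            r = rng.uniform(*spec.blob_radius_range)
            aspect = rng.uniform(*spec.aspect_range)
            radii.append((r, max(1.0, r * aspect)))

    truth = occupancy = None
    for _ in range(max_restarts):
        truth = np.zeros((h, w), dtype=bool)
        occupancy = np.zeros((h, w), dtype=bool)
        layout_ok = True
        for ry, rx in radii:
            placed = False
            for _ in range(max_tries):
                cy = rng.uniform(edge_margin + ry, h - 1 - edge_margin - ry)
                cx = rng.uniform(edge_margin + rx, w - 1 - edge_margin - rx)
                blob = _ellipse(h, w, cy, cx, ry, rx)
                if not (blob & occupancy).any():
                    truth |= blob
                    occupancy |= ndi.binary_dilation(blob, spacing,
                                                     iterations=spec.margin)
                    placed = True
                    break
            if not placed:
                layout_ok = False
                break
        if layout_ok:
            break
    else:
        raise RuntimeError(
            f"could not place {spec.blob_count} blobs in scenario "
            f"{spec.name!r} within {max_restarts} layout attempts"
        )

    base = np.full((h, w), spec.bg_probability, dtype=np.float64)
    base[truth] = spec.fg_probability

    if spec.border_bleed:
        bw = spec.border_width
        base[:bw, :] = spec.fg_probability
        base[-bw:, :] = spec.fg_probability
        base[:, :bw] = spec.fg_probability
        base[:, -bw:] = spec.fg_probability

    if spec.salt_count:
        frame = np.zeros((h, w), dtype=bool)
        if spec.border_bleed:
            bw = spec.border_width
            frame[:bw, :] = frame[-bw:, :] = True
            frame[:, :bw] = frame[:, -bw:] = True
        candidates = np.flatnonzero(~occupancy & ~frame)
        chosen = rng.choice(candidates, size=spec.salt_count, replace=False)
        base.ravel()[chosen] = spec.fg_probability

    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=(h, w))
    spm = np.clip(np.round(base), 0, 255).astype(np.uint8)
    return spm, truth


def class_suite(seed: int = 0) -> list[tuple[ScenarioSpec, ImageClass]]:
    """One scenario per image class, plus speckled variants, with intended labels.

    The dominant-region scenarios (I, K, L) differ from their A/C/E
    counterparts only in that one blob's area dominates, placing SR2 inside
    the corresponding decision interval; class G adds border bleed; class H
    is the flat no-response map.  Two speckled variants exercise the
    false-positive cleanup on classes whose component-count branch tolerates
    extra regions (E and F).  Per-scenario seeds are derived from ``seed``.
    """

    def s(i: int) -> int:
        return (seed * 1009 + i) % (2**31)

    specs: list[tuple[ScenarioSpec, ImageClass]] = [
        (ScenarioSpec("foreground-near", blob_count=2, blob_radius_range=(54, 60),
                      seed=s(1)), ImageClass.A),
        (ScenarioSpec("foreground-far", blob_count=2, blob_radius_range=(24, 27),
                      seed=s(2)), ImageClass.B),
        (ScenarioSpec("body-parts-near", blob_count=5, image_size=(320, 320),
                      blob_radius_range=(38, 42), seed=s(3)), ImageClass.C),
        (ScenarioSpec("body-parts-far", blob_count=5, blob_radius_range=(17, 19),
                      seed=s(4)), ImageClass.D),
        (ScenarioSpec("group-near", blob_count=8, image_size=(320, 320),
                      blob_radius_range=(28, 31), seed=s(5)), ImageClass.E),
        (ScenarioSpec("group-far", blob_count=8, image_size=(320, 320),
                      blob_radius_range=(13, 15), seed=s(6)), ImageClass.F),
        (ScenarioSpec("background-bleed", blob_count=1, blob_radius_range=(50, 54),
                      border_bleed=True, border_width=5, seed=s(7)), ImageClass.G),
        (ScenarioSpec("no-skin", blob_count=0, bg_probability=0.0,
                      fg_probability=230.0, noise_sd=0.0, seed=s(8)), ImageClass.H),
        (ScenarioSpec("foreground-near-dominant", blob_count=2, dominant_radius=80,
                      blob_radius_range=(3, 4), seed=s(9)), ImageClass.I),
        (ScenarioSpec("body-parts-dominant", blob_count=4, dominant_radius=80,
                      blob_radius_range=(5, 6), seed=s(10)), ImageClass.K),
        (ScenarioSpec("group-dominant", blob_count=6, dominant_radius=80,
                      blob_radius_range=(10, 12), seed=s(11)), ImageClass.L),
        (ScenarioSpec("group-near-speckled", blob_count=8, image_size=(320, 320),
                      blob_radius_range=(28, 31), salt_count=50, seed=s(12)),
         ImageClass.E),
        (ScenarioSpec("group-far-speckled", blob_count=8, image_size=(320, 320),
                      blob_radius_range=(13, 15), salt_count=50, seed=s(13)),
         ImageClass.F),
    ]
    return specs


def suite_with_seed(suite: Sequence[tuple[ScenarioSpec, ImageClass]], seed: int):
    """Re-seed an existing suite (helper for Monte-Carlo style checks)."""
    return [(replace(spec, seed=(seed * 7919 + i) % (2**31)), cls)
            for i, (spec, cls) in enumerate(suite)]
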