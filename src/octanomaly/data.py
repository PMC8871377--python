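"""Core data containers shared across the pipeline.

A :class:`LabeledImage` is one grayscale B-scan-like intensity array in
``[0, 1]`` with a three-way morphology label (NORMAL / DRY_AMD / WET_AMD).
The detection task itself is binary — both AMD forms count as positive —
so every image also carries a derived binary label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np


class Label(str, enum.Enum):
    """Morphological class of a B-scan."""

    NORMAL = "NORMAL"
    DRY_AMD = "DRY_AMD"
    WET_AMD = "WET_AMD"
    AMD = "AMD"  # pre-binarized data where the dry/wet morphology is unknown

    @property
    def binary(self) -> "BinaryLabel":
        return BinaryLabel.NORMAL if self is Label.NORMAL else BinaryLabel.AMD


class BinaryLabel(str, enum.Enum):
    """Detection-level class: AMD is the positive class."""

    NORMAL = "NORMAL"
    AMD = "AMD"


@dataclass
class LabeledImage:
    """One intensity image plus its labels.

    ``pixels`` is a 2-D float array in ``[0, 1]`` (channel replication to
    RGB happens at network-input time).  ``meta`` carries generator-side
    ground truth (band centerlines, lesion intervals) used by tests and
    never consumed by the detector.
    """

    pixels: np.ndarray
    label: Label
    source: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        self.label = Label(self.label)

    @property
    def binary_label(self) -> BinaryLabel:
        return self.label.binary


class ImageSet:
    """An ordered collection of :class:`LabeledImage`."""

    def __init__(self, images: Sequence[LabeledImage]):
        self.images = list(images)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[LabeledImage]:
        return iter(self.images)

    def __getitem__(self, idx):
        if isinstance(idx, (list, np.ndarray)):
            return ImageSet([self.images[i] for i in np.asarray(idx).ravel()])
        if isinstance(idx, slice):
            return ImageSet(self.images[idx])
        return self.images[idx]

    @property
    def labels(self) -> list[Label]:
        return [im.label for im in self.images]

    @property
    def binary_labels(self) -> list[BinaryLabel]:
        return [im.binary_label for im in self.images]

    def subset(self, mask) -> "ImageSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ImageSet([self.images[i] for i in idx])

    def count(self, label: Label | BinaryLabel) -> int:
        if isinstance(label, BinaryLabel):
            return sum(1 for im in self.images if im.binary_label == label)
        return sum(1 for im in self.images if im.label == label)
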