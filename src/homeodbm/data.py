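"""Synthetic shapes corpus and input-degradation operators.

The corpus consists of binary images of filled squares and filled isoceles
triangles (pointing up or down), each in two size classes, placed at every
valid position of the image grid.  Degradation operators model loss or
corruption of visual input: pepper masking, blank images, salt noise,
half-field blanking and fixed-image providers.

An optional loader for the MNIST IDX format is provided; nothing in the
package requires it.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "CATEGORIES",
    "SIZE_CLASSES",
    "CLASS_NAMES",
    "ShapeSpec",
    "ShapesDataset",
    "render_shape",
    "shape_glyph",
    "enumerate_instances",
    "sample_dataset",
    "corrupt_pepper",
    "blank",
    "salt_noise",
    "half_blank",
    "fixed_image_provider",
    "dataset_provider",
    "blank_provider",
    "salt_provider",
    "load_mnist",
]

CATEGORIES = ("square", "triangle_up", "triangle_down")
SIZE_CLASSES = ("small", "large")

#: canonical class ordering: category-major, then size class
CLASS_NAMES = tuple(f"{c}_{s}" for c in CATEGORIES for s in SIZE_CLASSES)


@dataclass(frozen=True)
class ShapeSpec:
    """A single shape instance: what, how large, and where."""

    category: str
    size_class: str
    side: int
    position: tuple[int, int]  # (row, col) of the bounding-box top-left, 0-based

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.side < 1:
            raise ValueError("side must be >= 1")

    @property
    def class_index(self) -> int:
        return CLASS_NAMES.index(f"{self.category}_{self.size_class}")


@dataclass
class ShapesDataset:
    """Binary images with per-image shape labels."""

    images: np.ndarray  # (n, H*W) float64 in {0, 1}
    labels: list[ShapeSpec]
    image_size: tuple[int, int]
    sides: dict[str, int] = field(default_factory=dict)  # size_class -> side

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_pixels(self) -> int:
        h, w = self.image_size
        return h * w

    @property
    def class_indices(self) -> np.ndarray:
        return np.array([s.class_index for s in self.labels], dtype=int)

    def image(self, i: int) -> np.ndarray:
        """Return image ``i`` as a 2-D array."""
        return self.images[i].reshape(self.image_size)


def shape_glyph(category: str, side: int) -> np.ndarray:
    """Binary bounding-box glyph (side x side) for a shape category.

    Squares are fully filled.  Upward triangles have row widths growing from
    1 at the top to ``side`` at the bottom; downward triangles are the
    vertical mirror image.
    """
    if category == "square":
        return np.ones((side, side))
    glyph = np.zeros((side, side))
    for i in range(side):  # row i from the top has width i + 1, centred
        width = i + 1
        left = (side - width) // 2
        glyph[i, left : left + width] = 1.0
    if category == "triangle_down":
        glyph = glyph[::-1].copy()
    elif category != "triangle_up":
        raise ValueError(f"unknown category {category!r}")
    return glyph


def render_shape(spec: ShapeSpec, image_size: tuple[int, int]) -> np.ndarray:
    """Render a shape instance into a blank binary image (2-D array)."""
    h, w = image_size
    r, c = spec.position
    s = spec.side
    if r < 0 or c < 0 or r + s > h or c + s > w:
        raise ValueError(f"shape {spec} does not fit in a {h}x{w} image")
    image = np.zeros(image_size)
    image[r : r + s, c : c + s] = shape_glyph(spec.category, s)
    return image


def enumerate_instances(
    image_size: tuple[int, int], sides: dict[str, int] | None = None
) -> ShapesDataset:
    """All distinct shape placements: every (category, size, position) once."""
    if sides is None:
        sides = {"small": 6, "large": 10}
    h, w = image_size
    images: list[np.ndarray] = []
    labels: list[ShapeSpec] = []
    for category in CATEGORIES:
        for size_class in SIZE_CLASSES:
            s = sides[size_class]
            for r in range(h - s + 1):
                for c in range(w - s + 1):
                    spec = ShapeSpec(category, size_class, s, (r, c))
                    images.append(render_shape(spec, image_size).ravel())
                    labels.append(spec)
    return ShapesDataset(np.array(images), labels, image_size, dict(sides))


def sample_dataset(
    n: int,
    seed: int | np.random.Generator,
    image_size: tuple[int, int] = (20, 20),
    sides: dict[str, int] | None = None,
) -> ShapesDataset:
    """Draw ``n`` instances with replacement from the full enumeration."""
    rng = np.random.default_rng(seed)
    full = enumerate_instances(image_size, sides)
    idx = rng.integers(0, len(full), size=n)
    return ShapesDataset(
        full.images[idx], [full.labels[i] for i in idx], image_size, full.sides
    )


# ---------------------------------------------------------------------------
# degradation operators
# ---------------------------------------------------------------------------


def corrupt_pepper(
    image: np.ndarray, fraction: float = 0.65, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Force a uniformly chosen ``round(fraction * n_pixels)`` subset to 0.

    Positions are sampled without replacement, so the masked count is exact
    per image; pixels outside the subset are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flat = np.asarray(image, dtype=float).ravel().copy()
    k = int(round(fraction * flat.size))
    if k:
        flat[rng.choice(flat.size, size=k, replace=False)] = 0.0
    return flat.reshape(np.shape(image))


def blank(image: np.ndarray) -> np.ndarray:
    """All-zero image of the same shape (models empty input)."""
    return np.zeros_like(np.asarray(image, dtype=float))


def salt_noise(
    image_size: tuple[int, int],
    fraction: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """White pixels at exactly ``round(fraction * n_pixels)`` uniform positions."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = image_size
    flat = np.zeros(h * w)
    k = int(round(fraction * flat.size))
    if k:
        flat[rng.choice(flat.size, size=k, replace=False)] = 1.0
    return flat.reshape(image_size)


def half_blank(image: np.ndarray, half: str = "top") -> np.ndarray:
    """Zero the chosen half of the image.

    The top half is rows ``0 .. ceil(H/2) - 1`` (0-based, row-major); this
    convention is used throughout the package.
    """
    image = np.asarray(image, dtype=float).copy()
    if image.ndim != 2:
        raise ValueError("half_blank expects a 2-D image")
    h = image.shape[0]
    split = (h + 1) // 2
    if half == "top":
        image[:split] = 0.0
    elif half == "bottom":
        image[split:] = 0.0
    else:
        raise ValueError("half must be 'top' or 'bottom'")
    return image


# ---------------------------------------------------------------------------
# trial input providers: callables (rng, n) -> (n, n_pixels) batch
# ---------------------------------------------------------------------------

Provider = Callable[[np.random.Generator, int], np.ndarray]


def fixed_image_provider(image: np.ndarray) -> Provider:
    """Provider returning the same image on every trial."""
    flat = np.asarray(image, dtype=float).ravel()

    def provide(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.tile(flat, (n, 1))

    return provide


def blank_provider(n_pixels: int) -> Provider:
    def provide(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.zeros((n, n_pixels))

    return provide


def salt_provider(image_size: tuple[int, int], fraction: float = 0.10) -> Provider:
    def provide(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.stack(
            [salt_noise(image_size, fraction, rng).ravel() for _ in range(n)]
        )

    return provide


def dataset_provider(
    dataset: ShapesDataset,
    transform: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    with_labels: bool = False,
) -> Provider:
    """Draw random dataset images per trial, optionally transformed (2-D in/out).

    With ``with_labels`` the provider returns ``(batch, class_indices)`` so
    downstream scoring can compare against the true categories.
    """
    class_indices = dataset.class_indices

    def provide(rng: np.random.Generator, n: int):
        idx = rng.integers(0, len(dataset), size=n)
        batch = dataset.images[idx]
        if transform is not None:
            batch = np.stack(
                [
                    transform(im.reshape(dataset.image_size), rng).ravel()
                    for im in batch
                ]
            )
        if with_labels:
            return batch, class_indices[idx]
        return batch

    return provide


# ---------------------------------------------------------------------------
# MNIST (optional)
# ---------------------------------------------------------------------------


def load_mnist(
    images_path: str, labels_path: str | None = None, binarize: float = 0.5
) -> tuple[np.ndarray, np.ndarray | None]:
    """Load MNIST from standard IDX files, binarizing at ``binarize``.

    Returns ``(images, labels)`` with images of shape (n, 784) in {0, 1}.
    Never required by the test suite.
    """
    with open(images_path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">IIII", fh.read(16))
        if magic != 2051:
            raise ValueError(f"not an IDX image file (magic {magic})")
        raw = np.frombuffer(fh.read(n * rows * cols), dtype=np.uint8)
    images = (raw.reshape(n, rows * cols) / 255.0 >= binarize).astype(float)
    labels = None
    if labels_path is not None:
        with open(labels_path, "rb") as fh:
            magic, n_lab = struct.unpack(">II", fh.read(8))
            if magic != 2049:
                raise ValueError(f"not an IDX label file (magic {magic})")
            labels = np.frombuffer(fh.read(n_lab), dtype=np.uint8).astype(int)
    return images, labels
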