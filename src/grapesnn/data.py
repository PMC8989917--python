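"""Download-free MNIST-like data generation, augmentation and IDX I/O.

The generator draws 10 distinct stroke-pattern glyphs on a 28x28 grid,
applies per-sample random affine jitter (shift/rotation/scale) and additive
pixel noise, and clips intensities to [0, 1].  The result is a balanced,
spatially structured classification task with the same geometry and value
range as MNIST, so every experiment in the package — including rate-coded
spiking input and pixel-permutation task sequences — runs without any
download.  It does not reproduce MNIST's statistics (stroke thickness
variation, writing styles), only its format and coarse difficulty.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LabeledImageSet",
    "generate_digits",
    "make_dataset",
    "augment_affine_elastic",
    "read_idx",
    "write_idx",
    "load_idx_dataset",
    "IdxFormatError",
]


@dataclass
class LabeledImageSet:
    """Images (count, H, W) with intensities in [0,1] and integer labels."""

    images: np.ndarray
    labels: np.ndarray
    split: str = "train"
    seed: int | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must be (count, H, W)")
        if len(self.images) != len(self.labels):
            raise ValueError("images/labels length mismatch")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("intensities must lie in [0, 1]")

    def flat(self) -> np.ndarray:
        """Images flattened to (count, H*W), for dense networks."""
        return self.images.reshape(len(self.images), -1)

    def __len__(self) -> int:
        return len(self.images)


# 7x7 stroke templates, one per class, upscaled to 28x28.  Every glyph has
# exactly 20 on-cells, so the pixel-value histogram is class-independent:
# class identity lives in the spatial arrangement only.  This matters for
# the permuted-pixel protocol — a permutation preserves each image's pixel
# multiset, so any histogram shortcut would make permuted tasks trivially
# transferable, unlike the handwritten digits they emulate.
_GLYPHS = [
    ".#####."
    "#.....#"
    "#.....#"
    "#.....#"
    "#.....#"
    "#.....#"
    ".#####.",  # 0: ring

    "..##..."
    ".###..."
    "..##..."
    "..##..."
    "..##..."
    "..##..."
    "#######",  # 1: vertical stroke with base

    ".#####."
    "......#"
    "......#"
    ".#####."
    "#......"
    "#......"
    "######.",  # 2: S-bend

    "######."
    "......#"
    "......#"
    "..####."
    "......#"
    "......#"
    "######.",  # 3: double bump

    "##..#.."
    "##..#.."
    "#...#.."
    "#######"
    "....#.."
    "....#.."
    "..###..",  # 4: cross-bar

    "#######"
    "#......"
    "#......"
    "######."
    "......#"
    "......#"
    "###....",  # 5: mirrored S

    ".#####."
    "#......"
    "#......"
    "#####.."
    "#...#.."
    "#...#.."
    ".####..",  # 6: lower loop

    "#######"
    ".....##"
    "....##."
    "...##.."
    "..##..."
    "..##..."
    ".###...",  # 7: diagonal

    ".#####."
    "#.....#"
    ".#####."
    "#.....#"
    "#.....#"
    ".####.."
    ".......",  # 8: double loop

    ".#####."
    "#.....#"
    "#.....#"
    ".######"
    "......#"
    "......#"
    "..###..",  # 9: upper loop
]


def _templates(side: int) -> np.ndarray:
    """Upscale the 7x7 string glyphs to side x side float templates."""
    base = np.array(
        [[1.0 if ch == "#" else 0.0 for ch in g] for g in _GLYPHS]
    ).reshape(10, 7, 7)
    zoom = side / 7.0
    out = np.stack([
        ndimage.zoom(t, zoom, order=1, prefilter=False) for t in base
    ])
    return np.clip(out, 0.0, 1.0)


def _affine_jitter(img: np.ndarray, rng: np.random.Generator,
                   max_rot: float, max_shift: float, max_scale: float) -> np.ndarray:
    angle = rng.uniform(-max_rot, max_rot) * np.pi / 180.0
    scale = 1.0 + rng.uniform(-max_scale, max_scale)
    shift = rng.uniform(-max_shift, max_shift, size=2)
    c, s = np.cos(angle), np.sin(angle)
    mat = np.array([[c, -s], [s, c]]) / scale
    center = (np.array(img.shape) - 1) / 2.0
    offset = center - mat @ (center + shift)
    return ndimage.affine_transform(img, mat, offset=offset, order=1, mode="constant")


def generate_digits(n: int, n_classes: int = 10, side: int = 28,
                    rng: np.random.Generator | None = None,
                    noise: float = 0.15, max_rot: float = 12.0,
                    max_shift: float = 2.0, max_scale: float = 0.12,
                    split: str = "train", seed: int | None = None) -> LabeledImageSet:
    """Generate a balanced synthetic digit set.

    Each sample is its class glyph under random affine jitter plus additive
    Gaussian pixel noise, clipped to [0, 1].  Classes are exactly balanced
    when ``n`` is divisible by ``n_classes``; the remainder goes to the
    lowest class indices.  Deterministic for a given generator state.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_classes < 2 or n_classes > 10:
        raise ValueError("n_classes must be in [2, 10]")
    if n < n_classes:
        raise ValueError("need at least one sample per class")
    if side < 7:
        raise ValueError("side must be >= 7")
    templates = _templates(side)[:n_classes]
    labels = np.arange(n) % n_classes
    rng.shuffle(labels)
    images = np.empty((n, side, side))
    for i, lab in enumerate(labels):
        img = _affine_jitter(templates[lab], rng, max_rot, max_shift, max_scale)
        img = img + rng.normal(0.0, noise, size=img.shape)
        images[i] = np.clip(img, 0.0, 1.0)
    return LabeledImageSet(images, labels, split=split, seed=seed)


def make_dataset(n_train: int, n_test: int, seed: int,
                 n_classes: int = 10, side: int = 28, **kw) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Train/test pair from one master seed (independent RNG streams)."""
    ss = np.random.SeedSequence(seed)
    s_train, s_test = ss.spawn(2)
    train = generate_digits(n_train, n_classes, side,
                            rng=np.random.default_rng(s_train), split="train",
                            seed=seed, **kw)
    test = generate_digits(n_test, n_classes, side,
                           rng=np.random.default_rng(s_test), split="test",
                           seed=seed, **kw)
    return train, test


def augment_affine_elastic(dataset: LabeledImageSet,
                           rng: np.random.Generator,
                           max_rot: float = 10.0, max_shift: float = 2.0,
                           max_scale: float = 0.1,
                           elastic_alpha: float = 4.0,
                           elastic_sigma: float = 4.0) -> LabeledImageSet:
    """Affine plus elastic deformation of every image; labels untouched.

    The elastic part displaces pixels along a Gaussian-smoothed random
    vector field of magnitude ``elastic_alpha`` (pixels) and smoothing
    scale ``elastic_sigma`` (pixels).  Zero magnitudes yield the identity
    bit-for-bit: the corresponding transform stage is skipped entirely.
    """
    for v in (max_rot, max_shift, max_scale, elastic_alpha, elastic_sigma):
        if v < 0:
            raise ValueError("augmentation magnitudes must be >= 0")
    do_affine = (max_rot > 0) or (max_shift > 0) or (max_scale > 0)
    do_elastic = elastic_alpha > 0
    images = dataset.images.copy()
    side = images.shape[1:]
    grid = np.meshgrid(*[np.arange(s, dtype=float) for s in side], indexing="ij")
    for i in range(len(images)):
        img = images[i]
        if do_affine:
            img = _affine_jitter(img, rng, max_rot, max_shift, max_scale)
        if do_elastic:
            disp = [
                ndimage.gaussian_filter(
                    rng.uniform(-1, 1, size=side), elastic_sigma
                ) * elastic_alpha
                for _ in side
            ]
            coords = [g + d for g, d in zip(grid, disp)]
            img = ndimage.map_coordinates(img, coords, order=1, mode="constant")
        images[i] = np.clip(img, 0.0, 1.0)
    return LabeledImageSet(images, dataset.labels.copy(),
                           split=dataset.split, seed=dataset.seed)


# ---------------------------------------------------------------------------
# IDX container (the MNIST dialect: big-endian, magic = 0x00 0x00 dtype ndim)

class IdxFormatError(ValueError):
    pass


_IDX_DTYPES = {
    0x08: np.dtype(">u1"),
    0x09: np.dtype(">i1"),
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}
_IDX_CODES = {v.base.newbyteorder("="): k for k, v in _IDX_DTYPES.items()}


def read_idx(path) -> np.ndarray:
    """Read an IDX tensor; raises :class:`IdxFormatError` on malformed files."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise IdxFormatError("truncated header at offset 0")
    zero1, zero2, code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0 or code not in _IDX_DTYPES:
        raise IdxFormatError(f"bad magic number at offset 0: {raw[:4]!r}")
    header_end = 4 + 4 * ndim
    if len(raw) < header_end:
        raise IdxFormatError(f"truncated dimension header at offset {len(raw)}")
    dims = struct.unpack(f">{ndim}I", raw[4:header_end])
    dtype = _IDX_DTYPES[code]
    expected = int(np.prod(dims)) * dtype.itemsize
    payload = raw[header_end:]
    if len(payload) != expected:
        raise IdxFormatError(
            f"payload length {len(payload)} at offset {header_end} does not "
            f"match dims {dims} x {dtype.itemsize} bytes = {expected}"
        )
    return np.frombuffer(payload, dtype=dtype).reshape(dims).astype(
        dtype.base.newbyteorder("="))


def write_idx(tensor: np.ndarray, path) -> None:
    """Write a tensor in the big-endian IDX container format."""
    tensor = np.asarray(tensor)
    native = tensor.dtype.newbyteorder("=")
    if native not in _IDX_CODES:
        raise IdxFormatError(f"dtype {tensor.dtype} not representable in IDX")
    code = _IDX_CODES[native]
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, code, tensor.ndim))
        fh.write(struct.pack(f">{tensor.ndim}I", *tensor.shape))
        fh.write(tensor.astype(_IDX_DTYPES[code]).tobytes())


def load_idx_dataset(images_path, labels_path, split: str = "train") -> LabeledImageSet:
    """Load an MNIST-layout pair of IDX files; uint8 images scaled to [0,1]."""
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if images.ndim != 3:
        raise IdxFormatError("image tensor must be 3-D (count, H, W)")
    if labels.ndim != 1:
        raise IdxFormatError("label tensor must be 1-D")
    return LabeledImageSet(images.astype(float) / 255.0, labels, split=split)
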