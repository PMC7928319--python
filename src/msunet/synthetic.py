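"""Seedable synthetic image/mask generation and the data-split protocol.

Four styles emulate the shape of common binary biomedical segmentation tasks
without any real data:

* ``blobs``     — one-to-a-few elliptical lesions, darker than the speckled
                  background (breast-ultrasound / dermoscopy lesion analogue);
                  mask foreground = lesion.
* ``membranes`` — tessellated cell interiors separated by thin dark walls
                  (electron-microscopy analogue); mask foreground = cell
                  interiors (white), membranes = background (black).
* ``bilobe``    — two large smooth dark regions on a brighter field
                  (chest-radiograph lung-field analogue); foreground = lobes.
* ``nuclei``    — many small dark blobs on a bright field (histology nuclei
                  analogue, 3-channel); foreground = nuclei.

Splitting follows the evaluation protocol used throughout the ablations: the
images are randomly divided into six near-equal subsets; one subset is held
out as the test set and the remaining pool is used for five-fold cross
validation with a fixed 4:1 train:validation ratio within each fold.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "SyntheticStyle", "Dataset", "SplitPlan",
    "synthesize_dataset", "make_splits", "write_dataset", "read_dataset",
    "STYLE_NAMES",
]

STYLE_NAMES = ("blobs", "membranes", "bilobe", "nuclei")

_STYLE_DEFAULTS = {
    #          channels, noise_sigma, speckle, objects
    "blobs": (1, 0.03, 0.25, (1, 3)),
    "membranes": (1, 0.05, 0.0, (6, 14)),
    "bilobe": (1, 0.04, 0.0, (2, 2)),
    "nuclei": (3, 0.04, 0.0, (8, 25)),
}


@dataclass(frozen=True)
class SyntheticStyle:
    """Generation recipe for one synthetic modality."""

    name: str = "blobs"
    image_size: int = 64
    channels: int | None = None     # None: per-style default
    noise_sigma: float | None = None
    speckle: float | None = None
    objects: tuple[int, int] | None = None

    def __post_init__(self):
        if self.name not in STYLE_NAMES:
            raise ValueError(f"unknown style {self.name!r}; choose from {STYLE_NAMES}")
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16")
        ch, sig, spk, obj = _STYLE_DEFAULTS[self.name]
        object.__setattr__(self, "channels", self.channels if self.channels is not None else ch)
        object.__setattr__(self, "noise_sigma",
                           sig if self.noise_sigma is None else self.noise_sigma)
        object.__setattr__(self, "speckle", spk if self.speckle is None else self.speckle)
        object.__setattr__(self, "objects", tuple(obj if self.objects is None else self.objects))
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.noise_sigma < 0 or self.speckle < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class Dataset:
    """In-memory image/mask pairs: images (C,H,W) float32 in [0,1],
    masks (H,W) uint8 in {0,1}."""

    images: list[np.ndarray] = field(default_factory=list)
    masks: list[np.ndarray] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i) -> tuple[np.ndarray, np.ndarray]:
        return self.images[i], self.masks[i]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grid(size: int):
    return np.meshgrid(np.arange(size), np.arange(size), indexing="ij")


def _ellipse(size: int, cy: float, cx: float, ry: float, rx: float, angle: float):
    yy, xx = _grid(size)
    y, x = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * y + s * x
    v = -s * y + c * x
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _finish(base: np.ndarray, style: SyntheticStyle, rng: np.random.Generator):
    """Smooth the ideal image, apply speckle and additive noise, scale [0,1]."""
    img = ndimage.gaussian_filter(base, sigma=style.image_size / 64.0)
    if style.speckle > 0:
        img = img * (1.0 + style.speckle * rng.standard_normal(img.shape))
    if style.noise_sigma > 0:
        img = img + style.noise_sigma * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    if style.channels == 3:
        jitter = 0.05 * rng.standard_normal((3, 1, 1)).astype(np.float32)
        img = np.clip(img[None] + jitter, 0.0, 1.0)
    else:
        img = img[None]
    return img


# ---------------------------------------------------------------------------
# per-style mask/intensity models
# ---------------------------------------------------------------------------

def _gen_blobs(style, rng):
    size = style.image_size
    n_obj = rng.integers(style.objects[0], style.objects[1] + 1)
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(max(1, n_obj)):
        ry, rx = rng.uniform(0.08, 0.22, 2) * size
        cy = rng.uniform(ry + 1, size - ry - 1)
        cx = rng.uniform(rx + 1, size - rx - 1)
        mask |= _ellipse(size, cy, cx, ry, rx, rng.uniform(0, np.pi))
    base = np.where(mask, 0.25, 0.65)
    return base, mask


def _gen_membranes(style, rng):
    size = style.image_size
    n_cells = int(rng.integers(style.objects[0], style.objects[1] + 1))
    pts = rng.uniform(0, size, (n_cells, 2))
    yy, xx = _grid(size)
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    labels = d2.argmin(axis=-1)
    wall = np.zeros((size, size), dtype=bool)
    wall[:-1] |= labels[:-1] != labels[1:]
    wall[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    wall = ndimage.binary_dilation(wall)  # membranes ~2-3 px thick
    mask = ~wall                          # foreground = cell interiors (white)
    base = np.where(mask, 0.75, 0.15)
    return base, mask


def _gen_bilobe(style, rng):
    size = style.image_size
    mask = np.zeros((size, size), dtype=bool)
    for cx_frac, tilt in ((0.30, 1), (0.70, -1)):
        ry = rng.uniform(0.26, 0.34) * size
        rx = rng.uniform(0.13, 0.18) * size
        cy = rng.uniform(0.45, 0.55) * size
        cx = cx_frac * size + rng.uniform(-0.03, 0.03) * size
        mask |= _ellipse(size, cy, cx, ry, rx, tilt * rng.uniform(0.05, 0.2))
    base = np.where(mask, 0.30, 0.70)
    return base, mask


def _gen_nuclei(style, rng):
    size = style.image_size
    n_obj = int(rng.integers(style.objects[0], style.objects[1] + 1))
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_obj):
        r = rng.uniform(0.02, 0.05) * size
        cy = rng.uniform(r + 1, size - r - 1)
        cx = rng.uniform(r + 1, size - r - 1)
        mask |= _ellipse(size, cy, cx, r, r * rng.uniform(0.7, 1.0), rng.uniform(0, np.pi))
    base = np.where(mask, 0.35, 0.85)
    return base, mask


_GENERATORS = {"blobs": _gen_blobs, "membranes": _gen_membranes,
               "bilobe": _gen_bilobe, "nuclei": _gen_nuclei}


def synthesize_dataset(style: SyntheticStyle, n: int, seed: int) -> Dataset:
    """Generate ``n`` image/mask pairs; bitwise reproducible for a fixed
    (style, n, seed). Every mask has at least one foreground pixel."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    gen = _GENERATORS[style.name]
    ds = Dataset(meta={"style": dataclasses.asdict(style), "n": n, "seed": seed})
    for _ in range(n):
        base, mask = gen(style, rng)
        ds.images.append(_finish(base, style, rng))
        ds.masks.append(mask.astype(np.uint8))
    return ds


# ---------------------------------------------------------------------------
# split protocol
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Six-subset assignment with a held-out test subset and 5 CV folds."""

    subset_of: np.ndarray          # image index -> subset id in 1..6
    test_subset: int
    folds: list[tuple[np.ndarray, np.ndarray]]   # (train indices, val indices)

    @property
    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.subset_of == self.test_subset)

    @property
    def pool_indices(self) -> np.ndarray:
        return np.flatnonzero(self.subset_of != self.test_subset)

    def to_json(self) -> dict:
        return {"subset_of": self.subset_of.tolist(),
                "test_subset": int(self.test_subset),
                "folds": [[tr.tolist(), va.tolist()] for tr, va in self.folds]}

    @classmethod
    def from_json(cls, d: dict) -> "SplitPlan":
        return cls(np.asarray(d["subset_of"]), int(d["test_subset"]),
                   [(np.asarray(tr), np.asarray(va)) for tr, va in d["folds"]])


def make_splits(n: int, seed: int, test_subset: int = 6, n_folds: int = 5) -> SplitPlan:
    """Randomly divide ``n`` images into six near-equal subsets, hold one out
    for testing, and split the rest into ``n_folds`` cross-validation folds
    with a 4:1 train:validation ratio."""
    if n < 12:
        raise ValueError("need at least 12 images to populate six subsets and five folds")
    if not 1 <= test_subset <= 6:
        raise ValueError("test_subset must be in 1..6")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    subset_of = np.empty(n, dtype=np.int64)
    for sid, chunk in enumerate(np.array_split(perm, 6), start=1):
        subset_of[chunk] = sid
    pool = perm[np.isin(subset_of[perm], [s for s in range(1, 7) if s != test_subset])]
    folds = []
    chunks = np.array_split(pool, n_folds)
    for k in range(n_folds):
        val = np.sort(chunks[k])
        train = np.sort(np.concatenate([chunks[j] for j in range(n_folds) if j != k]))
        folds.append((train, val))
    return SplitPlan(subset_of=subset_of, test_subset=test_subset, folds=folds)


# ---------------------------------------------------------------------------
# disk I/O: images/*.png|tif + masks/*.png|tif with matching stems
# ---------------------------------------------------------------------------

def _to_uint8(img: np.ndarray) -> np.ndarray:
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    chw = arr.shape[0] in (1, 3) and arr.ndim == 3
    if chw:
        arr = arr[0] if arr.shape[0] == 1 else arr.transpose(1, 2, 0)
    return np.round(arr * 255.0).astype(np.uint8)


def write_dataset(dataset: Dataset, path, fmt: str = "png") -> None:
    """Write ``images/`` and ``masks/`` trees (masks as {0,255} 8-bit) plus a
    ``manifest.json`` with generation metadata."""
    if fmt not in ("png", "tif"):
        raise ValueError("fmt must be 'png' or 'tif'")
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    writer = tifffile.imwrite if fmt == "tif" else iio.imwrite
    for i, (img, mask) in enumerate(dataset):
        stem = f"img_{i:05d}.{fmt}"
        writer(root / "images" / stem, _to_uint8(img))
        writer(root / "masks" / stem, (np.asarray(mask, dtype=np.uint8) * 255))
    manifest = dict(dataset.meta)
    manifest["count"] = len(dataset)
    if "split" in manifest and isinstance(manifest["split"], SplitPlan):
        manifest["split"] = manifest["split"].to_json()
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _read_image(p: Path) -> np.ndarray:
    arr = tifffile.imread(p) if p.suffix in (".tif", ".tiff") else iio.imread(p)
    return arr


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset` (round-trip lossless
    at 8-bit precision). Masks must be strictly {0, 255}."""
    root = Path(path)
    img_dir, mask_dir = root / "images", root / "masks"
    files = sorted(img_dir.glob("*")) if img_dir.is_dir() else []
    files = [p for p in files if p.suffix.lower() in (".png", ".tif", ".tiff")]
    ds = Dataset()
    if not files:
        warnings.warn(f"no images found under {img_dir}", stacklevel=2)
        return ds
    for p in files:
        mp = mask_dir / p.name
        if not mp.exists():
            raise FileNotFoundError(f"missing mask for image {p.name!r}")
        img = _read_image(p).astype(np.float32) / 255.0
        img = img.transpose(2, 0, 1) if img.ndim == 3 else img[None]
        mask = _read_image(mp)
        bad = np.setdiff1d(np.unique(mask), [0, 255])
        if bad.size:
            raise ValueError(
                f"mask {mp.name!r} is not binary: unexpected values {bad.tolist()[:5]} "
                "(expected 0 background / 255 foreground)")
        ds.images.append(img)
        ds.masks.append((mask == 255).astype(np.uint8))
    manifest = root / "manifest.json"
    if manifest.exists():
        ds.meta = json.loads(manifest.read_text())
    return ds
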