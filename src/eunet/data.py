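"""Dataset IO and seeded synthetic phantoms.

Datasets follow a DRIVE-style directory layout::

    root/
      images/<stem>.png|.tif
      masks/<stem>.png
      train.txt   # optional, one stem per line
      test.txt

Images are normalized to [0, 1] on load; masks are binarized with the
standard 8-bit threshold (values > 127 become foreground).

Two phantom families stand in for the evaluation imagery when real data
is unavailable:

* **cell** mode emulates low-resolution multi-photon microscopy of skin
  cells: soft-edged elliptical blobs with multiplicative texture and
  additive Gaussian noise, mask = union of the thresholded blobs;
* **vessel** mode emulates retinal fundus vasculature: thin smooth
  curvilinear bright tracks (random-walk paths dilated to widths 1–4 px)
  on a textured background, mask = exact track support.

Both are fully determined by their seed: the same config always yields
bitwise-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .errors import EUNetError

__all__ = [
    "SamplePair", "PhantomConfig", "PaddingRecord",
    "load_dataset", "save_dataset", "generate_phantoms", "pad_to_divisible",
]

F = np.float32


@dataclass
class SamplePair:
    image: np.ndarray  # (H, W) or (H, W, 3) float32 in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise EUNetError(
                f"{self.id}: image {self.image.shape} and mask {self.mask.shape} disagree")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise EUNetError(f"{self.id}: mask not binary after loading ({vals[:5]}...)")


@dataclass
class PhantomConfig:
    mode: str = "cell"  # cell | vessel
    count: int = 90
    size: tuple[int, int] = (128, 128)
    seed: int = 0
    blob_count_range: tuple[int, int] = (3, 7)
    curve_count_range: tuple[int, int] = (2, 5)
    noise_sd: float = 0.04
    texture_strength: float = 0.15
    #: acceptable band for the mean foreground fraction of a generated set
    prevalence_band: tuple[float, float] = (0.05, 0.40)

    def __post_init__(self):
        if self.mode not in ("cell", "vessel"):
            raise ValueError(f"mode must be 'cell' or 'vessel', got {self.mode!r}")
        if isinstance(self.size, int):
            self.size = (self.size, self.size)
        if min(self.size) < 16:
            raise ValueError(f"phantom size sides must be >= 16, got {self.size}")
        if self.count < 1 or self.noise_sd < 0:
            raise ValueError("count must be >= 1 and noise_sd >= 0")


# ---------------------------------------------------------------------------
# IO

_IMAGE_EXTS = (".png", ".tif", ".tiff")


def _read_image(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise EUNetError(f"unreadable image file {path}: {exc}") from exc
    return np.asarray(arr)


def _normalize_image(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return (arr.astype(F) / scale).astype(F)
    return np.clip(arr.astype(F), 0.0, 1.0)


def _binarize_mask(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) > 1:
        return (arr > 127).astype(np.uint8)
    return (arr > 0.5).astype(np.uint8) if arr.dtype.kind == "f" \
        else arr.astype(np.uint8)


def load_dataset(root, split: str | None = None) -> list[SamplePair]:
    """Load image/mask pairs from a DRIVE-style layout.

    ``split`` of ``"train"`` or ``"test"`` reads ``root/<split>.txt`` and
    returns exactly those stems in file order; ``None`` returns all pairs
    sorted by stem.  Orphan images (no matching mask) are an error.
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise EUNetError(f"{root} lacks images/ and masks/ subdirectories")
    images = {p.stem: p for p in sorted(img_dir.iterdir())
              if p.suffix.lower() in _IMAGE_EXTS}
    masks = {p.stem: p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() in _IMAGE_EXTS}
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise EUNetError(f"unpaired image/mask stems in {root}: {orphans}")

    if split is not None:
        list_file = root / f"{split}.txt"
        if not list_file.is_file():
            raise EUNetError(f"split list {list_file} not found")
        stems = [s.strip() for s in list_file.read_text().splitlines() if s.strip()]
        missing = [s for s in stems if s not in images]
        if missing:
            raise EUNetError(f"{list_file} names missing stems: {missing}")
    else:
        stems = sorted(images)

    return [
        SamplePair(image=_normalize_image(_read_image(images[s])),
                   mask=_binarize_mask(_read_image(masks[s])), id=s)
        for s in stems
    ]


def save_dataset(pairs: list[SamplePair], root, splits: dict[str, list[str]] | None = None,
                 force: bool = False) -> None:
    """Write pairs as 8-bit PNGs (masks as {0, 255}) plus split lists."""
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise EUNetError(f"output directory {root} is not empty (use force)")
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for s in pairs:
        img = np.clip(np.round(s.image * 255), 0, 255).astype(np.uint8)
        iio.imwrite(root / "images" / f"{s.id}.png", img)
        iio.imwrite(root / "masks" / f"{s.id}.png", (s.mask * 255).astype(np.uint8))
    for name, stems in (splits or {}).items():
        (root / f"{name}.txt").write_text("\n".join(stems) + "\n")


# ---------------------------------------------------------------------------
# phantoms


def _smooth_noise(rng: np.random.Generator, size, sigma: float) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.standard_normal(size), sigma)
    sd = n.std()
    return (n / sd if sd > 0 else n).astype(F)


def _cell_phantom(rng: np.random.Generator, cfg: PhantomConfig):
    h, w = cfg.size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    n_blobs = int(rng.integers(cfg.blob_count_range[0], cfg.blob_count_range[1] + 1))
    fieldmap = np.zeros((h, w), dtype=np.float64)
    rmin, rmax = 0.07 * min(h, w), 0.15 * min(h, w)
    for _ in range(n_blobs):
        a = max(2.0, rng.uniform(rmin, rmax))
        b = max(2.0, rng.uniform(rmin, rmax))
        cy = rng.uniform(a, h - a)
        cx = rng.uniform(b, w - b)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        q = (u / a) ** 2 + (v / b) ** 2
        # profile = 0.5 exactly on the ellipse boundary -> thresholdable
        fieldmap = np.maximum(fieldmap, np.exp(-np.log(2.0) * q ** 2))
    mask = (fieldmap > 0.5).astype(np.uint8)
    img = 0.15 + 0.65 * fieldmap
    img = img * (1.0 + cfg.texture_strength * _smooth_noise(rng, (h, w), 3.0))
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, (h, w))
    return np.clip(img, 0.0, 1.0).astype(F), mask


def _vessel_phantom(rng: np.random.Generator, cfg: PhantomConfig):
    h, w = cfg.size
    n_curves = int(rng.integers(cfg.curve_count_range[0], cfg.curve_count_range[1] + 1))
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_curves):
        track = np.zeros((h, w), dtype=bool)
        y = rng.uniform(0.1 * h, 0.9 * h)
        x = rng.uniform(0.1 * w, 0.9 * w)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(int(1.5 * max(h, w))):
            angle += rng.normal(0.0, 0.25)
            y += np.sin(angle)
            x += np.cos(angle)
            if not (0 <= y < h and 0 <= x < w):
                break
            track[int(y), int(x)] = True
        width = int(rng.integers(1, 5))
        if width > 1:
            # square structuring element of side k widens a 1-px track to ~k px
            track = ndimage.binary_dilation(track, structure=np.ones((width, width), bool))
        mask |= track
    background = 0.25 + 0.08 * _smooth_noise(rng, (h, w), 4.0)
    brightness = ndimage.gaussian_filter(mask.astype(np.float64), 0.6)
    peak = brightness.max()
    if peak > 0:
        brightness /= peak
    img = background + 0.55 * brightness
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, (h, w))
    return np.clip(img, 0.0, 1.0).astype(F), mask.astype(np.uint8)


def generate_phantoms(config: PhantomConfig) -> list[SamplePair]:
    """Generate a seeded phantom set; same config, same bits.

    Every mask is guaranteed non-empty, and the mean foreground fraction
    of the set is asserted to lie inside ``config.prevalence_band``.
    """
    pairs = []
    fractions = []
    draw = _cell_phantom if config.mode == "cell" else _vessel_phantom
    for i in range(config.count):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(config.count, i)))
        img, mask = draw(rng, config)
        if mask.sum() == 0:  # pragma: no cover - layout makes this unreachable
            raise EUNetError(f"phantom {i} generated an empty mask")
        fractions.append(mask.mean())
        pairs.append(SamplePair(image=img, mask=mask, id=f"{config.mode}_{i:03d}"))
    lo, hi = config.prevalence_band
    mean_frac = float(np.mean(fractions))
    if not lo <= mean_frac <= hi:
        raise EUNetError(
            f"phantom set prevalence {mean_frac:.3f} outside band [{lo}, {hi}]")
    return pairs


# ---------------------------------------------------------------------------
# padding


@dataclass(frozen=True)
class PaddingRecord:
    pad_h: tuple[int, int]
    pad_w: tuple[int, int]

    def crop(self, arr: np.ndarray) -> np.ndarray:
        """Exact inverse of the padding, applied to the spatial axes."""
        (t, b), (l, r) = self.pad_h, self.pad_w
        if arr.ndim == 2:
            return arr[slice(t, arr.shape[0] - b if b else None),
                       slice(l, arr.shape[1] - r if r else None)]
        sl_h = slice(t, arr.shape[-3] - b if b else None)
        sl_w = slice(l, arr.shape[-2] - r if r else None)
        return arr[..., sl_h, sl_w, :]


def pad_to_divisible(image: np.ndarray, levels: int) -> tuple[np.ndarray, PaddingRecord]:
    """Reflect-pad so both spatial sides are divisible by ``2**(levels-1)``.

    Works on (H, W), (H, W, C) or (N, H, W, C) arrays; ``record.crop``
    inverts the padding exactly.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    div = 2 ** (levels - 1)
    if image.ndim == 2:
        h, w = image.shape
        axes_pad = lambda ph, pw: (ph, pw)  # noqa: E731
    elif image.ndim == 3:
        h, w = image.shape[:2]
        axes_pad = lambda ph, pw: (ph, pw, (0, 0))  # noqa: E731
    elif image.ndim == 4:
        h, w = image.shape[1:3]
        axes_pad = lambda ph, pw: ((0, 0), ph, pw, (0, 0))  # noqa: E731
    else:
        raise ValueError(f"expected 2-4 dims, got shape {image.shape}")
    th = (-h) % div
    tw = (-w) % div
    ph = (th // 2, th - th // 2)
    pw = (tw // 2, tw - tw // 2)
    padded = np.pad(image, axes_pad(ph, pw), mode="reflect") if th or tw else image
    return padded, PaddingRecord(pad_h=ph, pad_w=pw)
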