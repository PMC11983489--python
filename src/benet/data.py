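"""Hyperspectral cube I/O, PCA band reduction, fold splitting and phantoms.

Real microscopic hyperspectral pathology images are 512x512 cubes with ~40
correlated spectral bands and pixel-level binary lesion masks.  The phantom
generator emulates their statistical structure at configurable size: two
tissue classes with overlapping smooth spectral signatures, lesion blobs of
varying size and shape, optional boundary blurring (the spectral transition
softens while the label stays crisp), isolated distractor structures in the
background, per-pixel signature jitter ("same object, different spectrum"),
and band-correlated noise.  Everything is deterministic given a seed.

Cubes are stored band-interleaved as multiband TIFF (or ``.npy``); masks as
8-bit PNG with labels {0, 1}, 1 = lesion, row-major with origin at the
top-left pixel center.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
import yaml
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from sklearn.decomposition import PCA

__all__ = [
    "HyperCube",
    "Mask",
    "PhantomParams",
    "FoldSplit",
    "generate_phantom",
    "generate_phantom_set",
    "easy_phantom_params",
    "boundary_blur_phantom_params",
    "pca_reduce",
    "kfold_split",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "write_manifest",
    "read_manifest",
    "nearest_centroid_mask",
]


@dataclass
class HyperCube:
    """H x W x B array of spectral intensities."""

    values: np.ndarray
    wavelengths: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3 or self.values.shape[2] < 1:
            raise ValueError("cube must be H x W x B with B >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")

    @property
    def band_count(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Mask:
    """H x W binary labels, 1 = lesion."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("mask labels must be in {0, 1}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class PhantomParams:
    """Generator settings for one synthetic MHSI phantom."""

    height: int = 64
    width: int = 64
    bands: int = 8
    n_blobs: tuple = (1, 4)
    blob_radius: tuple = (6, 16)          # pixels, before per-blob anisotropy
    boundary_blur_sigma: float = 0.0      # spectral transition softness (px)
    signature_separation: float = 1.0     # distance between class mean spectra
    within_class_jitter: float = 0.05     # per-pixel signature scale jitter
    distractor_density: float = 0.0       # expected distractors per 64x64 tile
    distractor_radius: tuple = (1, 3)
    noise_sigma: float = 0.05             # band-correlated Gaussian noise
    area_fraction: tuple = (0.1, 0.5)     # accepted lesion area window
    seed: int = 0

    def __post_init__(self):
        for name in ("boundary_blur_sigma", "within_class_jitter",
                     "distractor_density", "noise_sigma",
                     "signature_separation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.blob_radius[1] >= min(self.height, self.width):
            raise ValueError("blob radius must be smaller than the image")


@dataclass
class FoldSplit:
    """k disjoint index lists covering range(n)."""

    folds: list

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_val(self, fold: int):
        val = np.asarray(self.folds[fold])
        train = np.concatenate(
            [self.folds[i] for i in range(self.k) if i != fold])
        return train, val


def _class_signatures(bands: int, separation: float):
    """Two overlapping smooth band profiles (Gaussian bumps over band index)."""
    idx = np.arange(bands)
    c0 = 0.35 * bands
    c1 = c0 + 0.12 * bands * separation
    width = 0.25 * bands
    sig0 = 0.6 + 0.8 * np.exp(-0.5 * ((idx - c0) / width) ** 2)
    sig1 = 0.6 + 0.8 * np.exp(-0.5 * ((idx - c1) / width) ** 2)
    sig1 = sig1 + 0.08 * separation
    return sig0, sig1


def _random_blob_mask(rng, H, W, n_blobs, radius_range):
    mask = np.zeros((H, W), dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    n = rng.integers(n_blobs[0], n_blobs[1] + 1)
    for _ in range(n):
        cy = rng.uniform(0.15 * H, 0.85 * H)
        cx = rng.uniform(0.15 * W, 0.85 * W)
        r = rng.uniform(*radius_range)
        aspect = rng.uniform(0.6, 1.6)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        # wobble the radius to break circularity
        phase = np.arctan2(v, u)
        wobble = 1.0 + 0.25 * np.sin(3 * phase + rng.uniform(0, 2 * np.pi))
        mask |= (u / (r * aspect * wobble)) ** 2 + (v / (r / aspect * wobble)) ** 2 <= 1.0
    return mask


def generate_phantom(params: PhantomParams) -> tuple[HyperCube, Mask]:
    """Draw one synthetic cube + mask pair; deterministic given params.seed."""
    rng = np.random.default_rng(params.seed)
    H, W, B = params.height, params.width, params.bands
    sig0, sig1 = _class_signatures(B, params.signature_separation)

    for _ in range(64):
        lesion = _random_blob_mask(rng, H, W, params.n_blobs,
                                   params.blob_radius)
        frac = lesion.mean()
        if params.area_fraction[0] <= frac <= params.area_fraction[1]:
            break
    else:
        raise RuntimeError(
            "could not draw a lesion within the configured area fraction")

    # class-mixing field: crisp 0/1, optionally blurred at the boundary
    mix = lesion.astype(float)
    if params.boundary_blur_sigma > 0:
        mix = gaussian_filter(mix, params.boundary_blur_sigma)

    cube = (1.0 - mix)[:, :, None] * sig0 + mix[:, :, None] * sig1

    if params.distractor_density > 0:
        n_dis = rng.poisson(params.distractor_density * H * W / 64 ** 2)
        dis = np.zeros((H, W), dtype=bool)
        for _ in range(n_dis):
            dis |= _random_blob_mask(rng, H, W, (1, 1),
                                     params.distractor_radius)
        dis &= ~lesion
        # distractors look lesion-like but are labelled background
        cube[dis] = 0.7 * sig1 + 0.3 * sig0

    if params.within_class_jitter > 0:
        scale = 1.0 + params.within_class_jitter * rng.standard_normal((H, W))
        cube = cube * scale[:, :, None]

    if params.noise_sigma > 0:
        noise = rng.standard_normal((H, W, B))
        noise = gaussian_filter1d(noise, sigma=1.0, axis=2)  # band correlation
        cube = cube + params.noise_sigma * noise

    return HyperCube(cube.astype(np.float32)), Mask(lesion.astype(np.uint8))


def generate_phantom_set(params: PhantomParams, n: int, seed: int | None = None):
    """Generate n phantoms with per-item seeds derived from a base seed."""
    base = params.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    cubes, masks = [], []
    for child in ss.spawn(n):
        p = PhantomParams(**{**asdict(params),
                             "seed": int(child.generate_state(1)[0] % 2**31)})
        cube, mask = generate_phantom(p)
        cubes.append(cube)
        masks.append(mask)
    return cubes, masks


def easy_phantom_params(size: int = 64, bands: int = 8,
                        seed: int = 0) -> PhantomParams:
    """High class separation, little noise: every stage should segment this."""
    return PhantomParams(height=size, width=size, bands=bands,
                         signature_separation=2.0, within_class_jitter=0.03,
                         noise_sigma=0.05, boundary_blur_sigma=0.0,
                         distractor_density=0.0, seed=seed)


def boundary_blur_phantom_params(size: int = 64, bands: int = 8,
                                 seed: int = 0) -> PhantomParams:
    """Blurred, lower-contrast boundaries plus background distractors."""
    return PhantomParams(height=size, width=size, bands=bands,
                         signature_separation=1.0, within_class_jitter=0.08,
                         noise_sigma=0.15, boundary_blur_sigma=2.5,
                         distractor_density=3.0, seed=seed)


def nearest_centroid_mask(cube: HyperCube,
                          params: PhantomParams) -> np.ndarray:
    """Oracle segmentation: assign each pixel to the closer class spectrum."""
    sig0, sig1 = _class_signatures(cube.band_count,
                                   params.signature_separation)
    d0 = ((cube.values - sig0) ** 2).sum(axis=2)
    d1 = ((cube.values - sig1) ** 2).sum(axis=2)
    return (d1 < d0).astype(np.uint8)


def pca_reduce(cubes: list[HyperCube], n_components: int,
               fit_indices=None) -> list[HyperCube]:
    """Project all cubes onto components fitted on the fit-set pixels only.

    Bands are mean-centered (no variance scaling: bands share units) and the
    sign of each component is fixed so its largest-magnitude loading is
    positive, making outputs backend-independent.
    """
    if not cubes:
        raise ValueError("no cubes given")
    B = cubes[0].band_count
    if n_components > B:
        raise ValueError(f"n_components={n_components} exceeds band count {B}")
    if fit_indices is None:
        fit_indices = range(len(cubes))
    fit_indices = list(fit_indices)
    if not fit_indices:
        raise ValueError("fit set is empty")
    pooled = np.concatenate(
        [cubes[i].values.reshape(-1, B) for i in fit_indices], axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(pooled)
    comps = pca.components_.copy()
    for j, comp in enumerate(comps):
        if comp[np.argmax(np.abs(comp))] < 0:
            comps[j] = -comp
    out = []
    for cube in cubes:
        flat = cube.values.reshape(-1, B) - pca.mean_
        proj = flat @ comps.T
        out.append(HyperCube(proj.reshape(
            cube.shape[0], cube.shape[1], n_components).astype(np.float32)))
    return out


def kfold_split(n: int, k: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffled k-fold partition of range(n); fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    idx = np.random.default_rng(seed).permutation(n)
    return FoldSplit([np.sort(f).tolist() for f in np.array_split(idx, k)])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cube(path, cube: HyperCube):
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, cube.values)
    else:
        # band-interleaved multiband TIFF: (bands, H, W) pages
        tifffile.imwrite(path, np.moveaxis(cube.values, 2, 0),
                         photometric="minisblack")


def read_cube(path, expected_bands: int | None = None) -> HyperCube:
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        arr = np.asarray(iio.imread(path) if path.suffix == ".png"
                         else tifffile.imread(path))
        if arr.ndim == 2:
            values = arr[:, :, None]
        elif path.suffix == ".png":
            values = arr  # H x W x channels already
        else:
            values = np.moveaxis(arr, 0, 2)
    cube = HyperCube(values)
    if expected_bands is not None and cube.band_count != expected_bands:
        raise ValueError(
            f"{path} has {cube.band_count} bands, expected {expected_bands}")
    return cube


def write_mask(path, mask: Mask):
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_mask(path) -> Mask:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.max() > 1:  # tolerate 0/255 visual masks
        arr = (arr > 127).astype(np.uint8)
    return Mask(arr)


def write_manifest(path, pairs: list[tuple]):
    """YAML manifest of (cube_path, mask_path) pairs."""
    entries = [{"cube": str(c), "mask": str(m)} for c, m in pairs]
    Path(path).write_text(yaml.safe_dump({"samples": entries}))


def read_manifest(path):
    doc = yaml.safe_load(Path(path).read_text())
    root = Path(path).parent
    out = []
    for entry in doc["samples"]:
        cube_p, mask_p = Path(entry["cube"]), Path(entry["mask"])
        if not cube_p.is_absolute():
            cube_p = root / cube_p
        if not mask_p.is_absolute():
            mask_p = root / mask_p
        out.append((read_cube(cube_p), read_mask(mask_p)))
    return out
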