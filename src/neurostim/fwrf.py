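"""Feature-weighted receptive-field (fwRF) encoding models.

An fwRF encoding model predicts a brain region's scalar response to a visual
stimulus in three stages:

1. a fixed multi-resolution *feature bank* turns the image into stacks of
   rectified channel maps (coarse analogue of the convolutional layers of a
   pretrained deep network);
2. an isotropic Gaussian *pooling field*, parameterized by a center (in
   degrees of visual angle) and a radius (as a fraction of the field of
   view), collapses each channel map to one number;
3. a ridge regression maps the pooled feature vector to the measured
   regional response.

The pooling center, pooling radius and ridge penalty are hyperparameters
chosen by exhaustive grid search against Pearson correlation on a held-out
validation set.  A *group* model is the arithmetic mean of several subjects'
fitted models.

The stimulus field of view is 8.4 x 8.4 degrees of visual angle; pooling
centers use coordinates with the origin at the field center, x rightward and
y upward.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
from scipy import fft as sfft

FIELD_EXTENT_DEG = 8.4

_CONV_DTYPE = np.float32


# ---------------------------------------------------------------------------
# Feature bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One resolution level of a feature bank.

    ``n_channels`` filter maps are produced at spatial side ``map_side``
    (``map_side == 1`` means a global, spatially collapsed channel).
    """

    n_channels: int
    map_side: int
    kernel_side: int = 9

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.map_side < 1:
            raise ValueError("n_channels and map_side must be positive")
        if self.kernel_side % 2 == 0:
            raise ValueError("kernel_side must be odd")


@dataclass
class FeatureBank:
    """A fixed, seeded, rectified multi-resolution filter bank.

    Filters are oriented Gabor patches and center-surround
    (difference-of-Gaussian) kernels with seeded random parameters; the bank
    is fully determined by its configuration, so a serialized model only
    needs to store the configuration to reconstruct the bank exactly.

    ``declared_only`` banks carry layer-shape metadata (used to document the
    deep-network-scale configuration) but cannot extract features.
    """

    bank_id: str
    layers: tuple[LayerSpec, ...]
    image_side: int = 64
    rectify: bool = True
    seed: int = 0
    declared_only: bool = False
    _filters: np.ndarray | None = field(default=None, repr=False, compare=False)
    _filter_fft: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.layers = tuple(self.layers)
        for spec in self.layers:
            if not self.declared_only and self.image_side % spec.map_side:
                raise ValueError(
                    f"image side {self.image_side} not divisible by map side "
                    f"{spec.map_side}"
                )
        kernels = {spec.kernel_side for spec in self.layers}
        if len(kernels) != 1:
            raise ValueError("all layers must share one kernel_side")
        self.kernel_side = kernels.pop()

    # -- static description -------------------------------------------------
    @property
    def layer_shapes(self) -> tuple[tuple[int, int, int], ...]:
        return tuple((s.n_channels, s.map_side, s.map_side) for s in self.layers)

    @property
    def n_channels_total(self) -> int:
        return sum(s.n_channels for s in self.layers)

    @property
    def level_slices(self) -> tuple[slice, ...]:
        """Global channel index ranges, one per resolution level."""
        out, start = [], 0
        for spec in self.layers:
            out.append(slice(start, start + spec.n_channels))
            start += spec.n_channels
        return tuple(out)

    def to_config(self) -> dict:
        return {
            "bank_id": self.bank_id,
            "layers": [dataclasses.asdict(s) for s in self.layers],
            "image_side": self.image_side,
            "rectify": self.rectify,
            "seed": self.seed,
            "declared_only": self.declared_only,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "FeatureBank":
        layers = tuple(LayerSpec(**d) for d in cfg["layers"])
        return cls(
            bank_id=cfg["bank_id"],
            layers=layers,
            image_side=cfg["image_side"],
            rectify=cfg["rectify"],
            seed=cfg["seed"],
            declared_only=cfg.get("declared_only", False),
        )

    # -- filters ------------------------------------------------------------
    def filters(self) -> np.ndarray:
        """All filters, shape (n_channels_total, k, k); generated on demand."""
        if self.declared_only:
            raise ValueError(f"bank {self.bank_id!r} is shape-declaration only")
        if self._filters is None:
            self._filters = _make_filters(self)
        return self._filters

    def _fft(self, pad: int) -> np.ndarray:
        if self._filter_fft is None or self._filter_fft.shape[-2] != pad:
            filt = self.filters().astype(_CONV_DTYPE)
            self._filter_fft = sfft.rfft2(filt, s=(pad, pad))
        return self._filter_fft


def _gabor(k: int, theta: float, wavelength: float, phase: float,
           sigma: float) -> np.ndarray:
    half = (k - 1) / 2.0
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    u = x * np.cos(theta) + y * np.sin(theta)
    env = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    g = env * np.cos(2.0 * np.pi * u / wavelength + phase)
    g -= g.mean()
    return g / np.linalg.norm(g)

def _dog(k: int, sigma_c: float, ratio: float = 2.0) -> np.ndarray:
    half = (k - 1) / 2.0
    y, x = np.mgrid[-half:half + 1, -half:half + 1]
    r2 = x**2 + y**2
    g = (np.exp(-r2 / (2 * sigma_c**2)) / sigma_c**2
         - np.exp(-r2 / (2 * (ratio * sigma_c) ** 2)) / (ratio * sigma_c) ** 2)
    g -= g.mean()
    return g / np.linalg.norm(g)

def _make_filters(bank: FeatureBank) -> np.ndarray:
    out = []
    for level, spec in enumerate(bank.layers):
        rng = np.random.default_rng(np.random.SeedSequence([bank.seed, 7, level]))
        k = spec.kernel_side
        for c in range(spec.n_channels):
            if c % 4 == 3:  # every 4th channel is center-surround
                out.append(_dog(k, sigma_c=rng.uniform(0.7, 1.8)))
            else:
                out.append(_gabor(
                    k,
                    theta=rng.uniform(0.0, np.pi),
                    wavelength=rng.uniform(3.0, k + 1.0),
                    phase=rng.uniform(0.0, 2 * np.pi),
                    sigma=rng.uniform(k / 6.0, k / 3.0),
                ))
    return np.asarray(out)


def default_bank(seed: int = 0, image_side: int = 64, *,
                 n_gabor: int = 16, n_fine: int = 12, n_global: int = 4,
                 bank_id: str | None = None) -> FeatureBank:
    """Desk-scale default: 16 maps at 16x16, 12 at 8x8, 4 global channels."""
    layers = []
    if n_gabor:
        layers.append(LayerSpec(n_gabor, image_side // 4))
    if n_fine:
        layers.append(LayerSpec(n_fine, image_side // 8))
    if n_global:
        layers.append(LayerSpec(n_global, 1))
    if bank_id is None:
        bank_id = f"default-s{seed}-{image_side}px"
    return FeatureBank(bank_id=bank_id, layers=tuple(layers),
                       image_side=image_side, seed=seed)


def deepnet_scale_bank() -> FeatureBank:
    """Shape declaration matching a deep-network backbone.

    Concatenating same-resolution layers of an AlexNet-class backbone (with
    at most 512 maps kept per layer) yields stacks of shape (256, 27, 27),
    (896, 13, 13) and (1536, 1, 1).  This preset documents that shape
    plumbing; it cannot extract features (no pretrained weights are shipped).
    """
    layers = (LayerSpec(256, 27, 11), LayerSpec(896, 13, 11), LayerSpec(1536, 1, 11))
    return FeatureBank(bank_id="deepnet-scale", layers=layers,
                       image_side=227, declared_only=True)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureMapStack:
    """Per-level channel maps for one image; level ``l`` is (C_l, S_l, S_l)."""

    levels: tuple[np.ndarray, ...]

    @property
    def n_channels_total(self) -> int:
        return sum(lv.shape[0] for lv in self.levels)


def _conv_same_batch(pixels: np.ndarray, bank: FeatureBank) -> np.ndarray:
    """Linear 'same' convolution of (B,H,W) pixels with all bank filters.

    Returns (B, C_total, H, W) in float32.  Zero padding (not circular).
    """
    H = bank.image_side
    k = bank.kernel_side
    pad = sfft.next_fast_len(H + k - 1)
    Fi = sfft.rfft2(pixels.astype(_CONV_DTYPE), s=(pad, pad))
    out = sfft.irfft2(Fi[:, None] * bank._fft(pad)[None], s=(pad, pad))
    lo = (k - 1) // 2
    return out[..., lo:lo + H, lo:lo + H]

def _block_mean(maps: np.ndarray, side: int) -> np.ndarray:
    """Downsample (..., H, H) to (..., side, side) by block averaging."""
    H = maps.shape[-1]
    b = H // side
    shp = maps.shape[:-2] + (side, b, side, b)
    return maps.reshape(shp).mean(axis=(-3, -1))

def _extract_batch(pixels: np.ndarray, bank: FeatureBank,
                   chunk: int = 32) -> list[np.ndarray]:
    """Extract per-level stacks, (B, C_l, S_l, S_l) each, chunked over images."""
    if bank.declared_only:
        raise ValueError(f"bank {bank.bank_id!r} is shape-declaration only")
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[-1] != bank.image_side \
            or pixels.shape[-2] != bank.image_side:
        raise ValueError(
            f"expected pixels (B, {bank.image_side}, {bank.image_side}), "
            f"got {pixels.shape}")
    parts: list[list[np.ndarray]] = [[] for _ in bank.layers]
    for start in range(0, pixels.shape[0], chunk):
        conv = _conv_same_batch(pixels[start:start + chunk], bank)
        if bank.rectify:
            conv = np.maximum(conv, 0.0)
        for lev, (spec, sl) in enumerate(zip(bank.layers, bank.level_slices)):
            parts[lev].append(_block_mean(conv[:, sl], spec.map_side))
    return [np.concatenate(p, axis=0) for p in parts]


def extract_features(image, bank: FeatureBank) -> FeatureMapStack:
    """Extract the multi-resolution rectified feature maps of one image."""
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    levels = _extract_batch(pixels[None], bank)
    return FeatureMapStack(tuple(lv[0] for lv in levels))


def _stack_pixels(images: Sequence) -> np.ndarray:
    return np.asarray([np.asarray(getattr(im, "pixels", im), dtype=float)
                       for im in images])


# ---------------------------------------------------------------------------
# Channel selection
# ---------------------------------------------------------------------------

def _channel_scores(levels: list[np.ndarray], criterion: str) -> np.ndarray:
    scores = []
    for lv in levels:
        B, C = lv.shape[:2]
        flat = lv.reshape(B, C, -1)
        if criterion == "spatial":
            # spatial variance of each map, averaged over images
            scores.append(flat.var(axis=2).mean(axis=0))
        elif criterion == "across_images":
            # variance across images of the spatially averaged map
            scores.append(flat.mean(axis=2).var(axis=0))
        else:
            raise ValueError(f"unknown variance criterion {criterion!r}")
    return np.concatenate(scores).astype(float)

def _select_from_levels(levels: list[np.ndarray], bank: FeatureBank, K: int,
                        criterion: str) -> np.ndarray:
    scores = _channel_scores(levels, criterion)
    out = []
    for sl in bank.level_slices:
        idx = np.arange(sl.start, sl.stop)
        if idx.size <= K:
            out.append(idx)
            continue
        s = scores[sl]
        # stable top-K, ties broken by lower channel index
        order = np.lexsort((idx, -s))[:K]
        out.append(np.sort(idx[order]))
    return np.concatenate(out)


def select_feature_maps(images: Sequence, bank: FeatureBank, K: int, *,
                        criterion: str = "spatial") -> np.ndarray:
    """Keep the top-K channels per resolution level by variance score.

    The default score is the spatial variance of each channel map computed
    per image and averaged across images; levels with at most K channels are
    kept whole.  Returns sorted global channel indices.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(images) == 0:
        raise ValueError("empty image pool")
    levels = _extract_batch(_stack_pixels(images), bank)
    return _select_from_levels(levels, bank, K, criterion)


# ---------------------------------------------------------------------------
# Gaussian pooling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolingField:
    """Isotropic Gaussian pooling field.

    ``center`` is (x, y) in degrees (origin at field center, x rightward,
    y upward); ``radius`` is the Gaussian sigma as a fraction of the field
    extent (0.04 of an 8.4 deg field = 0.336 deg).
    """

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pooling radius must be positive")


def grid_coords(side: int, extent: float = FIELD_EXTENT_DEG):
    """Cell-center coordinates of an side x side grid over the field."""
    step = extent / side
    x = -extent / 2 + step * (np.arange(side) + 0.5)
    y = extent / 2 - step * (np.arange(side) + 0.5)   # row 0 at the top
    return np.meshgrid(x, y)

def pooling_weights(side: int, fld: PoolingField,
                    extent: float = FIELD_EXTENT_DEG) -> np.ndarray:
    """Gaussian weights on an side x side grid, renormalized to sum to 1.

    Renormalization (rather than analytic normalization) keeps the
    sum-to-one contract even when the Gaussian is truncated at field edges.
    1x1 grids pass through with weight 1.
    """
    if side == 1:
        return np.ones((1, 1))
    X, Y = grid_coords(side, extent)
    sigma = fld.radius * extent
    w = np.exp(-((X - fld.center[0]) ** 2 + (Y - fld.center[1]) ** 2)
               / (2.0 * sigma**2))
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("pooling field does not overlap the grid")
    return w / total


def pool_features(stack: FeatureMapStack, fld: PoolingField) -> np.ndarray:
    """Pool each channel map to a scalar; returns the concatenated vector."""
    out = []
    for lv in stack.levels:
        side = lv.shape[-1]
        w = pooling_weights(side, fld)
        out.append(np.tensordot(lv.astype(float), w, axes=([1, 2], [0, 1])))
    return np.concatenate(out)

def _pool_batch(levels: list[np.ndarray], fld: PoolingField) -> np.ndarray:
    """(B, C_total) pooled features from batch level stacks."""
    cols = []
    for lv in levels:
        side = lv.shape[-1]
        w = pooling_weights(side, fld).ravel()
        cols.append(lv.reshape(lv.shape[0], lv.shape[1], -1).astype(float) @ w)
    return np.concatenate(cols, axis=1)


# ---------------------------------------------------------------------------
# Hyperparameter grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperGrid:
    centers: tuple[tuple[float, float], ...]  # lexicographically ordered
    radii: tuple[float, ...]                  # strictly increasing
    lambdas: tuple[float, ...]                # strictly increasing

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii) <= 0) or np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("radii and lambdas must be strictly increasing")


def build_hypergrid(field_extent: float = FIELD_EXTENT_DEG,
                    spacing: float = 1.4,
                    n_radii: int = 8, r_min: float = 0.04, r_max: float = 0.4,
                    n_lambdas: int = 9, lam_min: float = 1e3,
                    lam_max: float = 1e7) -> HyperGrid:
    """Candidate centers / radii / ridge penalties for the grid search.

    Centers form a square lattice with the given spacing in degrees,
    anchored at the field center and clipped to the field; radii and
    penalties are log-spaced with the stated endpoints.  The defaults are
    the full-scale settings (1.4 deg spacing, 8 radii in [0.04, 0.4],
    9 penalties in [1e3, 1e7]).
    """
    if min(field_extent, spacing, r_min, r_max, lam_min, lam_max) <= 0:
        raise ValueError("all grid parameters must be positive")
    if n_radii < 2 or n_lambdas < 2:
        raise ValueError("need at least two radii and two lambdas")
    half = field_extent / 2.0
    kmax = int(np.floor(half / spacing + 1e-9))
    ticks = spacing * np.arange(-kmax, kmax + 1)
    centers = tuple((float(x), float(y)) for x in ticks for y in ticks)
    radii = tuple(np.geomspace(r_min, r_max, n_radii).tolist())
    lambdas = tuple(np.geomspace(lam_min, lam_max, n_lambdas).tolist())
    return HyperGrid(centers=centers, radii=radii, lambdas=lambdas)


def desk_hypergrid(**kw) -> HyperGrid:
    """Desk-scale default: same centers/radii, penalties rescaled to the
    synthetic feature magnitudes (1e-6..1e2)."""
    kw.setdefault("lam_min", 1e-6)
    kw.setdefault("lam_max", 1e2)
    return build_hypergrid(**kw)


# ---------------------------------------------------------------------------
# Ridge regression
# ---------------------------------------------------------------------------

def fit_ridge(X: np.ndarray, y: np.ndarray,
              lam: float) -> tuple[np.ndarray, float]:
    """Ridge with unpenalized intercept.

    Minimizes ||y - Xw - b||^2 + lam ||w||^2 with X centered internally;
    returns (w, b) on the original (uncentered) scale, so predictions are
    ``X @ w + b``.  ``lam=0`` falls back to minimum-norm least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in ridge inputs")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    if lam == 0:
        w = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    else:
        p = X.shape[1]
        w = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc)
    b = ym - float(xm @ w)
    return w, b


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        return np.nan
    return float(a @ b / den)


# ---------------------------------------------------------------------------
# Encoding model containers
# ---------------------------------------------------------------------------

@dataclass
class EncodingModel:
    """A fitted fwRF model: bank + channel subset + pooling field + readout."""

    bank_id: str
    selected_channels: np.ndarray
    field: PoolingField
    weights: np.ndarray
    bias: float
    region: str = ""
    subject_id: str = ""
    val_accuracy: float = np.nan
    bank: FeatureBank | None = None

    def __post_init__(self) -> None:
        self.selected_channels = np.asarray(self.selected_channels, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.selected_channels.shape:
            raise ValueError("|weights| must equal |selected_channels|")

    def _require_bank(self) -> FeatureBank:
        if self.bank is None or self.bank.bank_id != self.bank_id:
            raise ValueError(f"feature bank {self.bank_id!r} is not attached")
        return self.bank

    def predict(self, image) -> float:
        return float(self.predict_batch(_stack_pixels([image]))[0])

    def predict_batch(self, pixels: np.ndarray) -> np.ndarray:
        return predict_batch(self, pixels)

    def predict_from_levels(self, levels: list[np.ndarray]) -> np.ndarray:
        pooled = _pool_batch(levels, self.field)[:, self.selected_channels]
        return pooled @ self.weights + self.bias


@dataclass
class GroupModel:
    """Arithmetic mean of same-region encoding models."""

    base_models: list[EncodingModel]

    def __post_init__(self) -> None:
        if not self.base_models:
            raise ValueError("group model needs at least one base model")
        regions = {m.region for m in self.base_models}
        if len(regions) != 1:
            raise ValueError(f"mixed regions in group model: {sorted(regions)}")

    @property
    def region(self) -> str:
        return self.base_models[0].region

    def predict(self, image) -> float:
        return float(self.predict_batch(_stack_pixels([image]))[0])

    def predict_batch(self, pixels: np.ndarray) -> np.ndarray:
        return predict_batch(self, pixels)

    def predict_from_levels(self, levels: list[np.ndarray]) -> np.ndarray:
        return np.mean([m.predict_from_levels(levels) for m in self.base_models],
                       axis=0)


def make_group_model(models: Sequence[EncodingModel]) -> GroupModel:
    return GroupModel(base_models=list(models))


def _linearize(model) -> tuple[list[tuple[float, EncodingModel]], float]:
    """Flatten Encoding/Group/Ensemble models into (coef, base) terms + bias.

    Any of the model kinds used in this package predicts a weighted sum of
    plain fwRF readouts, which lets prediction and its pixel gradient share
    one feature extraction pass.
    """
    if isinstance(model, EncodingModel):
        return [(1.0, model)], 0.0
    if isinstance(model, GroupModel):
        coef = 1.0 / len(model.base_models)
        return [(coef, m) for m in model.base_models], 0.0
    # EnsembleModel (duck-typed to avoid a circular import)
    if hasattr(model, "ensemble_weights") and hasattr(model, "base_models"):
        terms = []
        for w, m in zip(model.ensemble_weights, model.base_models):
            sub, b = _linearize(m)
            terms.extend((float(w) * c, mm) for c, mm in sub)
        return terms, float(model.bias)
    raise TypeError(f"cannot linearize model of type {type(model)!r}")


def _common_bank(terms) -> FeatureBank:
    banks = {m.bank_id for _, m in terms}
    if len(banks) != 1:
        raise ValueError(f"models mix feature banks: {sorted(banks)}")
    return terms[0][1]._require_bank()


def predict_batch(model, pixels: np.ndarray) -> np.ndarray:
    """Predict responses for (B, H, W) pixels with any supported model."""
    terms, bias = _linearize(model)
    bank = _common_bank(terms)
    levels = _extract_batch(np.asarray(pixels, dtype=float), bank)
    out = np.full(pixels.shape[0], bias, dtype=float)
    for coef, m in terms:
        out += coef * m.predict_from_levels(levels)
    return out


def predict(model, image) -> float:
    """Predicted scalar regional response of one image."""
    return float(predict_batch(model, _stack_pixels([image]))[0])


def predict_from_levels(model, levels: list[np.ndarray]) -> np.ndarray:
    """Predict from pre-extracted feature levels (shared extraction pass)."""
    terms, bias = _linearize(model)
    out = np.full(levels[0].shape[0], bias, dtype=float)
    for coef, m in terms:
        out += coef * m.predict_from_levels(levels)
    return out


# ---------------------------------------------------------------------------
# Prediction gradient w.r.t. pixels (for gradient-mode stimulus synthesis)
# ---------------------------------------------------------------------------

def _upsampled_pool_grad(terms, bank: FeatureBank) -> np.ndarray:
    """Per-channel full-resolution linear weight maps, (C_total, H, H).

    d(prediction)/d(rectified conv map) for channel c is the model weight
    times the pooling weight of the cell the pixel falls in, divided by the
    block size (block averaging), summed over all linearized terms.
    """
    H = bank.image_side
    maps = np.zeros((bank.n_channels_total, H, H))
    for coef, m in terms:
        fld = m.field
        w_by_side: dict[int, np.ndarray] = {}
        for spec, sl in zip(bank.layers, bank.level_slices):
            side = spec.map_side
            if side not in w_by_side:
                block = H // side
                w = pooling_weights(side, fld) / block**2
                w_by_side[side] = np.repeat(np.repeat(w, block, 0), block, 1)
        sel = m.selected_channels
        for c, wt in zip(sel, m.weights):
            lev = next(i for i, sl in enumerate(bank.level_slices)
                       if sl.start <= c < sl.stop)
            side = bank.layers[lev].map_side
            maps[c] += coef * wt * w_by_side[side]
    return maps


def predict_and_grad(model, pixels: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and d(prediction)/d(pixels) for a batch of images.

    One shared convolution pass serves both the forward prediction and the
    backward (adjoint) pass; rectification contributes its 0/1 mask.
    Returns ``(pred (B,), grad (B, H, W))``.
    """
    terms, bias = _linearize(model)
    bank = _common_bank(terms)
    pixels = np.asarray(pixels, dtype=float)
    H, k = bank.image_side, bank.kernel_side
    pad = sfft.next_fast_len(H + k - 1)
    lo = (k - 1) // 2

    conv = _conv_same_batch(pixels, bank)            # (B, C, H, H)
    act = np.maximum(conv, 0.0) if bank.rectify else conv

    # forward
    pred = np.full(pixels.shape[0], bias, dtype=float)
    levels = [_block_mean(act[:, sl], spec.map_side)
              for spec, sl in zip(bank.layers, bank.level_slices)]
    for coef, m in terms:
        pred += coef * m.predict_from_levels(levels)

    # backward
    G = _upsampled_pool_grad(terms, bank)[None].astype(_CONV_DTYPE)
    if bank.rectify:
        G = G * (conv > 0)
    else:
        G = np.broadcast_to(G, conv.shape)
    emb = np.zeros(G.shape[:2] + (pad, pad), dtype=_CONV_DTYPE)
    emb[..., lo:lo + H, lo:lo + H] = G
    FG = sfft.rfft2(emb, s=(pad, pad))
    back = sfft.irfft2((FG * np.conj(bank._fft(pad))[None]).sum(axis=1),
                       s=(pad, pad))
    return pred, back[..., :H, :H].astype(float)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search_fit(train: tuple[Sequence, np.ndarray],
                    val: tuple[Sequence, np.ndarray],
                    bank: FeatureBank, K: int, grid: HyperGrid, *,
                    region: str = "", subject_id: str = "",
                    criterion: str = "spatial") -> EncodingModel:
    """Exhaustively search (center, radius, lambda) and return the best model.

    For every candidate pooling field the selected channels are pooled on
    the training and validation images, a ridge readout is fitted per
    penalty, and the model is scored by Pearson r between predicted and
    measured validation responses.  Ties are broken deterministically by
    lower radius index, then lower penalty index, then lexicographic center.
    """
    train_images, train_y = train
    val_images, val_y = val
    train_y = np.asarray(train_y, dtype=float)
    val_y = np.asarray(val_y, dtype=float)
    if len(val_images) < 3:
        raise ValueError("validation set must contain at least 3 images")
    tr_ids = {getattr(im, "image_id", i) for i, im in enumerate(train_images)}
    va_ids = {getattr(im, "image_id", -1 - i) for i, im in enumerate(val_images)}
    if tr_ids & va_ids:
        raise ValueError("train and validation sets share image ids")

    tr_levels = _extract_batch(_stack_pixels(train_images), bank)
    va_levels = _extract_batch(_stack_pixels(val_images), bank)
    selected = _select_from_levels(tr_levels, bank, K, criterion)

    n_c, n_r, n_l = len(grid.centers), len(grid.radii), len(grid.lambdas)
    scores = np.full((n_r, n_l, n_c), -np.inf)
    lam_arr = np.asarray(grid.lambdas)
    ym = train_y.mean()
    yc = train_y - ym

    for ic, center in enumerate(grid.centers):
        for ir, rad in enumerate(grid.radii):
            fld = PoolingField(center=center, radius=rad)
            Xtr = _pool_batch(tr_levels, fld)[:, selected]
            Xva = _pool_batch(va_levels, fld)[:, selected]
            xm = Xtr.mean(axis=0)
            U, S, Vt = np.linalg.svd(Xtr - xm, full_matrices=False)
            Uty = U.T @ yc
            # ridge path for every lambda from one SVD
            shrink = S[None, :] / (S[None, :] ** 2 + lam_arr[:, None])
            W = (shrink * Uty[None, :]) @ Vt        # (n_l, K)
            preds = (Xva - xm) @ W.T + ym           # (n_val, n_l)
            for il in range(n_l):
                r = _pearson(preds[:, il], val_y)
                if np.isfinite(r):
                    scores[ir, il, ic] = r

    flat = int(np.argmax(scores))       # first max in (radius, lambda, center)
    ir, il, ic = np.unravel_index(flat, scores.shape)
    best = PoolingField(center=grid.centers[ic], radius=grid.radii[ir])
    Xtr = _pool_batch(tr_levels, best)[:, selected]
    w, b = fit_ridge(Xtr, train_y, grid.lambdas[il])
    return EncodingModel(
        bank_id=bank.bank_id, selected_channels=selected, field=best,
        weights=w, bias=b, region=region, subject_id=subject_id,
        val_accuracy=float(scores[ir, il, ic]), bank=bank)


# ---------------------------------------------------------------------------
# Serialization (HDF5 payload + JSON sidecar)
# ---------------------------------------------------------------------------

def save_encoding_model(model: EncodingModel, path: str) -> None:
    """Write weights to ``path`` (HDF5) and config to ``path + '.json'``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=model.weights)
        f.create_dataset("selected_channels", data=model.selected_channels)
        f.attrs["bias"] = model.bias
        f.attrs["center_x"] = model.field.center[0]
        f.attrs["center_y"] = model.field.center[1]
        f.attrs["radius"] = model.field.radius
    sidecar = {
        "bank": model._require_bank().to_config(),
        "field": {"center": list(model.field.center),
                  "radius": model.field.radius},
        "region": model.region,
        "subject_id": model.subject_id,
        "val_accuracy": None if np.isnan(model.val_accuracy)
        else float(model.val_accuracy),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_encoding_model(path: str) -> EncodingModel:
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    bank = FeatureBank.from_config(sidecar["bank"])
    with h5py.File(path, "r") as f:
        weights = f["weights"][()]
        selected = f["selected_channels"][()]
        bias = float(f.attrs["bias"])
        fld = PoolingField(center=(float(f.attrs["center_x"]),
                                   float(f.attrs["center_y"])),
                           radius=float(f.attrs["radius"]))
    acc = sidecar.get("val_accuracy")
    return EncodingModel(
        bank_id=bank.bank_id, selected_channels=selected, field=fld,
        weights=weights, bias=bias, region=sidecar["region"],
        subject_id=sidecar["subject_id"],
        val_accuracy=np.nan if acc is None else float(acc), bank=bank)
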