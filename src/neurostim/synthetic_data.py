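"""Virtual cohorts, stimulus pools and noisy regional responses.

This module emulates the statistical structure of a large natural-scenes
fMRI cohort (several "base" subjects, each with a large subject-unique image
set plus a shared set viewed by everyone, 2-3 repeats per image) and of two
prospective experimental sessions in novel subjects, without any external
download.

Images are parametric grayscale patterns (smooth Gaussian blobs plus an
oriented, Gaussian-windowed grating) whose parameters vary systematically by
an integer class label and are jittered per image.  Classes therefore drive
distinct feature-bank channels, which is what the class-probing step of the
stimulus synthesis module relies on.

Ground-truth regional responses follow exactly the fwRF functional form

    response = gain * sum_k w*_k * pool(F_k(image); center, radius) + eps

with eps ~ Normal(0, noise_sd^2) independently per (image, repeat), so that
encoding-model recovery is well posed.  Responses are in arbitrary units and
are meant to be z-scored downstream; no hemodynamics are simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .fwrf import FIELD_EXTENT_DEG, FeatureBank, _extract_batch, _pool_batch, \
    PoolingField

# stream tags keeping the seeded substreams of one pool/cohort independent
_TAG_CLASS, _TAG_IMAGE, _TAG_COHORT, _TAG_RESPONSE = 11, 13, 17, 19

TRIAL_COLUMNS = ["subject_id", "image_id", "repeat_index", "region", "response"]
MANIFEST_COLUMNS = ["image_id", "file", "source", "condition",
                    "target_region", "class_label"]


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass
class ImageStim:
    """A square stimulus in [0, 1] covering an 8.4 x 8.4 degree field.

    Pixels may be rendered lazily: a pool of tens of thousands of images is
    cheap to enumerate, and pixels are materialized (and cached) on first
    access.
    """

    image_id: str
    side: int = 64
    source: str = "natural"              # "natural" | "synthetic"
    condition: str | None = None
    target_region: str | None = None
    class_label: int | None = None
    _pixels: np.ndarray | None = field(default=None, repr=False)
    _render: Callable[[], np.ndarray] | None = field(default=None, repr=False)

    @property
    def pixels(self) -> np.ndarray:
        if self._pixels is None:
            if self._render is None:
                raise ValueError(f"image {self.image_id!r} has no pixel source")
            px = np.asarray(self._render(), dtype=float)
            if px.shape != (self.side, self.side):
                raise ValueError("renderer returned wrong image shape")
            if px.min() < 0 or px.max() > 1:
                raise ValueError("pixel values must lie in [0, 1]")
            self._pixels = px
        return self._pixels

    @classmethod
    def from_pixels(cls, image_id: str, pixels: np.ndarray, **kw) -> "ImageStim":
        px = np.asarray(pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("pixels must be a square grid")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        return cls(image_id=image_id, side=px.shape[0],
                   _pixels=np.clip(px, 0.0, 1.0), **kw)

    def relabeled(self, condition: str | None = None,
                  target_region: str | None = None) -> "ImageStim":
        """Copy sharing the pixel source but with new labels."""
        out = dataclasses.replace(self)
        if condition is not None:
            out.condition = condition
        if target_region is not None:
            out.target_region = target_region
        return out


@dataclass
class StimulusPool:
    """A pool of stimuli with subject-ownership and class bookkeeping.

    ``ownership`` maps image id to either ``"shared"`` or the owning base
    subject's index; shared images form one set common to all subjects and
    unique images are disjoint across subjects.
    """

    stimuli: list[ImageStim]
    ownership: dict[str, int | str]
    class_label: dict[str, int]

    def __post_init__(self) -> None:
        ids = [s.image_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image ids in pool")

    @property
    def shared(self) -> list[ImageStim]:
        return [s for s in self.stimuli if self.ownership[s.image_id] == "shared"]

    @property
    def unique(self) -> list[ImageStim]:
        return [s for s in self.stimuli if self.ownership[s.image_id] != "shared"]

    def owned_by(self, subject_index: int) -> list[ImageStim]:
        return [s for s in self.stimuli
                if self.ownership[s.image_id] == subject_index]

    def get(self, image_id: str) -> ImageStim:
        for s in self.stimuli:
            if s.image_id == image_id:
                return s
        raise KeyError(image_id)


# -- parametric pattern rendering -------------------------------------------

def _class_params(seed: int, class_id: int, n_classes: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_CLASS,
                                                        class_id]))
    # orientation and frequency tile the class range so classes separate
    theta = np.pi * (class_id + rng.uniform(0.1, 0.9)) / max(n_classes, 1)
    return {
        "theta": theta,
        "freq": rng.uniform(2.0, 6.0),
        "contrast": rng.uniform(0.35, 0.6),
        "env_center": rng.uniform(0.3, 0.7, size=2),
        "env_width": rng.uniform(0.18, 0.3),
        "blob_pos": rng.uniform(0.2, 0.8, size=(2, 2)),
        "blob_width": rng.uniform(0.06, 0.16, size=2),
        "blob_amp": rng.uniform(0.2, 0.45, size=2) * rng.choice([-1, 1], size=2),
    }


def render_pattern(side: int, params: Mapping, rng: np.random.Generator
                   ) -> np.ndarray:
    """Render one jittered class pattern; values clipped to [0, 1]."""
    u = (np.arange(side) + 0.5) / side
    X, Y = np.meshgrid(u, u)
    img = np.full((side, side), 0.5)
    for (px, py), bw, amp in zip(params["blob_pos"], params["blob_width"],
                                 params["blob_amp"]):
        jx, jy = px + rng.normal(0, 0.02), py + rng.normal(0, 0.02)
        img += amp * (1 + rng.normal(0, 0.1)) * np.exp(
            -((X - jx) ** 2 + (Y - jy) ** 2) / (2 * bw**2))
    th = params["theta"] + rng.normal(0, 0.05)
    phase = rng.uniform(0, 2 * np.pi)
    cx, cy = params["env_center"] + rng.normal(0, 0.02, size=2)
    env = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * params["env_width"]**2))
    grating = np.cos(2 * np.pi * params["freq"] * (X * np.cos(th)
                                                   + Y * np.sin(th)) + phase)
    img += params["contrast"] * (1 + rng.normal(0, 0.1)) * env * grating
    return np.clip(img, 0.0, 1.0)


def make_pool(n_subjects: int, n_unique_per_subject: int, n_shared: int,
              n_classes: int, seed: int, side: int = 64) -> StimulusPool:
    """Build a pool of class-structured natural-like stimuli.

    The pool holds ``n_subjects * n_unique_per_subject`` subject-unique
    images plus ``n_shared`` images common to all subjects; pixel content is
    deterministic given the seed and rendered lazily.
    """
    if min(n_subjects, n_unique_per_subject, n_shared) < 0:
        raise ValueError("counts must be non-negative")
    if n_classes < 1:
        raise ValueError("need at least one class")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_IMAGE]))
    n_total = n_subjects * n_unique_per_subject + n_shared
    classes = rng.integers(0, n_classes, size=n_total)
    params = {c: _class_params(seed, c, n_classes) for c in range(n_classes)}

    stimuli: list[ImageStim] = []
    ownership: dict[str, int | str] = {}
    labels: dict[str, int] = {}

    def _add(image_id: str, index: int, owner) -> None:
        c = int(classes[index])
        img_seed = np.random.SeedSequence([seed, _TAG_IMAGE, index + 1])

        def render(_p=params[c], _s=img_seed, _side=side):
            return render_pattern(_side, _p, np.random.default_rng(_s))

        stimuli.append(ImageStim(image_id=image_id, side=side,
                                 source="natural", class_label=c,
                                 _render=render))
        ownership[image_id] = owner
        labels[image_id] = c

    index = 0
    for subj in range(n_subjects):
        for j in range(n_unique_per_subject):
            _add(f"s{subj:02d}_u{j:05d}", index, subj)
            index += 1
    for j in range(n_shared):
        _add(f"shared_{j:05d}", index, "shared")
        index += 1
    return StimulusPool(stimuli=stimuli, ownership=ownership, class_label=labels)


# ---------------------------------------------------------------------------
# Virtual subjects
# ---------------------------------------------------------------------------

@dataclass
class VirtualSubjectSpec:
    """Ground-truth fwRF parameters of one simulated subject's region."""

    subject_id: str
    tuning_weights: np.ndarray          # over all feature-bank channels
    pooling_center: tuple[float, float]  # degrees, origin at field center
    pooling_radius: float                # fraction of the field extent
    noise_sd: float                      # response units
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.tuning_weights = np.asarray(self.tuning_weights, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        half = FIELD_EXTENT_DEG / 2
        if abs(self.pooling_center[0]) > half or abs(self.pooling_center[1]) > half:
            raise ValueError("pooling center outside the field of view")

    @property
    def field(self) -> PoolingField:
        return PoolingField(center=self.pooling_center,
                            radius=self.pooling_radius)


def make_virtual_cohort(n_subjects: int, shared_tuning_fraction: float,
                        noise_sd_range: tuple[float, float], seed: int, *,
                        n_channels: int = 32,
                        id_prefix: str = "sub",
                        center_box: float = 2.1,
                        radius_range: tuple[float, float] = (0.08, 0.3),
                        center_choices: Sequence[tuple[float, float]] | None = None,
                        radius_choices: Sequence[float] | None = None,
                        noise_sds: Sequence[float] | None = None,
                        common_direction: np.ndarray | None = None,
                        shape_matrix: np.ndarray | None = None,
                        gain: float = 1.0) -> list[VirtualSubjectSpec]:
    """Draw a cohort of ground-truth subjects.

    Each subject's tuning is the unit-normalized mixture
    ``f * w_common + (1 - f) * w_idiosyncratic`` of a cohort-shared and a
    private random direction; noise_sd is uniform in ``noise_sd_range``.
    Pooling centers/radii are drawn from ``center_choices``/``radius_choices``
    when given (e.g. to place the ground truth on a hyperparameter grid) and
    otherwise uniformly from a central box / log-uniform radius range.
    An explicit per-subject ``noise_sds`` sequence (e.g. a noise ladder)
    overrides the uniform draw; ``common_direction`` pins the shared tuning
    component (so separate cohorts — e.g. base and novel subjects of one
    region — can share it); ``shape_matrix`` (typically the pooled-feature
    covariance, see :func:`feature_covariance`) shapes the random tuning
    draws so both the shared and the idiosyncratic components live on the
    stimulus feature manifold.
    """
    f = shared_tuning_fraction
    if not 0 <= f <= 1:
        raise ValueError("shared_tuning_fraction must be in [0, 1]")
    lo, hi = noise_sd_range
    if not 0 <= lo <= hi:
        raise ValueError("noise_sd_range must satisfy 0 <= lo <= hi")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_COHORT]))

    def _draw_direction() -> np.ndarray:
        g = rng.standard_normal(n_channels)
        if shape_matrix is not None:
            g = np.asarray(shape_matrix) @ g
        return g / np.linalg.norm(g)

    if common_direction is not None:
        w_common = np.asarray(common_direction, dtype=float)
        w_common = w_common / np.linalg.norm(w_common)
        _draw_direction()                  # keep the stream aligned
    else:
        w_common = _draw_direction()
    cohort = []
    for i in range(n_subjects):
        w_idio = _draw_direction()
        w = f * w_common + (1 - f) * w_idio
        norm = np.linalg.norm(w)
        if norm > 0:
            w = w / norm
        if center_choices is not None:
            center = tuple(center_choices[rng.integers(len(center_choices))])
        else:
            center = tuple(rng.uniform(-center_box, center_box, size=2))
        if radius_choices is not None:
            radius = float(radius_choices[rng.integers(len(radius_choices))])
        else:
            radius = float(np.exp(rng.uniform(np.log(radius_range[0]),
                                              np.log(radius_range[1]))))
        drawn_sd = float(rng.uniform(lo, hi))
        cohort.append(VirtualSubjectSpec(
            subject_id=f"{id_prefix}{i:02d}",
            tuning_weights=w,
            pooling_center=center,
            pooling_radius=radius,
            noise_sd=float(noise_sds[i]) if noise_sds is not None else drawn_sd,
            gain=gain,
        ))
    return cohort


def feature_covariance(stimuli: Sequence[ImageStim], bank: FeatureBank,
                       field: PoolingField, *,
                       levels: list[np.ndarray] | None = None) -> np.ndarray:
    """Covariance of the pooled feature vector across the given stimuli."""
    if levels is None:
        levels = _extract_batch(np.asarray([s.pixels for s in stimuli]),
                                bank)
    F = _pool_batch(levels, field)
    Fc = F - F.mean(axis=0)
    return Fc.T @ Fc / len(F)


def stimulus_aligned_direction(stimuli: Sequence[ImageStim],
                               bank: FeatureBank, field: PoolingField,
                               rng: np.random.Generator, *,
                               levels: list[np.ndarray] | None = None
                               ) -> np.ndarray:
    """Draw a tuning direction shaped by the stimulus feature covariance.

    A region's tuning is sensitive to features that actually vary across
    natural stimuli; a direction drawn isotropically in channel space can
    be nearly orthogonal to the (low-rank) pooled-feature manifold, which
    would make inter-subject response similarity a coin flip.  Returns
    ``Sigma @ g`` (unit-normalized) for white ``g``, where Sigma is the
    pooled-feature covariance at the given field.
    """
    cov = feature_covariance(stimuli, bank, field, levels=levels)
    w = cov @ rng.standard_normal(cov.shape[0])
    return w / np.linalg.norm(w)


def signal_values(subject: VirtualSubjectSpec, levels: list[np.ndarray]
                  ) -> np.ndarray:
    """Noise-free fwRF responses of one subject to pre-extracted stimuli."""
    pooled = _pool_batch(levels, subject.field)
    return subject.gain * (pooled @ subject.tuning_weights)


def calibrate_gains(subjects: Sequence[VirtualSubjectSpec],
                    stimuli: Sequence[ImageStim],
                    bank: FeatureBank) -> None:
    """Rescale each subject's gain so signal sd is 1 over the given stimuli.

    Puts noise_sd on an interpretable scale: with unit signal sd, repeat
    reliability is 1 / (1 + noise_sd^2).
    """
    px = np.asarray([s.pixels for s in stimuli])
    levels = _extract_batch(px, bank)
    for sub in subjects:
        sd = signal_values(sub, levels).std()
        if sd > 0:
            sub.gain = sub.gain / sd


# ---------------------------------------------------------------------------
# Response simulation
# ---------------------------------------------------------------------------

def simulate_responses(subjects: Sequence[VirtualSubjectSpec],
                       stimuli: Sequence[ImageStim], region: str,
                       n_repeats: int, feature_bank: FeatureBank,
                       seed: int) -> pd.DataFrame:
    """Simulate a long-format trial table for one region.

    One row per (subject, image, repeat); the response is the subject's
    ground-truth fwRF signal plus i.i.d. Gaussian noise per (image, repeat).
    """
    if len(stimuli) == 0:
        raise ValueError("empty stimulus list")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    px = np.asarray([s.pixels for s in stimuli])
    levels = _extract_batch(px, feature_bank)
    image_ids = [s.image_id for s in stimuli]
    frames = []
    for si, sub in enumerate(subjects):
        sig = signal_values(sub, levels)
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, _TAG_RESPONSE, si]))
        noise = rng.normal(0.0, sub.noise_sd, size=(n_repeats, len(stimuli)))
        for rep in range(n_repeats):
            frames.append(pd.DataFrame({
                "subject_id": sub.subject_id,
                "image_id": image_ids,
                "repeat_index": rep + 1,
                "region": region,
                "response": sig + noise[rep],
            }))
    table = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    return table


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check the trial-table invariants (key uniqueness, contiguous repeats)."""
    key = ["subject_id", "image_id", "region"]
    if table.duplicated(subset=key + ["repeat_index"]).any():
        raise ValueError("duplicate (subject, image, repeat, region) rows")
    reps = table.groupby(key, sort=False)["repeat_index"]
    bad = reps.apply(lambda r: sorted(r) != list(range(1, len(r) + 1)))
    if bad.any():
        raise ValueError("repeat_index must be contiguous from 1")


# ---------------------------------------------------------------------------
# Session designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetEntry:
    condition: str
    source: str       # "natural" | "synthetic"
    provider: str     # model identifier
    count: int

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("condition counts must be positive")


@dataclass
class SessionDesign:
    """Named condition sets, target regions and repeat count of a session."""

    session: int
    entries: list[SetEntry]
    target_regions: list[str]
    n_repeats: int = 2

    def __post_init__(self) -> None:
        names = [e.condition for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")

    @property
    def n_images(self) -> int:
        return sum(e.count for e in self.entries)


def make_session_tables(design: SessionDesign,
                        sets: Mapping[str, Sequence[ImageStim]],
                        subjects_by_region: Mapping[str, Sequence[VirtualSubjectSpec]],
                        feature_bank: FeatureBank, seed: int,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manifest and simulated trial table for one session design.

    ``sets`` maps condition name to its stimuli (already labeled with a
    target region); responses are simulated for every region listed in the
    design with the design's repeat count.
    """
    stimuli: list[ImageStim] = []
    rows = []
    for entry in design.entries:
        if entry.condition not in sets:
            raise ValueError(f"no stimulus set for condition {entry.condition!r}")
        imgs = list(sets[entry.condition])
        if len(imgs) < entry.count:
            raise ValueError(
                f"condition {entry.condition!r} needs {entry.count} images, "
                f"have {len(imgs)}")
        for im in imgs[:entry.count]:
            stimuli.append(im)
            rows.append({
                "image_id": im.image_id, "file": f"{im.image_id}.png",
                "source": im.source, "condition": entry.condition,
                "target_region": im.target_region or "",
                "class_label": im.class_label,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if not len(manifest):
        return manifest, pd.DataFrame(columns=TRIAL_COLUMNS)
    if manifest["image_id"].duplicated().any():
        raise ValueError("duplicate image ids across session conditions")

    tables = []
    for ri, region in enumerate(design.target_regions):
        tables.append(simulate_responses(
            subjects_by_region[region], stimuli, region, design.n_repeats,
            feature_bank, seed=int(np.random.SeedSequence(
                [seed, _TAG_RESPONSE, 100 + ri]).generate_state(1)[0] % (2**31))))
    table = (pd.concat(tables, ignore_index=True)
             if tables else pd.DataFrame(columns=TRIAL_COLUMNS))
    return manifest, table


# ---------------------------------------------------------------------------
# Plain-text / PNG interchange
# ---------------------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)

def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")

def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)

def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")

def write_images(stimuli: Sequence[ImageStim], directory) -> None:
    """Write stimuli as 8-bit grayscale PNGs named ``<image_id>.png``."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in stimuli:
        arr = np.round(s.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / f"{s.image_id}.png")

def read_image(path, **kw) -> ImageStim:
    from pathlib import Path
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return ImageStim.from_pixels(Path(path).stem, arr, **kw)
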