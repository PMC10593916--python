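"""Optimal synthetic stimulus generation (class probe + noise optimization).

The generator maps a one-hot class vector and a continuous noise vector to
an image, mirroring the class/noise factorization of a conditional GAN at
desk scale: each class has a seeded smooth template (blobs + oriented
grating) and the noise vector modulates the amplitudes of a fixed set of
smooth spatial modes before a logistic squash into [0, 1].  The map is
differentiable in the noise vector, with an analytic Jacobian.

Synthesis proceeds in the two NeuroGen steps:

1. *class probe* — render the same seeded noise vectors for every class,
   score each class by the mean predicted activation of its images, and
   rank classes (descending for Max, ascending |score| for Avg);
2. *noise optimization* — for the best classes, minimize

       L_Max(z) = -yhat(render(c, z)) + lam_z ||z||^2
       L_Avg(z) = |yhat(render(c, z))| + lam_z ||z||^2

   by gradient descent through the full model-of-renderer chain (or by
   seeded random search), keeping the best-so-far noise vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .fwrf import predict_and_grad, predict_batch
from .selection import StimulusSet
from .synthetic_data import ImageStim, _class_params, render_pattern

_TAG_TEMPLATE, _TAG_MODE, _TAG_PROBE = 31, 37, 41


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-t))


@dataclass
class GeneratorSpec:
    """Seeded differentiable parametric image generator.

    ``render`` maps (class id, noise vector) deterministically to pixels in
    [0, 1]:  ``sigmoid(slope * (template_c - 1/2 + sum_j a_cj z_j M_j))``
    with class templates built from the same parametric pattern family as
    the natural pool, fixed smooth modes ``M_j`` and class-specific mode
    amplitudes ``a_cj``.
    """

    n_classes: int
    noise_dim: int = 6
    side: int = 64
    seed: int = 0
    slope: float = 3.0
    mode_scale: float = 0.35
    differentiable_in_z: bool = True
    _templates: np.ndarray | None = field(default=None, repr=False)
    _modes: np.ndarray | None = field(default=None, repr=False)
    _amps: np.ndarray | None = field(default=None, repr=False)

    def _materialize(self) -> None:
        if self._templates is not None:
            return
        tpls = np.empty((self.n_classes, self.side, self.side))
        for c in range(self.n_classes):
            params = _class_params(self.seed + 1_000_003, c, self.n_classes)
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, _TAG_TEMPLATE, c]))
            tpls[c] = render_pattern(self.side, params, rng)
        self._templates = tpls
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, _TAG_MODE]))
        u = (np.arange(self.side) + 0.5) / self.side
        X, Y = np.meshgrid(u, u)
        modes = []
        for j in range(self.noise_dim):
            if j % 2 == 0:   # smooth bump
                cx, cy = rng.uniform(0.2, 0.8, size=2)
                w = rng.uniform(0.12, 0.3)
                m = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * w**2))
            else:            # low-frequency wave
                th = rng.uniform(0, np.pi)
                fr = rng.uniform(1.0, 3.0)
                ph = rng.uniform(0, 2 * np.pi)
                m = np.sin(2 * np.pi * fr * (X * np.cos(th) + Y * np.sin(th))
                           + ph)
            modes.append(m - m.mean())
        self._modes = np.asarray(modes)
        self._amps = rng.uniform(0.5, 1.5, size=(self.n_classes,
                                                 self.noise_dim))
        self._amps *= self.mode_scale / np.sqrt(self.noise_dim)

    def _presquash(self, class_id: int, Z: np.ndarray) -> np.ndarray:
        self._materialize()
        base = self._templates[class_id] - 0.5
        mod = np.tensordot(Z * self._amps[class_id], self._modes, axes=(1, 0))
        return self.slope * (base[None] + mod)

    def render(self, class_id: int, z: np.ndarray) -> np.ndarray:
        """Pixels in [0, 1] for one (class, noise) pair."""
        return self.render_batch(class_id, np.asarray(z, dtype=float)[None])[0]

    def render_batch(self, class_id: int, Z: np.ndarray) -> np.ndarray:
        if not 0 <= class_id < self.n_classes:
            raise ValueError(f"class_id {class_id} out of range")
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != self.noise_dim:
            raise ValueError("noise vector has wrong dimension")
        return _sigmoid(self._presquash(class_id, Z))

    def render_grad(self, class_id: int, Z: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Pixels and d(pixels)/dz, shapes (B, S, S) and (B, dim, S, S)."""
        t = self._presquash(class_id, Z)
        pix = _sigmoid(t)
        dsig = self.slope * pix * (1.0 - pix)
        jac = dsig[:, None] * (self._amps[class_id][None, :, None, None]
                               * self._modes[None])
        return pix, jac


# ---------------------------------------------------------------------------
# Configuration / results
# ---------------------------------------------------------------------------

@dataclass
class SynthesisConfig:
    mode: str = "Max"                 # "Max" | "Avg"
    reg_weight: float = 0.01          # lam_z on ||z||^2
    n_probe_per_class: int = 100
    n_top_classes: int = 10
    steps: int = 200
    step_size: float = 0.05
    optimizer: str = "gradient"       # "gradient" | "random-search"
    z_init_scale: float = 1.0
    z_bound: float = 2.0              # truncation: |z_i| <= z_bound
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("Max", "Avg"):
            raise ValueError("mode must be 'Max' or 'Avg'")
        if self.steps < 1 or self.n_probe_per_class < 1:
            raise ValueError("steps and n_probe_per_class must be >= 1")


@dataclass
class OptimizationResult:
    class_id: int
    z_final: np.ndarray
    image: ImageStim
    predicted_activation: float
    trajectory: pd.DataFrame          # per-step loss and prediction
    best_loss_curve: np.ndarray       # non-increasing


# ---------------------------------------------------------------------------
# Class probing
# ---------------------------------------------------------------------------

@dataclass
class ClassProbe:
    scores: np.ndarray                # mean predicted activation per class
    order: np.ndarray                 # classes sorted for the given mode
    mode: str
    noise: np.ndarray                 # the shared probe noise vectors


def probe_classes(gen: GeneratorSpec, model, n_per_class: int, seed: int, *,
                  mode: str = "Max") -> ClassProbe:
    """Score every generator class by mean predicted activation.

    The same ``n_per_class`` seeded noise vectors are reused across classes
    so class scores differ only through the class, not the noise draw.
    Classes are returned best-first: descending score for Max, ascending
    absolute score for Avg.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _TAG_PROBE]))
    noise = rng.standard_normal((n_per_class, gen.noise_dim))
    scores = np.empty(gen.n_classes)
    for c in range(gen.n_classes):
        pix = gen.render_batch(c, noise)
        scores[c] = predict_batch(model, pix).mean()
    key = -scores if mode == "Max" else np.abs(scores)
    order = np.lexsort((np.arange(gen.n_classes), key))
    return ClassProbe(scores=scores, order=order, mode=mode, noise=noise)


# ---------------------------------------------------------------------------
# Noise-vector optimization
# ---------------------------------------------------------------------------

def minimize_noise_objective(loss_fn: Callable[[np.ndarray], float],
                             grad_fn: Callable[[np.ndarray], np.ndarray] | None,
                             z0: np.ndarray, cfg: SynthesisConfig,
                             rng: np.random.Generator | None = None,
                             value_and_grad: Callable | None = None,
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generic seeded minimizer over the truncated noise space.

    Gradient mode takes fixed-size descent steps and clips to the
    truncation bound (``value_and_grad``, when given, supplies loss and
    gradient from one shared pass); random-search mode proposes Gaussian
    perturbations of the incumbent and keeps improvements.  Returns
    ``(z_best, losses_per_step, z_per_step)``.
    """
    z = np.clip(np.asarray(z0, dtype=float), -cfg.z_bound, cfg.z_bound)
    best_z = z.copy()
    best_loss = loss_fn(z)
    losses = [best_loss]
    zs = [z.copy()]
    if cfg.optimizer == "gradient":
        if grad_fn is None and value_and_grad is None:
            raise ValueError("gradient mode requires a differentiable chain")
        if value_and_grad is None:
            def value_and_grad(zz):  # noqa: F811 - fallback from parts
                return loss_fn(zz), grad_fn(zz)
        _, g = value_and_grad(z)
        for _ in range(cfg.steps):
            z = np.clip(z - cfg.step_size * g, -cfg.z_bound, cfg.z_bound)
            cur, g = value_and_grad(z)
            losses.append(cur)
            zs.append(z.copy())
            if cur < best_loss:
                best_loss, best_z = cur, z.copy()
    elif cfg.optimizer == "random-search":
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.steps):
            cand = np.clip(best_z + rng.normal(0, cfg.step_size, size=z.shape),
                           -cfg.z_bound, cfg.z_bound)
            cur = loss_fn(cand)
            losses.append(cur)
            zs.append(cand.copy())
            if cur < best_loss:
                best_loss, best_z = cur, cand.copy()
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    return best_z, np.asarray(losses), np.asarray(zs)


def optimize_noise(gen: GeneratorSpec, model, class_id: int,
                   cfg: SynthesisConfig, *,
                   image_id: str | None = None) -> OptimizationResult:
    """Optimize the noise vector of one class against the Max or Avg loss."""
    if not 0 <= class_id < gen.n_classes:
        raise ValueError("class_id out of range")
    if cfg.optimizer == "gradient" and not gen.differentiable_in_z:
        raise ValueError("gradient mode requires a differentiable generator")
    rng = np.random.default_rng(cfg.seed)
    z0 = rng.normal(0.0, cfg.z_init_scale, size=gen.noise_dim)

    def predict_one(z: np.ndarray) -> float:
        return float(predict_batch(model, gen.render(class_id, z)[None])[0])

    def loss_fn(z: np.ndarray) -> float:
        y = predict_one(z)
        pen = cfg.reg_weight * float(z @ z)
        return (-y if cfg.mode == "Max" else abs(y)) + pen

    def value_and_grad(z: np.ndarray) -> tuple[float, np.ndarray]:
        pix, jac = gen.render_grad(class_id, z[None])
        y, gpix = predict_and_grad(model, pix)
        dy_dz = np.tensordot(jac[0], gpix[0], axes=([1, 2], [0, 1]))
        sign = -1.0 if cfg.mode == "Max" else float(np.sign(y[0]))
        loss = ((-y[0] if cfg.mode == "Max" else abs(y[0]))
                + cfg.reg_weight * float(z @ z))
        return loss, sign * dy_dz + 2.0 * cfg.reg_weight * z

    z_best, losses, _ = minimize_noise_objective(
        loss_fn, None, z0, cfg, rng,
        value_and_grad=value_and_grad if gen.differentiable_in_z else None)
    pix = gen.render(class_id, z_best)
    pred = float(predict_batch(model, pix[None])[0])
    if image_id is None:
        image_id = f"syn_c{class_id:03d}_s{cfg.seed}"
    image = ImageStim.from_pixels(image_id, pix, source="synthetic",
                                  class_label=class_id)
    traj = pd.DataFrame({"step": np.arange(len(losses)), "loss": losses})
    return OptimizationResult(
        class_id=class_id, z_final=z_best, image=image,
        predicted_activation=pred, trajectory=traj,
        best_loss_curve=np.minimum.accumulate(losses))


def _split_counts(N: int, n_classes: int) -> list[int]:
    """Spread N optimizations over classes, remainder to the best classes."""
    base, rem = divmod(N, n_classes)
    return [base + (1 if i < rem else 0) for i in range(n_classes)]


def generate_set(gen: GeneratorSpec, model, mode: str, N: int,
                 cfg: SynthesisConfig, *, id_prefix: str = "syn",
                 condition: str | None = None,
                 target_region: str | None = None,
                 provider: str = "",
                 probe: ClassProbe | None = None,
                 ) -> tuple[StimulusSet, pd.DataFrame]:
    """Generate N synthetic stimuli via class probing + noise optimization.

    The probe ranks classes for the requested mode; N optimizations are
    spread evenly over the ``cfg.n_top_classes`` best classes (remainder
    going to the better classes), each with its own derived seed.  The
    output set is ordered by predicted activation (mode-appropriately) and
    accompanied by a synthesis log table.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if cfg.n_top_classes > gen.n_classes:
        raise ValueError("n_top_classes exceeds the number of classes")
    cfg = SynthesisConfig(**{**cfg.__dict__, "mode": mode})
    if probe is None:
        probe = probe_classes(gen, model, cfg.n_probe_per_class, cfg.seed,
                              mode=mode)
    key_scores = -probe.scores if mode == "Max" else np.abs(probe.scores)
    order = np.lexsort((np.arange(gen.n_classes), key_scores))
    top = order[:cfg.n_top_classes]
    counts = _split_counts(N, len(top))
    results: list[OptimizationResult] = []
    rows = []
    i = 0
    for class_id, cnt in zip(top, counts):
        for _ in range(cnt):
            child_seed = int(np.random.SeedSequence(
                [cfg.seed, 43, i]).generate_state(1)[0] % (2**31))
            run_cfg = SynthesisConfig(**{**cfg.__dict__, "seed": child_seed})
            res = optimize_noise(gen, model, int(class_id), run_cfg,
                                 image_id=f"{id_prefix}_{i:03d}")
            if condition is not None:
                res.image.condition = condition
            if target_region is not None:
                res.image.target_region = target_region
            results.append(res)
            rows.append({"image_id": res.image.image_id,
                         "class_id": int(class_id), "seed": child_seed,
                         "steps": cfg.steps,
                         "final_loss": float(res.best_loss_curve[-1]),
                         "predicted_activation": res.predicted_activation,
                         "z_final": ",".join(f"{v:.8g}" for v in res.z_final)})
            i += 1
    key = ((lambda r: (-r.predicted_activation, r.image.image_id))
           if mode == "Max"
           else (lambda r: (abs(r.predicted_activation), r.image.image_id)))
    results.sort(key=key)
    log = pd.DataFrame(rows)
    st = StimulusSet(condition=condition or mode, provider=provider,
                     stimuli=[r.image for r in results],
                     predictions=np.array([r.predicted_activation
                                           for r in results]))
    return st, log
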