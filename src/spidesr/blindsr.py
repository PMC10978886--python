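"""Blind super-resolution with iterative blur-kernel correction.

Inference follows the predictor -> SR -> corrector loop:

    k_0 = P(I_LR)                       (kernel predictor)
    repeat i = 1, 2, ...:
        I_SR(i-1) = S(I_LR, k_(i-1))    (kernel-conditioned SR network)
        dk_i      = C(I_SR(i-1), k_(i-1))
        k_i       = renormalize(k_(i-1) + dk_i)
    until ||dk_i||_2 < tol or i = max_iter

and the final image is the SR output computed with the last kernel.
Training is staged: the SR network is fitted first with pixel MSE given the
true bank kernels and then frozen; the predictor (loss ||K - P(I_LR)||^2)
and the corrector (loss ||K - (C(I_SR, k) + k)||^2, measured along unrolled
correction iterations) are then trained alternately with Adam
(beta1 = 0.9, beta2 = 0.999, lr = 1e-4).

Kernel legality (nonnegative entries summing to 1) is restored after every
prediction and correction by clipping negatives and renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import nn
from .degradation import (BlurKernel, TrainingPairs, _bicubic_sample,
                          kernel_mse)
from .io import ImageGrid
from .networks import CorrectorNet, PredictorNet, SRNet

__all__ = [
    "SRTrace",
    "BlindSuperResolver",
    "train_sr_module",
    "predict_kernel",
    "super_resolve",
    "correct_kernel",
    "enhance",
]


@dataclass
class SRTrace:
    """Per-iteration record of the kernel-correction loop."""

    records: list[dict] = field(default_factory=list)
    converged_at: int | None = None

    def add(self, iteration: int, kernel: BlurKernel,
            delta_norm: float | None, mse_true: float | None = None):
        self.records.append({
            "iteration": iteration,
            "sigma_estimate": kernel.width_estimate(),
            "delta_norm": delta_norm,
            "kernel_mse": mse_true,
        })

    @property
    def iterations(self) -> list[int]:
        return [r["iteration"] for r in self.records]

    def kernel_mses(self) -> list[float]:
        return [r["kernel_mse"] for r in self.records]


def _as_triples(pairs):
    if isinstance(pairs, TrainingPairs):
        return pairs.triples
    return list(pairs)


class BlindSuperResolver(BaseEstimator):
    """Estimator bundling the kernel predictor, SR network and corrector.

    ``fit`` consumes (hr, lr, kernel) triples produced by the degradation
    module; the true bank kernels supervise all three stages.  ``transform``
    / :meth:`enhance` run the blind inference loop with the default budget
    of ``max_iter`` = 9 iterations and increment tolerance ``tol`` = 1e-4.

    Fitted attributes: ``sr_net_``, ``predictor_``, ``corrector_``, and the
    per-stage loss curves ``sr_losses_``, ``predictor_losses_``,
    ``corrector_losses_``.
    """

    def __init__(self, scale: int = 4, kernel_size: int = 21,
                 sigma_range: tuple[float, float] = (0.2, 4.0),
                 code_dim: int = 10, sr_channels: int = 24,
                 sr_blocks: int = 4, predictor_channels: int = 16,
                 corrector_channels: int = 16, epochs_sr: int = 60,
                 epochs_alt: int = 20, unroll: int = 3, batch_size: int = 4,
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 max_iter: int = 9, tol: float = 1e-4, random_state: int = 0):
        self.scale = scale
        self.kernel_size = kernel_size
        self.sigma_range = sigma_range
        self.code_dim = code_dim
        self.sr_channels = sr_channels
        self.sr_blocks = sr_blocks
        self.predictor_channels = predictor_channels
        self.corrector_channels = corrector_channels
        self.epochs_sr = epochs_sr
        self.epochs_alt = epochs_alt
        self.unroll = unroll
        self.batch_size = batch_size
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "sr_net_"):
            raise NotFittedError("blind SR stack is not fitted; call fit()")

    @staticmethod
    def _to01(grid: ImageGrid) -> np.ndarray:
        return grid.rescaled().pixels / 255.0

    def _prepare(self, pairs):
        """(hr01, lr01, k_flat, bicubic01) stacks, channels as samples."""
        hrs, lrs, ks, bups = [], [], [], []
        for hr, lr, k in pairs:
            if k is None:
                raise ValueError("training triples must carry true kernels")
            if k.size != self.kernel_size:
                raise ValueError(
                    f"kernel size {k.size} != configured {self.kernel_size}")
            hr01, lr01 = self._to01(hr), self._to01(lr)
            for hc, lc in zip(hr01, lr01):
                hrs.append(hc)
                lrs.append(lc)
                ks.append(k.weights.ravel())
                bups.append(_bicubic_sample(lc, hc.shape[0], hc.shape[1]))
        return (np.asarray(hrs)[:, None], np.asarray(lrs)[:, None],
                np.asarray(ks), np.asarray(bups)[:, None])

    def fit(self, pairs, y=None):
        pairs = _as_triples(pairs)
        if not pairs:
            raise ValueError("no training pairs")
        hr, lr, kf, bup = self._prepare(pairs)
        rng = np.random.default_rng(self.random_state)
        n = hr.shape[0]
        self.sr_net_ = SRNet(rng, scale=self.scale, channels=self.sr_channels,
                             n_blocks=self.sr_blocks, code_dim=self.code_dim,
                             kernel_size=self.kernel_size)
        self.predictor_ = PredictorNet(rng, channels=self.predictor_channels,
                                       kernel_size=self.kernel_size,
                                       sigma_range=self.sigma_range)
        self.corrector_ = CorrectorNet(rng, channels=self.corrector_channels,
                                       kernel_size=self.kernel_size,
                                       sigma_range=self.sigma_range)

        # stage 1: SR network with true kernels, pixel MSE, then frozen
        opt = nn.Adam(self.sr_net_.params(), lr=self.lr,
                      beta1=self.beta1, beta2=self.beta2)
        self.sr_losses_ = []
        for _ in range(self.epochs_sr):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                self.sr_net_.zero_grad()
                out = self.sr_net_.forward(lr[idx], kf[idx], bup[idx])
                diff = out - hr[idx]
                losses.append(float(np.mean(diff ** 2)))
                self.sr_net_.backward(2.0 * diff / diff.size)
                opt.step()
            self.sr_losses_.append(float(np.mean(losses)))

        # stage 2: predictor and corrector, alternating epochs
        opt_p = nn.Adam(self.predictor_.params(), lr=self.lr,
                        beta1=self.beta1, beta2=self.beta2)
        opt_c = nn.Adam(self.corrector_.params(), lr=self.lr,
                        beta1=self.beta1, beta2=self.beta2)
        self.predictor_losses_ = []
        self.corrector_losses_ = []
        for _ in range(self.epochs_alt):
            # predictor epoch: ||K - P(I_LR)||^2
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                self.predictor_.zero_grad()
                pred = self.predictor_.forward(lr[idx])
                diff = pred - kf[idx]
                losses.append(float(np.mean(diff ** 2)))
                self.predictor_.backward(2.0 * diff / diff.size)
                opt_p.step()
            self.predictor_losses_.append(float(np.mean(losses)))

            # corrector epoch: unrolled ||K - (C(I_SR, k) + k)||^2 with the
            # frozen SR network producing the intermediate SR images
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                k_cur = np.stack([
                    BlurKernel.from_raw(
                        r.reshape(self.kernel_size, self.kernel_size)
                    ).weights.ravel()
                    for r in self.predictor_.forward(lr[idx])])
                self.corrector_.zero_grad()
                step_losses = []
                for _ in range(self.unroll):
                    sr_img = self.sr_net_.forward(lr[idx], k_cur, bup[idx])
                    ghat = self.corrector_.corrected(sr_img, k_cur)
                    diff = ghat - kf[idx]
                    step_losses.append(float(np.mean(diff ** 2)))
                    self.corrector_.backward(2.0 * diff / diff.size)
                    k_cur = np.stack([
                        BlurKernel.from_raw(
                            g.reshape(self.kernel_size, self.kernel_size)
                        ).weights.ravel() for g in ghat])
                opt_c.step()
                losses.append(float(np.mean(step_losses)))
            self.corrector_losses_.append(float(np.mean(losses)))
        return self

    # ------------------------------------------------------------------
    def predict_kernel(self, lr: ImageGrid) -> BlurKernel:
        """k0 = P(I_LR), clipped to nonnegative and renormalized to sum 1."""
        self._check_fitted()
        raw = self.predictor_.forward(self._to01(lr)[:1][:, None])[0]
        return BlurKernel.from_raw(
            raw.reshape(self.kernel_size, self.kernel_size))

    def super_resolve(self, lr: ImageGrid, kernel: BlurKernel) -> ImageGrid:
        """S(I_LR, k): output dims exactly scale x input, clipped to range."""
        self._check_fitted()
        if kernel.size != self.kernel_size:
            raise ValueError(
                f"kernel size {kernel.size} != configured {self.kernel_size}")
        lr01 = self._to01(lr)
        h, w = lr.shape
        H, W = h * self.scale, w * self.scale
        kf = np.tile(kernel.weights.ravel(), (lr01.shape[0], 1))
        bup = np.stack([_bicubic_sample(c, H, W) for c in lr01])
        out01 = self.sr_net_.forward(lr01[:, None], kf, bup[:, None])[:, 0]
        lo, hi = lr.value_range
        native = out01 * 255.0 * lr.rescale_factor() + lo
        return lr.with_pixels(np.clip(native, lo, hi))

    def correct_kernel(self, sr: ImageGrid, k_prev: BlurKernel) -> BlurKernel:
        """k_i = renormalize(k_(i-1) + C(I_SR, k_(i-1)))."""
        self._check_fitted()
        delta = self._delta(sr, k_prev)
        return BlurKernel.from_raw(k_prev.weights + delta)

    def _delta(self, sr: ImageGrid, k_prev: BlurKernel) -> np.ndarray:
        if k_prev.size != self.kernel_size:
            raise ValueError("kernel size mismatch")
        sr01 = self._to01(sr)[:1][:, None]
        kf = k_prev.weights.ravel()[None]
        return self.corrector_.forward(sr01, kf)[0].reshape(
            self.kernel_size, self.kernel_size)

    def enhance(self, lr: ImageGrid, max_iter: int | None = None,
                tol: float | None = None, true_kernel: BlurKernel | None = None,
                denoiser=None) -> tuple[ImageGrid, SRTrace]:
        """Run the full blind inference loop on one LR image.

        ``true_kernel`` (when known, e.g. on synthetic validation data) adds
        kernel-MSE-to-truth to the trace; ``denoiser`` (a fitted
        :class:`~spidesr.denoise.NeighborSubsampleDenoiser`) is applied to
        the input first, composing the two modules in their pipeline order.
        """
        self._check_fitted()
        max_iter = self.max_iter if max_iter is None else max_iter
        tol = self.tol if tol is None else tol
        if max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if denoiser is not None:
            lr = denoiser.denoise_one(lr)
        trace = SRTrace()
        k = self.predict_kernel(lr)
        trace.add(0, k, None,
                  kernel_mse(k, true_kernel) if true_kernel else None)
        for i in range(1, max_iter + 1):
            sr = self.super_resolve(lr, k)
            delta = self._delta(sr, k)
            k = BlurKernel.from_raw(k.weights + delta)
            dn = float(np.linalg.norm(delta))
            trace.add(i, k, dn,
                      kernel_mse(k, true_kernel) if true_kernel else None)
            if dn < tol:
                trace.converged_at = i
                break
        return self.super_resolve(lr, k), trace

    def transform(self, X):
        return [self.enhance(lr)[0] for lr in X]


    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize parameters and weights to an ``.npz`` checkpoint."""
        self._check_fitted()
        import json
        arrays = {}
        for name, net in (("sr", self.sr_net_), ("pred", self.predictor_),
                          ("corr", self.corrector_)):
            for i, a in enumerate(net.state_list()):
                arrays[f"{name}_{i}"] = a
        np.savez(path, __config=json.dumps(self.get_params()), **arrays)

    @classmethod
    def load(cls, path: str) -> "BlindSuperResolver":
        import json
        with np.load(path, allow_pickle=False) as data:
            model = cls(**json.loads(str(data["__config"])))
            rng = np.random.default_rng(model.random_state)
            model.sr_net_ = SRNet(rng, scale=model.scale,
                                  channels=model.sr_channels,
                                  n_blocks=model.sr_blocks,
                                  code_dim=model.code_dim,
                                  kernel_size=model.kernel_size)
            model.predictor_ = PredictorNet(rng,
                                            channels=model.predictor_channels,
                                            kernel_size=model.kernel_size,
                                            sigma_range=model.sigma_range)
            model.corrector_ = CorrectorNet(rng,
                                            channels=model.corrector_channels,
                                            kernel_size=model.kernel_size,
                                            sigma_range=model.sigma_range)
            for name, net in (("sr", model.sr_net_), ("pred", model.predictor_),
                              ("corr", model.corrector_)):
                n = len(net.params())
                net.load_state_list([data[f"{name}_{i}"] for i in range(n)])
        return model


# thin functional wrappers over the estimator --------------------------------

def train_sr_module(pairs, **config) -> BlindSuperResolver:
    """Fit the predictor/corrector/SR stack on (hr, lr, kernel) triples."""
    return BlindSuperResolver(**config).fit(pairs)


def predict_kernel(model: BlindSuperResolver, lr: ImageGrid) -> BlurKernel:
    return model.predict_kernel(lr)


def super_resolve(model: BlindSuperResolver, lr: ImageGrid,
                  kernel: BlurKernel) -> ImageGrid:
    return model.super_resolve(lr, kernel)


def correct_kernel(model: BlindSuperResolver, sr: ImageGrid,
                   k_prev: BlurKernel) -> BlurKernel:
    return model.correct_kernel(sr, k_prev)


def enhance(lr: ImageGrid, models: BlindSuperResolver,
            max_iter: int | None = None, tol: float | None = None,
            **kw) -> tuple[ImageGrid, SRTrace]:
    return models.enhance(lr, max_iter=max_iter, tol=tol, **kw)
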