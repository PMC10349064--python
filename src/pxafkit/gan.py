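"""1-D GAN for two-lead ECG synthesis (Pulse2Pulse-style U-Net generator).

The generator maps a 2-lead noise signal through six strided
down-sampling blocks (1-D convolution + Leaky ReLU) and six up-sampling
blocks (nearest-neighbour upsampling, constant padding, 1-D convolution,
ReLU) with U-Net skip connections, producing a 2-lead signal of the
input's shape.  The discriminator stacks seven convolutional layers in
Convolution + Leaky ReLU + phase-shuffle order and outputs one raw
score per signal.

Training follows the classic two-player minimax objective
``min_G max_D  E[log D(x)] + E[log(1 - D(G(z)))]``
with scores mapped to probabilities by a logistic transform.  The
generator step uses the non-saturating surrogate ``-E[log D(G(z))]`` by
default (the literal minimax generator term is available via
``generator_objective="saturating"``).

Reference (full-scale) settings are 2x5000 signals, 8000 epochs and
learning rate 1e-4 with the adaptive-moment optimizer; the desk-scale
defaults here (2x512, tens of epochs, width 16) exercise the identical
architecture at a size a single CPU handles.  Since 5000 is not
divisible by 2^6, full-scale lengths are internally padded to the next
multiple of 64 and cropped on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .types import ECGSegment, InvalidParameterError

__all__ = ["GANConfig", "GANLossTerms", "Generator", "Discriminator",
           "generator_forward", "discriminator_forward", "gan_loss",
           "gan_train", "gan_sample", "GANDivergenceError"]

_EPS = 1e-7


class GANDivergenceError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


@dataclass
class GANConfig:
    """Architecture and training hyper-parameters.

    ``noise_shape`` is (leads, length); length must be divisible by 64
    unless ``pad_to_multiple`` is set, in which case the generator pads
    internally and crops the output (the full-scale 2x5000 case).
    """

    noise_shape: tuple[int, int] = (2, 512)
    g_down_blocks: int = 6
    g_up_blocks: int = 6
    d_conv_layers: int = 7
    phase_shuffle_n: int = 2
    epochs: int = 50
    learning_rate: float = 1e-4
    batch_size: int = 16
    base_width: int = 16
    kernel_size: int = 5
    width_cap: int = 2
    amp_mv: float = 1.5            # tanh output scale (millivolts)
    generator_objective: str = "non_saturating"
    pad_to_multiple: bool = False
    dtype: str = "float32"         # array dtype for parameters/training
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_down_blocks != self.g_up_blocks:
            raise InvalidParameterError("down/up block counts must match")
        if self.noise_shape[1] % (2 ** self.g_down_blocks) and \
                not self.pad_to_multiple:
            raise InvalidParameterError(
                f"signal length {self.noise_shape[1]} is not divisible by "
                f"2^{self.g_down_blocks}; enable pad_to_multiple"
            )


@dataclass
class GANLossTerms:
    """Discriminator and generator loss values for one evaluation."""

    d_loss: float
    g_loss: float


def _widths(base: int, blocks: int, cap: int = 2) -> list[int]:
    return [base * min(2 ** i, cap) for i in range(blocks)]


def _dtype(cfg) -> np.dtype:
    return np.dtype(cfg.dtype)


class Generator:
    """U-Net 1-D generator; see module docstring for the block layout."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        with ad.using_dtype(_dtype(cfg)):
            self._build(rng)

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        k = cfg.kernel_size
        leads = cfg.noise_shape[0]
        widths = _widths(cfg.base_width, cfg.g_down_blocks, cfg.width_cap)
        self.params: list[ad.Parameter] = []
        self.down: list[tuple[ad.Parameter, ad.Parameter]] = []
        c_in = leads
        for c_out in widths:
            w = ad.Parameter(ad.kaiming_init((c_out, c_in, k), c_in * k, rng))
            b = ad.Parameter(np.zeros(c_out))
            self.down.append((w, b))
            self.params += [w, b]
            c_in = c_out
        self.up: list[tuple[ad.Parameter, ad.Parameter]] = []
        for i in range(cfg.g_up_blocks):
            skip_c = widths[-(i + 2)] if i < cfg.g_up_blocks - 1 else leads
            c_out = widths[-(i + 2)] if i < cfg.g_up_blocks - 1 else cfg.base_width
            cin_up = c_in + skip_c
            w = ad.Parameter(ad.kaiming_init((c_out, cin_up, k), cin_up * k, rng))
            b = ad.Parameter(np.zeros(c_out))
            self.up.append((w, b))
            self.params += [w, b]
            c_in = c_out
        w = ad.Parameter(ad.kaiming_init((leads, c_in, k), c_in * k, rng,
                                         gain=1.0))
        b = ad.Parameter(np.zeros(leads))
        self.head = (w, b)
        self.params += [w, b]

    def forward(self, noise: ad.Tensor) -> ad.Tensor:
        cfg = self.cfg
        k = cfg.kernel_size
        pad = k // 2
        length = noise.shape[2]
        mult = 2 ** cfg.g_down_blocks
        padded = 0
        x = noise
        if length % mult:
            padded = mult - length % mult
            x = ad.pad1d(x, 0, padded)
        skips = [x]
        for w, b in self.down:
            x = ad.conv1d(x, w, b, stride=2, padding=pad)
            x = ad.leaky_relu(x, 0.2)
            skips.append(x)
        for i, (w, b) in enumerate(self.up):
            x = ad.upsample1d_nearest(x, 2)
            skip = skips[-(i + 2)]
            x = ad.concat([x, skip], axis=1)
            x = ad.pad1d(x, pad, pad)
            x = ad.conv1d(x, w, b, stride=1, padding=0)
            x = ad.relu(x)
        w, b = self.head
        x = ad.conv1d(x, w, b, stride=1, padding=pad)
        out = ad.tanh(x) * ad.Tensor(cfg.amp_mv)
        if padded:
            out = _crop1d(out, 0, length)
        return out


def _crop1d(x: ad.Tensor, start: int, length: int) -> ad.Tensor:
    out = ad.Tensor(x.data[:, :, start:start + length], parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, :, start:start + length] = g
        x._accum(full)
    out._backward = bw
    return out


class Discriminator:
    """Seven Conv + LeakyReLU + phase-shuffle layers and a dense head."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        with ad.using_dtype(_dtype(cfg)):
            self._build(rng)

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.cfg
        k = cfg.kernel_size
        leads, length = cfg.noise_shape
        widths = _widths(cfg.base_width, cfg.d_conv_layers, cfg.width_cap)
        self.layers: list[tuple[ad.Parameter, ad.Parameter]] = []
        self.params: list[ad.Parameter] = []
        c_in = leads
        cur_len = length
        for c_out in widths:
            w = ad.Parameter(ad.kaiming_init((c_out, c_in, k), c_in * k, rng))
            b = ad.Parameter(np.zeros(c_out))
            self.layers.append((w, b))
            self.params += [w, b]
            c_in = c_out
            cur_len = (cur_len + 2 * (k // 2) - k) // 2 + 1
        feat = c_in * cur_len
        self.w_out = ad.Parameter(ad.kaiming_init((feat, 1), feat, rng,
                                                  gain=1.0))
        self.b_out = ad.Parameter(np.zeros(1))
        self.params += [self.w_out, self.b_out]

    def forward(self, signal: ad.Tensor,
                rng: np.random.Generator | None = None) -> ad.Tensor:
        cfg = self.cfg
        if signal.shape[1:] != tuple(cfg.noise_shape):
            raise InvalidParameterError(
                f"discriminator expects {cfg.noise_shape}, "
                f"got {signal.shape[1:]}"
            )
        k = cfg.kernel_size
        x = signal
        shuffle_rng = rng if rng is not None else np.random.default_rng(0)
        for w, b in self.layers:
            x = ad.conv1d(x, w, b, stride=2, padding=k // 2)
            x = ad.leaky_relu(x, 0.2)
            x = ad.phase_shuffle1d(x, cfg.phase_shuffle_n, shuffle_rng)
        n = x.shape[0]
        x = x.reshape(n, -1)
        return ad.linear(x, self.w_out, self.b_out).reshape(n)


def generator_forward(gen: Generator, noise: np.ndarray) -> np.ndarray:
    """Run the generator on a (leads, length) or (N, leads, length) noise
    array; returns an array of the same shape."""
    z = np.asarray(noise, dtype=np.float64)
    single = z.ndim == 2
    if single:
        z = z[None]
    if z.shape[2] % (2 ** gen.cfg.g_down_blocks) and not gen.cfg.pad_to_multiple:
        raise InvalidParameterError(
            f"length {z.shape[2]} not divisible by "
            f"{2 ** gen.cfg.g_down_blocks}; enable pad_to_multiple"
        )
    with ad.using_dtype(gen.params[0].data.dtype):
        out = gen.forward(ad.Tensor(z)).data
    return out[0] if single else out


def discriminator_forward(disc: Discriminator, signal: np.ndarray,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Score one (leads, length) signal or a batch; higher = more real."""
    x = np.asarray(signal, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    with ad.using_dtype(disc.params[0].data.dtype):
        out = disc.forward(ad.Tensor(x), rng).data
    return float(out[0]) if single else out


def gan_loss(d_real_scores: np.ndarray, d_fake_scores: np.ndarray,
             generator_objective: str = "non_saturating") -> GANLossTerms:
    """Minimax losses from raw discriminator scores.

    Scores pass through a logistic transform; probabilities are clamped
    to [eps, 1-eps].  ``d_loss = -mean log D(x) - mean log(1 - D(G(z)))``;
    the generator term is ``-mean log D(G(z))`` (non-saturating, default)
    or ``+mean log(1 - D(G(z)))`` (the literal minimax term).
    """
    p_real = np.clip(_sigmoid(np.asarray(d_real_scores, float)), _EPS, 1 - _EPS)
    p_fake = np.clip(_sigmoid(np.asarray(d_fake_scores, float)), _EPS, 1 - _EPS)
    d_loss = float(-np.mean(np.log(p_real)) - np.mean(np.log(1 - p_fake)))
    if generator_objective == "non_saturating":
        g_loss = float(-np.mean(np.log(p_fake)))
    elif generator_objective == "saturating":
        g_loss = float(np.mean(np.log(1 - p_fake)))
    else:
        raise InvalidParameterError(
            f"unknown generator objective: {generator_objective!r}")
    return GANLossTerms(d_loss=d_loss, g_loss=g_loss)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _loss_tensors(scores: ad.Tensor, target_real: bool) -> ad.Tensor:
    """-mean log D (target_real) or -mean log(1-D), on the graph."""
    p = ad.clip(ad.sigmoid(scores), _EPS, 1 - _EPS)
    if target_real:
        return -(ad.log(p).mean())
    return -(ad.log(ad.Tensor(1.0) - p).mean())


def gan_train(real_segments: list[ECGSegment], cfg: GANConfig
              ) -> tuple[Generator, Discriminator, dict]:
    """Alternating D/G training on real segments.

    Returns the trained generator, discriminator and a history dict with
    per-epoch mean ``d_loss`` / ``g_loss`` (for loss-curve plots).  With
    ``epochs=0`` the initialized networks and empty history are
    returned.  Raises :class:`GANDivergenceError` (naming the epoch) if
    a loss becomes non-finite.
    """
    if not real_segments:
        raise InvalidParameterError("need at least one real segment")
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg, rng)
    disc = Discriminator(cfg, rng)
    opt_g = ad.Adam(gen.params, lr=cfg.learning_rate)
    opt_d = ad.Adam(disc.params, lr=cfg.learning_rate)
    data = np.stack([s.signals for s in real_segments]).astype(_dtype(cfg))
    history: dict[str, list[float]] = {"d_loss": [], "g_loss": []}

    with ad.using_dtype(_dtype(cfg)):
        _train_loop(cfg, gen, disc, opt_g, opt_d, data, rng, history)
    return gen, disc, history


def _train_loop(cfg, gen, disc, opt_g, opt_d, data, rng, history) -> None:
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        d_losses, g_losses = [], []
        for start in range(0, len(data), cfg.batch_size):
            batch = data[order[start:start + cfg.batch_size]]
            nb = len(batch)
            # --- discriminator step
            z = rng.standard_normal((nb,) + tuple(cfg.noise_shape))
            fake = gen.forward(ad.Tensor(z)).data  # constant for D
            sh_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
            s_real = disc.forward(ad.Tensor(batch), sh_rng)
            s_fake = disc.forward(ad.Tensor(fake), sh_rng)
            d_loss = _loss_tensors(s_real, True) + _loss_tensors(s_fake, False)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            # --- generator step
            z = rng.standard_normal((nb,) + tuple(cfg.noise_shape))
            fake_t = gen.forward(ad.Tensor(z))
            sh_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
            s_fake = disc.forward(fake_t, sh_rng)
            if cfg.generator_objective == "non_saturating":
                g_loss = _loss_tensors(s_fake, True)
            else:
                g_loss = -_loss_tensors(s_fake, False)
            opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()
            d_losses.append(d_loss.item())
            g_losses.append(g_loss.item())
        d_ep, g_ep = float(np.mean(d_losses)), float(np.mean(g_losses))
        if not (np.isfinite(d_ep) and np.isfinite(g_ep)):
            raise GANDivergenceError(
                f"non-finite loss at epoch {epoch}: d={d_ep}, g={g_ep}")
        history["d_loss"].append(d_ep)
        history["g_loss"].append(g_ep)


def gan_sample(gen: Generator, n: int, seed: int = 0,
               fs: float = 128.0) -> list[ECGSegment]:
    """Draw ``n`` synthetic PxAF-labeled segments from the generator."""
    rng = np.random.default_rng(seed)
    out: list[ECGSegment] = []
    for i in range(n):
        z = rng.standard_normal((1,) + tuple(gen.cfg.noise_shape))
        with ad.using_dtype(gen.params[0].data.dtype), ad.no_grad():
            sig = gen.forward(ad.Tensor(z)).data[0].astype(np.float64)
        out.append(ECGSegment(sig, fs=fs, label="pxaf",
                              source_record=f"gan-sample-{seed}-{i}"))
    return out


def save_checkpoint(gen: Generator, disc: Discriminator, path: str | Path,
                    history: dict | None = None) -> Path:
    """Serialize all parameters (and optional history) to an .npz file."""
    path = Path(path)
    arrays = {f"g{i}": p.data for i, p in enumerate(gen.params)}
    arrays.update({f"d{i}": p.data for i, p in enumerate(disc.params)})
    if history:
        arrays["hist_d"] = np.asarray(history["d_loss"])
        arrays["hist_g"] = np.asarray(history["g_loss"])
    np.savez(path, **arrays)
    return path


def load_checkpoint(gen: Generator, disc: Discriminator,
                    path: str | Path) -> None:
    data = np.load(Path(path))
    for i, p in enumerate(gen.params):
        p.data = data[f"g{i}"]
    for i, p in enumerate(disc.params):
        p.data = data[f"d{i}"]
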