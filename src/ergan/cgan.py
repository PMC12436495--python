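"""Conditional GAN for synthetic ERG waveforms.

Generator and discriminator share a BLSTM trunk: the full-size model uses a
bidirectional LSTM over the 235-sample axis with a 512-wide concatenated
output, a 1024-wide fully connected trunk with LeakyReLU activations and
dropout, and (for the generator) a 235-wide linear head with tanh output in
normalised amplitude units; the discriminator ends in 1024 -> 512 -> 1 with
a sigmoid.  Both networks receive the binary class label as a one-hot
vector, concatenated to every BLSTM input step and to the first trunk
layer, so that sampling can be steered to either group.

Training is the standard two-player game: the discriminator maximises
log D(x|y) + log(1 - D(G(z|y))), the generator minimises log(1 - D(G(z|y)))
(by default via the non-saturating -log D(G(z|y)) form, which has the same
fixed points).  ``scale_factor`` shrinks layer widths and epoch counts
proportionally for CPU-scale runs; the architecture is otherwise unchanged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .dataio import LabeledDataset, Normalization
from .grid import DEFAULT_GRID, TimeGrid
from .nn import autodiff as ad
from .nn.layers import BiLSTM, Dropout, Linear, Module
from .nn.optim import Adam


class LeakageError(RuntimeError):
    """Raised when GAN training is attempted on a non-train partition."""


@dataclass(frozen=True)
class GeneratorSpec:
    latent_dim: int = 100
    seq_len: int = 235
    per_step_features: int = 8  # latent projection width per timestep
    hidden_per_dir: int = 256  # BLSTM output width 512 when concatenated
    fc_width: int = 1024
    condition_dim: int = 2


@dataclass(frozen=True)
class DiscriminatorSpec:
    seq_len: int = 235
    hidden_per_dir: int = 256
    fc_width: int = 1024  # trunk 1024 -> 1024, 1024 -> 512, 512 -> 1
    condition_dim: int = 2


@dataclass(frozen=True)
class CGANTrainConfig:
    """Training hyperparameters; defaults follow the full-size recipe
    (batch 15, 10000 epochs, dropout 0.2, Adam lr 2e-4 for both networks)."""

    batch_size: int = 15
    epochs: int = 10000
    dropout: float = 0.2
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    scale_factor: float = 1.0  # multiplies layer widths and epochs
    non_saturating: bool = True
    eps: float = 1e-7  # score clamp inside the BCE losses
    require_normalized: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.scale_factor <= 1:
            raise ValueError("scale_factor must be in (0, 1]")

    @property
    def effective_epochs(self) -> int:
        return max(1, round(self.epochs * self.scale_factor))


def _scaled(width: int, factor: float) -> int:
    return max(4, round(width * factor))


class Generator(Module):
    def __init__(self, spec: GeneratorSpec, dropout: float, scale: float,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        h = _scaled(spec.hidden_per_dir, scale)
        w = _scaled(spec.fc_width, scale)
        p = spec.per_step_features
        c = spec.condition_dim
        self.seq_proj = Linear(spec.latent_dim + c, spec.seq_len * p, rng)
        self.blstm = BiLSTM(p + c, h, rng)
        # flattened BLSTM sequence output, projected into the FC trunk
        self.trunk_in = Linear(2 * h * spec.seq_len + c, w, rng)
        self.fc1 = Linear(w, w, rng)
        self.fc2 = Linear(w, w, rng)
        self.drop = Dropout(dropout, rng)
        self.head = Linear(w, spec.seq_len, rng)

    def __call__(self, z: np.ndarray, y_onehot: np.ndarray) -> ad.Tensor:
        B = z.shape[0]
        zc = ad.Tensor(np.concatenate([z, y_onehot], axis=1))
        seq = self.seq_proj(zc).reshape(B, self.spec.seq_len, self.spec.per_step_features)
        cond_seq = np.repeat(y_onehot[:, None, :], self.spec.seq_len, axis=1)
        seq = ad.concat([seq, ad.Tensor(cond_seq)], axis=-1)
        out = self.blstm(seq)  # (B, T, 2H)
        flat = out.reshape(B, out.shape[1] * out.shape[2])
        h = ad.concat([flat, ad.Tensor(y_onehot)], axis=-1)
        h = ad.leaky_relu(self.trunk_in(h))
        h = ad.leaky_relu(self.fc1(h))
        h = self.drop(ad.leaky_relu(self.fc2(h)))
        return ad.tanh(self.head(h))


class Discriminator(Module):
    def __init__(self, spec: DiscriminatorSpec, dropout: float, scale: float,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        h = _scaled(spec.hidden_per_dir, scale)
        w = _scaled(spec.fc_width, scale)
        w2 = _scaled(spec.fc_width // 2, scale)
        c = spec.condition_dim
        self.blstm = BiLSTM(1 + c, h, rng)
        self.trunk_in = Linear(2 * h * spec.seq_len + c, w, rng)
        self.fc1 = Linear(w, w, rng)
        self.fc2 = Linear(w, w2, rng)
        self.drop = Dropout(dropout, rng)
        self.head = Linear(w2, 1, rng)

    def __call__(self, x, y_onehot: np.ndarray) -> ad.Tensor:
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(x)
        B, T = x.shape
        seq = x.reshape(B, T, 1)
        cond_seq = np.repeat(y_onehot[:, None, :], T, axis=1)
        seq = ad.concat([seq, ad.Tensor(cond_seq)], axis=-1)
        out = self.blstm(seq)
        flat = out.reshape(B, out.shape[1] * out.shape[2])
        h = ad.concat([flat, ad.Tensor(y_onehot)], axis=-1)
        h = ad.leaky_relu(self.trunk_in(h))
        h = ad.leaky_relu(self.fc1(h))
        h = self.drop(ad.leaky_relu(self.fc2(h)))
        return ad.sigmoid(self.head(h))


# -- losses -------------------------------------------------------------------

def gan_losses(d_real, d_fake, eps: float = 1e-7, non_saturating: bool = True):
    """Scalar GAN losses from discriminator scores.

    d_loss = -[log d_real + log(1 - d_fake)], g_loss = -log d_fake (the
    non-saturating form of minimising log(1 - d_fake); set
    ``non_saturating=False`` for the literal form).  Scores are clamped to
    [eps, 1-eps]; array inputs are averaged.
    """
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    if np.any((d_real <= 0) | (d_real >= 1)) or np.any((d_fake <= 0) | (d_fake >= 1)):
        logging.getLogger(__name__).warning(
            "discriminator score at 0 or 1 clamped to eps=%g", eps
        )
    d_real = np.clip(d_real, eps, 1.0 - eps)
    d_fake = np.clip(d_fake, eps, 1.0 - eps)
    d_loss = float(np.mean(-(np.log(d_real) + np.log(1.0 - d_fake))))
    if non_saturating:
        g_loss = float(np.mean(-np.log(d_fake)))
    else:
        g_loss = float(np.mean(np.log(1.0 - d_fake)))
    return d_loss, g_loss


def _bce_real(score: ad.Tensor, eps: float) -> ad.Tensor:
    return -(ad.log(score + eps).mean())


def _bce_fake(score: ad.Tensor, eps: float) -> ad.Tensor:
    return -(ad.log(1.0 - score + eps).mean())


def _onehot(y: np.ndarray, k: int = 2) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), np.asarray(y, dtype=int)] = 1.0
    return out


@dataclass
class TrainedCGAN:
    generator: Generator
    discriminator: Discriminator
    gspec: GeneratorSpec
    dspec: DiscriminatorSpec
    config: CGANTrainConfig
    history: pd.DataFrame  # columns: step, d_loss, g_loss
    normalization: Normalization | None
    grid: TimeGrid = field(default_factory=TimeGrid)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "generator.npz", **self.generator.state_dict())
        np.savez(directory / "discriminator.npz", **self.discriminator.state_dict())
        cfg = {
            "gspec": asdict(self.gspec),
            "dspec": asdict(self.dspec),
            "config": asdict(self.config),
            "normalization": self.normalization.to_dict() if self.normalization else None,
            "grid": self.grid.to_dict(),
        }
        (directory / "config.json").write_text(json.dumps(cfg, indent=1))
        self.history.to_csv(directory / "history.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedCGAN":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        cfg["config"]["betas"] = tuple(cfg["config"]["betas"])
        gspec = GeneratorSpec(**cfg["gspec"])
        dspec = DiscriminatorSpec(**cfg["dspec"])
        config = CGANTrainConfig(**cfg["config"])
        rng = np.random.default_rng(0)
        gen = Generator(gspec, config.dropout, config.scale_factor, rng)
        disc = Discriminator(dspec, config.dropout, config.scale_factor, rng)
        gen.load_state_dict(dict(np.load(directory / "generator.npz")))
        disc.load_state_dict(dict(np.load(directory / "discriminator.npz")))
        norm = cfg["normalization"]
        return cls(
            generator=gen,
            discriminator=disc,
            gspec=gspec,
            dspec=dspec,
            config=config,
            history=pd.read_csv(directory / "history.csv"),
            normalization=Normalization(**norm) if norm else None,
            grid=TimeGrid.from_dict(cfg["grid"]),
        )


def train_cgan(
    train: LabeledDataset,
    cfg: CGANTrainConfig = CGANTrainConfig(),
    gspec: GeneratorSpec | None = None,
    dspec: DiscriminatorSpec | None = None,
) -> TrainedCGAN:
    """Adversarially train the conditional generator on a train partition.

    ``train`` must be tagged as the train side of a hold-out split
    (:class:`LeakageError` otherwise) and normalised unless the config says
    otherwise.  Per batch the discriminator is updated on real and fake
    scores, then the generator on refreshed fake scores.  Deterministic for
    a fixed seed.
    """
    if train.partition != "train":
        raise LeakageError(
            "train_cgan accepts only the train member of a hold-out split "
            f"(partition tag is {train.partition!r})"
        )
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    if cfg.require_normalized and train.normalization is None:
        raise ValueError("training data must be normalised before GAN training")

    gspec = gspec or GeneratorSpec(seq_len=train.grid.n_samples)
    dspec = dspec or DiscriminatorSpec(seq_len=train.grid.n_samples)
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(gspec, cfg.dropout, cfg.scale_factor, rng)
    disc = Discriminator(dspec, cfg.dropout, cfg.scale_factor, rng)
    opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, betas=cfg.betas)

    X, y = train.X, train.y
    n = len(train)
    history = []
    step = 0
    for _ in range(cfg.effective_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], _onehot(y[idx])
            z = rng.standard_normal((len(idx), gspec.latent_dim))

            # discriminator step
            fake = gen(z, yb)
            d_real = disc(xb, yb)
            d_fake = disc(fake.detach(), yb)
            d_loss = _bce_real(d_real, cfg.eps) + _bce_fake(d_fake, cfg.eps)
            disc.zero_grad()
            d_loss.backward()
            opt_d.step()

            # generator step against the updated discriminator
            d_fake2 = disc(fake, yb)
            if cfg.non_saturating:
                g_loss = _bce_real(d_fake2, cfg.eps)
            else:
                g_loss = ad.log(1.0 - d_fake2 + cfg.eps).mean()
            gen.zero_grad()
            disc.zero_grad()
            g_loss.backward()
            opt_g.step()

            dl, gl = float(d_loss.data), float(g_loss.data)
            if not (math.isfinite(dl) and math.isfinite(gl)):
                raise RuntimeError(f"non-finite GAN loss at step {step}")
            history.append((step, dl, gl))
            step += 1

    return TrainedCGAN(
        generator=gen,
        discriminator=disc,
        gspec=gspec,
        dspec=dspec,
        config=cfg,
        history=pd.DataFrame(history, columns=["step", "d_loss", "g_loss"]),
        normalization=train.normalization,
        grid=train.grid,
    )


def sample_synthetic(
    model: TrainedCGAN,
    y: int,
    n: int,
    seed: int = 0,
    filter_hz: float | None = 300.0,
) -> LabeledDataset:
    """Draw ``n`` class-``y`` waveforms from the trained generator.

    Outputs are mapped back to data units with the normalisation stored at
    training time and low-pass filtered (300 Hz Butterworth by default;
    ``filter_hz=None`` disables).  Records are flagged as synthetic; flash
    strength is undefined (NaN) because conditioning is on class only.
    """
    if y not in (0, 1):
        raise ValueError(f"class label must be 0 or 1, got {y}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    model.generator.eval()
    if n == 0:
        X = np.zeros((0, model.grid.n_samples))
    else:
        z = rng.standard_normal((n, model.gspec.latent_dim))
        X = model.generator(z, _onehot(np.full(n, y))).data
        if model.normalization is not None:
            X = model.normalization.invert(X)
        if filter_hz is not None:
            X = lowpass_butterworth(X, cutoff_hz=filter_hz, grid=model.grid)
    model.generator.train()
    meta = pd.DataFrame(
        {
            "id": [f"synth-{y}-{seed}-{i:05d}" for i in range(n)],
            "subject": "synthetic",
            "eye": "-",
            "group": y,
            "strength": np.nan,
            "replicate": 1,
            "synthetic": True,
        },
        columns=["id", "subject", "eye", "group", "strength", "replicate", "synthetic"],
    )
    return LabeledDataset(X=X, meta=meta, grid=model.grid)


def augment(
    train: LabeledDataset,
    model: TrainedCGAN,
    ratio_real_to_synth: float = 2.0,
    seed: int = 0,
    filter_hz: float | None = 300.0,
) -> LabeledDataset:
    """Append class-conditional synthetic records at a real:synthetic ratio.

    Per class, round(n_real / ratio) synthetic records are generated, so the
    additions are proportional to the per-class real counts (default 2:1 as
    in the augmentation protocol).
    """
    if not (math.isfinite(ratio_real_to_synth) and ratio_real_to_synth > 0):
        raise ValueError(f"ratio must be finite and positive, got {ratio_real_to_synth}")
    out = train
    real = train.meta["synthetic"].to_numpy()
    for cls in (0, 1):
        n_real = int(np.sum((train.y == cls) & ~real))
        n_synth = round(n_real / ratio_real_to_synth)
        if n_synth == 0:
            continue
        synth = sample_synthetic(model, cls, n_synth, seed=seed + cls, filter_hz=filter_hz)
        if train.normalization is not None:
            synth_X = train.normalization.apply(synth.X)
            synth = LabeledDataset(
                X=synth_X, meta=synth.meta, grid=synth.grid,
                normalization=train.normalization,
            )
        synth.partition = train.partition
        out = out.concat(synth)
    return out


def lowpass_butterworth(
    x: np.ndarray,
    cutoff_hz: float = 300.0,
    order: int = 4,
    grid: TimeGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the time axis (DC gain 1)."""
    if cutoff_hz <= 0 or cutoff_hz >= grid.nyquist:
        raise ValueError(
            f"cutoff must lie in (0, {grid.nyquist:.1f}) Hz, got {cutoff_hz}"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=grid.fs)
    return filtfilt(b, a, np.asarray(x, dtype=np.float64), axis=-1)
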