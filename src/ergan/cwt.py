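"""Continuous wavelet transform front-end for scalogram images.

The transform is the direct discretisation of

    X_w(a, b) = |a|^{-1/2} * sum_n x[n] * conj(psi)((n - b) / a)

with translation b on the sample grid and scale a in sample units, so the
scale-to-frequency conversion f = fc / (a * dt) uses the physical sampling
period dt of the waveform grid.  Three mother wavelets (Ricker, first
derivative of Gaussian, complex Morlet) give the three channels of the
scalogram image fed to the image classifier.

Per scale the evaluation uses the Toeplitz structure of the kernel matrix:
psi is sampled once on the 2N-1 possible lags and assembled with
``scipy.linalg.toeplitz``, which makes the transform exactly equal to the
naive double sum at vastly lower cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import toeplitz
from skimage.transform import resize

from .grid import DEFAULT_GRID, TimeGrid

MORLET_OMEGA0 = 5.0


def _ricker(t: np.ndarray) -> np.ndarray:
    return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * (1.0 - t**2) * np.exp(-0.5 * t**2)


def _gaus1(t: np.ndarray) -> np.ndarray:
    # first derivative of a Gaussian, unit L2 norm
    return -2.0 * t * np.exp(-(t**2)) * (2.0 / np.pi) ** 0.25


def _morlet(t: np.ndarray) -> np.ndarray:
    # complex Morlet, omega0 = 5 (admissible to ~1e-5)
    return np.pi**-0.25 * np.exp(1j * MORLET_OMEGA0 * t) * np.exp(-0.5 * t**2)


@dataclass(frozen=True)
class MotherWavelet:
    """A mother wavelet with its analytic spectral-peak frequency.

    ``fc`` is in cycles per unit of the wavelet argument (cycles/sample once
    the transform is taken on the sample grid); it is the location of the
    peak of |FT(psi)| computed analytically for each family.
    """

    name: str
    fc: float
    evaluate: Callable[[np.ndarray], np.ndarray]
    support_radius: float = 8.0

    def admissibility_defect(self, n: int = 4096) -> float:
        """|integral of psi| on a dense grid; ~0 for an admissible wavelet."""
        t = np.linspace(-self.support_radius, self.support_radius, n)
        return float(abs(np.trapezoid(self.evaluate(t), t)))


RICKER = MotherWavelet("ricker", np.sqrt(2.0) / (2.0 * np.pi), _ricker)
GAUSSIAN1 = MotherWavelet("gaussian", np.sqrt(2.0) / (2.0 * np.pi) / np.sqrt(2.0), _gaus1)
MORLET = MotherWavelet("morlet", MORLET_OMEGA0 / (2.0 * np.pi), _morlet)

DEFAULT_MOTHERS = (RICKER, GAUSSIAN1, MORLET)
DEFAULT_SCALES = np.arange(1, 129, dtype=float)

_kernel_cache: dict[tuple, np.ndarray] = {}


def _scale_kernel(mother: MotherWavelet, scale: float, n: int) -> np.ndarray:
    """Kernel K[b, t] = conj(psi)((t - b)/a) as an n x n Toeplitz matrix."""
    key = (mother.name, float(scale), n)
    if key not in _kernel_cache:
        lags = np.arange(-(n - 1), n, dtype=float) / scale
        v = np.conj(mother.evaluate(lags))
        col = v[n - 1 :: -1]  # K[b, 0] = psi(-b/a)
        row = v[n - 1 :]  # K[0, t] = psi(t/a)
        _kernel_cache[key] = toeplitz(col, row)
    return _kernel_cache[key]


def cwt_transform(
    x: np.ndarray, mother: MotherWavelet, scales=DEFAULT_SCALES
) -> np.ndarray:
    """CWT coefficients of one or more waveforms.

    ``x`` is (n_samples,) or (n_records, n_samples); the result is
    (n_scales, n_samples) or (n_records, n_scales, n_samples).  Coefficients
    are complex for the Morlet channel and real otherwise; the transform is
    linear in ``x`` by construction.
    """
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    if np.any(scales <= 0):
        raise ValueError("scales must be strictly positive")
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    xb = np.atleast_2d(x)  # (R, N)
    n = xb.shape[1]
    dtype = complex if np.iscomplexobj(mother.evaluate(np.zeros(1))) else float
    out = np.empty((xb.shape[0], len(scales), n), dtype=dtype)
    for i, a in enumerate(scales):
        k = _scale_kernel(mother, a, n)
        out[:, i, :] = (xb @ k.T) * (abs(a) ** -0.5)
    return out[0] if single else out


def scale_to_frequency(a, fc: float, dt: float):
    """Map wavelet scale to frequency in Hz: f = fc / (a * dt[s])."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0) or dt <= 0:
        raise ValueError("scale and sampling period must be positive")
    return fc / (a * dt)


@dataclass
class Scalogram:
    """Three-channel time-frequency image of one waveform."""

    coefficients: np.ndarray  # (3, n_scales, n_samples) magnitudes
    image: np.ndarray  # (3, side, side) in [0, 1]
    scales: np.ndarray
    channel_names: tuple[str, ...]


def _to_unit_range(c: np.ndarray) -> np.ndarray:
    lo, hi = c.min(), c.max()
    if hi == lo:
        return np.zeros_like(c)
    return (c - lo) / (hi - lo)


def scalogram_image(
    x: np.ndarray,
    mothers=DEFAULT_MOTHERS,
    scales=DEFAULT_SCALES,
    side: int = 224,
) -> Scalogram:
    """Scalogram image of one waveform.

    Channel order follows ``mothers`` (default: Ricker, Gaussian, Morlet).
    Each channel is the coefficient magnitude at the given scales,
    independently min-max scaled to [0, 1], then bilinearly resampled to
    ``side x side``.
    """
    if len(mothers) != 3:
        raise ValueError(f"exactly three mother wavelets required, got {len(mothers)}")
    mags = np.stack([np.abs(cwt_transform(x, m, scales)) for m in mothers])
    img = np.stack(
        [
            resize(
                _to_unit_range(c),
                (side, side),
                order=1,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            )
            for c in mags
        ]
    )
    return Scalogram(
        coefficients=mags,
        image=img,
        scales=np.atleast_1d(np.asarray(scales, dtype=float)),
        channel_names=tuple(m.name for m in mothers),
    )


def scalogram_batch(
    X: np.ndarray, mothers=DEFAULT_MOTHERS, scales=DEFAULT_SCALES, side: int = 224
) -> np.ndarray:
    """Scalogram images for a waveform block; returns (n, 3, side, side)."""
    if len(mothers) != 3:
        raise ValueError(f"exactly three mother wavelets required, got {len(mothers)}")
    mags = [np.abs(cwt_transform(X, m, scales)) for m in mothers]  # 3 x (n, S, N)
    n = X.shape[0]
    out = np.empty((n, 3, side, side))
    for i in range(n):
        for ch in range(3):
            out[i, ch] = resize(
                _to_unit_range(mags[ch][i]),
                (side, side),
                order=1,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            )
    return out


def default_sampling_period(grid: TimeGrid = DEFAULT_GRID) -> float:
    """Sampling period (s) used in the scale-to-frequency map."""
    return grid.dt_seconds
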