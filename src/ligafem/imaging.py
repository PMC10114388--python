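"""Two-channel pixel-ratio elastin-content estimation.

Multiphoton imaging of ligament shows collagen by second-harmonic
generation (SHG, conventionally pseudocoloured blue) and elastin by
autofluorescence (green).  The content estimate is the ratio of elastin
pixels to the total of collagen + elastin pixels after binarizing each
channel at a fixed intensity threshold; a pixel positive in both channels
is assigned to the brighter one (ties go to collagen).

A synthetic generator produces co-registered two-channel images with a
configurable true elastin pixel fraction, fibre-like smoothed-noise
morphology, and additive Gaussian noise, so the estimator can be validated
without microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ImageError

__all__ = [
    "ChannelImage",
    "estimate_content",
    "generate_synthetic_channels",
    "read_channels_tiff",
]


@dataclass
class ChannelImage:
    """Co-registered collagen (SHG) and elastin (autofluorescence) channels."""

    collagen_channel: np.ndarray
    elastin_channel: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.collagen_channel, dtype=float)
        e = np.asarray(self.elastin_channel, dtype=float)
        if c.ndim != 2 or c.shape != e.shape:
            raise ImageError(
                f"channels must be 2-D arrays of equal shape, got {c.shape} "
                f"and {e.shape}"
            )
        if not (np.isfinite(c).all() and np.isfinite(e).all()):
            raise ImageError("channel intensities must be finite")
        if (c < 0).any() or (e < 0).any():
            raise ImageError("channel intensities must be nonnegative")
        self.collagen_channel = c
        self.elastin_channel = e


def estimate_content(
    img: ChannelImage,
    threshold_collagen: float = 0.0,
    threshold_elastin: float = 0.0,
) -> float:
    """Elastin pixel fraction green / (green + blue) after binarization.

    Pixels above threshold in both channels are assigned to the brighter
    channel; exact intensity ties count as collagen.
    """
    if threshold_collagen < 0 or threshold_elastin < 0:
        raise ImageError("thresholds must be nonnegative")
    blue = img.collagen_channel > threshold_collagen
    green = img.elastin_channel > threshold_elastin
    both = blue & green
    greener = img.elastin_channel > img.collagen_channel  # tie -> collagen
    n_green = int(np.count_nonzero((green & ~both) | (both & greener)))
    n_blue = int(np.count_nonzero((blue & ~both) | (both & ~greener)))
    if n_green + n_blue == 0:
        raise ImageError("no pixel exceeds either threshold; content undefined")
    return n_green / (n_green + n_blue)


def generate_synthetic_channels(
    shape: tuple[int, int] = (512, 512),
    true_fraction: float = 0.164,
    blob_scale: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    foreground_fraction: float = 0.3,
    signal: float = 200.0,
) -> ChannelImage:
    """Synthetic co-registered SHG + autofluorescence channel pair.

    A smoothed random field defines a fibrous foreground covering
    ``foreground_fraction`` of the image; foreground pixels are partitioned
    into elastin and collagen by a second smoothed field so that the elastin
    share equals ``true_fraction`` to within one pixel.  Each pixel emits
    intensity ``signal`` in its own channel only; Gaussian noise of standard
    deviation ``noise_sd`` is then added to both channels and clipped at
    zero.  Deterministic for a fixed seed.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ImageError(f"true_fraction must lie in [0, 1], got {true_fraction}")
    if not 0.0 < foreground_fraction <= 1.0:
        raise ImageError("foreground_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), blob_scale)
    cut = np.quantile(field, 1.0 - foreground_fraction)
    fg = field > cut
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise ImageError("foreground is empty at this shape/fraction")
    n_elastin = int(round(true_fraction * n_fg))
    if n_elastin > n_fg:
        raise ImageError("requested elastin fraction impossible at this shape")

    # spatially coherent partition: elastin = top-k of a second smoothed field
    part = ndimage.gaussian_filter(rng.standard_normal(shape), blob_scale / 2.0)
    order = np.argsort(part[fg], kind="stable")[::-1]
    fg_idx = np.nonzero(fg.ravel())[0]
    elastin_mask = np.zeros(fg.size, dtype=bool)
    elastin_mask[fg_idx[order[:n_elastin]]] = True
    elastin_mask = elastin_mask.reshape(shape)
    collagen_mask = fg & ~elastin_mask

    collagen = signal * collagen_mask.astype(float)
    elastin = signal * elastin_mask.astype(float)
    if noise_sd > 0:
        collagen = collagen + rng.normal(0.0, noise_sd, shape)
        elastin = elastin + rng.normal(0.0, noise_sd, shape)
    return ChannelImage(np.clip(collagen, 0.0, None), np.clip(elastin, 0.0, None))


def read_channels_tiff(
    path: str | Path, elastin_path: str | Path | None = None
) -> ChannelImage:
    """Read a two-channel TIFF (collagen first) or two single-channel TIFFs."""
    import tifffile

    a = tifffile.imread(str(path))
    if elastin_path is not None:
        b = tifffile.imread(str(elastin_path))
        return ChannelImage(np.asarray(a), np.asarray(b))
    a = np.asarray(a)
    if a.ndim != 3:
        raise ImageError(
            "expected a two-channel TIFF (CYX or YXC) or two single-channel files"
        )
    if a.shape[0] == 2:
        return ChannelImage(a[0], a[1])
    if a.shape[-1] == 2:
        return ChannelImage(a[..., 0], a[..., 1])
    raise ImageError(f"cannot interpret TIFF of shape {a.shape} as two channels")
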