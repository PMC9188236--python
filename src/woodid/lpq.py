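"""Local Phase Quantization (LPQ) texture descriptor.

LPQ characterises local texture through the phase of the short-term Fourier
transform (STFT) computed over a sliding M x M window.  At each pixel the
STFT is evaluated at four low frequencies

    u1 = (a, 0),  u2 = (0, a),  u3 = (a, a),  u4 = (a, -a),      a = 1/M,

giving four complex coefficients.  The signs of their real and imaginary
parts are quantized into an 8-bit code (0..255); the descriptor of an image
is the normalised 256-bin histogram of these codes.  Phase is invariant to
centrally symmetric blur and to positive affine intensity changes, which is
what makes the descriptor suitable for micrographs digitised under varying
conditions.

Only pixels whose full window fits inside the image are coded (valid-region
convolution), so the code image of an H x W input is (H-M+1) x (W-M+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

# magnitudes below this fraction of the coefficient scale are treated as
# exact zeros before sign quantization, so that analytically-zero
# coefficients (e.g. on constant patches) quantize as +0 regardless of
# floating-point summation order
_ZERO_SNAP = 1e-9


@dataclass(frozen=True)
class LPQConfig:
    """Descriptor parameters.

    window_size
        Side M of the local window (odd, >= 3).  Default 7.
    frequency
        Scalar frequency a of the four STFT samples; ``None`` means 1/M,
        which places the samples one DFT bin away from DC and makes the
        descriptor exactly invariant to additive intensity offsets.
    decorrelate
        Whiten the 8-vector of coefficient parts before quantization using
        the covariance implied by a first-order Markov image model with
        correlation ``decorrelation_rho`` between adjacent pixels.
    """

    window_size: int = 7
    frequency: float | None = None
    decorrelate: bool = False
    decorrelation_rho: float = 0.9

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd integer >= 3")
        if self.frequency is not None and not (0.0 < self.frequency <= 0.5):
            raise ValueError("frequency must lie in (0, 0.5]")

    @property
    def a(self) -> float:
        return 1.0 / self.window_size if self.frequency is None else self.frequency


def _corr1d(x: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Valid-region correlation along one axis (direct summation)."""
    win = sliding_window_view(x, len(kernel), axis=axis)
    return np.tensordot(win, kernel, axes=([-1], [0]))


def _stft_coefficients(img: np.ndarray, M: int, a: float) -> np.ndarray:
    """The 8 real coefficient planes [Re F1..F4, Im F1..F4], valid region."""
    d = np.arange(-(M // 2), M // 2 + 1)
    w0 = np.ones(M, dtype=complex)
    wa = np.exp(-2j * np.pi * a * d)
    # frequency component along rows first, then columns
    rows_a = _corr1d(img.astype(np.float64), wa, axis=0)
    rows_0 = _corr1d(img.astype(np.float64), w0, axis=0)
    f1 = _corr1d(rows_a, w0, axis=1)            # (a, 0)
    f2 = _corr1d(rows_0, wa, axis=1)            # (0, a)
    f3 = _corr1d(rows_a, wa, axis=1)            # (a, a)
    f4 = _corr1d(rows_a, np.conj(wa), axis=1)   # (a, -a)
    coeffs = np.stack(
        [f1.real, f2.real, f3.real, f4.real, f1.imag, f2.imag, f3.imag, f4.imag]
    )
    scale = max(1.0, float(np.abs(img).max())) * M * M
    coeffs[np.abs(coeffs) < _ZERO_SNAP * scale] = 0.0
    return coeffs


def _whitening_transform(M: int, a: float, rho: float) -> np.ndarray:
    """Decorrelating rotation for the 8 coefficient parts.

    Assumes pixel covariance sigma_ij = rho^{||x_i - x_j||} over the window
    positions; the covariance of the coefficient vector is W Sigma W^T with W
    the 8 x M^2 real STFT matrix, and the transform is V^T from its SVD.
    """
    d = np.arange(-(M // 2), M // 2 + 1)
    yy, xx = np.meshgrid(d, d, indexing="ij")
    pos = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    sigma = rho ** dist
    freqs = np.array([[a, 0.0], [0.0, a], [a, a], [a, -a]])
    basis = np.exp(-2j * np.pi * (freqs @ pos.T))  # 4 x M^2
    W = np.vstack([basis.real, basis.imag])        # 8 x M^2
    cov = W @ sigma @ W.T
    _, _, vt = np.linalg.svd(cov)
    return vt


def lpq_code_image(img: np.ndarray, cfg: LPQConfig | None = None) -> np.ndarray:
    """Per-pixel 8-bit LPQ codes over the valid region.

    Bit j (j = 0 least significant .. 7) is 1 iff coefficient part j is
    >= 0, parts ordered [Re F1..F4, Im F1..F4].  A constant image therefore
    codes to 255 everywhere (all coefficients are exactly zero).
    """
    cfg = cfg or LPQConfig()
    img = np.asarray(img, dtype=np.float64)
    M = cfg.window_size
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.shape[0] < M or img.shape[1] < M:
        raise ValueError(
            f"image {img.shape} smaller than the {M}x{M} analysis window"
        )
    g = _stft_coefficients(img, M, cfg.a)
    if cfg.decorrelate:
        vt = _whitening_transform(M, cfg.a, cfg.decorrelation_rho)
        g = np.tensordot(vt, g, axes=([1], [0]))
    bits = (g >= 0.0).astype(np.uint16)
    weights = (1 << np.arange(8, dtype=np.uint16)).reshape(8, 1, 1)
    return (bits * weights).sum(axis=0).astype(np.uint8)


def lpq_descriptor(img: np.ndarray, cfg: LPQConfig | None = None) -> np.ndarray:
    """256-bin normalised histogram of LPQ codes (the image's feature vector)."""
    codes = lpq_code_image(img, cfg)
    hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    return hist / hist.sum()


def descriptor_table(index, cfg: LPQConfig | None = None, *, loader=None) -> pd.DataFrame:
    """LPQ features for every record of a dataset index.

    Returns a DataFrame with metadata columns (image_id, species, genus,
    family, tree_id, view, specimen_id, piece_index) and feature columns
    f0..f255.  ``loader`` maps an ImageRecord to a grayscale array; the
    default reads the image from disk and converts to grayscale.
    """
    from .augment import to_grayscale  # local import to avoid a cycle
    import imageio.v3 as iio

    if loader is None:
        def loader(rec):
            return to_grayscale(iio.imread(index.root / rec.path))

    rows = []
    feats = []
    for rec in index.records:
        genus, family = index.taxonomy.entries[rec.species]
        rows.append(
            dict(
                image_id=rec.image_id, species=rec.species, genus=genus,
                family=family, tree_id=rec.tree_id, view=rec.view,
                specimen_id=rec.specimen_id, piece_index=rec.piece_index,
            )
        )
        feats.append(lpq_descriptor(loader(rec), cfg))
    meta = pd.DataFrame(rows)
    fmat = pd.DataFrame(np.array(feats), columns=[f"f{i}" for i in range(256)])
    return pd.concat([meta, fmat], axis=1)


FEATURE_COLUMNS = [f"f{i}" for i in range(256)]

__all__ = [
    "LPQConfig", "lpq_code_image", "lpq_descriptor", "descriptor_table",
    "FEATURE_COLUMNS",
]
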