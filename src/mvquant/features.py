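"""Multi-scale per-pixel feature stack.

Each pixel of a grayscale image is described by its raw intensity plus local
context at several Gaussian scales — the canonical trainable-segmentation
feature set. For scales ``sigmas = (s1 < s2 < ...)`` the stack contains, in
this fixed order:

* raw intensity,
* Gaussian-smoothed intensity at each sigma,
* Gaussian gradient magnitude at each sigma,
* difference of Gaussians for each consecutive sigma pair,
* min / max / mean / variance over a ``(2*ceil(s) + 1)`` square window at
  each sigma.

Borders use reflect padding. The small scales respond to capillary-sized
blobs (a few pixels); the large scales distinguish isolated microvessels
from perimysial agglomerates, which stay dark under heavy smoothing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, ParameterError
from .image_io import GrayImage

__all__ = ["MultiscaleFeatureExtractor", "DEFAULT_SIGMAS"]

DEFAULT_SIGMAS = (1.0, 2.0, 4.0, 8.0)

# scipy 'reflect' pads (d c b a | a b c d): symmetric half-sample reflection.
_BORDER = "reflect"


class MultiscaleFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping a grayscale image to a feature raster.

    Parameters
    ----------
    sigmas : sequence of float, default (1, 2, 4, 8)
        Gaussian scales in pixels; must be non-empty, strictly increasing
        and positive. The feature order derived from them is identical at
        train and predict time.

    Notes
    -----
    The transform is deterministic: the same image and configuration produce
    bit-identical output.
    """

    def __init__(self, sigmas: tuple[float, ...] = DEFAULT_SIGMAS):
        self.sigmas = tuple(float(s) for s in sigmas)

    def _validate(self) -> None:
        s = self.sigmas
        if len(s) == 0:
            raise ParameterError("sigmas must be non-empty")
        if any(x <= 0 for x in s):
            raise ParameterError(f"sigmas must be positive, got {s}")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ParameterError(f"sigmas must be strictly increasing, got {s}")

    @staticmethod
    def window_size(sigma: float) -> int:
        return 2 * math.ceil(sigma) + 1

    @property
    def max_window(self) -> int:
        self._validate()
        return self.window_size(self.sigmas[-1])

    @property
    def feature_names(self) -> list[str]:
        self._validate()

        def fmt(s: float) -> str:
            return f"{s:g}"

        names = ["raw"]
        names += [f"gauss_s{fmt(s)}" for s in self.sigmas]
        names += [f"grad_s{fmt(s)}" for s in self.sigmas]
        names += [f"dog_s{fmt(a)}_s{fmt(b)}" for a, b in zip(self.sigmas, self.sigmas[1:])]
        for s in self.sigmas:
            w = self.window_size(s)
            names += [f"min_w{w}", f"max_w{w}", f"mean_w{w}", f"var_w{w}"]
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def fit(self, X=None, y=None) -> "MultiscaleFeatureExtractor":
        self._validate()
        return self

    def transform(self, img: GrayImage | np.ndarray) -> np.ndarray:
        """Compute the feature stack for one image.

        Parameters
        ----------
        img : GrayImage or (H, W) array.

        Returns
        -------
        (H, W, n_features) float64 raster.

        Raises
        ------
        DegenerateInputError
            If either image dimension is smaller than the largest feature
            window ``2*ceil(max(sigmas)) + 1``.
        """
        self._validate()
        pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
        if pixels.ndim != 2:
            raise ParameterError("expected a 2-D grayscale raster")
        h, w = pixels.shape
        win = self.max_window
        if h < win or w < win:
            raise DegenerateInputError(
                f"image {w}x{h} is smaller than the largest feature window "
                f"({win}px at sigma {self.sigmas[-1]:g}); use smaller sigmas"
            )
        x = pixels.astype(np.float64)
        planes: list[np.ndarray] = [x]
        gaussians = [ndimage.gaussian_filter(x, s, mode=_BORDER) for s in self.sigmas]
        planes += gaussians
        planes += [
            ndimage.gaussian_gradient_magnitude(x, s, mode=_BORDER) for s in self.sigmas
        ]
        planes += [g2 - g1 for g1, g2 in zip(gaussians, gaussians[1:])]
        for s in self.sigmas:
            size = self.window_size(s)
            mean = ndimage.uniform_filter(x, size, mode=_BORDER)
            mean_sq = ndimage.uniform_filter(x * x, size, mode=_BORDER)
            planes += [
                ndimage.minimum_filter(x, size, mode=_BORDER),
                ndimage.maximum_filter(x, size, mode=_BORDER),
                mean,
                np.maximum(mean_sq - mean * mean, 0.0),  # guard fp cancellation
            ]
        return np.stack(planes, axis=-1)

    def transform_flat(self, img: GrayImage | np.ndarray) -> np.ndarray:
        """Feature stack reshaped to (H*W, n_features), row-major."""
        stack = self.transform(img)
        return stack.reshape(-1, stack.shape[-1])
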