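"""Phasor-domain conditioning: spatial binning, median filtering, masking.

The unmixing step is preceded by the same conditioning the analysis
pipeline applies to clinical data: neighbouring pixels are binned to
raise per-pixel photon counts without discarding information, a 3x3
median filter is applied to the phasor coordinates (never to the
intensity image), low-photon pixels are thresholded out, and large
keratin-rich features (hairs, folds) can be excluded so they do not
dominate distribution statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phasor import PhasorField
from .synthetic import DecayStack

logger = logging.getLogger(__name__)

DEFAULT_BIN_FACTOR = 4
DEFAULT_MIN_PHOTONS = 30
DEFAULT_KERATIN_THRESHOLD = 0.5
DEFAULT_KERATIN_MIN_AREA = 200


@dataclass(frozen=True)
class PixelMask:
    """Boolean per-pixel inclusion map with a provenance note."""

    include: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", np.asarray(self.include, dtype=bool))
        self.include.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.include.shape

    def __and__(self, other: "PixelMask") -> "PixelMask":
        if self.shape != other.shape:
            raise ValueError("mask shapes differ")
        return PixelMask(
            self.include & other.include,
            provenance=f"({self.provenance}) AND ({other.provenance})",
        )

    def __invert__(self) -> "PixelMask":
        return PixelMask(~self.include, provenance=f"NOT ({self.provenance})")


def _crop_to_factor(arr: np.ndarray, factor: int, what: str) -> np.ndarray:
    h, w = arr.shape[:2]
    nh, nw = (h // factor) * factor, (w // factor) * factor
    if (nh, nw) != (h, w):
        logger.warning(
            "%s of shape %dx%d not divisible by %d; dropping trailing %d row(s) "
            "and %d column(s)",
            what, h, w, factor, h - nh, w - nw,
        )
    return arr[:nh, :nw]


def bin_spatial(obj: "DecayStack | PhasorField", factor: int):
    """Sum non-overlapping factor x factor pixel blocks.

    For a :class:`DecayStack`, block counts are summed per time bin, so
    photons over the retained region are conserved exactly.  For a
    :class:`PhasorField`, the underlying Fourier numerators are summed —
    i.e. (g, s) are combined as photon-weighted means, never unweighted
    averages — and intensity is summed; this commutes with the phasor
    transform.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return obj
    if isinstance(obj, DecayStack):
        counts = _crop_to_factor(obj.counts, factor, "stack")
        h, w, nb = counts.shape
        binned = counts.reshape(h // factor, factor, w // factor, factor, nb).sum(
            axis=(1, 3)
        )
        return replace(obj, counts=binned)
    if isinstance(obj, PhasorField):
        intensity = _crop_to_factor(
            np.asarray(obj.intensity, dtype=float), factor, "field"
        )
        h, w = intensity.shape
        blocks = (h // factor, factor, w // factor, factor)
        wsum = intensity.reshape(blocks).sum(axis=(1, 3))
        g: dict[int, np.ndarray] = {}
        s: dict[int, np.ndarray] = {}
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.where(wsum != 0, wsum, np.nan)
            for n in obj.harmonics:
                for coord, out in ((obj.g[n], g), (obj.s[n], s)):
                    num = _crop_to_factor(coord, factor, "field") * intensity
                    # zero-photon pixels carry NaN coords but zero weight
                    num = np.where(intensity > 0, num, 0.0)
                    out[n] = num.reshape(blocks).sum(axis=(1, 3)) / denom
        out_intensity = _crop_to_factor(obj.intensity, factor, "field").reshape(
            blocks
        ).sum(axis=(1, 3))
        return PhasorField(
            g=g,
            s=s,
            intensity=out_intensity,
            harmonics=obj.harmonics,
            acquisition=obj.acquisition,
            calibrated=obj.calibrated,
        )
    raise TypeError(f"cannot bin object of type {type(obj).__name__}")


def _nanmedian3(a: np.ndarray, kernel: int) -> np.ndarray:
    """Median filter ignoring NaNs, reflect edges, vectorized via shifts."""
    r = kernel // 2
    padded = np.pad(a, r, mode="symmetric")  # edge-repeating reflection
    windows = np.stack(
        [
            padded[i : i + a.shape[0], j : j + a.shape[1]]
            for i in range(kernel)
            for j in range(kernel)
        ],
        axis=-1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(windows, axis=-1)


def median_filter_phasor(
    field: PhasorField, kernel: int = 3, passes: int = 1
) -> PhasorField:
    """Median-filter the phasor coordinates; intensity is untouched.

    Each g/s channel at every harmonic is filtered independently with a
    ``kernel x kernel`` window (reflected edges, undefined pixels excluded
    from windows).  The spatial intensity image is returned bit-identical,
    mirroring the pipeline's phasor-domain-only smoothing.
    """
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("kernel must be odd and >= 1")
    if not field.calibrated:
        raise ValueError("median filter operates on the calibrated field")
    g = {n: np.array(field.g[n], dtype=float) for n in field.harmonics}
    s = {n: np.array(field.s[n], dtype=float) for n in field.harmonics}
    for _ in range(passes):
        for n in field.harmonics:
            g[n] = _nanmedian3(g[n], kernel)
            s[n] = _nanmedian3(s[n], kernel)
    return PhasorField(
        g=g,
        s=s,
        intensity=field.intensity,
        harmonics=field.harmonics,
        acquisition=field.acquisition,
        calibrated=field.calibrated,
    )


def threshold_mask(field: PhasorField, min_photons: float = DEFAULT_MIN_PHOTONS) -> PixelMask:
    """Mask of pixels with at least ``min_photons`` and a defined phasor."""
    if min_photons < 0:
        raise ValueError("min_photons must be >= 0")
    include = (field.intensity >= min_photons) & field.defined
    return PixelMask(include, provenance=f"intensity >= {min_photons} and defined")


def mask_large_keratin_features(
    fractions,
    f_threshold: float = DEFAULT_KERATIN_THRESHOLD,
    min_area: int = DEFAULT_KERATIN_MIN_AREA,
) -> PixelMask:
    """Exclusion mask of large keratin-rich structures (hairs, cysts).

    Connected components (8-connectivity) of pixels whose keratin
    fractional intensity exceeds ``f_threshold`` are marked for exclusion
    when their area reaches ``min_area`` pixels; smaller keratin-rich
    specks are retained.  Returns the pixels to EXCLUDE.
    """
    from .unmixing import FractionField

    if not isinstance(fractions, FractionField):
        raise TypeError("expected a FractionField")
    if "keratin" not in fractions.names:
        raise ValueError("fractions contain no 'keratin' component")
    keratin = fractions.fraction("keratin")
    above = keratin > f_threshold
    labels, n_lab = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    exclude = np.zeros_like(above, dtype=bool)
    if n_lab:
        areas = np.bincount(labels.ravel())
        big = np.flatnonzero(areas >= min_area)
        big = big[big != 0]
        if big.size:
            exclude = np.isin(labels, big)
    return PixelMask(
        exclude,
        provenance=(
            f"keratin fraction > {f_threshold} in connected components "
            f">= {min_area} px (8-connectivity); mask marks exclusions"
        ),
    )
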