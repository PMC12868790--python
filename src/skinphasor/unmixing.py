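"""Pixel-wise multicomponent unmixing from two-harmonic phasor coordinates.

Four epidermal fluorophores — keratin (1.1 ns), melanin (0.0 ns), free
NADH (0.4 ns) and protein-bound NADH (3.4 ns) — define a tetragon in
phasor space at each harmonic.  A measured pixel's phasor at harmonics 1
and 2 gives four linear constraints on the component photon fractions
f_i; together with the normalization sum(f) = 1 this determines the four
fractions.  The normalization is enforced exactly and the four phasor
equations are solved by least squares within the affine subspace, so
phasors falling outside the tetragon (low SNR) legitimately produce
negative fractional intensities — a diagnostic, not an error.

Fractional intensity is the fraction of a pixel's photons attributed to a
component; multiplying by the pixel's photon count gives per-component
photon maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterator, Sequence

import numpy as np

from .phasor import PhasorField, analytic_phasor
from .processing import PixelMask
from .synthetic import AcquisitionModel

logger = logging.getLogger(__name__)

UNMIX_HARMONICS = (1, 2)

#: Reference lifetimes (ns) of the default epidermal component set.
DEFAULT_LIFETIMES = {
    "free_nadh": 0.4,
    "bound_nadh": 3.4,
    "keratin": 1.1,
    "melanin": 0.0,
}


@dataclass(frozen=True)
class Component:
    """A named fluorophore with a reference mono-exponential lifetime."""

    name: str
    tau: float

    def phasor(self, n: int, acq: AcquisitionModel) -> tuple[float, float]:
        """Derived phasor coordinates at harmonic n (on the universal circle)."""
        return analytic_phasor(self.tau, n, acq)


@dataclass(frozen=True)
class ComponentSet:
    """Ordered set of 2-4 uniquely named components (the unmixing basis)."""

    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        if not (2 <= len(self.components) <= 4):
            raise ValueError("ComponentSet requires between 2 and 4 components")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError(f"component names must be unique, got {names}")

    @classmethod
    def default(cls) -> "ComponentSet":
        """Free NADH 0.4 ns, bound NADH 3.4 ns, keratin 1.1 ns, melanin 0 ns."""
        return cls(tuple(Component(n, t) for n, t in DEFAULT_LIFETIMES.items()))

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, float]]) -> "ComponentSet":
        return cls(tuple(Component(n, t) for n, t in pairs))

    def __iter__(self) -> Iterator[Component]:
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def taus(self) -> tuple[float, ...]:
        return tuple(c.tau for c in self.components)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no component named {name!r}") from None


@dataclass
class FractionField:
    """Per-pixel fractional intensities of each component.

    ``fractions`` is (rows, cols, k); fractions sum to 1 at every defined
    pixel but individual values may be negative (phasors outside the
    component tetragon).  ``intensity`` is the per-pixel photon count from
    the source phasor field.
    """

    fractions: np.ndarray
    intensity: np.ndarray
    names: tuple[str, ...]
    taus: tuple[float, ...]
    mask: PixelMask | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.fractions.shape[:2]

    def fraction(self, name: str) -> np.ndarray:
        return self.fractions[..., self.names.index(name)]

    def photons(self, name: str) -> np.ndarray:
        """Per-component photon map f_i * N."""
        return self.fraction(name) * self.intensity

    @property
    def defined(self) -> np.ndarray:
        ok = np.isfinite(self.fractions).all(axis=-1)
        if self.mask is not None:
            ok = ok & self.mask.include
        return ok


def component_matrix(
    components: ComponentSet, acq: AcquisitionModel | None = None
) -> np.ndarray:
    """Design matrix of the unmixing system (5 rows x k columns).

    Rows are the component coordinates [g1, s1, g2, s2] at harmonics 1
    and 2 plus the normalization row of ones; columns follow the
    ComponentSet order.  Raises if two components share a lifetime (the
    system would be rank-deficient).
    """
    if acq is None:
        acq = AcquisitionModel()
    taus = components.taus
    for i in range(len(taus)):
        for j in range(i + 1, len(taus)):
            if abs(taus[i] - taus[j]) < 1e-9:
                raise ValueError(
                    "rank-deficient component matrix: "
                    f"{components.names[i]!r} and {components.names[j]!r} share "
                    f"lifetime {taus[i]} ns"
                )
    cols = []
    for c in components:
        g1, s1 = c.phasor(1, acq)
        g2, s2 = c.phasor(2, acq)
        cols.append([g1, s1, g2, s2, 1.0])
    M = np.array(cols).T
    if np.linalg.matrix_rank(M) < len(components):
        raise ValueError(
            f"rank-deficient component matrix for components {components.names}"
        )
    return M


def _constrained_solver(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear map (W, v) with f = W @ b + v solving the constrained LSQ.

    Minimizes ||A f - b||^2 subject to sum(f) = 1, where A is the phasor
    block (first four rows of M) and b the measured [G1, S1, G2, S2].
    KKT system: [[A^T A, 1], [1^T, 0]] [f; lam] = [A^T b; 1].
    """
    A = M[:4, :]
    k = A.shape[1]
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = A.T @ A
    K[:k, k] = 1.0
    K[k, :k] = 1.0
    Kinv = np.linalg.inv(K)
    W = Kinv[:k, :k] @ A.T  # (k, 4)
    v = Kinv[:k, k]  # (k,)
    return W, v


def unmix(
    field: PhasorField,
    components: ComponentSet | None = None,
    mask: PixelMask | None = None,
) -> FractionField:
    """Solve per-pixel component fractions from a calibrated phasor field.

    Requires harmonics 1 and 2.  Negative fractions are legal outputs;
    the normalization sum(f) = 1 holds exactly (to solver precision) at
    every solved pixel.  Pixels excluded by ``mask`` or undefined in the
    field carry NaN fractions.
    """
    if components is None:
        components = ComponentSet.default()
    if not field.calibrated:
        raise ValueError("unmixing requires a calibrated phasor field")
    for n in UNMIX_HARMONICS:
        if n not in field.harmonics:
            raise ValueError(
                f"harmonic {n} missing from field; re-run phasor_transform "
                f"with harmonics (1, 2)"
            )
    M = component_matrix(components, field.acquisition)
    W, v = _constrained_solver(M)
    b = np.stack(
        [field.g[1], field.s[1], field.g[2], field.s[2]], axis=-1
    )  # (H, W, 4)
    fractions = b @ W.T + v
    solved = field.defined
    if mask is not None:
        if mask.shape != field.shape:
            raise ValueError("mask shape does not match field")
        solved = solved & mask.include
    fractions = np.where(solved[..., None], fractions, np.nan)
    return FractionField(
        fractions=fractions,
        intensity=np.asarray(field.intensity, dtype=float),
        names=components.names,
        taus=components.taus,
        mask=mask,
    )


def bound_nadh_ratio(fractions: FractionField, eps: float = 1e-6) -> np.ndarray:
    """Per-pixel metabolic ratio f_bound / (f_bound + f_free) of NADH.

    Pixels whose total NADH fraction does not exceed ``eps`` are returned
    as NaN (the ratio is undefined there).  The ratio decreases toward
    glycolytic metabolic states.
    """
    for name in ("bound_nadh", "free_nadh"):
        if name not in fractions.names:
            raise ValueError(f"fractions lack the {name!r} component")
    fb = fractions.fraction("bound_nadh")
    ff = fractions.fraction("free_nadh")
    total = fb + ff
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > eps, fb / total, np.nan)
    return ratio


DEFAULT_COLORS = {
    "keratin": (1.0, 0.0, 0.0),
    "melanin": (0.0, 0.3, 1.0),
    "bound_nadh": (1.0, 0.9, 0.0),
    "free_nadh": (0.6, 0.0, 0.8),
}


def combined_fraction_map(
    fractions: FractionField,
    colors: dict[str, tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Merged color-coded RGB render of the component fractions.

    Per pixel, RGB = sum_i clip(f_i, 0, 1) * color_i, scaled by the
    pixel's intensity normalized to the image maximum; zero-intensity
    pixels are black.  Deterministic given its inputs.
    """
    if colors is None:
        colors = DEFAULT_COLORS
    missing = [n for n in fractions.names if n not in colors]
    if missing:
        raise ValueError(f"no colors specified for components {missing}")
    h, w, k = fractions.fractions.shape
    rgb = np.zeros((h, w, 3))
    fr = np.nan_to_num(fractions.fractions, nan=0.0)
    for i, name in enumerate(fractions.names):
        rgb += np.clip(fr[..., i], 0.0, 1.0)[..., None] * np.asarray(colors[name])
    peak = fractions.intensity.max()
    scale = (fractions.intensity / peak) if peak > 0 else np.zeros((h, w))
    return np.clip(rgb * scale[..., None], 0.0, 1.0)
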