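"""Manders overlap coefficients on binary label masks, plus the surface
biotinylation ratio arithmetic.

M_A is the fraction of channel-A pixels that also carry channel B
(``|A n B| / |A|``); M_B is the converse.  For a confocal stack the
intersection and denominator counts are pooled across all sections of a
region of interest (one cell) before dividing, yielding one coefficient per
cell.  Coefficients with an empty denominator channel are flagged undefined,
never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError


@dataclass(frozen=True)
class ChannelMaskPair:
    """Two boolean masks of identical shape, with an optional ROI mask."""

    mask_a: np.ndarray
    mask_b: np.ndarray
    roi: np.ndarray | None = None
    z_index: int | None = None

    def __post_init__(self):
        a = np.asarray(self.mask_a, dtype=bool)
        b = np.asarray(self.mask_b, dtype=bool)
        if a.shape != b.shape:
            raise DomainError(f"mask shapes differ: {a.shape} vs {b.shape}")
        roi = self.roi
        if roi is not None:
            roi = np.asarray(roi, dtype=bool)
            if roi.shape != a.shape:
                raise DomainError(f"ROI shape {roi.shape} does not match masks {a.shape}")
        object.__setattr__(self, "mask_a", a)
        object.__setattr__(self, "mask_b", b)
        object.__setattr__(self, "roi", roi)


@dataclass(frozen=True)
class ColocResult:
    """Directional Manders coefficients with their underlying pixel counts."""

    n_a: int
    n_b: int
    n_overlap: int

    @property
    def m_a(self) -> float | None:
        """|A n B| / |A|, or None (undefined) when channel A is empty."""
        return self.n_overlap / self.n_a if self.n_a else None

    @property
    def m_b(self) -> float | None:
        return self.n_overlap / self.n_b if self.n_b else None

    @property
    def m_a_defined(self) -> bool:
        return self.n_a > 0

    @property
    def m_b_defined(self) -> bool:
        return self.n_b > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "M_A": np.nan if self.m_a is None else self.m_a,
                "M_B": np.nan if self.m_b is None else self.m_b,
                "n_a": self.n_a, "n_b": self.n_b, "n_overlap": self.n_overlap,
            }]
        )


def manders(pair: ChannelMaskPair) -> ColocResult:
    """Manders coefficients for one mask pair, restricted to the ROI if given."""
    a, b = pair.mask_a, pair.mask_b
    if pair.roi is not None:
        a = a & pair.roi
        b = b & pair.roi
    if not a.any() and not b.any():
        raise DomainError("both channels empty: nothing to colocalize")
    return ColocResult(
        n_a=int(a.sum()), n_b=int(b.sum()), n_overlap=int((a & b).sum())
    )


def stack_manders(stack_a, stack_b, roi=None) -> ColocResult:
    """Single per-cell coefficient: counts pooled across all stack sections.

    ``stack_a`` and ``stack_b`` are (n_sections, ...) boolean arrays (or
    sequences of 2-D masks); ``roi`` may be one 2-D mask applied to every
    section or a full per-section stack.
    """
    a = np.asarray(stack_a, dtype=bool)
    b = np.asarray(stack_b, dtype=bool)
    if a.shape[0] != b.shape[0]:
        raise DomainError(
            f"section counts differ: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape != b.shape:
        raise DomainError(f"stack shapes differ: {a.shape} vs {b.shape}")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape == a.shape[1:]:
            roi = np.broadcast_to(roi, a.shape)
        elif roi.shape != a.shape:
            raise DomainError("ROI must match one section or the full stack")
        a = a & roi
        b = b & roi
    if not a.any() and not b.any():
        raise DomainError("both channels empty within the ROI")
    return ColocResult(
        n_a=int(a.sum()), n_b=int(b.sum()), n_overlap=int((a & b).sum())
    )


def threshold_mask(image, threshold: float | str = "otsu") -> np.ndarray:
    """Convenience global threshold producing a boolean mask.

    ``threshold`` may be a number (mask = image > threshold) or ``"otsu"``.
    This is a pragmatic helper for raw intensity images; the coefficient
    definitions above operate on whatever masks the user supplies.
    """
    img = np.asarray(image, dtype=float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise DomainError(f"unknown threshold method {threshold!r}")
        from skimage.filters import threshold_otsu

        return img > threshold_otsu(img)
    return img > float(threshold)


@dataclass(frozen=True)
class BiotinylationRatios:
    surface_total_ratio: float
    apical_fraction: float
    basolateral_fraction: float


def biotinylation_ratios(
    apical_surface: float,
    basolateral_surface: float,
    apical_total: float,
    basolateral_total: float,
) -> BiotinylationRatios:
    """Surface/total and apical/basolateral distribution from band intensities.

    surface/total = (apical_s + basolateral_s) / [ (apical_t + basolateral_t) / 2 * 10 ];
    the /2 averages the duplicate total-lysate determinations and the *10
    corrects for loading only 10% of the lysate.  The apical fraction is
    apical_s / (apical_s + basolateral_s).
    """
    if apical_total <= 0 or basolateral_total <= 0:
        raise DomainError("total intensities must be > 0")
    if apical_surface < 0 or basolateral_surface < 0:
        raise DomainError("surface intensities must be >= 0")
    surf = apical_surface + basolateral_surface
    if surf == 0:
        raise DomainError("no surface signal: apical fraction undefined")
    denom = (apical_total + basolateral_total) / 2 * 10
    apical_fraction = apical_surface / surf
    return BiotinylationRatios(
        surface_total_ratio=surf / denom,
        apical_fraction=apical_fraction,
        basolateral_fraction=1.0 - apical_fraction,
    )


def fold_change(before: float, after: float, rounded: bool = False) -> float:
    """before/after fold decrease; ``rounded`` snaps to the nearest integer.

    ``after == 0`` yields +inf (infinite-fold flag)."""
    if after < 0 or before < 0:
        raise DomainError("percentages must be >= 0")
    if after == 0:
        return float("inf")
    fold = before / after
    return float(round(fold)) if rounded else fold
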