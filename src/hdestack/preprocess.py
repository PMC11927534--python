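"""Spectral smoothing, normalization, fusion and train/test splitting.

Savitzky-Golay smoothing suppresses band-wise instrument noise while
preserving the peak/valley structure the downstream band selectors rely
on; min-max normalization puts heterogeneous morphological scales on a
common [0, 1] footing so every feature contributes comparably; fusion is
feature-level concatenation of the two modality blocks.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import savgol_filter
from sklearn.model_selection import train_test_split

from .containers import FeatureTable, SpectralSet

logger = logging.getLogger(__name__)


def sg_smooth(s: SpectralSet, window: int = 11, polyorder: int = 2) -> SpectralSet:
    """Savitzky-Golay filter each spectrum along the wavelength axis.

    ``window`` must be odd, larger than ``polyorder`` and no larger than
    the number of bands; the wavelength grid is unchanged.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > s.n_bands:
        raise ValueError("window exceeds the number of bands")
    smoothed = savgol_filter(s.reflectance, window, polyorder, axis=1)
    return SpectralSet(s.wavelengths.copy(), smoothed, list(s.sample_ids))


def minmax_normalize(
    t: FeatureTable,
    fit_rows: np.ndarray | None = None,
    ranges: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[FeatureTable, tuple[np.ndarray, np.ndarray]]:
    """Map each feature to (x - min) / (max - min).

    Ranges are learned on ``fit_rows`` only (all rows by default) so that
    held-out data never leaks into the scaling; pass ``ranges`` to apply a
    previously fitted scaling. Constant features map to 0 by convention.
    Held-out values may fall outside [0, 1]; this is permitted and logged.
    """
    if ranges is None:
        rows = np.arange(t.n_samples) if fit_rows is None else np.asarray(fit_rows)
        if rows.size == 0:
            raise ValueError("fit_rows must be non-empty")
        lo = t.values[rows].min(axis=0)
        hi = t.values[rows].max(axis=0)
    else:
        lo, hi = ranges
    span = hi - lo
    out = np.zeros_like(t.values)
    nonconst = span > 0
    out[:, nonconst] = (t.values[:, nonconst] - lo[nonconst]) / span[nonconst]
    n_outside = int(np.sum((out < 0) | (out > 1)))
    if n_outside:
        logger.info("minmax_normalize: %d values fall outside [0, 1]", n_outside)
    table = FeatureTable(
        out, list(t.feature_names), list(t.modalities), t.labels.copy(), list(t.sample_ids)
    )
    return table, (lo, hi)


def fuse(morph: FeatureTable, spec: FeatureTable) -> FeatureTable:
    """Feature-level fusion: concatenate columns, morphological block first."""
    if spec.n_features == 0:
        return morph
    if morph.n_features == 0:
        return spec
    if morph.n_samples != spec.n_samples or not np.array_equal(morph.labels, spec.labels):
        raise ValueError("fuse requires identical sample ordering and labels")
    return FeatureTable(
        np.hstack([morph.values, spec.values]),
        list(morph.feature_names) + list(spec.feature_names),
        list(morph.modalities) + list(spec.modalities),
        morph.labels.copy(),
        list(morph.sample_ids),
    )


def split(
    t: FeatureTable, train_frac: float = 0.7, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split (disjoint, union = t)."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    counts = np.bincount(t.labels)
    if np.any(counts[np.unique(t.labels)] < 2):
        raise ValueError("every class needs at least 2 samples to stratify")
    idx = np.arange(t.n_samples)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, random_state=seed, stratify=t.labels
    )
    return t.take_rows(np.sort(train_idx)), t.take_rows(np.sort(test_idx))
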