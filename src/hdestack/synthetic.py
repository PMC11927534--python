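"""Synthetic multimodal seed datasets.

Emulates the statistical structure of a maize-kernel study design: eleven
visually similar varieties, ~150 near-infrared reflectance curves per
variety on a 350-2500 nm grid, and a 52-column block of geometric /
texture / color morphological descriptors with heterogeneous scales.

Spectra are smooth curves sharing a common peak/valley morphology
(Gaussian bumps on a linear baseline) with class-dependent amplitude
scalings and offsets, so band-selection algorithms see localized signal.
Morphological columns mix class-informative features with pure-noise
fillers, on deliberately different numeric ranges so that normalization
matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import MORPH, FeatureTable, SpectralSet

#: Peak / valley centers (nm) of the shared base reflectance curve.
DEFAULT_PEAKS = (863.0, 1105.0, 1295.0, 1680.0, 2015.0)
DEFAULT_VALLEYS = (980.0, 1175.0, 1450.0, 1780.0, 1915.0)

#: Named morphological features, by family: geometric (E, r, Hu moments),
#: texture (hist0, contrast, entropy), color means / deviations.
NAMED_MORPH_FEATURES = (
    "E", "r", "Hu2", "area", "perimeter",
    "hist0", "contrast", "entropy",
    "g_mean", "b_mean", "h_mean", "l_mean", "a_mean",
    "g_dev", "a_dev", "s_dev",
)


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the reference study design."""

    n_classes: int = 11
    n_per_class: int = 150
    wavelength_start: float = 350.0
    wavelength_end: float = 2500.0
    wavelength_step: float = 1.0
    peak_centers: tuple[float, ...] = DEFAULT_PEAKS
    valley_centers: tuple[float, ...] = DEFAULT_VALLEYS
    bump_width: float = 40.0          # Gaussian bump sd, nm
    class_shift_sd: float = 0.004     # reflectance units
    noise_sd: float = 0.012           # reflectance units
    n_morph: int = 52
    n_informative_morph: int = 15
    morph_effect_size: float = 0.5    # standardized mean separation
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_centers = tuple(self.peak_centers)
        self.valley_centers = tuple(self.valley_centers)
        if self.n_classes < 1 or self.n_per_class < 1:
            raise ValueError("n_classes and n_per_class must be positive")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength_step must be positive")
        if self.wavelength_end <= self.wavelength_start:
            raise ValueError("wavelength range must be non-empty")
        if self.n_morph < 1:
            raise ValueError("n_morph must be positive")
        if self.n_informative_morph > self.n_morph:
            raise ValueError("n_informative_morph exceeds n_morph")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wavelength_end - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.n_per_class


def _labels(cfg: SynthConfig) -> np.ndarray:
    return np.repeat(np.arange(cfg.n_classes), cfg.n_per_class)


def base_curve(cfg: SynthConfig) -> np.ndarray:
    """Shared smooth reflectance baseline: linear trend + peak/valley bumps."""
    wl = cfg.wavelengths
    span = cfg.wavelength_end - cfg.wavelength_start
    curve = 0.35 + 0.10 * (wl - cfg.wavelength_start) / span
    for c in cfg.peak_centers:
        curve = curve + 0.08 * np.exp(-0.5 * ((wl - c) / cfg.bump_width) ** 2)
    for c in cfg.valley_centers:
        curve = curve - 0.08 * np.exp(-0.5 * ((wl - c) / cfg.bump_width) ** 2)
    return curve


def generate_spectra(cfg: SynthConfig) -> tuple[SpectralSet, np.ndarray]:
    """Generate class-structured reflectance curves.

    Each class perturbs the shared base curve by (i) amplitude rescaling of
    the peak bumps and (ii) a small additive offset, both of magnitude
    ``class_shift_sd``; i.i.d. Gaussian noise of sd ``noise_sd`` is added
    per sample and band.

    Returns the spectra and the integer class labels (0..n_classes-1).
    """
    rng = np.random.default_rng(cfg.seed)  # fixed offset 0 for spectra
    wl = cfg.wavelengths
    base = base_curve(cfg)
    labels = _labels(cfg)

    # class-specific structure: per-peak amplitude deltas + flat offset
    peak_shapes = np.stack(
        [np.exp(-0.5 * ((wl - c) / cfg.bump_width) ** 2) for c in cfg.peak_centers]
    )
    amp = rng.normal(0.0, cfg.class_shift_sd, size=(cfg.n_classes, len(cfg.peak_centers)))
    offset = rng.normal(0.0, cfg.class_shift_sd, size=cfg.n_classes)
    class_curves = base + amp @ peak_shapes + offset[:, None]

    refl = class_curves[labels] + rng.normal(0.0, cfg.noise_sd, size=(labels.size, wl.size))
    ids = [f"s{i:05d}" for i in range(labels.size)]
    return SpectralSet(wl, refl, ids), labels


def generate_morphology(cfg: SynthConfig) -> FeatureTable:
    """Generate the morphological block.

    The first ``n_informative_morph`` columns (named after the field's
    geometric/texture/color descriptors) carry class-dependent means
    separated by ``morph_effect_size`` standardized units; the remainder
    (m00..mNN) are label-independent noise. Every column is then mapped to
    its own scale and offset (log-uniform scales over four decades) so the
    block exercises min-max normalization downstream.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # fixed offset 1 for morphology
    labels = _labels(cfg)
    n, p = labels.size, cfg.n_morph
    k = cfg.n_informative_morph

    class_means = rng.normal(0.0, cfg.morph_effect_size, size=(cfg.n_classes, k))
    x = rng.normal(0.0, 1.0, size=(n, p))
    x[:, :k] += class_means[labels]

    scales = 10.0 ** rng.uniform(-2.0, 2.0, size=p)
    shifts = rng.normal(0.0, 5.0, size=p) * scales
    x = x * scales + shifts

    names = list(NAMED_MORPH_FEATURES[:min(p, len(NAMED_MORPH_FEATURES))])
    names += [f"m{i:02d}" for i in range(len(names), p)]
    ids = [f"s{i:05d}" for i in range(n)]
    return FeatureTable(x, names, [MORPH] * p, labels, ids)


def make_dataset(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[FeatureTable, SpectralSet, np.ndarray]:
    """Paired morphological + spectral dataset with aligned sample identities.

    Optionally writes ``morphology.csv`` and ``spectra.csv`` fixtures.
    """
    spectra, labels = generate_spectra(cfg)
    morph = generate_morphology(cfg)
    if morph.n_samples != spectra.n_samples:
        raise RuntimeError("modalities generated mismatched sample counts")
    if not np.array_equal(morph.labels, labels):
        raise RuntimeError("modalities generated mismatched labels")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        morph.to_csv(out / "morphology.csv")
        spectra.to_csv(out / "spectra.csv", labels=labels)
    return morph, spectra, labels
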