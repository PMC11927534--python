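"""Core data containers shared by every pipeline stage.

Two containers circulate between stages: :class:`SpectralSet` holds raw
reflectance curves on a common wavelength grid, and :class:`FeatureTable`
is the universal samples x features currency (morphological columns,
selected spectral bands, or their fusion) with integer-coded class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MORPH = "morph"
SPECTRAL = "spectral"


@dataclass
class SpectralSet:
    """Reflectance spectra on a shared, strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of float, shape (n_bands,)
        Wavelength grid in nm, strictly increasing.
    reflectance : array of float, shape (n_samples, n_bands)
        One reflectance curve per row.
    sample_ids : list of str
        One identifier per row.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {self.reflectance.shape[1]} bands but the "
                f"grid has {self.wavelengths.size}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def to_feature_table(self, labels: np.ndarray) -> "FeatureTable":
        """View the spectra as a FeatureTable with wavelength-named columns."""
        names = [f"{int(round(w))}" for w in self.wavelengths]
        return FeatureTable(
            values=self.reflectance.copy(),
            feature_names=names,
            modalities=[SPECTRAL] * self.n_bands,
            labels=np.asarray(labels, dtype=int),
            sample_ids=list(self.sample_ids),
        )

    def to_csv(self, path, labels: np.ndarray | None = None) -> None:
        cols = {"sample_id": self.sample_ids}
        if labels is not None:
            cols["label"] = np.asarray(labels, dtype=int)
        df = pd.DataFrame(cols)
        spec = pd.DataFrame(
            self.reflectance, columns=[f"{int(round(w))}" for w in self.wavelengths]
        )
        pd.concat([df, spec], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> tuple["SpectralSet", np.ndarray | None]:
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=int) if "label" in df else None
        ids = df.pop("sample_id").astype(str).tolist()
        wavelengths = np.array([float(c) for c in df.columns])
        return cls(wavelengths, df.to_numpy(dtype=float), ids), labels


@dataclass
class FeatureTable:
    """Samples x named features with class labels and per-feature modality."""

    values: np.ndarray
    feature_names: list[str]
    modalities: list[str]
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(self.modalities) != self.values.shape[1]:
            raise ValueError("modalities length mismatch")
        if self.labels.size != self.values.shape[0]:
            raise ValueError("labels length mismatch")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def take_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            modalities=list(self.modalities),
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def take_features(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            modalities=[self.modalities[i] for i in idx],
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, modality: str | list[str] = MORPH
    ) -> "FeatureTable":
        df = df.copy()
        labels = df.pop("label").to_numpy(dtype=int)
        ids = (
            df.pop("sample_id").astype(str).tolist()
            if "sample_id" in df
            else []
        )
        names = [str(c) for c in df.columns]
        if isinstance(modality, str):
            modalities = [modality] * len(names)
        else:
            modalities = list(modality)
        return cls(df.to_numpy(dtype=float), names, modalities, labels, ids)

    @classmethod
    def from_csv(cls, path, modality: str | list[str] = MORPH) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path), modality)
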