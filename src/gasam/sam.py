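"""Spectral-angle-mapper (SAM) nearest-centroid classification on a band subset.

The SAM assigns a spectrum to the species whose reference spectrum (the
per-species mean of the training set, restricted to the selected bands)
subtends the smallest angle with it in band space. Because the angle is
invariant to positive scaling, the classifier is insensitive to overall
brightness differences between leaves. Overall classification accuracy on
the validation half is the fitness the genetic band selector maximises.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import SpectralLibrary, SplitLibrary


def spectral_angle(target: Sequence[float], reference: Sequence[float]) -> float:
    """Angle in radians between two spectra in n-dimensional band space.

    theta = arccos(<t, r> / (||t|| ||r||)), with the cosine clamped to
    [-1, 1] to absorb floating-point overshoot on near-identical spectra.
    Symmetric, and invariant to positive scaling of either argument.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    if t.shape != r.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("spectra must be 1-D vectors of equal length >= 1")
    nt = np.linalg.norm(t)
    nr = np.linalg.norm(r)
    if nt == 0.0 or nr == 0.0:
        raise ValueError("spectral angle undefined for a zero-norm spectrum")
    cos = np.clip(np.dot(t, r) / (nt * nr), -1.0, 1.0)
    return float(np.arccos(cos))


@dataclass(frozen=True)
class ReferenceSet:
    """Per-species mean training spectra restricted to selected bands.

    ``references`` is an (n_species, k) matrix; rows follow ``labels``
    (alphabetical species order).
    """

    band_indices: tuple[int, ...]
    labels: tuple[str, ...]
    references: np.ndarray

    def __post_init__(self) -> None:
        refs = np.asarray(self.references, dtype=float)
        if refs.shape != (len(self.labels), len(self.band_indices)):
            raise ValueError("reference matrix shape does not match labels/bands")
        if np.any(np.linalg.norm(refs, axis=1) == 0.0):
            raise ValueError("a reference spectrum has zero norm")
        object.__setattr__(self, "references", refs)


def _check_bands(lib: SpectralLibrary, bands: Sequence[int]) -> np.ndarray:
    idx = np.asarray(bands, dtype=int)
    if idx.size == 0:
        raise ValueError("band subset is empty")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError(f"band indices not distinct: {sorted(idx.tolist())}")
    if np.any(idx < 0) or np.any(idx >= lib.grid.n_bands):
        raise ValueError("band index out of range")
    invalid = idx[~lib.grid.valid_mask[idx]]
    if invalid.size:
        raise ValueError(f"band indices fall on masked bands: {invalid.tolist()}")
    return idx


def build_references(train: SpectralLibrary, bands: Sequence[int]) -> ReferenceSet:
    """Per-species mean training spectrum over the selected bands."""
    idx = _check_bands(train, bands)
    labels = train.species
    refs = np.vstack([train.species_values(s)[:, idx].mean(axis=0) for s in labels])
    return ReferenceSet(
        band_indices=tuple(int(i) for i in idx), labels=labels, references=refs
    )


def classify(spectrum_values: Sequence[float], refs: ReferenceSet) -> str:
    """Species whose reference minimises the spectral angle.

    ``spectrum_values`` is a full-grid spectrum; it is restricted to the
    reference set's bands. Exact ties go to the alphabetically first
    species code (labels are stored sorted).
    """
    v = np.asarray(spectrum_values, dtype=float)[list(refs.band_indices)]
    angles = [spectral_angle(v, refs.references[i]) for i in range(len(refs.labels))]
    return refs.labels[int(np.argmin(angles))]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square species confusion matrix: rows true, columns predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.labels)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall classification accuracy in percent: 100 * trace / total."""
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return 100.0 * float(np.trace(self.counts)) / self.total

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def write_csv(self, path: str | Path) -> None:
        """Write as CSV with label header row/column and a trailing
        overall-accuracy line, two decimals."""
        path = Path(path)
        with path.open("w") as fh:
            self.to_dataframe().to_csv(fh)
            fh.write(f"overall_accuracy,{self.accuracy:.2f}%\n")


class BatchSAM:
    """Vectorised SAM evaluation of many band subsets against one split.

    Precomputes the training-mean operator and validation matrix once so a
    genetic-algorithm run can score thousands of chromosomes cheaply. The
    mathematics is identical to :func:`classify` applied spectrum by
    spectrum (nearest angle, alphabetical tie-break).
    """

    def __init__(self, split: SplitLibrary) -> None:
        self.split = split
        self.labels = split.train.species
        train = split.train
        self._train_values = train.values
        n_t = train.n_spectra
        mean_op = np.zeros((len(self.labels), n_t))
        for i, s in enumerate(self.labels):
            rows = train.indices_of(s)
            mean_op[i, rows] = 1.0 / rows.size
        self._mean_op = mean_op
        self._val_values = split.validation.values
        label_to_i = {s: i for i, s in enumerate(self.labels)}
        self._val_y = np.array(
            [label_to_i[s] for s in split.validation.species_codes], dtype=int
        )
        self._cache: dict[tuple[int, ...], float] = {}

    def _predict(self, bands: Sequence[int]) -> np.ndarray:
        idx = np.asarray(bands, dtype=int)
        refs = self._mean_op @ self._train_values[:, idx]
        vals = self._val_values[:, idx]
        ref_norm = np.linalg.norm(refs, axis=1)
        val_norm = np.linalg.norm(vals, axis=1)
        if np.any(ref_norm == 0.0) or np.any(val_norm == 0.0):
            raise ValueError("spectral angle undefined for a zero-norm spectrum")
        cos = np.clip((vals @ refs.T) / np.outer(val_norm, ref_norm), -1.0, 1.0)
        # smallest angle == largest cosine; argmax takes the first (lowest
        # label index, i.e. alphabetically first) on exact ties
        return np.argmax(cos, axis=1)

    def accuracy(self, bands: Sequence[int]) -> float:
        """Overall validation accuracy (%) of a band subset, cached."""
        key = tuple(int(b) for b in bands)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        acc = 100.0 * float(np.mean(self._predict(key) == self._val_y))
        self._cache[key] = acc
        return acc

    def confusion(self, bands: Sequence[int]) -> ConfusionMatrix:
        pred = self._predict(bands)
        n = len(self.labels)
        counts = np.zeros((n, n), dtype=int)
        np.add.at(counts, (self._val_y, pred), 1)
        return ConfusionMatrix(labels=self.labels, counts=counts)


def confusion_for(
    lib: SpectralLibrary, refs: ReferenceSet
) -> ConfusionMatrix:
    """Confusion matrix of the SAM over any library given fixed references."""
    labels = lib.species
    if labels != refs.labels:
        raise ValueError("library species do not match the reference set")
    idx = list(refs.band_indices)
    vals = lib.values[:, idx]
    ref_norm = np.linalg.norm(refs.references, axis=1)
    val_norm = np.linalg.norm(vals, axis=1)
    if np.any(ref_norm == 0.0) or np.any(val_norm == 0.0):
        raise ValueError("spectral angle undefined for a zero-norm spectrum")
    cos = np.clip((vals @ refs.references.T) / np.outer(val_norm, ref_norm), -1.0, 1.0)
    pred = np.argmax(cos, axis=1)
    label_to_i = {s: i for i, s in enumerate(labels)}
    true = np.array([label_to_i[s] for s in lib.species_codes], dtype=int)
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(labels=labels, counts=counts)


def evaluate(
    split: SplitLibrary, bands: Sequence[int]
) -> tuple[ConfusionMatrix, float]:
    """Validation confusion matrix and overall accuracy (%) of a band subset."""
    idx = _check_bands(split.train, bands)
    if split.validation.n_spectra == 0:
        raise ValueError("empty validation set")
    refs = build_references(split.train, idx)
    cm = confusion_for(split.validation, refs)
    return cm, cm.accuracy
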