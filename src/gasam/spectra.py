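"""Labelled mid/thermal-infrared emissivity spectral libraries.

Data model and I/O for leaf emissivity spectra sampled on a shared
band-centre wavelength grid spanning 2.5-14 um: Kirchhoff conversion from
directional-hemispherical reflectance (DHR), masking of noisy wavelength
regions (e.g. the 6-8 um water-absorption window), seeded per-species
train/validation splitting, and a plain-CSV on-disk format.

Bands are masked rather than removed, so band indices and wavelengths stay
comparable across configurations; downstream selection operates on valid
bands only.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Physical wavelength span of the instrument domain, in micrometres.
WAVELENGTH_MIN_UM = 2.5
WAVELENGTH_MAX_UM = 14.0

#: Water-absorption window excluded from analysis, in micrometres.
DEFAULT_EXCLUSION_UM = (6.0, 8.0)


class SpectralDomainError(ValueError):
    """A spectral value lies outside its physical domain [0, 1]."""


class LibraryFormatError(ValueError):
    """A spectral-library file violates the expected CSV dialect."""


@dataclass(frozen=True, eq=False)
class SpectralGrid:
    """Shared band-centre wavelength grid with a per-band validity mask.

    Parameters
    ----------
    wavelengths_um
        Strictly increasing band-centre wavelengths in micrometres, all
        within [2.5, 14.0].
    valid_mask
        Boolean per band; ``False`` marks bands inside excluded regions.
    """

    wavelengths_um: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_um, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if mask.shape != wl.shape:
            raise ValueError("valid_mask shape does not match wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths not increasing")
        if wl[0] < WAVELENGTH_MIN_UM - 1e-9 or wl[-1] > WAVELENGTH_MAX_UM + 1e-9:
            raise ValueError(
                f"wavelengths must lie within [{WAVELENGTH_MIN_UM}, "
                f"{WAVELENGTH_MAX_UM}] um, got span [{wl[0]}, {wl[-1]}]"
            )
        if not mask.any():
            raise ValueError("grid has no valid bands")
        object.__setattr__(self, "wavelengths_um", wl)
        object.__setattr__(self, "valid_mask", mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return np.array_equal(
            self.wavelengths_um, other.wavelengths_um
        ) and np.array_equal(self.valid_mask, other.valid_mask)

    def __hash__(self) -> int:
        return hash((self.wavelengths_um.tobytes(), self.valid_mask.tobytes()))

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_um.size)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_indices(self) -> np.ndarray:
        """Indices of all valid (unmasked) bands, ascending."""
        return np.flatnonzero(self.valid_mask)

    def excluded_regions(self) -> list[tuple[float, float]]:
        """Contiguous masked runs as (lo_um, hi_um) wavelength intervals."""
        regions: list[tuple[float, float]] = []
        invalid = ~self.valid_mask
        i = 0
        n = self.n_bands
        while i < n:
            if invalid[i]:
                j = i
                while j + 1 < n and invalid[j + 1]:
                    j += 1
                regions.append(
                    (float(self.wavelengths_um[i]), float(self.wavelengths_um[j]))
                )
                i = j + 1
            else:
                i += 1
        return regions

    def nearest_band(self, wavelength_um: float) -> int:
        """Index of the valid band closest to ``wavelength_um``."""
        valid = self.valid_indices
        return int(valid[np.argmin(np.abs(self.wavelengths_um[valid] - wavelength_um))])


def make_grid(
    n_bands: int = 3024,
    lo_um: float = WAVELENGTH_MIN_UM,
    hi_um: float = WAVELENGTH_MAX_UM,
) -> SpectralGrid:
    """Evenly spaced, fully valid grid over [lo_um, hi_um]."""
    wl = np.linspace(lo_um, hi_um, n_bands)
    return SpectralGrid(wl, np.ones(n_bands, dtype=bool))


def kirchhoff_to_emissivity(reflectance_values: Sequence[float]) -> np.ndarray:
    """Convert directional-hemispherical reflectance to emissivity.

    For an opaque surface Kirchhoff's law gives emissivity = 1 - R.

    Raises
    ------
    SpectralDomainError
        If any reflectance lies outside [0, 1]; the message names the
        offending band index.
    """
    r = np.asarray(reflectance_values, dtype=float)
    bad = np.flatnonzero((r < 0.0) | (r > 1.0) | ~np.isfinite(r))
    if bad.size:
        i = int(bad[0])
        raise SpectralDomainError(
            f"reflectance outside [0, 1] at band index {i}: {r[i]!r}"
        )
    return 1.0 - r


def apply_exclusion(grid: SpectralGrid, lo_um: float, hi_um: float) -> SpectralGrid:
    """Mask all bands with lo_um <= wavelength <= hi_um.

    Wavelengths and band count are unchanged — bands are masked, never
    removed. Raises ``ValueError`` if the exclusion would leave no valid
    band, or if ``lo_um >= hi_um``.
    """
    if not lo_um < hi_um:
        raise ValueError(f"exclusion bounds must satisfy lo < hi, got ({lo_um}, {hi_um})")
    inside = (grid.wavelengths_um >= lo_um) & (grid.wavelengths_um <= hi_um)
    new_mask = grid.valid_mask & ~inside
    if not new_mask.any():
        raise ValueError(f"excluding [{lo_um}, {hi_um}] um would leave no valid bands")
    return SpectralGrid(grid.wavelengths_um, new_mask)


@dataclass(frozen=True)
class Spectrum:
    """One leaf's emissivity spectrum with its species label."""

    values: np.ndarray
    species_code: str
    leaf_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("spectrum values must be 1-D")
        if not self.species_code:
            raise ValueError("species_code must be non-empty")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SpectralLibrary:
    """Collection of labelled spectra sharing one wavelength grid.

    ``values`` is an (n_spectra, n_bands) matrix; row order matches
    ``species_codes`` / ``leaf_ids``. Emissivity must lie in [0, 1] on
    valid bands (masked bands may hold anything finite — real instruments
    produce out-of-range noise in excluded windows).
    """

    grid: SpectralGrid
    values: np.ndarray
    species_codes: tuple[str, ...]
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        codes = tuple(self.species_codes)
        leaves = tuple(self.leaf_ids)
        if v.ndim != 2 or v.shape[1] != self.grid.n_bands:
            raise ValueError(
                f"values must be (n_spectra, {self.grid.n_bands}), got {v.shape}"
            )
        if len(codes) != v.shape[0] or len(leaves) != v.shape[0]:
            raise ValueError("labels do not match the number of spectra rows")
        keys = list(zip(codes, leaves))
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate (species, leaf_id): {dup}")
        on_valid = v[:, self.grid.valid_mask]
        bad_rows = np.flatnonzero(
            ((on_valid < 0.0) | (on_valid > 1.0) | ~np.isfinite(on_valid)).any(axis=1)
        )
        if bad_rows.size:
            i = int(bad_rows[0])
            raise SpectralDomainError(
                f"emissivity outside [0, 1] on a valid band in spectrum "
                f"{codes[i]}_{leaves[i]} (row {i})"
            )
        uniq, counts = np.unique(np.asarray(codes), return_counts=True)
        few = uniq[counts < 2]
        if few.size:
            raise ValueError(f"species with fewer than 2 spectra: {list(few)}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "species_codes", codes)
        object.__setattr__(self, "leaf_ids", leaves)

    @classmethod
    def from_spectra(cls, grid: SpectralGrid, spectra: Iterable[Spectrum]) -> "SpectralLibrary":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("empty spectrum collection")
        for sp in spectra:
            if sp.values.size != grid.n_bands:
                raise ValueError(
                    f"spectrum {sp.species_code}_{sp.leaf_id} has "
                    f"{sp.values.size} bands, grid has {grid.n_bands}"
                )
        return cls(
            grid=grid,
            values=np.vstack([sp.values for sp in spectra]),
            species_codes=tuple(sp.species_code for sp in spectra),
            leaf_ids=tuple(sp.leaf_id for sp in spectra),
        )

    @property
    def n_spectra(self) -> int:
        return int(self.values.shape[0])

    @property
    def species(self) -> tuple[str, ...]:
        """Distinct species codes, alphabetically ordered."""
        return tuple(sorted(set(self.species_codes)))

    def indices_of(self, species_code: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.species_codes) == species_code)

    def species_values(self, species_code: str) -> np.ndarray:
        """(n_replicates, n_bands) value matrix for one species."""
        return self.values[self.indices_of(species_code)]

    def subset(self, rows: Sequence[int]) -> "SpectralLibrary":
        rows = np.asarray(rows, dtype=int)
        return SpectralLibrary(
            grid=self.grid,
            values=self.values[rows],
            species_codes=tuple(self.species_codes[i] for i in rows),
            leaf_ids=tuple(self.leaf_ids[i] for i in rows),
        )

    def iter_spectra(self) -> Iterator[Spectrum]:
        for i in range(self.n_spectra):
            yield Spectrum(self.values[i], self.species_codes[i], self.leaf_ids[i])


@dataclass(frozen=True)
class SplitLibrary:
    """Disjoint, species-balanced train/validation partition of a library."""

    train: SpectralLibrary
    validation: SpectralLibrary
    seed: int

    def __post_init__(self) -> None:
        t_keys = set(zip(self.train.species_codes, self.train.leaf_ids))
        v_keys = set(zip(self.validation.species_codes, self.validation.leaf_ids))
        if t_keys & v_keys:
            raise ValueError("train and validation overlap")
        if self.train.species != self.validation.species:
            raise ValueError("train and validation must contain the same species")


def split_per_species(lib: SpectralLibrary, n_train: int, seed: int) -> SplitLibrary:
    """Seeded per-species train/validation split.

    Per species, ``n_train`` spectra are drawn uniformly without
    replacement into the training half; the validation half holds
    ``min(n_train, n_species_replicates - n_train)`` of the remainder, so
    with an odd replicate count (e.g. 35 leaves, 17 training) one spectrum
    per species is held out unused and both halves stay the same size.
    """
    if n_train < 2:
        raise ValueError("n_train must be >= 2")
    counts = {s: lib.indices_of(s).size for s in lib.species}
    too_few = [s for s, c in counts.items() if c < n_train + 1]
    if too_few:
        raise ValueError(
            f"species with fewer than n_train+1={n_train + 1} replicates: {too_few}"
        )
    rng = np.random.default_rng(seed)
    train_rows: list[int] = []
    val_rows: list[int] = []
    for s in lib.species:
        idx = lib.indices_of(s)
        perm = rng.permutation(idx)
        n_val = min(n_train, idx.size - n_train)
        train_rows.extend(int(i) for i in perm[:n_train])
        val_rows.extend(int(i) for i in perm[n_train : n_train + n_val])
    return SplitLibrary(
        train=lib.subset(train_rows), validation=lib.subset(val_rows), seed=seed
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Layout: optional leading "# key = value" metadata lines (excluded regions),
# then a header row "wavelength_um,<SPECIES>_<LEAFID>,...", then one row per
# band with the ascending band-centre wavelength followed by per-leaf
# emissivity.
# ---------------------------------------------------------------------------

_EXCLUDED_KEY = "excluded_um"


def write_library(lib: SpectralLibrary, path: str | Path) -> None:
    """Write a library to the plain-CSV spectral-library format."""
    path = Path(path)
    cols = [f"{s}_{l}" for s, l in zip(lib.species_codes, lib.leaf_ids)]
    df = pd.DataFrame(lib.values.T, columns=cols)
    df.insert(0, "wavelength_um", lib.grid.wavelengths_um)
    with path.open("w") as fh:
        regions = lib.grid.excluded_regions()
        if regions:
            spec = ";".join(f"{lo:.10g}:{hi:.10g}" for lo, hi in regions)
            fh.write(f"# {_EXCLUDED_KEY} = {spec}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_library(path: str | Path) -> SpectralLibrary:
    """Read a library from the plain-CSV spectral-library format.

    Raises ``LibraryFormatError`` for structural problems (ragged rows,
    non-increasing wavelengths, duplicate leaf columns) and
    ``SpectralDomainError`` for emissivity outside [0, 1] on valid bands;
    messages carry the offending line or column.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise LibraryFormatError(f"{path}: no CSV body found")

    header = [c.strip() for c in body_lines[0].rstrip("\n").split(",")]
    if not header or header[0] != "wavelength_um":
        raise LibraryFormatError(
            f"{path}: first column must be 'wavelength_um', got {header[:1]}"
        )
    leaf_cols = header[1:]
    if len(set(leaf_cols)) != len(leaf_cols):
        dup = next(c for c in leaf_cols if leaf_cols.count(c) > 1)
        raise LibraryFormatError(f"{path}: duplicate leaf column '{dup}'")
    keys = []
    for c in leaf_cols:
        if "_" not in c:
            raise LibraryFormatError(
                f"{path}: column '{c}' is not of the form SPECIES_LEAFID"
            )
        keys.append(tuple(c.rsplit("_", 1)))

    try:
        df = pd.read_csv(io.StringIO("".join(body_lines)))
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise LibraryFormatError(f"{path}: malformed CSV ({exc})") from exc

    wl = df["wavelength_um"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        i = int(np.flatnonzero(np.diff(wl) <= 0)[0]) + 1
        raise LibraryFormatError(
            f"{path}: wavelengths not increasing at data line {i + 1} "
            f"(wavelength {wl[i]})"
        )
    mask = np.ones(wl.size, dtype=bool)
    if _EXCLUDED_KEY in meta and meta[_EXCLUDED_KEY]:
        for region in meta[_EXCLUDED_KEY].split(";"):
            lo_s, _, hi_s = region.partition(":")
            lo, hi = float(lo_s), float(hi_s)
            mask &= ~((wl >= lo) & (wl <= hi))
    grid = SpectralGrid(wl, mask)
    values = df[leaf_cols].to_numpy(dtype=float).T
    return SpectralLibrary(
        grid=grid,
        values=values,
        species_codes=tuple(k[0] for k in keys),
        leaf_ids=tuple(k[1] for k in keys),
    )
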