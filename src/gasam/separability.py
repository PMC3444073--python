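"""Jeffries-Matusita (J-M) class separability under a Gaussian model.

Each species on a band subset is modelled as multivariate Gaussian (sample
mean and covariance, ridge-regularised). The Bhattacharyya distance

    B = 1/8 (mu1-mu2)^T Sbar^-1 (mu1-mu2)
        + 1/2 ln( det Sbar / sqrt(det S1 det S2) ),   Sbar = (S1+S2)/2

maps to the saturating J-M distance JM = 2 (1 - exp(-B)) in [0, 2]. The
module also provides the random-band baseline comparison (Welch t-test per
species pair over per-chromosome J-M samples) and the normality /
variance-homogeneity assumption report.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectralLibrary

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-8


@dataclass(frozen=True)
class ClassModel:
    """Gaussian model of one species over the selected bands."""

    species_code: str
    mean: np.ndarray
    covariance: np.ndarray
    n: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        c = np.asarray(self.covariance, dtype=float)
        if c.shape != (m.size, m.size):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        if self.n < 2:
            raise ValueError("class model needs n >= 2 samples")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "covariance", c)


def fit_class_model(
    spectra_values: np.ndarray,
    bands: Sequence[int],
    ridge: float = DEFAULT_RIDGE,
    species_code: str = "?",
) -> ClassModel:
    """Sample mean and covariance (denominator n-1) over a band subset.

    ``ridge * I`` is added to the covariance; if the result is still not
    positive definite the ridge escalates tenfold (logged) until it is.
    """
    x = np.asarray(spectra_values, dtype=float)[:, list(bands)]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 spectra to fit a class model")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    r = ridge
    while True:
        candidate = cov + r * np.eye(cov.shape[0])
        try:
            np.linalg.cholesky(candidate)
            break
        except np.linalg.LinAlgError:
            r *= 10.0
            logger.info("ridge escalated to %.1e for species %s", r, species_code)
            if r > 1.0:
                raise
    return ClassModel(species_code=species_code, mean=mean, covariance=candidate, n=x.shape[0])


def _logdet(cov: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance has non-positive determinant")
    return float(val)


def bhattacharyya(m1: ClassModel, m2: ClassModel) -> float:
    """Gaussian Bhattacharyya distance between two class models."""
    if m1.mean.size != m2.mean.size:
        raise ValueError("models must share the band count")
    pooled = 0.5 * (m1.covariance + m2.covariance)
    d = m1.mean - m2.mean
    term_mean = 0.125 * float(d @ np.linalg.solve(pooled, d))
    term_cov = 0.5 * (_logdet(pooled) - 0.5 * (_logdet(m1.covariance) + _logdet(m2.covariance)))
    return term_mean + term_cov


def jm_from_b(b: float) -> float:
    """Map a Bhattacharyya distance to the J-M distance 2(1 - e^-B)."""
    return 2.0 * (1.0 - np.exp(-b))


def jm_distance(m1: ClassModel, m2: ClassModel) -> float:
    """Jeffries-Matusita distance in [0, 2] between two class models."""
    return jm_from_b(bhattacharyya(m1, m2))


def fit_all_models(
    lib: SpectralLibrary, bands: Sequence[int], ridge: float = DEFAULT_RIDGE
) -> dict[str, ClassModel]:
    return {
        s: fit_class_model(lib.species_values(s), bands, ridge=ridge, species_code=s)
        for s in lib.species
    }


def species_pairs(species: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered species pairs in deterministic alphabetical order."""
    return list(itertools.combinations(sorted(species), 2))


def pairwise_jm(
    lib: SpectralLibrary, bands: Sequence[int], ridge: float = DEFAULT_RIDGE
) -> pd.DataFrame:
    """J-M distance for every species pair on one band subset.

    Returns a DataFrame with columns ``species_a``, ``species_b``, ``jm``
    over all S(S-1)/2 pairs in alphabetical pair order.
    """
    if len(lib.species) < 2:
        raise ValueError("need at least 2 species")
    models = fit_all_models(lib, bands, ridge=ridge)
    rows = [
        {"species_a": a, "species_b": b, "jm": jm_distance(models[a], models[b])}
        for a, b in species_pairs(lib.species)
    ]
    return pd.DataFrame(rows)


def assumption_checks(
    lib: SpectralLibrary, bands: Sequence[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normality and variance-homogeneity report for the Gaussian model.

    Shapiro-Wilk per (species, band) — ``p`` is NaN (not applicable) for
    constant within-species values — and median-centred Levene per band
    across species. Report only; nothing is gated on the outcome.
    """
    bands = [int(b) for b in bands]
    norm_rows = []
    for s in lib.species:
        vals = lib.species_values(s)
        if vals.shape[0] < 3:
            raise ValueError("normality checks need >= 3 spectra per species")
        for b in bands:
            x = vals[:, b]
            if np.ptp(x) == 0.0:
                p = np.nan
            else:
                p = float(stats.shapiro(x).pvalue)
            norm_rows.append(
                {
                    "species": s,
                    "band_index": b,
                    "wavelength_um": float(lib.grid.wavelengths_um[b]),
                    "shapiro_p": p,
                }
            )
    lev_rows = []
    for b in bands:
        groups = [lib.species_values(s)[:, b] for s in lib.species]
        if all(np.ptp(g) == 0.0 for g in groups):
            p = np.nan  # no within-group spread: homogeneity test undefined
        else:
            p = float(stats.levene(*groups, center="median").pvalue)
        lev_rows.append(
            {
                "band_index": b,
                "wavelength_um": float(lib.grid.wavelengths_um[b]),
                "levene_p": p,
            }
        )
    return pd.DataFrame(norm_rows), pd.DataFrame(lev_rows)


@dataclass(frozen=True)
class SeparabilityReport:
    """Per-pair J-M comparison of selected vs random band subsets."""

    pairs: pd.DataFrame  # species_a, species_b, jm_ga_mean, jm_random_mean, t, p
    alpha: float
    n_ga: int
    n_random: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_significant(self) -> int:
        return int((self.pairs["p"] <= self.alpha).sum())

    def p_value_matrix(self) -> pd.DataFrame:
        """Upper-triangular per-pair p-value matrix (species x species)."""
        species = sorted(set(self.pairs["species_a"]) | set(self.pairs["species_b"]))
        mat = pd.DataFrame(np.nan, index=species, columns=species)
        for _, row in self.pairs.iterrows():
            mat.loc[row["species_a"], row["species_b"]] = row["p"]
        return mat


def _random_chromosomes(
    grid_valid: np.ndarray, k: int, n: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    return [
        tuple(sorted(int(i) for i in rng.choice(grid_valid, size=k, replace=False)))
        for _ in range(n)
    ]


def compare_jm(
    ga_chromosomes: Sequence[Sequence[int]],
    lib: SpectralLibrary,
    n_random: int,
    alpha: float = 0.05,
    ridge: float = DEFAULT_RIDGE,
    seed: int = 0,
) -> SeparabilityReport:
    """Welch-t comparison of J-M distances: selected vs random bands.

    For every species pair, the per-chromosome J-M distances over the
    winner chromosomes are compared with those over ``n_random`` uniformly
    drawn chromosomes of the same size (distinct valid bands each) by a
    Welch (unequal-variance) two-sample t-test. J-M is computed on the full
    library — all replicates — for covariance stability.
    """
    ga_list = [tuple(int(b) for b in ch) for ch in ga_chromosomes]
    if len(ga_list) < 2:
        raise ValueError("need at least 2 selected chromosomes")
    if n_random < 2:
        raise ValueError("need at least 2 random chromosomes")
    k = len(ga_list[0])
    rng = np.random.default_rng(seed)
    random_list = _random_chromosomes(lib.grid.valid_indices, k, n_random, rng)

    pairs = species_pairs(lib.species)
    jm_ga = np.zeros((len(ga_list), len(pairs)))
    jm_rand = np.zeros((len(random_list), len(pairs)))
    for out, chroms in ((jm_ga, ga_list), (jm_rand, random_list)):
        for i, ch in enumerate(chroms):
            models = fit_all_models(lib, ch, ridge=ridge)
            out[i] = [jm_distance(models[a], models[b]) for a, b in pairs]

    rows = []
    for j, (a, b) in enumerate(pairs):
        ga_sample = jm_ga[:, j]
        rand_sample = jm_rand[:, j]
        if np.ptp(ga_sample) == 0.0 and np.ptp(rand_sample) == 0.0:
            t, p = (0.0, 1.0) if ga_sample[0] == rand_sample[0] else (np.inf, 0.0)
        else:
            res = stats.ttest_ind(ga_sample, rand_sample, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "jm_ga_mean": float(ga_sample.mean()),
                "jm_random_mean": float(rand_sample.mean()),
                "t": t,
                "p": p,
            }
        )
    return SeparabilityReport(
        pairs=pd.DataFrame(rows), alpha=alpha, n_ga=len(ga_list), n_random=n_random
    )


def adjust_p_values(report: SeparabilityReport, method: str = "bonferroni") -> pd.DataFrame:
    """Optional multiple-testing adjustment ('bonferroni' or 'bh') of the
    per-pair p-values; the main report keeps raw p-values."""
    p = report.pairs["p"].to_numpy()
    m = p.size
    if method == "bonferroni":
        adj = np.minimum(p * m, 1.0)
    elif method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
    else:
        raise ValueError(f"unknown adjustment method: {method}")
    out = report.pairs.copy()
    out["p_adjusted"] = adj
    return out
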