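"""Phantom cohorts with known components, loads, and load-linked outcomes.

Every pipeline stage is testable without external data: components are
smooth Gaussian-blob maps on a masked grid, subject loads are Dirichlet or
gamma draws on the capped simplex, images are ``loads @ dictionary`` plus
nonnegative noise, and clinical outcomes are generated from the loads via
linear (Gaussian noise) or logistic links with an age covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

from voxnmf.clinical import ClinicalTable
from voxnmf.errors import ArgumentError, GenerationError
from voxnmf.imaging_io import MaskedGrid, VoxelMatrix, vectorize

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
MAX_COMPONENT_CORR = 0.6


@dataclass(frozen=True)
class OutcomeLink:
    """How a synthetic clinical outcome depends on age and loads."""

    name: str
    family: str  # "binary" | "continuous"
    intercept: float = 0.0
    age_coef: float = 0.0
    load_coefs: tuple = ()
    noise_sd: float = 1.0  # continuous only

    def __post_init__(self) -> None:
        if self.family not in ("binary", "continuous"):
            raise ArgumentError(f"bad family {self.family!r}")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    dictionary: np.ndarray  # (r, v)
    loads: np.ndarray  # (n, r)
    noise_sd: float
    links: tuple
    seed: int
    ages: np.ndarray = field(default=None)


def default_grid(size: int = 24) -> MaskedGrid:
    """Ellipsoidal mask inside a cubic grid (~5-6k voxels at size 24)."""
    ax = np.arange(size) - (size - 1) / 2.0
    i, j, k = np.meshgrid(ax, ax, ax, indexing="ij")
    semi = (size * 0.45, size * 0.42, size * 0.40)
    mask = (i / semi[0]) ** 2 + (j / semi[1]) ** 2 + (k / semi[2]) ** 2 <= 1.0
    return MaskedGrid.from_mask(mask)


def _blob_map(
    grid: MaskedGrid, centers: np.ndarray, fwhm_voxels: float
) -> np.ndarray:
    vol = np.zeros(grid.shape)
    for c in centers:
        vol[tuple(c)] += 1.0
    sigma = max(fwhm_voxels * _FWHM_TO_SIGMA, 0.5)
    vol = gaussian_filter(vol, sigma=sigma, mode="constant")
    flat = vectorize(vol, grid)
    m = flat.max()
    return flat / m if m > 0 else flat


def generate_components(
    grid: MaskedGrid,
    r: int,
    blob_count_per_component: int = 2,
    fwhm_voxels: float = 4.0,
    seed: int = 0,
    max_attempts: int = 100,
) -> np.ndarray:
    """Smooth nonnegative component maps with bounded pairwise correlation.

    Each component is a sum of Gaussian blobs at seeded random mask
    locations, max-normalized to 1. Components correlating >= 0.6 with an
    accepted one are resampled (up to ``max_attempts`` times each).
    """
    if r < 1:
        raise ArgumentError("r must be >= 1")
    if grid.n_voxels == 0:
        raise ArgumentError("mask is empty")
    rng = np.random.default_rng(seed)
    comps: list = []
    for _ in range(r):
        for attempt in range(max_attempts):
            idx = rng.integers(0, grid.n_voxels, size=blob_count_per_component)
            flat = _blob_map(grid, grid.voxel_index[idx], fwhm_voxels)
            if flat.std() == 0:
                continue
            if all(abs(np.corrcoef(flat, c)[0, 1]) < MAX_COMPONENT_CORR for c in comps):
                comps.append(flat)
                break
        else:
            raise GenerationError(
                f"could not place component {len(comps) + 1} with pairwise "
                f"correlation < {MAX_COMPONENT_CORR} in {max_attempts} attempts; "
                "use a larger mask or fewer components"
            )
    return np.vstack(comps)


def generate_loads(
    n: int,
    r: int,
    rng: np.random.Generator,
    distribution: str = "dirichlet",
    concentration: float = 1.0,
    gamma_shape: float = 2.0,
    gamma_scale: float = 1.0,
    fill: float = 0.85,
) -> np.ndarray:
    """Nonnegative load rows on the capped simplex (row sums <= ``fill``)."""
    if distribution == "dirichlet":
        L = rng.dirichlet(np.full(r, concentration), size=n) * fill
    elif distribution == "gamma":
        raw = rng.gamma(gamma_shape, gamma_scale, size=(n, r))
        sums = raw.sum(axis=1, keepdims=True)
        over = sums > 1.0
        raw = np.where(over, raw / sums * fill, raw * fill)
        L = raw
    else:
        raise ArgumentError(f"unknown load distribution {distribution!r}")
    return L


def generate_cohort(
    dictionary: np.ndarray,
    n: int,
    grid: MaskedGrid,
    noise_sd: float = 0.0,
    load_distribution: str = "dirichlet",
    concentration: float = 1.0,
    age_range: tuple = (55.0, 85.0),
    outcome_links: Sequence[OutcomeLink] = (),
    seed: int = 0,
    modality: str = "MRI",
    id_prefix: str = "sub",
) -> tuple[VoxelMatrix, ClinicalTable, SyntheticTruth]:
    """Draw a full phantom cohort from a known dictionary.

    ``X = L @ D + noise`` with truncated-Gaussian noise clipped at zero;
    binary outcomes are Bernoulli draws through a logistic link on
    (age, loads), continuous outcomes are linear with Gaussian noise.
    """
    if noise_sd < 0:
        raise ArgumentError("noise_sd must be >= 0")
    D = np.asarray(dictionary, float)
    r = D.shape[0]
    rng = np.random.default_rng(seed)
    L = generate_loads(n, r, rng, distribution=load_distribution, concentration=concentration)
    X = L @ D
    if noise_sd > 0:
        X = np.clip(X + rng.normal(0.0, noise_sd, size=X.shape), 0.0, None)
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(n)]
    matrix = VoxelMatrix(values=X, subject_ids=ids, modality=modality, grid=grid)

    ages = rng.uniform(*age_range, size=n)
    clin = {"age": ages}
    binary, continuous = [], []
    for link in outcome_links:
        coefs = np.asarray(link.load_coefs, float)
        if coefs.shape != (r,):
            raise ArgumentError(
                f"outcome {link.name!r}: expected {r} load coefficients, got {coefs.shape}"
            )
        eta = link.intercept + link.age_coef * ages + L @ coefs
        if link.family == "binary":
            clin[link.name] = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
            binary.append(link.name)
        else:
            clin[link.name] = eta + rng.normal(0.0, link.noise_sd, size=n)
            continuous.append(link.name)
    table = ClinicalTable(
        pd.DataFrame(clin, index=pd.Index(ids, name="subject_id")), binary, continuous
    )
    truth = SyntheticTruth(
        dictionary=D, loads=L, noise_sd=noise_sd, links=tuple(outcome_links),
        seed=seed, ages=ages,
    )
    return matrix, table, truth


def match_components(D_est: np.ndarray, D_true: np.ndarray):
    """Optimal one-to-one matching of estimated to true components.

    Maximizes total Pearson correlation over the assignment; zero-variance
    estimated rows are flagged as unmatched (correlation NaN).

    Returns ``(assignment, correlations)`` where ``assignment[i]`` is the
    true-component index matched to estimated row ``i``.
    """
    D_est = np.asarray(D_est, float)
    D_true = np.asarray(D_true, float)
    if D_est.shape[1] != D_true.shape[1]:
        raise ArgumentError("component maps must have equal voxel counts")
    if D_est.shape[0] > D_true.shape[0]:
        raise ArgumentError("more estimated than true components")
    valid_est = D_est.std(axis=1) > 0
    corr = np.full((D_est.shape[0], D_true.shape[0]), -1.0)
    for i in np.flatnonzero(valid_est):
        for j in range(D_true.shape[0]):
            if D_true[j].std() > 0:
                corr[i, j] = np.corrcoef(D_est[i], D_true[j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    assignment = np.full(D_est.shape[0], -1, dtype=int)
    matched_corr = np.full(D_est.shape[0], np.nan)
    for i, j in zip(rows, cols):
        assignment[i] = j
        if valid_est[i]:
            matched_corr[i] = corr[i, j]
    return assignment, matched_corr
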