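"""Rank selection by repeated k-fold cross-validated reconstruction error.

For every candidate rank, the subjects are split into ``k`` folds, the NMF
is fit on the k-1 discovery folds, the held-out fold is projected onto the
fitted dictionary, and the mean absolute reconstruction error is recorded
for both sides. The whole split-and-fit cycle is repeated ``m`` times with
fresh random folds, yielding ``k * m`` (discovery, hold-out) error pairs per
rank — 25 pairs under the default 5-fold / 5-repeat setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from voxnmf.errors import ArgumentError
from voxnmf.minvol_nmf import (
    NMFConfig,
    fit_minvol_nmf,
    project_loads,
    reconstruction_mae,
)


@dataclass
class RankScanResult:
    """Per-rank paired CV reconstruction errors plus the chosen rank."""

    ranks: list
    errors: pd.DataFrame  # columns: rank, repeat, fold, discovery_mae, holdout_mae
    chosen_rank: int
    rule: str = "one-standard-error"

    def pairs_for_rank(self, rank: int) -> pd.DataFrame:
        return self.errors[self.errors["rank"] == rank]

    def holdout_means(self) -> pd.Series:
        return self.errors.groupby("rank")["holdout_mae"].mean().loc[self.ranks]

    def to_csv(self, path) -> None:
        self.errors.to_csv(path, index=False)


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels, sizes differing by at most one."""
    labels = np.tile(np.arange(k), n // k + 1)[:n]
    rng.shuffle(labels)
    return labels


def cv_rank_scan(
    X,
    ranks,
    k: int = 5,
    m: int = 5,
    config_template: NMFConfig | None = None,
    seed: int = 0,
) -> RankScanResult:
    """Scan candidate ranks with repeated k-fold CV reconstruction error.

    Every (rank, repeat, fold) fit uses a deterministic seed offset from
    ``seed`` so the scan is reproducible yet fits are independent.
    """
    from voxnmf.minvol_nmf import _values

    Xv = _values(X)
    n = Xv.shape[0]
    ranks = [int(r) for r in ranks]
    if not ranks:
        raise ArgumentError("ranks must be nonempty")
    if k < 2 or n < k:
        raise ArgumentError(f"need n >= k >= 2, got n={n}, k={k}")
    largest_fold = n // k + (1 if n % k else 0)
    discovery_min = n - largest_fold  # smallest discovery set the scan will fit on
    for r in ranks:
        if r > min(discovery_min, Xv.shape[1]):
            raise ArgumentError(
                f"rank {r} infeasible for discovery folds of size >= {discovery_min} "
                f"and {Xv.shape[1]} voxels"
            )
    if config_template is None:
        config_template = NMFConfig(rank=ranks[0])

    records = []
    for repeat in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, repeat]))
        folds = _fold_assignments(n, k, rng)
        for ri, rank in enumerate(ranks):
            for fold in range(k):
                hold = folds == fold
                fit_seed = int(
                    np.random.SeedSequence([seed, repeat, ri, fold]).generate_state(1)[0]
                    % (2**31)
                )
                cfg = config_template.replace(rank=rank, seed=fit_seed)
                model, summary = fit_minvol_nmf(Xv[~hold], cfg)
                L_hold = project_loads(Xv[hold], model.dictionary)
                records.append(
                    {
                        "rank": rank,
                        "repeat": repeat,
                        "fold": fold,
                        "discovery_mae": summary.reconstruction_mae,
                        "holdout_mae": reconstruction_mae(
                            Xv[hold], L_hold, model.dictionary
                        ),
                    }
                )
    errors = pd.DataFrame.from_records(records)
    result = RankScanResult(ranks=ranks, errors=errors, chosen_rank=ranks[0])
    result.chosen_rank = choose_rank(result)
    return result


def choose_rank(result: RankScanResult) -> int:
    """One-standard-error rule toward smaller ranks.

    Returns the smallest rank whose mean hold-out MAE lies within one
    standard error of the global minimum mean, where the SE is computed over
    the error pairs at the minimizing rank.
    """
    if result.errors.empty:
        raise ArgumentError("empty rank-scan result")
    grouped = result.errors.groupby("rank")["holdout_mae"]
    means = grouped.mean()
    best_rank = means.idxmin()
    vals = grouped.get_group(best_rank).to_numpy()
    se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    threshold = float(means.loc[best_rank]) + se
    for rank in sorted(result.ranks):
        if float(means.loc[rank]) <= threshold:
            return int(rank)
    return int(best_rank)
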