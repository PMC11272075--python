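"""Back-projection of prediction-model slopes into voxel space.

Each component's voxel-weight map is scaled by that component's regression
slope and the scaled maps are summed, giving a single signed 3D image that
shows the magnitude and direction of every voxel's contribution to the
model's prediction. Age and intercept terms are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from voxnmf.clinical import PredictionModel
from voxnmf.errors import DimensionError
from voxnmf.imaging_io import MaskedGrid, devectorize, save_volume


@dataclass
class CoefficientMap:
    """Signed voxel map of slope-weighted component contributions."""

    volume: np.ndarray
    grid: MaskedGrid
    outcome: str
    modalities: tuple

    def save(self, path) -> None:
        save_volume(self.volume, self.grid, path)


def combine_slopes_with_dictionary(slopes: np.ndarray, dictionary: np.ndarray) -> np.ndarray:
    """Flat map ``sum_j slope_j * D[j, :]``."""
    slopes = np.asarray(slopes, float)
    dictionary = np.asarray(dictionary, float)
    if slopes.ndim != 1 or slopes.shape[0] != dictionary.shape[0]:
        raise DimensionError(
            f"{slopes.shape[0] if slopes.ndim == 1 else slopes.shape} slopes for "
            f"{dictionary.shape[0]} dictionary rows"
        )
    return slopes @ dictionary


def build_coefficient_map(
    model: PredictionModel,
    dictionary: np.ndarray,
    grid: MaskedGrid,
    prefix: str | None = None,
    original_scale: bool = False,
) -> CoefficientMap:
    """Back-project a model's component slopes through the dictionary.

    Slopes are taken on the standardized-predictor scale by default (so
    magnitudes are comparable across components); ``original_scale=True``
    switches to raw-predictor slopes. ``prefix`` selects one modality's load
    columns when the model was fit on a combined design.
    """
    slopes = model.component_slopes(prefix=prefix, original_scale=original_scale)
    flat = combine_slopes_with_dictionary(slopes.to_numpy(), dictionary)
    return CoefficientMap(
        volume=devectorize(flat, grid, fill=0.0),
        grid=grid,
        outcome=model.outcome.name,
        modalities=model.modalities,
    )
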