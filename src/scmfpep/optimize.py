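"""Grid search over the four free mean-field parameters.

The model has four free parameters — damping memory lam, rotamer-count
exponent gamma, energy truncation threshold, and temperature kT.  They are
tuned by running the full prediction (without background enrichment) on
one or more calibration ensembles, averaging all position rows into a
single 20-component amino-acid composition, and ranking parameter
combinations by cosine distance to a known target background composition:
a good parameter set should reproduce generic amino-acid usage on
non-specific complexes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import predict_specificity
from .interaction_model import InteractionGraph, SpecificityProfile, ValidationError
from .scmf import MFParameters

__all__ = ["ParameterGrid", "grid_search"]


@dataclass(frozen=True)
class ParameterGrid:
    """Candidate values for each free parameter.

    The defaults are the canonical calibration grid: 3 x 6 x 6 x 5 = 540
    combinations.
    """

    lam_values: tuple[float, ...] = (0.25, 0.5, 0.75)
    gamma_values: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    threshold_values: tuple[float, ...] = (5.0, 10.0, 50.0, 100.0, 250.0, 500.0)
    kT_values: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)

    def __post_init__(self) -> None:
        for name in ("lam_values", "gamma_values", "threshold_values", "kT_values"):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty")

    def combinations(self):
        """Cartesian product in fixed (lam, gamma, threshold, kT) order."""
        return itertools.product(
            self.lam_values, self.gamma_values, self.threshold_values, self.kT_values
        )

    def __len__(self) -> int:
        return (
            len(self.lam_values)
            * len(self.gamma_values)
            * len(self.threshold_values)
            * len(self.kT_values)
        )


def _mean_composition(profiles: Sequence[SpecificityProfile]) -> np.ndarray:
    rows = np.vstack([p.freq for p in profiles])
    return rows.mean(axis=0)


def grid_search(
    ensembles: Sequence[Sequence[InteractionGraph]],
    target_background: SpecificityProfile,
    grid: ParameterGrid | None = None,
    base_params: MFParameters | None = None,
) -> pd.DataFrame:
    """Rank parameter combinations by cosine distance to a target composition.

    For every (lam, gamma, threshold, kT) combination, each calibration
    ensemble is predicted without enrichment; all position rows of all
    predicted profiles are averaged into one 20-vector, and the score is
    ``1 - cosine`` between that vector and the position-averaged target
    background.  Lower is better.  The returned table is sorted ascending
    by score with ties broken by grid order (stable), so the ranking is
    fully deterministic.  A failing combination is recorded with a NaN
    score and its error message rather than aborting the search.
    """
    if grid is None:
        grid = ParameterGrid()
    if base_params is None:
        base_params = MFParameters()
    if not ensembles:
        raise ValidationError("need at least one calibration ensemble")
    target = _mean_composition([target_background])
    target = target / np.linalg.norm(target)

    records = []
    for order, (lam, gamma, threshold, kT) in enumerate(grid.combinations()):
        params = base_params.replace(
            lam=lam, gamma=gamma, threshold=threshold, kT=kT
        )
        try:
            profiles = [
                predict_specificity(list(graphs), params).profile
                for graphs in ensembles
            ]
            composition = _mean_composition(profiles)
            score = 1.0 - float(
                composition @ target / np.linalg.norm(composition)
            )
            error = ""
        except Exception as exc:  # recorded per combination, not fatal
            score, error = np.nan, f"{type(exc).__name__}: {exc}"
        records.append(
            {
                "lam": lam,
                "gamma": gamma,
                "threshold": threshold,
                "kT": kT,
                "score": score,
                "error": error,
                "_order": order,
            }
        )

    table = pd.DataFrame.from_records(records)
    table = table.sort_values(
        ["score", "_order"], kind="mergesort", na_position="last"
    ).drop(columns="_order")
    return table.reset_index(drop=True)
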