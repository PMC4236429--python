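"""Tables behind the model's three summary figures.

The contract is the table, not the plot: each function returns a pandas
DataFrame that is deterministic given its parameters and can be written as
TSV.  ``fig2`` shows how central and peripheral tolerance shape
self-reactivity across abundances; ``fig3`` shows baseline versus
over-expressed targeting probabilities (the tumor-detection construction);
``fig4`` traces the discrimination-ability/MDI trade-off and its operating
regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ModelParams
from .targeting import (
    DEFAULT_REGION_BOUNDARIES,
    classify_region,
    discrimination_ability,
    fold_change_targeting_prob,
    minimum_detectable_increment,
)
from .tolerance import (
    efficient_presentation_prob,
    targeting_probability_central,
    tolerance_probability,
)

__all__ = ["figure_data"]


def _fig2(params: ModelParams, log10_range: tuple[float, float], n_points: int) -> pd.DataFrame:
    a = np.logspace(log10_range[0], log10_range[1], n_points)
    untolerated = 1.0 - tolerance_probability(a, params.t0, params.m)
    presented = efficient_presentation_prob(a, params.N, params.n_star, mode="exact")
    central_only = targeting_probability_central(a, params.t0, params.m)
    return pd.DataFrame(
        {
            "abundance": a,
            "untolerated_prob": untolerated,
            "efficient_presentation_prob": presented,
            "targeting_prob_no_peripheral": central_only,
            "targeting_prob": central_only * presented,
        }
    )


def _fig3(
    params: ModelParams,
    points: list[tuple[float, float]],
    log10_range: tuple[float, float],
    n_points: int,
) -> pd.DataFrame:
    a_star = params.a_star
    if a_star is None:
        raise ValueError("fig3 requires n_star and N (the threshold a*)")
    grid = np.logspace(log10_range[0], log10_range[1], n_points)
    baseline = pd.DataFrame(
        {
            "kind": "baseline",
            "basal_abundance": grid,
            "fold_change": 1.0,
            "abundance": grid,
            "targeting_prob_no_peripheral": targeting_probability_central(
                grid, params.t0, params.m
            ),
            "targeting_prob": fold_change_targeting_prob(grid, 1.0, params),
        }
    )
    rows = []
    for a_basal, k in points:
        rows.append(
            {
                "kind": "overexpressed",
                "basal_abundance": a_basal,
                "fold_change": k,
                "abundance": k * a_basal,
                "targeting_prob_no_peripheral": targeting_probability_central(
                    np.asarray(k * a_basal), params.t0, params.m, a_basal=np.asarray(a_basal)
                ),
                "targeting_prob": fold_change_targeting_prob(a_basal, k, params),
            }
        )
    table = pd.concat([baseline, pd.DataFrame(rows)], ignore_index=True)
    table["detectable"] = table["abundance"] >= a_star
    return table


def _fig4(
    mdi_grid: np.ndarray, m: int, boundaries: tuple[float, float]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "MDI": mdi_grid,
            "delta": [discrimination_ability(x, m) for x in mdi_grid],
            "region": [classify_region(x, boundaries) for x in mdi_grid],
        }
    )


def figure_data(
    which: str,
    params: ModelParams | None = None,
    *,
    points: list[tuple[float, float]] | None = None,
    mdi_grid=None,
    log10_range: tuple[float, float] = (-6.0, -1.0),
    n_points: int = 200,
    region_boundaries: tuple[float, float] = DEFAULT_REGION_BOUNDARIES,
) -> pd.DataFrame:
    """Deterministic table for one of the three model figures.

    ``fig2``: tolerance and presentation curves over a log-abundance grid.
    ``fig3``: baseline targeting curve plus over-expressed ``(a_basal, k)``
    points with detectability flags; defaults to the canonical MDI = a*.t0
    construction point (the antigen at a^max raised by exactly the MDI).
    ``fig4``: discrimination ability and operating region over an MDI grid
    (default 1..1000, log-spaced).
    """
    if which == "fig2":
        if params is None:
            raise ValueError("fig2 requires params")
        return _fig2(params, log10_range, n_points)
    if which == "fig3":
        if params is None:
            raise ValueError("fig3 requires params")
        if points is None:
            a_max = 1.0 / params.t0
            points = [(a_max, minimum_detectable_increment(params))]
        return _fig3(params, points, log10_range, n_points)
    if which == "fig4":
        m = params.m if params is not None else 1
        if mdi_grid is None:
            mdi_grid = np.concatenate([[1.0], np.logspace(0.01, 3, n_points - 1)])
        return _fig4(np.asarray(mdi_grid, dtype=float), m, region_boundaries)
    raise ValueError(f"unknown figure {which!r}; choose fig2, fig3 or fig4")
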