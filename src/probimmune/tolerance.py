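"""Central and peripheral tolerance closed forms.

Central tolerance (thymic negative selection): during maturation a
self-reactive lymphocyte experiences ``t0`` antigen presentations, each
landing on its cognate antigen with probability equal to that antigen's
effective abundance ``a_i``.  The clone is deleted if it sees its cognate
antigen at least once, so with ``m`` naive clones per self antigen the
probability that antigen ``A_i`` ends up tolerated is

    f_i = (1 - exp(-a_i * t0)) ** m

(the Poisson zero-count approximation to the exact binomial survival).

Peripheral tolerance (efficient-presentation threshold): activation needs
at least ``n*`` MHC-peptide-TCR complexes on one APC with ``N`` slots, so
an antigen is efficiently presented only above the abundance threshold
``a* = n*/N``.  The exact probability of occupying >= n* slots is the
Poisson survival function at rate ``a_i * N``; for moderately large ``N``
this is well approximated by a Heaviside step at ``a*``.

All functions accept scalars or numpy arrays for the abundance argument.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import stats

from .environment import AntigenEnvironment
from .params import DerivedQuantities, ModelParams

__all__ = [
    "tolerance_probability",
    "presentation_count_pmf",
    "targeting_probability_central",
    "riskiest_abundance",
    "efficient_presentation_prob",
    "presentation_threshold",
    "targeting_probability",
    "derive",
]


def _check_abundance(a, name: str = "a_i") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return a


def _check_counts(**kw) -> None:
    for name, v in kw.items():
        if v is None or v < 1 or int(v) != v:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")


def tolerance_probability(a_i, t0: int, m: int = 1):
    """Probability f_i that self antigen with abundance ``a_i`` is tolerated.

    ``f_i = (1 - exp(-a_i t0))^m``: all ``m`` naive clones reactive to the
    antigen must be negatively selected.  Monotone increasing in each of
    ``a_i``, ``t0`` and ``m``.  For ``a_i * t0`` beyond the exp underflow
    range the exact limit 1 is returned.
    """
    a = _check_abundance(a_i)
    _check_counts(t0=t0, m=m)
    out = (-np.expm1(-a * t0)) ** m
    return out if out.ndim else float(out)


def presentation_count_pmf(a_i, t0: int, k, count_model: str = "binomial"):
    """Probability that an antigen is presented exactly ``k`` times in ``t0``.

    ``binomial`` is the exact distribution of per-antigen presentation
    counts; ``poisson`` is the large-``t0`` approximation at rate
    ``a_i * t0``.
    """
    a = _check_abundance(a_i)
    _check_counts(t0=t0)
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("presentation count k must be >= 0")
    if count_model == "binomial":
        if np.any(k > t0):
            raise ValueError("binomial presentation count k cannot exceed t0")
        out = stats.binom.pmf(k, t0, a)
    elif count_model == "poisson":
        out = stats.poisson.pmf(k, a * t0)
    else:
        raise ValueError(f"unknown count_model {count_model!r}")
    out = np.asarray(out)
    return out if out.ndim else float(out)


def _one_minus_f(a, t0: int, m: int):
    # 1 - (1 - e^{-a t0})^m, stable for tiny e^{-a t0}
    with np.errstate(divide="ignore"):
        log1p_term = np.log1p(-np.exp(-np.asarray(a, dtype=float) * t0))
    return -np.expm1(m * log1p_term)


def targeting_probability_central(a_i, t0: int, m: int = 1, a_basal=None):
    """Probability of erroneously targeting a self antigen, central tolerance only.

    ``1 - (1 - a_i (1 - f_i))^m`` with the tolerance probability ``f_i``
    evaluated at the basal abundance (``a_basal``, defaulting to ``a_i``).
    For ``m = 1`` this reduces to ``a_i * exp(-a_i t0)``.
    """
    a = _check_abundance(a_i)
    _check_counts(t0=t0, m=m)
    basal = a if a_basal is None else _check_abundance(a_basal, "a_basal")
    q = a * _one_minus_f(basal, t0, m)
    with np.errstate(divide="ignore"):
        out = -np.expm1(m * np.log1p(-q))
    return out if out.ndim else float(out)


def riskiest_abundance(t0: int, m: int = 1) -> float:
    """Abundance a^max = 1/(t0 m) maximizing the central-only targeting risk.

    Exact maximizer of the targeting probability for ``m = 1``; for
    ``m > 1`` it is the stated closed form, which grid searches show to be
    accurate only to within a factor ~2 of the numerical argmax.
    """
    _check_counts(t0=t0, m=m)
    return 1.0 / (t0 * m)


def efficient_presentation_prob(a_i, N: int, n_star: int, mode: str = "exact"):
    """Probability that an antigen occupies at least ``n*`` of ``N`` MHC slots.

    ``exact``: Poisson survival function at rate ``a_i * N`` (the printed
    finite sum is the complementary Poisson CDF; computed through scipy's
    survival-function primitive for numerical stability).  ``step``:
    Heaviside approximation, 0 below ``a* = n*/N`` and 1 at or above it.
    """
    a = _check_abundance(a_i)
    _check_counts(N=N, n_star=n_star)
    if n_star > N:
        raise ValueError("n_star cannot exceed N")
    if mode == "exact":
        out = stats.poisson.sf(n_star - 1, a * N)
    elif mode == "step":
        out = (a >= n_star / N).astype(float)
    else:
        raise ValueError(f"unknown presentation mode {mode!r}")
    out = np.asarray(out)
    return out if out.ndim else float(out)


def presentation_threshold(N: int, n_star: int) -> float:
    """Efficient-presentation threshold a* = n*/N."""
    _check_counts(N=N, n_star=n_star)
    if n_star > N:
        raise ValueError("n_star cannot exceed N")
    return n_star / N


def targeting_probability(a_i, params: ModelParams, a_basal=None):
    """Probability of targeting an antigen under central + peripheral tolerance.

    ``step`` mode (default): zero below ``a*``, the central-only form at or
    above it.  ``exact`` mode: central-only form times the Poisson
    efficient-presentation probability.  Tolerance is evaluated at the
    basal abundance.
    """
    a = _check_abundance(a_i)
    if params.n_star is None or params.N is None:
        raise ValueError("params must define n_star and N for peripheral tolerance")
    central = targeting_probability_central(a, params.t0, params.m, a_basal=a_basal)
    gate = efficient_presentation_prob(a, params.N, params.n_star, mode=params.presentation_mode)
    out = np.asarray(central) * np.asarray(gate)
    return out if out.ndim else float(out)


def derive(
    env: AntigenEnvironment,
    params: ModelParams,
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
):
    """Per-antigen analytic table plus scalar summary for an environment.

    Returns ``(table, DerivedQuantities)`` where the table has one row per
    antigen with its tolerance probability, efficient-presentation
    probability and targeting probability.  Pathogen antigens are never
    tolerated (the naive repertoire recognizes virtually everything), so
    their ``f_i`` is zero.  Optionally writes the table as TSV and the
    summary as JSON.
    """
    table = env.to_frame()
    f = np.where(
        env.self_mask,
        tolerance_probability(env.basal_abundances, params.t0, params.m),
        0.0,
    )
    # basal=0 for pathogens gives f=0 through the formula as well; keep explicit
    basal = np.where(env.self_mask, env.basal_abundances, 0.0)
    table["f_i"] = f
    table["efficient_presentation_prob"] = efficient_presentation_prob(
        env.abundances, params.N, params.n_star, mode=params.presentation_mode
    )
    table["targeting_prob"] = targeting_probability(env.abundances, params, a_basal=basal)

    summary = DerivedQuantities(
        a_star=params.a_star,
        a_max=riskiest_abundance(params.t0, params.m),
    )
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    return table, summary
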