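"""Pathogen targeting, bystander autoimmunity and tumor detection.

The *correct targeting ratio* R compares the probability of targeting a
pathogen antigen (effective abundance ``p``, assumed at or above the
efficient-presentation threshold ``a*``) with the probability of targeting
the riskiest self antigen, the one sitting at ``a*``:

    R = p / ((1 - p) * [1 - (1 - a* (1 - f*))^m]),   f* = (1 - e^{-a* t0})^m

For ``m = 1`` this is exactly ``p e^{a* t0} / ((1 - p) a*)``.  In the least
favorable regime (``p = a*``, small abundances) it reduces to
``R ≈ e^{K s n*}``, which for physiological parameter values exceeds 1e20:
pathogen targeting is extremely reliable.  All ratios are computed in log
space; linear-space accessors exponentiate (and may overflow to inf for
extreme parameters, which is meaningful).

Tumor detection: a self antigen with basal abundance below ``a*`` becomes
visible only after a fold-increase ``k`` with ``k a_i >= a*``.  The most
change-sensitive antigens sit at ``a^max = 1/t0``, defining the minimum
detectable increment ``MDI = a*/a^max = a* t0 = K s n*``.  The
discrimination ability Δ quantifies the certainty that detecting such an
antigen reflects a true abundance change rather than chance presentation;
for ``m = 1`` it is exactly ``tanh((MDI - 1)/2)``.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParams
from .tolerance import _one_minus_f

__all__ = [
    "log_correct_targeting_ratio",
    "correct_targeting_ratio",
    "approx_correct_targeting_ratio",
    "lower_bound_ratio",
    "log_lower_bound_ratio",
    "raised_self_targeting_ratio",
    "fold_change_targeting_prob",
    "minimum_detectable_increment",
    "discrimination_ability",
    "discrimination_complement",
    "classify_region",
]

DEFAULT_REGION_BOUNDARIES = (3.0, 20.0)


def _log_targeting_bracket(a_eff: float, a_basal: float, t0: int, m: int) -> float:
    """log of 1 - (1 - a_eff (1 - f(a_basal)))^m, stable for tiny arguments."""
    q = a_eff * float(np.asarray(_one_minus_f(a_basal, t0, m)))
    if q <= 0:
        return -math.inf
    if q >= 1:
        return 0.0
    # -expm1(m log1p(-q)) can underflow only if q does; log it directly
    return math.log(-math.expm1(m * math.log1p(-q)))


def log_correct_targeting_ratio(p: float, a_star: float, t0: int, m: int = 1) -> float:
    """log R for a pathogen at abundance p versus the riskiest self antigen.

    Exact quotient; no order-of-magnitude truncation.  Returns ``-inf``
    (R = 0) when ``p < a*``: the pathogen sits below the
    efficient-presentation threshold and is invisible to the adaptive
    system, so any response hits a self antigen.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"pathogen abundance p must lie in (0, 1), got {p!r}")
    if not 0.0 < a_star < 1.0:
        raise ValueError(f"a_star must lie in (0, 1), got {a_star!r}")
    if p < a_star:
        return -math.inf
    return math.log(p) - math.log1p(-p) - _log_targeting_bracket(a_star, a_star, t0, m)


def correct_targeting_ratio(p: float, a_star: float, t0: int, m: int = 1) -> float:
    """R = Pr{pathogen targeted} / Pr{self antigen at a* targeted}.

    Linear-space accessor for :func:`log_correct_targeting_ratio`;
    R = 0 when the pathogen is below the presentation threshold.
    """
    logr = log_correct_targeting_ratio(p, a_star, t0, m)
    if logr == -math.inf:
        return 0.0
    return math.exp(logr) if logr < 709 else math.inf


def approx_correct_targeting_ratio(p: float, a_star: float, t0: int, m: int = 1) -> float:
    """Truncated form R ≈ p e^{a* t0} / ((1-p) a* m^2).

    Kept separate for comparison only; the exact quotient is authoritative.
    """
    if not 0.0 < p < 1.0 or not 0.0 < a_star < 1.0:
        raise ValueError("p and a_star must lie in (0, 1)")
    log_r = math.log(p) - math.log1p(-p) + a_star * t0 - math.log(a_star) - 2 * math.log(m)
    return math.exp(log_r) if log_r < 709 else math.inf


def log_lower_bound_ratio(K: int, s: float, n_star: int) -> float:
    """log of the least-favorable-scenario ratio, K*s*n*."""
    if K < 1 or n_star < 1:
        raise ValueError("K and n_star must be >= 1")
    if not 0.0 < s <= 1.0:
        raise ValueError(f"s must lie in (0, 1], got {s!r}")
    return K * s * n_star


def lower_bound_ratio(K: int, s: float, n_star: int) -> float:
    """R ≈ e^{K s n*}: correct targeting ratio when p is as low as a*."""
    lr = log_lower_bound_ratio(K, s, n_star)
    return math.exp(lr) if lr < 709 else math.inf


def raised_self_targeting_ratio(
    p: float,
    a_basal: float,
    a_new: float,
    t0: int,
    m: int = 1,
    a_star: float | None = None,
) -> float:
    """Correct targeting ratio against a self antigen raised from a_basal to a_new.

    Tolerance is evaluated at the basal abundance (it was induced before
    the change), while exposure uses the raised abundance.  If ``a_star``
    is given and ``a_new`` is still below it, the self antigen remains
    invisible and the ratio is ``inf``.  With ``a_basal = 1/t0`` (the most
    change-sensitive antigen) and ``a_new = p = a*`` the ratio is
    ``e/(1 - a*) ≈ 3``: bystander autoimmunity against infection-raised
    self antigens is only about three times less likely than correct
    pathogen targeting.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"pathogen abundance p must lie in (0, 1), got {p!r}")
    for name, v in (("a_basal", a_basal), ("a_new", a_new)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    if a_star is not None and a_new < a_star:
        return math.inf
    log_bracket = _log_targeting_bracket(a_new, a_basal, t0, m)
    logr = math.log(p) - math.log1p(-p) - log_bracket
    return math.exp(logr) if logr < 709 else math.inf


def fold_change_targeting_prob(a_i, k: float, params: ModelParams, a_star: float | None = None):
    """Probability of targeting a self antigen after a k-fold abundance increase.

    Zero while ``k a_i`` stays below the threshold ``a*``; otherwise
    ``1 - (1 - k a_i (1 - f_i))^m`` with tolerance ``f_i`` at the basal
    abundance ``a_i``.  ``k = 1`` recovers the step-mode targeting
    probability.
    """
    if k <= 0:
        raise ValueError(f"fold factor k must be positive, got {k!r}")
    a = np.asarray(a_i, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("a_i must lie in [0, 1]")
    if np.any(k * a > 1):
        raise ValueError("k * a_i exceeds 1: not a valid effective abundance")
    if a_star is None:
        a_star = params.a_star
    if a_star is None:
        raise ValueError("an efficient-presentation threshold a* is required")
    q = k * a * np.asarray(_one_minus_f(a, params.t0, params.m))
    with np.errstate(divide="ignore"):
        prob = -np.expm1(params.m * np.log1p(-q))
    out = np.where(k * a < a_star, 0.0, prob)
    return out if out.ndim else float(out)


def minimum_detectable_increment(
    params: ModelParams | None = None,
    *,
    a_star: float | None = None,
    t0: int | None = None,
    K: int | None = None,
    s: float | None = None,
    n_star: int | None = None,
    rtol: float = 1e-9,
) -> float:
    """MDI = a*/a^max: fold increase needed to expose the most sensitive antigen.

    Computed as ``a* * t0`` when those are available, or equivalently as
    ``K * s * n*`` (the two coincide algebraically through ``t0 = K N s``
    and ``a* = n*/N``).  If both parameterizations are supplied they must
    agree to relative tolerance ``rtol``.
    """
    if params is not None:
        a_star = params.a_star if a_star is None else a_star
        t0 = params.t0 if t0 is None else t0
        K, s, n_star = K or params.K, s or params.s, n_star or params.n_star
    via_at = a_star * t0 if (a_star is not None and t0 is not None) else None
    via_ksn = K * s * n_star if None not in (K, s, n_star) else None
    if via_at is None and via_ksn is None:
        raise ValueError("need (a_star, t0) or (K, s, n_star) to compute the MDI")
    if via_at is not None and via_ksn is not None:
        if abs(via_at - via_ksn) > rtol * max(via_at, via_ksn):
            raise ValueError(
                f"inconsistent parameters: a*.t0 = {via_at} but K.s.n* = {via_ksn}"
            )
    return via_at if via_at is not None else via_ksn


def _delta_quotient(mdi: float, m: int) -> float:
    """δ = (1 - (1-e^{-1})^m) / (1 - (1-e^{-MDI})^m), in log space."""
    log_num = math.log(-math.expm1(m * math.log1p(-math.exp(-1.0))))
    log_den = math.log(-math.expm1(m * math.log1p(-math.exp(-min(mdi, 745.0)))))
    return math.exp(log_num - log_den)


def discrimination_ability(mdi: float, m: int = 1) -> float:
    """Discrimination ability Δ in [0, 1).

    Certainty that a detected self antigen reflects a true abundance
    change rather than chance presentation.  For ``m = 1``,
    ``Δ = (e^{MDI-1} - 1)/(e^{MDI-1} + 1) = tanh((MDI-1)/2)`` exactly; for
    ``m > 1`` the quotient form ``Δ = (δ-1)/(δ+1)`` with
    ``δ = (1-(1-e^{-1})^m)/(1-(1-e^{-MDI})^m)`` (terms of order a*^2
    discarded).  Independent of the other model parameters.
    """
    if mdi < 1:
        raise ValueError(f"MDI must be >= 1, got {mdi!r}")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return math.tanh((mdi - 1.0) / 2.0)
    d = _delta_quotient(mdi, m)
    return (d - 1.0) / (d + 1.0)


def discrimination_complement(mdi: float, m: int = 1) -> float:
    """1 - Δ, computed without catastrophic cancellation.

    For large MDI the complement is ~2 e^{-(MDI-1)} (m = 1), far below
    float resolution of ``1 - discrimination_ability(...)``; e.g. at
    MDI = 50 it is ~1e-21.
    """
    if mdi < 1:
        raise ValueError(f"MDI must be >= 1, got {mdi!r}")
    if m == 1:
        # 1 - tanh(x/2) = 2 / (e^x + 1) with x = MDI - 1
        x = mdi - 1.0
        return 2.0 * math.exp(-x) / (1.0 + math.exp(-x))
    d = _delta_quotient(mdi, m)
    return 2.0 / (d + 1.0)


def classify_region(
    mdi: float, boundaries: tuple[float, float] = DEFAULT_REGION_BOUNDARIES
) -> int:
    """Operating region of the immune system on the Δ-MDI trade-off.

    Region 1 (MDI < b1): responds to small changes with low
    discrimination — elevated autoimmunity risk.  Region 2 (b1 <= MDI <
    b2): moderate changes, high discrimination — optimal tumor detection.
    Region 3 (MDI >= b2): only large increases are detectable; vertebrate
    parameter estimates (MDI ~ 50-500) fall here.  The default boundaries
    (3, 20) are an explicitly arbitrary convention; bounds are half-open
    with the lower edge inclusive.
    """
    b1, b2 = boundaries
    if not b1 < b2:
        raise ValueError(f"boundaries must be increasing, got {boundaries!r}")
    if mdi < b1:
        return 1
    if mdi < b2:
        return 2
    return 3
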