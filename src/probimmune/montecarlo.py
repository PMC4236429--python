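"""Stochastic simulation of maturation, antigen presentation and response.

This module is the brute-force counterpart of the closed forms in
:mod:`probimmune.tolerance` and :mod:`probimmune.targeting`.  It samples
the exact finite-count distributions (binomial presentation counts during
maturation, multinomial slot occupancy on the APC surface) rather than
their Poisson approximations, so it can be used to validate those
approximations as well as the closed forms built on them.

Model of one replicate:

1. *Maturation* (on basal abundances): each of the ``m`` naive clones per
   self antigen independently experiences ``t0`` presentations; its
   cognate antigen's presentation count is binomial(t0, a_i) and the clone
   survives negative selection iff that count is zero.  Pathogen-reactive
   clones are always available (the naive repertoire recognizes virtually
   everything).
2. *Presentation* (on current abundances): one activated APC fills its
   ``N`` MHC slots by a multinomial draw over the environment.
3. *Response*: one slot is inspected uniformly at random.  The antigen in
   that slot is targeted iff it occupies at least ``n*`` slots on the APC
   and a surviving reactive clone exists; otherwise there is no response.
   This rule reproduces the closed-form marginal Pr{A_i targeted} =
   a_i (1 - f_i) exactly for m = 1, since the uniformly chosen slot lands
   on antigen i with probability E[c_i]/N = a_i.

Scenario drivers compose these steps into the situations of interest:
healthy baseline, infection, sub-threshold pathogen (bystander risk) and
k-fold self over-expression (tumor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import AntigenEnvironment, add_pathogen, overexpress
from .params import ModelParams

__all__ = [
    "Repertoire",
    "ScenarioResult",
    "simulate_maturation",
    "simulate_maturations",
    "sample_apc",
    "simulate_response",
    "run_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class Repertoire:
    """Surviving self-reactive clone counts after negative selection.

    ``counts[i]`` is the number of surviving clones cognate to antigen i,
    in [0, m].  Pathogen antigens always carry the full ``m``.
    """

    antigen_ids: tuple[str, ...]
    counts: np.ndarray
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if np.any(self.counts < 0) or np.any(self.counts > self.m):
            raise ValueError("clone counts must lie in [0, m]")
        self.counts.setflags(write=False)

    @property
    def reactive_mask(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class ScenarioResult:
    """Aggregated Monte-Carlo estimates for one scenario."""

    scenario: str
    n_reps: int
    seed: int
    antigen_ids: tuple[str, ...]
    targeting_frequency: np.ndarray
    targeting_se: np.ndarray
    tolerance_fraction: np.ndarray
    no_response_frequency: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "antigen_id": self.antigen_ids,
                "targeting_frequency": self.targeting_frequency,
                "targeting_se": self.targeting_se,
                "tolerance_fraction": self.tolerance_fraction,
            }
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "antigen_ids": list(self.antigen_ids),
            "targeting_frequency": self.targeting_frequency.tolist(),
            "targeting_se": self.targeting_se.tolist(),
            "tolerance_fraction": self.tolerance_fraction.tolist(),
            "no_response_frequency": self.no_response_frequency,
        }


# -- elementary stochastic steps -------------------------------------------


def simulate_maturations(
    env: AntigenEnvironment,
    params: ModelParams,
    rng: np.random.Generator,
    n_reps: int = 1,
) -> np.ndarray:
    """Surviving clone counts for ``n_reps`` independent maturations.

    Returns an ``(n_reps, n_antigens)`` integer array.  Each clone's
    cognate presentation count is the binomial marginal of the multinomial
    over its own ``t0`` presentations (clones are distinct cells maturing
    independently); the clone is deleted on any encounter.  Maturation
    uses basal abundances.
    """
    a = env.basal_abundances
    m, t0 = params.m, params.t0
    # (n_reps, m, n_ag) presentation counts; survival iff count == 0
    counts = rng.binomial(t0, a[None, None, :], size=(n_reps, m, len(env)))
    surviving = (counts == 0).sum(axis=1)
    surviving[:, env.pathogen_mask] = m
    return surviving


def simulate_maturation(
    env: AntigenEnvironment, params: ModelParams, rng: np.random.Generator
) -> Repertoire:
    """One negative-selection pass; see :func:`simulate_maturations`."""
    counts = simulate_maturations(env, params, rng, n_reps=1)[0]
    return Repertoire(env.antigen_ids, counts, params.m)


def sample_apc(
    env: AntigenEnvironment,
    N: int,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Multinomial slot occupancy of one (or ``size``) APC surfaces.

    Each of the ``N`` MHC slots independently displays antigen i with
    probability equal to its current effective abundance.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return rng.multinomial(N, env.abundances, size=size)


def _pick_slot_antigens(counts: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """Index of the antigen occupying one uniformly chosen slot per APC row."""
    u = rng.integers(0, N, size=counts.shape[0])
    cum = counts.cumsum(axis=1)
    return (u[:, None] >= cum).sum(axis=1)


def simulate_response(
    env: AntigenEnvironment,
    repertoire: Repertoire,
    params: ModelParams,
    rng: np.random.Generator,
) -> str | None:
    """One danger-activated APC-lymphocyte encounter.

    Returns the targeted antigen id, or None if the inspected slot's
    antigen is below the activation threshold or lacks reactive clones.
    """
    idx = _simulate_responses(env, repertoire.reactive_mask[None, :], params, rng, 1)[0]
    return None if idx < 0 else env.antigen_ids[idx]


def _simulate_responses(
    env: AntigenEnvironment,
    reactive: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    n_reps: int,
) -> np.ndarray:
    """Vectorized response decisions; -1 marks no response.

    ``reactive`` is (n_reps, n_antigens) or (1, n_antigens) boolean.
    """
    if params.N is None or params.n_star is None:
        raise ValueError("params must define N and n_star for a response decision")
    counts = sample_apc(env, params.N, rng, size=n_reps)
    idx = _pick_slot_antigens(counts, params.N, rng)
    rows = np.arange(n_reps)
    if reactive.shape[0] == 1:
        is_reactive = reactive[0][idx]
    else:
        is_reactive = reactive[rows, idx]
    eligible = (counts[rows, idx] >= params.n_star) & is_reactive
    return np.where(eligible, idx, -1)


# -- scenario drivers ------------------------------------------------------


def _scenario_environment(env: AntigenEnvironment, name: str, knobs: dict) -> AntigenEnvironment:
    if name == "healthy":
        return env
    if name in ("infection", "pathogen_below_threshold"):
        p = knobs.get("p")
        if p is None:
            raise ValueError(f"scenario {name!r} requires a pathogen abundance 'p'")
        return add_pathogen(env, p, knobs.get("n_pathogen_ags", 1))
    if name == "tumor":
        target, k = knobs.get("antigen_id"), knobs.get("k")
        if target is None or k is None:
            raise ValueError("scenario 'tumor' requires 'antigen_id' and 'k'")
        return overexpress(env, target, k, renormalize=True)
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("healthy", "infection", "pathogen_below_threshold", "tumor")


def run_scenario(
    env: AntigenEnvironment,
    params: ModelParams,
    scenario: str = "healthy",
    n_reps: int = 10_000,
    seed: int = 0,
    batch_size: int = 200_000,
    **knobs,
) -> ScenarioResult:
    """Repeat maturation + response ``n_reps`` times and aggregate.

    Maturation always happens on the *basal* environment (tolerance is
    induced before the perturbation); presentation and response use the
    perturbed environment.  Results are deterministic for a fixed seed.
    Replicates are processed in batches to bound memory.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(seed)
    perturbed = _scenario_environment(env, scenario, knobs)
    # perturbed.basal_abundances carry the pre-perturbation values, so
    # maturation below still sees the basal environment
    n_ag = len(perturbed)

    hits = np.zeros(n_ag, dtype=np.int64)
    tolerated = np.zeros(n_ag, dtype=np.int64)
    no_response = 0
    done = 0
    while done < n_reps:
        b = min(batch_size, n_reps - done)
        surviving = simulate_maturations(perturbed, params, rng, n_reps=b)
        reactive = surviving > 0
        tolerated += (~reactive).sum(axis=0)
        targets = _simulate_responses(perturbed, reactive, params, rng, b)
        no_response += int((targets < 0).sum())
        hit_counts = np.bincount(targets[targets >= 0], minlength=n_ag)
        hits += hit_counts
        done += b

    freq = hits / n_reps
    se = np.sqrt(freq * (1.0 - freq) / n_reps)
    return ScenarioResult(
        scenario=scenario,
        n_reps=n_reps,
        seed=seed,
        antigen_ids=perturbed.antigen_ids,
        targeting_frequency=freq,
        targeting_se=se,
        tolerance_fraction=tolerated / n_reps,
        no_response_frequency=no_response / n_reps,
    )
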