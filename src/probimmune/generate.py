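"""Synthetic antigenic environments.

Real antigenic microenvironments are not catalogued; what the model needs
is a normalized abundance vector spanning several orders of magnitude, the
way effective abundances (concentration x accessibility x MHC affinity)
plausibly do.  The generator draws raw abundances across a configurable
decade range — log-uniform by default, log-normal as an alternative — and
normalizes them.
"""

from __future__ import annotations

import numpy as np

from .environment import AntigenEnvironment, make_environment

__all__ = ["generate_environment"]


def generate_environment(
    n_antigens: int,
    log10_range: tuple[float, float] = (-6.0, -2.0),
    distribution: str = "log-uniform",
    rng: np.random.Generator | int | None = None,
    id_prefix: str = "A",
) -> AntigenEnvironment:
    """Draw a random self-antigen environment over a decade range.

    ``log-uniform`` draws log10-abundance uniformly over ``log10_range``;
    ``log-normal`` centers a normal on the range midpoint with sigma a
    quarter of the range width (so ~95% of draws fall inside the range).
    Abundances are then normalized to sum to one.  Deterministic for a
    fixed seed.
    """
    if n_antigens < 1:
        raise ValueError("n_antigens must be >= 1")
    lo, hi = log10_range
    if not lo < hi:
        raise ValueError(f"log10_range must be increasing, got {log10_range!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if distribution == "log-uniform":
        exponents = rng.uniform(lo, hi, size=n_antigens)
    elif distribution == "log-normal":
        exponents = rng.normal((lo + hi) / 2.0, (hi - lo) / 4.0, size=n_antigens)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    ids = tuple(f"{id_prefix}{i + 1}" for i in range(n_antigens))
    return make_environment(10.0 ** exponents, ids)
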