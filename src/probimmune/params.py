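"""Scalar model parameters and derived summaries."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = ["ModelParams", "DerivedQuantities"]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the probabilistic innate-adaptive communication model.

    Parameters
    ----------
    t0
        Number of antigen presentations a maturing lymphocyte experiences
        during negative selection.  May be given directly or derived as
        ``K * N * s`` (each of the K scanned APCs exposes a fraction s of
        its N MHC slots).
    N
        Number of MHC-peptide complexes on one APC surface.
    n_star
        Minimum number of MHC-peptide-TCR complexes on a single APC needed
        to activate a lymphocyte; induces the efficient-presentation
        threshold ``a* = n*/N``.
    K
        Number of APCs a lymphocyte scans during maturation.
    s
        Fraction of an APC surface scanned per encounter, in (0, 1].
    m
        Number of naive self-reactive clones per self antigen (default 1).
    presentation_mode
        ``"step"``: Heaviside threshold at ``a*`` (default, matches the
        closed forms downstream); ``"exact"``: Poisson survival form.
    count_model
        ``"binomial"`` (exact presentation counts) or ``"poisson"``
        (large-``t0`` approximation).
    enforce_consistency
        If True and K, N, s are all set, require ``t0 == round(K*N*s)``.
    """

    t0: Optional[int] = None
    N: Optional[int] = None
    n_star: Optional[int] = None
    K: Optional[int] = None
    s: Optional[float] = None
    m: int = 1
    presentation_mode: str = "step"
    count_model: str = "binomial"
    enforce_consistency: bool = False

    def __post_init__(self) -> None:
        for name in ("t0", "N", "n_star", "K"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        if self.s is not None and not 0.0 < self.s <= 1.0:
            raise ValueError(f"s must lie in (0, 1], got {self.s!r}")
        if self.n_star is not None and self.N is not None and self.n_star > self.N:
            raise ValueError("n_star cannot exceed N")
        if self.presentation_mode not in ("step", "exact"):
            raise ValueError(f"unknown presentation_mode {self.presentation_mode!r}")
        if self.count_model not in ("binomial", "poisson"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.enforce_consistency and None not in (self.t0, self.K, self.N, self.s):
            expected = round(self.K * self.N * self.s)
            if self.t0 != expected:
                raise ValueError(
                    f"t0={self.t0} inconsistent with K*N*s={self.K * self.N * self.s}"
                )
        if self.t0 is None and None not in (self.K, self.N, self.s):
            object.__setattr__(self, "t0", round(self.K * self.N * self.s))
        if self.t0 is None:
            raise ValueError("t0 must be given directly or via K, N and s")

    @property
    def a_star(self) -> Optional[float]:
        """Efficient-presentation threshold n*/N, if both are set."""
        if self.n_star is None or self.N is None:
            return None
        return self.n_star / self.N

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class DerivedQuantities:
    """Analytic summary for one environment + parameter set.

    Per-antigen vectors live in the accompanying table emitted by
    :func:`probimmune.tolerance.derive`; this object carries the scalars.
    """

    a_star: Optional[float] = None
    a_max: Optional[float] = None
    R: Optional[float] = None
    log_R: Optional[float] = None
    MDI: Optional[float] = None
    delta: Optional[float] = None
    region: Optional[int] = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("extras"))
        return d
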