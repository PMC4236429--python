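"""Antigenic microenvironments.

An antigenic microenvironment is a set of antigens, each carrying an
*effective abundance*: the normalized product of its concentration, its
accessibility to antigen-presenting cells (APCs) and the affinity of the
MHC-peptide complex.  Effective abundances behave like molar fractions:
they are non-negative and sum to one, so ``a_i`` is the probability that a
randomly chosen MHC slot on an APC displays antigen ``i``.

The environment can be perturbed in two ways that matter for the model:

* a pathogen of total effective abundance ``p`` enters, rescaling every
  self abundance by ``(1 - p)``;
* a self antigen is over-expressed ``k``-fold (the tumor scenario).

Both perturbations keep track of the *basal* abundances — the abundances
at the time central tolerance was induced — because tolerance is always
evaluated against those.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AntigenEnvironment",
    "make_environment",
    "add_pathogen",
    "overexpress",
    "read_environment_tsv",
    "write_environment_tsv",
]

_NORM_TOL = 1e-12
_CATEGORIES = frozenset({"self", "pathogen"})


@dataclass(frozen=True)
class AntigenEnvironment:
    """Immutable set of antigens with normalized effective abundances.

    Attributes
    ----------
    antigen_ids
        Ordered, unique, opaque string identifiers.
    abundances
        Current effective abundance per antigen; sums to one.
    categories
        Per-antigen label, ``"self"`` or ``"pathogen"``.
    basal_abundances
        Effective abundances at the time tolerance was induced.  Defaults
        to the current abundances at construction.  Tolerance computations
        must always use these.
    """

    antigen_ids: tuple[str, ...]
    abundances: np.ndarray
    categories: tuple[str, ...]
    basal_abundances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))
        if self.basal_abundances is None:
            object.__setattr__(self, "basal_abundances", self.abundances.copy())
        else:
            object.__setattr__(
                self, "basal_abundances", np.asarray(self.basal_abundances, dtype=float)
            )
        n = len(self.antigen_ids)
        if n == 0:
            raise ValueError("environment must contain at least one antigen")
        if len(set(self.antigen_ids)) != n:
            raise ValueError("antigen ids must be unique")
        if self.abundances.shape != (n,) or self.basal_abundances.shape != (n,):
            raise ValueError("abundance vectors must match the number of antigens")
        if len(self.categories) != n:
            raise ValueError("categories must match the number of antigens")
        bad = set(self.categories) - _CATEGORIES
        if bad:
            raise ValueError(f"unknown antigen categories: {sorted(bad)}")
        if np.any(self.abundances < 0) or np.any(self.basal_abundances < 0):
            raise ValueError("effective abundances must be non-negative")
        if abs(self.abundances.sum() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"abundances must sum to 1 (got {self.abundances.sum()!r}); "
                "use make_environment to normalize raw values"
            )
        if abs(self.basal_abundances.sum() - 1.0) > _NORM_TOL:
            raise ValueError("basal abundances must sum to 1")
        self.abundances.setflags(write=False)
        self.basal_abundances.setflags(write=False)

    # -- convenience views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.antigen_ids)

    @property
    def self_mask(self) -> np.ndarray:
        return np.asarray([c == "self" for c in self.categories])

    @property
    def pathogen_mask(self) -> np.ndarray:
        return ~self.self_mask

    def index_of(self, antigen_id: str) -> int:
        try:
            return self.antigen_ids.index(antigen_id)
        except ValueError:
            raise KeyError(f"unknown antigen id: {antigen_id!r}") from None

    def abundance_of(self, antigen_id: str) -> float:
        return float(self.abundances[self.index_of(antigen_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "antigen_id": self.antigen_ids,
                "abundance": self.abundances,
                "basal_abundance": self.basal_abundances,
                "category": self.categories,
            }
        )

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "antigen_ids": list(self.antigen_ids),
            "abundances": self.abundances.tolist(),
            "categories": list(self.categories),
            "basal_abundances": self.basal_abundances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AntigenEnvironment":
        return cls(
            antigen_ids=tuple(d["antigen_ids"]),
            abundances=np.asarray(d["abundances"], dtype=float),
            categories=tuple(d["categories"]),
            basal_abundances=np.asarray(d["basal_abundances"], dtype=float)
            if d.get("basal_abundances") is not None
            else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "AntigenEnvironment":
        return cls.from_dict(json.loads(s))


def make_environment(
    abundances: Sequence[float] | np.ndarray,
    ids: Iterable[str] | None = None,
    categories: Iterable[str] | None = None,
) -> AntigenEnvironment:
    """Build a normalized environment from raw non-negative abundances.

    Raw abundances are divided by their sum, so any non-negative,
    not-all-zero vector is accepted.  ``ids`` default to ``A1..An`` and
    ``categories`` default to all-self.
    """
    raw = np.asarray(abundances, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("abundances must be a non-empty 1-D sequence")
    if np.any(raw < 0):
        raise ValueError("effective abundances must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("at least one abundance must be positive")
    ids = tuple(ids) if ids is not None else tuple(f"A{i + 1}" for i in range(raw.size))
    cats = tuple(categories) if categories is not None else ("self",) * raw.size
    return AntigenEnvironment(ids, raw / total, cats)


def add_pathogen(
    env: AntigenEnvironment,
    p: float,
    n_pathogen_ags: int = 1,
    id_prefix: str = "P",
) -> AntigenEnvironment:
    """Introduce a pathogen of total effective abundance ``p``.

    Every existing abundance is rescaled by ``(1 - p)`` and the pathogen
    mass ``p`` is split equally over ``n_pathogen_ags`` new antigens
    labelled ``pathogen``.  Basal abundances of existing antigens are kept
    (rescaled the same way is *not* applied to them: tolerance was induced
    before the infection); new pathogen antigens get basal abundance zero.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"pathogen abundance p must lie in (0, 1), got {p!r}")
    if n_pathogen_ags < 1:
        raise ValueError("n_pathogen_ags must be >= 1")
    new_ids = tuple(f"{id_prefix}{i + 1}" for i in range(n_pathogen_ags))
    clash = set(new_ids) & set(env.antigen_ids)
    if clash:
        raise ValueError(f"pathogen ids collide with existing antigens: {sorted(clash)}")
    abundances = np.concatenate(
        [env.abundances * (1.0 - p), np.full(n_pathogen_ags, p / n_pathogen_ags)]
    )
    # pathogen antigens were absent when tolerance was induced: basal mass 0,
    # self basal abundances unchanged (they still sum to one).
    basal = np.concatenate([env.basal_abundances, np.zeros(n_pathogen_ags)])
    return AntigenEnvironment(
        env.antigen_ids + new_ids,
        abundances,
        env.categories + ("pathogen",) * n_pathogen_ags,
        basal_abundances=basal,
    )


def overexpress(
    env: AntigenEnvironment,
    antigen_id: str,
    k: float,
    renormalize: bool = False,
) -> AntigenEnvironment:
    """Raise one antigen's effective abundance ``k``-fold.

    With ``renormalize=True`` the whole vector is rescaled back to sum one
    and a proper :class:`AntigenEnvironment` is returned, with the
    pre-change abundances recorded as basal.  With ``renormalize=False``
    (the convention of the closed-form fold-change expressions) the other
    abundances are left untouched, so the vector no longer sums to one; an
    :class:`OverexpressedEnvironment` wrapping the raw vector is returned
    instead.  The discrepancy between the two conventions is of order
    ``k * a_i``.
    """
    if k <= 0:
        raise ValueError(f"fold factor k must be positive, got {k!r}")
    i = env.index_of(antigen_id)
    new = env.abundances.copy()
    new[i] = new[i] * k
    if renormalize:
        return AntigenEnvironment(
            env.antigen_ids,
            new / new.sum(),
            env.categories,
            basal_abundances=env.abundances.copy(),
        )
    return OverexpressedEnvironment(
        antigen_ids=env.antigen_ids,
        raw_abundances=new,
        categories=env.categories,
        basal_abundances=env.abundances.copy(),
    )


@dataclass(frozen=True)
class OverexpressedEnvironment:
    """Un-renormalized environment after a k-fold over-expression.

    The abundance vector deliberately does not sum to one (analytic
    convention for fold-change targeting); call :meth:`normalized` to get a
    proper :class:`AntigenEnvironment` for sampling.
    """

    antigen_ids: tuple[str, ...]
    raw_abundances: np.ndarray
    categories: tuple[str, ...]
    basal_abundances: np.ndarray

    def normalized(self) -> AntigenEnvironment:
        return AntigenEnvironment(
            self.antigen_ids,
            self.raw_abundances / self.raw_abundances.sum(),
            self.categories,
            basal_abundances=self.basal_abundances,
        )


# -- tabular I/O -----------------------------------------------------------


def write_environment_tsv(env: AntigenEnvironment, path) -> None:
    env.to_frame().to_csv(path, sep="\t", index=False)


def read_environment_tsv(path) -> AntigenEnvironment:
    """Read an environment from TSV.

    Requires columns ``antigen_id`` and ``abundance``; ``category`` and
    ``basal_abundance`` are optional (defaults: all-self, basal = current).
    Raw abundances are normalized on read.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"antigen_id", "abundance"} - set(df.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    cats = (
        tuple(df["category"].astype(str))
        if "category" in df.columns
        else ("self",) * len(df)
    )
    env = make_environment(
        df["abundance"].to_numpy(float), tuple(df["antigen_id"].astype(str)), cats
    )
    if "basal_abundance" in df.columns:
        basal = df["basal_abundance"].to_numpy(float)
        env = AntigenEnvironment(
            env.antigen_ids, env.abundances, env.categories, basal / basal.sum()
        )
    return env
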