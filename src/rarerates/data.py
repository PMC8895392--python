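"""Domain containers and plain-text I/O for per-area rare-cancer count tables.

The fundamental data object is a :class:`CountTable`: one cancer entity's
observed case counts ``C_i`` and expected case counts ``E_i`` across ``I``
areas (countries).  Expected counts are the cases an area would record under
reference age/sex-specific rates and are treated as a fixed, known offset.

Prior and sampler configuration are carried by small frozen dataclasses so
that fits are fully described by ``(CountTable, PriorSpec, McmcConfig)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountTable:
    """Observed and expected case counts for one cancer entity across areas.

    Parameters
    ----------
    entity_id
        Free-text label of the cancer entity.
    area_ids
        Ordered area (country) labels; order is preserved through every
        downstream operation.
    observed
        Non-negative integer case counts ``C_i`` per area.
    expected
        Positive expected case counts ``E_i`` per area (fixed offsets).
    """

    entity_id: str
    area_ids: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        observed = np.asarray(self.observed)
        expected = np.asarray(self.expected, dtype=float)
        object.__setattr__(self, "area_ids", tuple(str(a) for a in self.area_ids))
        if not (len(self.area_ids) == observed.shape[0] == expected.shape[0]):
            raise ValidationError(
                f"entity {self.entity_id!r}: area_ids, observed and expected "
                f"must have equal length, got {len(self.area_ids)}, "
                f"{observed.shape[0]}, {expected.shape[0]}"
            )
        if observed.shape[0] < 2:
            raise ValidationError(
                f"entity {self.entity_id!r}: at least 2 areas required"
            )
        if not np.all(np.isfinite(observed)) or np.any(observed < 0):
            bad = int(np.flatnonzero(~np.isfinite(observed) | (observed < 0))[0])
            raise ValidationError(
                f"entity {self.entity_id!r}, row {bad} "
                f"({self.area_ids[bad]}): observed count must be a "
                f"non-negative integer, got {observed[bad]!r}"
            )
        if np.any(observed != np.floor(observed)):
            bad = int(np.flatnonzero(observed != np.floor(observed))[0])
            raise ValidationError(
                f"entity {self.entity_id!r}, row {bad} "
                f"({self.area_ids[bad]}): observed count must be an integer, "
                f"got {observed[bad]!r}"
            )
        if not np.all(np.isfinite(expected)) or np.any(expected <= 0):
            bad = int(np.flatnonzero(~np.isfinite(expected) | (expected <= 0))[0])
            raise ValidationError(
                f"entity {self.entity_id!r}, row {bad} "
                f"({self.area_ids[bad]}): expected count must be positive, "
                f"got {expected[bad]!r}"
            )
        object.__setattr__(self, "observed", observed.astype(np.int64))
        object.__setattr__(self, "expected", expected)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area": list(self.area_ids),
             "observed": self.observed,
             "expected": self.expected}
        )

    def permuted(self, order: Sequence[int]) -> "CountTable":
        """Return the table with rows reordered (used by invariance checks)."""
        order = list(order)
        return CountTable(
            entity_id=self.entity_id,
            area_ids=tuple(self.area_ids[k] for k in order),
            observed=self.observed[order],
            expected=self.expected[order],
        )


def read_count_table(path: str | Path, entity_id: str | None = None) -> CountTable:
    """Read a ``area,observed,expected`` CSV into a validated CountTable.

    Row order in the file is preserved.  ``entity_id`` defaults to the file
    stem.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"area", "observed", "expected"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    return CountTable(
        entity_id=entity_id if entity_id is not None else path.stem,
        area_ids=tuple(str(a) for a in df["area"]),
        observed=df["observed"].to_numpy(),
        expected=df["expected"].to_numpy(dtype=float),
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_report(results, path: str | Path, format: str = "csv") -> None:
    """Write a result table (DataFrame) or mapping to CSV or JSON.

    CSV numeric fields round-trip at full double precision (pandas writes
    repr-level precision, i.e. 17 significant digits).
    """
    path = Path(path)
    if format not in {"csv", "json"}:
        raise ValidationError(f"unknown report format {format!r}")
    if results is None or (hasattr(results, "__len__") and len(results) == 0):
        raise ValidationError("refusing to write an empty report")
    if format == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, index=False)
    else:
        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="records")
        else:
            payload = results
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# prior specification
# ---------------------------------------------------------------------------

PRIOR_FAMILIES = ("uniform_sigma", "hierarchical_uniform_sigma", "gamma_precision")


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the random-effect scale of the Poisson log-normal model.

    Three families are supported:

    ``uniform_sigma``
        sigma ~ Uniform(lb, ub).  An "unbounded" uniform is represented by a
        large finite ub (default surrogate 1e6).
    ``hierarchical_uniform_sigma``
        LB ~ Uniform(0, lb_hyper_max), UB ~ Uniform(LB, ub_hyper_max),
        sigma | LB, UB ~ Uniform(LB, UB).
    ``gamma_precision``
        tau = 1/sigma^2 ~ Gamma(gamma_shape, gamma_rate).
    """

    family: str
    lb: float = 0.0
    ub: float = 500.0
    lb_hyper_max: float = 5.0
    ub_hyper_max: float = 500.0
    gamma_shape: float = 1e-5
    gamma_rate: float = 1e-5

    def __post_init__(self) -> None:
        if self.family not in PRIOR_FAMILIES:
            raise ValidationError(
                f"unknown prior family {self.family!r}; "
                f"expected one of {PRIOR_FAMILIES}"
            )
        if self.family == "uniform_sigma":
            if not (0 <= self.lb < self.ub):
                raise ValidationError(
                    f"uniform_sigma requires 0 <= lb < ub, got "
                    f"lb={self.lb}, ub={self.ub}"
                )
        if self.family == "hierarchical_uniform_sigma":
            if not (self.lb_hyper_max > 0 and self.ub_hyper_max > 0):
                raise ValidationError("hierarchical bounds must be positive")
        if self.family == "gamma_precision":
            if not (self.gamma_shape > 0 and self.gamma_rate > 0):
                raise ValidationError(
                    "gamma_precision requires gamma_shape > 0 and gamma_rate > 0"
                )

    @classmethod
    def uniform(cls, lb: float, ub: float) -> "PriorSpec":
        return cls(family="uniform_sigma", lb=lb, ub=ub)

    @classmethod
    def hierarchical(cls, lb_hyper_max: float = 5.0,
                     ub_hyper_max: float = 500.0) -> "PriorSpec":
        return cls(family="hierarchical_uniform_sigma",
                   lb_hyper_max=lb_hyper_max, ub_hyper_max=ub_hyper_max)

    @classmethod
    def gamma(cls, shape: float = 1e-5, rate: float = 1e-5) -> "PriorSpec":
        return cls(family="gamma_precision", gamma_shape=shape, gamma_rate=rate)


#: The nine Bayesian prior configurations compared in the study, keyed by
#: model id.  Models 1-6: sigma ~ Uniform(LB, 500) with increasing lower
#: bounds; model 7: hierarchical bounds; model 8: Gamma(1e-5, 1e-5) on the
#: precision; model 9: sigma ~ Uniform(0, "infinity") (1e6 surrogate).
MODEL_PRIORS: Mapping[str, PriorSpec] = {
    "m1": PriorSpec.uniform(0.0, 500.0),
    "m2": PriorSpec.uniform(0.1, 500.0),
    "m3": PriorSpec.uniform(0.2, 500.0),
    "m4": PriorSpec.uniform(0.3, 500.0),
    "m5": PriorSpec.uniform(0.5, 500.0),
    "m6": PriorSpec.uniform(1.0, 500.0),
    "m7": PriorSpec.hierarchical(5.0, 500.0),
    "m8": PriorSpec.gamma(1e-5, 1e-5),
    "m9": PriorSpec.uniform(0.0, 1e6),
}


# ---------------------------------------------------------------------------
# sampler configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    """Run settings for the Metropolis-within-Gibbs sampler.

    ``n_iter`` counts post-burn-in iterations per chain; the number of kept
    draws is ``n_chains * (n_iter // thin)``.
    """

    n_chains: int = 2
    n_iter: int = 5000
    n_burnin: int = 2500
    thin: int = 1
    seed: int = 0
    proposal_scales: tuple[float, float, float] = (0.1, 0.5, 0.3)  # mu, nu, sigma
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_burnin < 0 or self.thin < 1:
            raise ValidationError(
                "McmcConfig requires n_iter >= 1, n_burnin >= 0, thin >= 1"
            )
        if self.n_chains < 1:
            raise ValidationError("McmcConfig requires n_chains >= 1")
        if any(s <= 0 for s in self.proposal_scales):
            raise ValidationError("proposal scales must be positive")

    @property
    def n_keep_per_chain(self) -> int:
        return self.n_iter // self.thin


# ---------------------------------------------------------------------------
# interval estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalEstimate:
    """A method-tagged point estimate and interval for lambda_i (case scale)."""

    method: str
    area_id: str
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValidationError(f"level must be in (0,1), got {self.level}")
        if self.lower > self.upper:
            raise ValidationError(
                f"lower={self.lower} exceeds upper={self.upper} "
                f"({self.method}, {self.area_id})"
            )
        if self.point < 0 or self.lower < 0:
            raise ValidationError("point and lower must be non-negative")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def intervals_to_frame(intervals: Iterable[IntervalEstimate]) -> pd.DataFrame:
    return pd.DataFrame([asdict(iv) for iv in intervals])


# ---------------------------------------------------------------------------
# configuration files and seeding
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config carrying ``prior`` and ``mcmc`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict = {}
    if raw is None:
        return out
    if "prior" in raw:
        out["prior"] = PriorSpec(**raw["prior"])
    if "mcmc" in raw:
        out["mcmc"] = McmcConfig(**{
            k: (tuple(v) if k == "proposal_scales" else v)
            for k, v in raw["mcmc"].items()
        })
    return out


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministically split one integer seed into ``n`` child seeds (< 2^31).

    All randomness in the package flows from a single seed through this
    splitter, so runs are bit-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2 ** 31)]
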