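"""Face-centered central composite designs and factor coding.

A face-centered cubic (FCC) central composite design places, for ``k``
continuous factors, ``2**k`` factorial points at the cube corners (coded
±1), ``2k`` axial points on the cube faces (one coordinate ±1, the rest
0, i.e. axial distance alpha = 1) and a number of replicated center
points (all coordinates 0).  The replicated centers supply the pure-error
degrees of freedom used by the lack-of-fit test.

Raw factor settings relate to coded units through the affine map

    coded = 2 * (raw - mid) / (high - low),   mid = (low + high) / 2

so that ``low -> -1``, ``mid -> 0`` and ``high -> +1``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "DesignTable",
    "EEInput",
    "AssayInconsistencyError",
    "build_fcc_ccd",
    "code",
    "decode",
    "encapsulation_efficiency",
]


class AssayInconsistencyError(ValueError):
    """Free drug exceeding the drug input: the assay contradicts itself."""


@dataclass(frozen=True)
class FactorSpec:
    """One continuous formulation factor with its low/high levels.

    ``low`` and ``high`` are in raw units (e.g. % w/v for the chitosan
    concentration CC; dimensionless mass ratios for the chitosan/TPP
    ratio CT and the chitosan/drug ratio CP).
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"factor {self.name!r}: levels must be finite")
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low must be < high")

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def to_coded(self, raw):
        return (np.asarray(raw, dtype=float) - self.mid) / self.half_range

    def to_raw(self, coded):
        return self.mid + np.asarray(coded, dtype=float) * self.half_range


@dataclass(frozen=True)
class DesignPoint:
    """A single run: raw settings plus its geometric role in the design."""

    run_id: str
    raw: Mapping[str, float]
    role: str  # "factorial" | "face-center" | "center" | "custom"


def _check_factors(factors: Sequence[FactorSpec]) -> None:
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names: {names}")


def code(raw_point: Mapping[str, float], factors: Sequence[FactorSpec]) -> dict[str, float]:
    """Map a raw-unit point onto the coded [-1, +1] scale."""
    by_name = {f.name: f for f in factors}
    out = {}
    for name, value in raw_point.items():
        if name not in by_name:
            raise KeyError(f"unknown factor {name!r}; have {sorted(by_name)}")
        out[name] = float(by_name[name].to_coded(value))
    return out


def decode(coded_point: Mapping[str, float], factors: Sequence[FactorSpec]) -> dict[str, float]:
    """Inverse of :func:`code`: coded settings back to raw units."""
    by_name = {f.name: f for f in factors}
    out = {}
    for name, value in coded_point.items():
        if name not in by_name:
            raise KeyError(f"unknown factor {name!r}; have {sorted(by_name)}")
        out[name] = float(by_name[name].to_raw(value))
    return out


@dataclass
class DesignTable:
    """Runs-by-(factors + responses) table backing every fit in the package.

    ``data`` is indexed by ``run_id`` and carries one raw-unit column per
    factor plus one column per measured response.  Encapsulation
    efficiency is stored as a *fraction* in [0, 1]; display layers
    multiply by 100.
    """

    factors: list[FactorSpec]
    data: pd.DataFrame
    response_names: list[str] = field(default_factory=list)
    roles: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_factors(self.factors)
        missing = [f.name for f in self.factors if f.name not in self.data.columns]
        if missing:
            raise ValueError(f"design table lacks factor columns {missing}")

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return len(self.data)

    def raw(self) -> pd.DataFrame:
        return self.data[self.factor_names].astype(float)

    def coded(self) -> pd.DataFrame:
        raw = self.raw()
        return pd.DataFrame(
            {f.name: f.to_coded(raw[f.name].to_numpy()) for f in self.factors},
            index=raw.index,
        )

    def response(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"no response {name!r}; have {self.response_names}")
        return self.data[name].astype(float)

    def replicate_groups(self) -> list[np.ndarray]:
        """Run-id groups sharing *exactly* equal raw settings.

        Designs are constructed, not measured, so equality is exact
        (tolerance zero).  Only groups of two or more runs are returned;
        they are what the pure-error sum of squares is computed from.
        """
        raw = self.raw()
        groups = raw.groupby(self.factor_names, sort=False).groups
        return [np.asarray(idx) for idx in groups.values() if len(idx) > 1]

    def subset(self, run_ids) -> "DesignTable":
        roles = self.roles.loc[run_ids] if self.roles is not None else None
        return DesignTable(self.factors, self.data.loc[run_ids].copy(),
                           list(self.response_names), roles)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "run_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, factors: Sequence[FactorSpec],
                 response_names: Iterable[str] | None = None) -> "DesignTable":
        df = pd.read_csv(path, comment="#", index_col="run_id")
        fnames = [f.name for f in factors]
        if response_names is None:
            response_names = [c for c in df.columns if c not in fnames]
        return cls(list(factors), df, list(response_names))


def factors_from_json(path) -> list[FactorSpec]:
    entries = json.loads(Path(path).read_text())
    return [FactorSpec(**e) for e in entries]


def factors_to_json(factors: Sequence[FactorSpec], path) -> None:
    Path(path).write_text(json.dumps(
        [{"name": f.name, "low": f.low, "high": f.high, "units": f.units}
         for f in factors], indent=1) + "\n")


def build_fcc_ccd(factors: Sequence[FactorSpec], n_center: int = 3) -> DesignTable:
    """Construct a face-centered central composite design.

    Runs are ordered deterministically: the ``2**k`` factorial corners in
    standard Yates order (first factor alternating fastest), then the
    ``2k`` face centers factor by factor (low face before high face),
    then the ``n_center`` center replicates.  Fitting is order-invariant.
    """
    _check_factors(factors)
    k = len(factors)
    if k < 2:
        raise ValueError("a central composite design needs at least 2 factors")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    coded_rows: list[tuple[float, ...]] = []
    roles: list[str] = []
    # factorial corners, Yates order: first factor varies fastest
    for levels in itertools.product((-1.0, 1.0), repeat=k):
        coded_rows.append(tuple(reversed(levels)))
        roles.append("factorial")
    for j in range(k):
        for level in (-1.0, 1.0):
            point = [0.0] * k
            point[j] = level
            coded_rows.append(tuple(point))
            roles.append("face-center")
    for _ in range(n_center):
        coded_rows.append((0.0,) * k)
        roles.append("center")

    coded = np.array(coded_rows)
    raw = np.column_stack([f.to_raw(coded[:, j]) for j, f in enumerate(factors)])
    index = pd.Index([str(i + 1) for i in range(len(coded_rows))], name="run_id")
    data = pd.DataFrame(raw, columns=[f.name for f in factors], index=index)
    return DesignTable(list(factors), data, [], pd.Series(roles, index=index))


@dataclass(frozen=True)
class EEInput:
    """Drug-mass balance for one encapsulation-efficiency measurement.

    ``d_theoretical`` is the amount of drug added to the formulation and
    ``d_free`` the amount recovered unencapsulated (same units).
    """

    d_theoretical: float
    d_free: float

    def __post_init__(self) -> None:
        if not self.d_theoretical > 0:
            raise ValueError("d_theoretical must be positive")
        if self.d_free < 0:
            raise ValueError("d_free cannot be negative")
        if self.d_free > self.d_theoretical:
            raise AssayInconsistencyError(
                f"free drug ({self.d_free}) exceeds drug input "
                f"({self.d_theoretical}): assay inconsistency"
            )


def encapsulation_efficiency(x: EEInput) -> float:
    """EE = (D_theoretical - D_free) / D_theoretical, as a fraction in [0, 1]."""
    return (x.d_theoretical - x.d_free) / x.d_theoretical
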