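"""Synthetic data with known ground truth for every pipeline stage.

Two generators mirror the statistical structure the pipeline assumes:

* quadratic response surfaces over a coded FCC-CCD factor cube with
  i.i.d. Gaussian measurement noise (replicated center points get
  independent noise draws, which is what makes pure error estimable);
* drug descriptor panels with planted linear / log / exp / quadratic
  descriptor–property relationships, independent-noise filler
  descriptors and optional zero-variance columns.

All randomness flows from the single explicit ``seed`` stored in the
truth object; regeneration from the same truth is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_space import DesignTable, FactorSpec, build_fcc_ccd
from .descriptor_screen import DescriptorTable, PropertyTable
from .response_surface import Term, parse_terms

__all__ = [
    "SyntheticTruth",
    "PlantedRelation",
    "DEFAULT_FACTORS",
    "simulate_ccd_responses",
    "simulate_descriptor_panel",
]

# the formulation cube the package ships fixtures for: chitosan % w/v,
# chitosan/TPP mass ratio, chitosan/drug mass ratio
DEFAULT_FACTORS = (
    FactorSpec("CC", 0.1, 0.3, "% w/v"),
    FactorSpec("CT", 3.0, 7.0),
    FactorSpec("CP", 0.25, 0.5),
)


@dataclass(frozen=True)
class PlantedRelation:
    """One known descriptor -> property relationship to plant in a panel."""

    descriptor: str
    property: str
    form: str  # linear | log | exp | quadratic
    coefficients: tuple[float, ...]
    sigma: float = 0.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        c = self.coefficients
        if self.form == "linear":
            return c[0] + c[1] * x
        if self.form == "log":
            return c[0] + c[1] * np.log(x)
        if self.form == "exp":
            return c[0] * np.exp(c[1] * x)
        if self.form == "quadratic":
            return c[0] + c[1] * x + c[2] * x * x
        raise ValueError(f"unknown form {self.form!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a simulated response surface study.

    ``coefficients`` maps term labels (coded space, e.g. "CC", "CC:CT",
    "CT^2", "1" for the intercept) to values; ``sigma`` is the Gaussian
    measurement noise SD in response units.
    """

    coefficients: Mapping[str, float]
    sigma: float
    seed: int
    factors: tuple[FactorSpec, ...] = DEFAULT_FACTORS
    n_center: int = 3
    response: str = "y"
    descriptor_relations: tuple[PlantedRelation, ...] = ()

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        seen = set()
        for rel in self.descriptor_relations:
            key = (rel.descriptor, rel.property)
            if key in seen:
                raise ValueError(f"conflicting relations planted for {key}")
            seen.add(key)

    def terms(self) -> list[Term]:
        return parse_terms([k for k in self.coefficients if k != "1"])

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["coefficients"] = dict(self.coefficients)
        payload["factors"] = [asdict(f) for f in self.factors]
        payload["descriptor_relations"] = [asdict(r) for r in self.descriptor_relations]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["factors"] = tuple(FactorSpec(**f) for f in payload["factors"])
        payload["descriptor_relations"] = tuple(
            PlantedRelation(**{**r, "coefficients": tuple(r["coefficients"])})
            for r in payload["descriptor_relations"])
        return cls(**payload)


def simulate_ccd_responses(truth: SyntheticTruth) -> DesignTable:
    """Generate an FCC-CCD design with noisy responses from ``truth``.

    Response = polynomial(coded settings; truth coefficients) + N(0, sigma^2),
    independently per run, so replicated centers carry pure error.
    """
    design = build_fcc_ccd(list(truth.factors), truth.n_center)
    coded = design.coded()
    values = {c: coded[c].to_numpy() for c in coded.columns}
    mean = np.full(design.n_runs, float(truth.coefficients.get("1", 0.0)))
    for label, value in truth.coefficients.items():
        if label == "1":
            continue
        mean = mean + value * Term.parse(label).value(values)
    rng = np.random.default_rng(truth.seed)
    y = mean + rng.normal(0.0, truth.sigma, size=design.n_runs)
    data = design.data.copy()
    data[truth.response] = y
    return DesignTable(list(truth.factors), data, [truth.response], design.roles)


def simulate_descriptor_panel(
    truth: SyntheticTruth,
    n_drugs: int = 6,
    noise_descriptors: Sequence[str] = (),
    zero_variance: Sequence[str] = (),
    x_range: tuple[float, float] = (1.0, 10.0),
) -> tuple[DescriptorTable, PropertyTable]:
    """Generate a descriptor panel realizing ``truth.descriptor_relations``.

    Descriptors named in the relations get values drawn uniformly on
    ``x_range`` (strictly positive, so log/exp domains are valid);
    ``noise_descriptors`` are standard-normal filler with no relation to
    any property; ``zero_variance`` columns are constant.  Each property
    is the sum of its planted contributions plus each relation's noise.
    """
    if n_drugs < 4:
        raise ValueError("need at least 4 drugs")
    rng = np.random.default_rng(truth.seed)
    drugs = [f"drug{i + 1}" for i in range(n_drugs)]

    desc_cols: dict[str, np.ndarray] = {}
    for rel in truth.descriptor_relations:
        if rel.descriptor not in desc_cols:
            desc_cols[rel.descriptor] = rng.uniform(*x_range, size=n_drugs)
    for name in noise_descriptors:
        desc_cols.setdefault(name, rng.normal(size=n_drugs))
    for name in zero_variance:
        desc_cols[name] = np.full(n_drugs, 1.0)

    prop_cols: dict[str, np.ndarray] = {}
    for rel in truth.descriptor_relations:
        contribution = rel.evaluate(desc_cols[rel.descriptor])
        contribution = contribution + rng.normal(0.0, rel.sigma, size=n_drugs)
        prop_cols[rel.property] = prop_cols.get(rel.property, 0.0) + contribution

    desc = DescriptorTable(pd.DataFrame(desc_cols, index=pd.Index(drugs, name="drug")))
    props = PropertyTable(pd.DataFrame(prop_cols, index=pd.Index(drugs, name="drug")))
    return desc, props
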