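"""Descriptor–property correlation screening.

For a small panel of drugs, each numeric molecular descriptor is
correlated with each measured nanogel property (size, PDI, zeta
potential) under four functional forms:

    linear      y = a + b*x
    log         y = a + b*ln(x)          (requires x > 0)
    exp         y = a*exp(b*x)           (requires y > 0; log-linearized)
    quadratic   y = a + b*x + c*x**2

Each cell reports a signed R-squared — the magnitude is goodness of fit,
the sign encodes the direction of the trend (slope sign for linear, log
and exp; Pearson-correlation sign for quadratic) — plus an F-test
p-value against the intercept-only model.  Domain violations
(non-positive x for log, non-positive y for exp) and zero-variance
descriptors invalidate the cell explicitly rather than being skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FORMS",
    "DescriptorTable",
    "PropertyTable",
    "FormFit",
    "ScreenResult",
    "fit_form",
    "screen_all",
    "permutation_null",
]

FORMS = ("linear", "log", "exp", "quadratic")

# the 15-descriptor screening panel (constitutional + topological + logP)
DEFAULT_PANEL = (
    "nAcid", "nBase", "nRings", "nHBAcc", "nHBDon",
    "apol", "bpol", "WPATH", "WPOL", "TopoPSA",
    "TopoDiameter", "Toposhape", "ALogP", "XLogP", "MW",
)


@dataclass
class DescriptorTable:
    """Drugs x molecular descriptors, numeric values only."""

    data: pd.DataFrame  # index: drug label, columns: descriptor names

    @property
    def drugs(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptors(self) -> list[str]:
        return list(self.data.columns)

    def zero_variance(self) -> list[str]:
        return [c for c in self.data.columns if self.data[c].nunique() <= 1]

    @classmethod
    def from_csv(cls, path) -> "DescriptorTable":
        return cls(pd.read_csv(path, comment="#", index_col=0).astype(float))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="drug")


@dataclass
class PropertyTable:
    """Drugs x measured nanogel properties (replicate means)."""

    data: pd.DataFrame

    @classmethod
    def from_csv(cls, path) -> "PropertyTable":
        return cls(pd.read_csv(path, comment="#", index_col=0).astype(float))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="drug")


@dataclass
class FormFit:
    form: str
    r2: float  # unsigned, on the original y scale
    r2_signed: float
    p: float
    coefficients: tuple[float, ...]
    valid: bool
    reason: str = ""
    vertex: float | None = None  # quadratic only: -b/(2c)


def _ls_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return beta, rss, tss


def _f_pvalue(rss: float, tss: float, n: int, k: int) -> float:
    # k = number of slope parameters; F-test of the fit vs intercept-only
    df2 = n - k - 1
    if df2 <= 0 or rss <= 0 or tss <= rss:
        return float("nan") if df2 <= 0 else (0.0 if rss <= 0 else 1.0)
    f = ((tss - rss) / k) / (rss / df2)
    return float(stats.f.sf(f, k, df2))


def fit_form(x, y, form: str) -> FormFit:
    """Fit one functional form to one descriptor/property pair."""
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; choose from {FORMS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y lengths differ")
    n_min = 4 if form == "quadratic" else 3
    if n < n_min:
        return FormFit(form, 0.0, 0.0, float("nan"), (), False,
                       f"need at least {n_min} observations")
    if np.ptp(x) == 0:
        return FormFit(form, 0.0, 0.0, float("nan"), (), False,
                       "zero-variance descriptor")
    if form == "log" and (x <= 0).any():
        return FormFit(form, 0.0, 0.0, float("nan"), (), False,
                       "invalid arguments: non-positive x for log fit")
    if form == "exp" and (y <= 0).any():
        return FormFit(form, 0.0, 0.0, float("nan"), (), False,
                       "invalid arguments: non-positive y for exp fit")

    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return FormFit(form, 0.0, 0.0, float("nan"), (), False,
                       "zero-variance property")

    vertex = None
    if form == "linear":
        X = np.column_stack([np.ones(n), x])
        beta, rss, _ = _ls_fit(X, y)
        r2 = 1.0 - rss / tss
        p = _f_pvalue(rss, tss, n, 1)
        sign = np.sign(beta[1]) or 1.0
        coeffs = (beta[0], beta[1])
    elif form == "log":
        X = np.column_stack([np.ones(n), np.log(x)])
        beta, rss, _ = _ls_fit(X, y)
        r2 = 1.0 - rss / tss
        p = _f_pvalue(rss, tss, n, 1)
        sign = np.sign(beta[1]) or 1.0
        coeffs = (beta[0], beta[1])
    elif form == "exp":
        # least squares on ln y; R^2 recomputed on the original y scale
        ly = np.log(y)
        X = np.column_stack([np.ones(n), x])
        beta, rss_log, tss_log = _ls_fit(X, ly)
        a, b = float(np.exp(beta[0])), float(beta[1])
        yhat = a * np.exp(b * x)
        r2 = max(0.0, 1.0 - float(((y - yhat) ** 2).sum()) / tss)
        p = _f_pvalue(rss_log, tss_log, n, 1)  # test on the fitting scale
        sign = np.sign(b) or 1.0
        coeffs = (a, b)
    else:  # quadratic
        X = np.column_stack([np.ones(n), x, x * x])
        beta, rss, _ = _ls_fit(X, y)
        r2 = 1.0 - rss / tss
        p = _f_pvalue(rss, tss, n, 2)
        rho = np.corrcoef(x, y)[0, 1]
        sign = np.sign(rho) if rho == rho and rho != 0 else 1.0
        coeffs = (beta[0], beta[1], beta[2])
        if beta[2] != 0:
            vertex = float(-beta[1] / (2 * beta[2]))
    r2 = float(min(max(r2, 0.0), 1.0))
    return FormFit(form, r2, float(sign) * r2, p, tuple(map(float, coeffs)),
                   True, vertex=vertex)


def _strength(r2: float) -> str:
    if r2 > 0.7:
        return "strong"
    if r2 > 0.5:
        return "moderate"
    return "weak"


@dataclass
class ScreenResult:
    """Full descriptor x property x form grid of fits."""

    grid: pd.DataFrame  # columns: descriptor, property, form, r2, r2_signed, p, ...
    drugs: list[str] = field(default_factory=list)

    def cell(self, descriptor: str, prop: str, form: str) -> pd.Series:
        hit = self.grid[(self.grid.descriptor == descriptor)
                        & (self.grid.property == prop)
                        & (self.grid.form == form)]
        if hit.empty:
            raise KeyError(f"no cell ({descriptor}, {prop}, {form})")
        return hit.iloc[0]

    def strong(self, alpha: float = 0.05) -> pd.DataFrame:
        g = self.grid
        return g[(g.r2 > 0.7) & (g.p < alpha) & g.valid]

    def render(self, form: str = "linear") -> str:
        sub = self.grid[self.grid.form == form]
        wide = sub.pivot(index="descriptor", columns="property", values="r2_signed")
        return wide.round(3).to_string()

    def to_records(self) -> list[dict]:
        return self.grid.to_dict(orient="records")


def screen_all(desc: DescriptorTable, props: PropertyTable,
               forms: Sequence[str] = FORMS,
               exclude: Iterable[str] = ()) -> ScreenResult:
    """Fit every (descriptor, property, form) cell over the common drugs.

    ``exclude`` drops drugs (e.g. a salt form whose counter-ion would
    confound the gelation) from every fit.  Quadratic cells whose fitted
    vertex lies outside the observed descriptor range are flagged
    ``overfit_risk``: the curvature is not supported by the data.
    """
    exclude = set(exclude)
    drugs = [d for d in desc.drugs if d in set(props.data.index) and d not in exclude]
    if len(drugs) < 3:
        raise ValueError(f"need at least 3 common drugs, have {len(drugs)}")
    dropped = (set(desc.drugs) ^ set(props.data.index)) - exclude
    if dropped:
        raise ValueError(f"drug labels do not match between tables: {sorted(dropped)}")

    rows = []
    for descriptor in desc.descriptors:
        x = desc.data.loc[drugs, descriptor].to_numpy()
        for prop in props.data.columns:
            y = props.data.loc[drugs, prop].to_numpy()
            for form in forms:
                fit = fit_form(x, y, form)
                overfit = (form == "quadratic" and fit.valid
                           and fit.vertex is not None
                           and not (x.min() <= fit.vertex <= x.max()))
                rows.append({
                    "descriptor": descriptor, "property": prop, "form": form,
                    "r2": fit.r2, "r2_signed": fit.r2_signed, "p": fit.p,
                    "coefficients": fit.coefficients, "valid": fit.valid,
                    "reason": fit.reason, "strength": _strength(fit.r2),
                    "overfit_risk": bool(overfit),
                })
    return ScreenResult(pd.DataFrame(rows), drugs)


def permutation_null(x, y, form: str = "linear", n_perm: int = 999,
                     seed: int = 0) -> np.ndarray:
    """Null distribution of R^2 under random pairing of y with x.

    Context utility for judging how often a small-n screen produces
    large R^2 by chance; no multiplicity correction is applied to the
    per-cell p-values themselves.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = fit_form(x, rng.permutation(y), form).r2
    return out
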