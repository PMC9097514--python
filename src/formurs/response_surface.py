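"""Polynomial response-surface fitting, ANOVA and validation.

Quadratic response surfaces over a coded factor cube are fitted by
ordinary least squares.  The term language covers main effects,
two-factor interactions and pure quadratics; model search is stepwise
with *effect heredity*: an interaction or quadratic term may only enter
together with its parent main effect(s), and a parent is protected from
removal while any of its children remain.

The ANOVA uses sequential (fit-order, type-I) sums of squares for the
per-term rows and decomposes the residual into lack-of-fit and
pure-error components whenever the design contains replicated points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design_space import DesignTable, FactorSpec, code

__all__ = [
    "Term",
    "ModelSpec",
    "FittedModel",
    "AnovaTable",
    "FitStats",
    "SingularDesignError",
    "full_quadratic_terms",
    "fit_ols",
    "anova",
    "stepwise_select",
    "predict",
    "kfold_cv",
    "test_set_q2",
]


class SingularDesignError(ValueError):
    """The model matrix is rank deficient for this design."""


@dataclass(frozen=True, order=True)
class Term:
    """One polynomial model term: intercept, main effect, interaction or quadratic."""

    kind: str  # "intercept" | "main" | "interaction" | "quadratic"
    factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "intercept" and self.factors:
            raise ValueError("intercept carries no factors")
        if self.kind == "main" and len(self.factors) != 1:
            raise ValueError("main effect needs exactly one factor")
        if self.kind == "quadratic" and len(self.factors) != 1:
            raise ValueError("quadratic term references a single factor")
        if self.kind == "interaction":
            if len(self.factors) != 2 or self.factors[0] == self.factors[1]:
                raise ValueError("interaction needs two distinct factors")
            object.__setattr__(self, "factors", tuple(sorted(self.factors)))

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "1"
        if self.kind == "main":
            return self.factors[0]
        if self.kind == "interaction":
            return ":".join(self.factors)
        return f"{self.factors[0]}^2"

    @classmethod
    def parse(cls, text: str) -> "Term":
        text = text.strip()
        if text in ("1", "intercept"):
            return cls("intercept")
        m = re.fullmatch(r"(\w+)\^2", text)
        if m:
            return cls("quadratic", (m.group(1),))
        if any(sep in text for sep in (":", "*", "×")):
            parts = re.split(r"[:*×]", text)
            return cls("interaction", tuple(p.strip() for p in parts))
        return cls("main", (text,))

    def parents(self) -> list["Term"]:
        """Main effects that heredity requires alongside this term."""
        if self.kind in ("interaction", "quadratic"):
            return [Term("main", (f,)) for f in self.factors]
        return []

    def value(self, values: Mapping[str, np.ndarray | float]):
        if self.kind == "intercept":
            some = next(iter(values.values()))
            return np.ones_like(np.asarray(some, dtype=float))
        if self.kind == "main":
            return np.asarray(values[self.factors[0]], dtype=float)
        if self.kind == "interaction":
            a, b = self.factors
            return np.asarray(values[a], dtype=float) * np.asarray(values[b], dtype=float)
        v = np.asarray(values[self.factors[0]], dtype=float)
        return v * v

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_terms(terms: Iterable[str | Term]) -> list[Term]:
    return [t if isinstance(t, Term) else Term.parse(t) for t in terms]


def full_quadratic_terms(factor_names: Sequence[str]) -> list[Term]:
    """All mains, pairwise interactions and quadratics for these factors."""
    names = list(factor_names)
    out = [Term("main", (n,)) for n in names]
    out += [Term("interaction", (a, b))
            for i, a in enumerate(names) for b in names[i + 1:]]
    out += [Term("quadratic", (n,)) for n in names]
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A response name plus an ordered polynomial term set (intercept implicit)."""

    response: str
    terms: tuple[Term, ...]
    coding: str = "coded"  # fitting space: "coded" or "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(parse_terms(self.terms)))
        if self.coding not in ("coded", "raw"):
            raise ValueError("coding must be 'coded' or 'raw'")

    @classmethod
    def from_strings(cls, response: str, terms: Iterable[str], coding: str = "coded"):
        return cls(response, tuple(parse_terms(terms)), coding)

    def heredity_violations(self) -> list[Term]:
        present = set(self.terms)
        return sorted({p for t in self.terms for p in t.parents() if p not in present})

    def with_heredity(self) -> "ModelSpec":
        """Return a spec with any missing parent main effects prepended."""
        missing = self.heredity_violations()
        if not missing:
            return self
        return replace(self, terms=tuple(missing) + self.terms)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]


def _model_matrix(terms: Sequence[Term], values: Mapping[str, np.ndarray]) -> np.ndarray:
    n = len(np.asarray(next(iter(values.values()))))
    cols = [np.ones(n)] + [t.value(values) for t in terms]
    return np.column_stack(cols)


@dataclass
class FittedModel:
    """OLS fit of a :class:`ModelSpec` on a design, in the fitting space of the spec."""

    spec: ModelSpec
    factors: list[FactorSpec]
    coefficients: dict[str, float]  # term label -> estimate, "1" = intercept
    r2: float
    training_runs: int
    sigma2: float  # residual mean square
    std_errors: dict[str, float] = field(default_factory=dict)
    zero_variance: bool = False

    def _space_values(self, values: Mapping[str, np.ndarray | float],
                      coding: str) -> dict[str, np.ndarray]:
        names = [f.name for f in self.factors]
        missing = [n for n in names if n not in values]
        if missing:
            raise KeyError(f"missing factor value(s) {missing}")
        arrs = {n: np.atleast_1d(np.asarray(values[n], dtype=float)) for n in names}
        if coding == self.spec.coding:
            return arrs
        if coding == "raw" and self.spec.coding == "coded":
            by = {f.name: f for f in self.factors}
            return {n: by[n].to_coded(v) for n, v in arrs.items()}
        if coding == "coded" and self.spec.coding == "raw":
            by = {f.name: f for f in self.factors}
            return {n: by[n].to_raw(v) for n, v in arrs.items()}
        raise ValueError(f"unknown coding {coding!r}")

    def predict(self, point: Mapping[str, np.ndarray | float],
                coding: str = "raw") -> np.ndarray:
        """Evaluate the fitted polynomial at one or many points.

        ``point`` maps factor names to scalars or arrays in the units
        named by ``coding``; extrapolation outside the design cube is
        allowed (callers may check :meth:`in_cube`).
        """
        scalar = all(np.ndim(v) == 0 for v in point.values())
        vals = self._space_values(point, coding)
        beta = np.array([self.coefficients["1"]]
                        + [self.coefficients[t.label] for t in self.spec.terms])
        X = _model_matrix(self.spec.terms, vals)
        yhat = X @ beta
        return float(yhat[0]) if scalar else yhat

    def raw_coefficients(self) -> dict[str, float]:
        """Coefficients of the equivalent raw-unit polynomial.

        Obtained by substituting coded = (raw - mid)/half into the coded
        polynomial and collecting monomials; exact, no refit needed.
        When the spec was fitted in raw space this is just a copy.
        """
        if self.spec.coding == "raw":
            return dict(self.coefficients)
        by = {f.name: f for f in self.factors}
        out: dict[str, float] = {"1": self.coefficients["1"]}

        def add(label: str, value: float) -> None:
            out[label] = out.get(label, 0.0) + value

        for term in self.spec.terms:
            b = self.coefficients[term.label]
            if term.kind == "main":
                f = by[term.factors[0]]
                add(term.label, b / f.half_range)
                add("1", -b * f.mid / f.half_range)
            elif term.kind == "interaction":
                fa, fb = (by[n] for n in term.factors)
                scale = b / (fa.half_range * fb.half_range)
                add(term.label, scale)
                add(term.factors[0], -scale * fb.mid)
                add(term.factors[1], -scale * fa.mid)
                add("1", scale * fa.mid * fb.mid)
            else:  # quadratic
                f = by[term.factors[0]]
                scale = b / f.half_range**2
                add(term.label, scale)
                add(term.factors[0], -2.0 * scale * f.mid)
                add("1", scale * f.mid**2)
        return out

    def in_cube(self, point: Mapping[str, np.ndarray | float],
                coding: str = "raw", tol: float = 1e-9) -> np.ndarray:
        vals = self._space_values(point, "coded" if self.spec.coding == "raw" else coding)
        if self.spec.coding == "raw":  # convert raw-space values to coded for the check
            by = {f.name: f for f in self.factors}
            vals = {n: by[n].to_coded(v) for n, v in
                    self._space_values(point, coding).items()}
        coded = np.vstack([np.abs(v) for v in vals.values()])
        return (coded <= 1 + tol).all(axis=0)


def _design_values(design: DesignTable, coding: str) -> dict[str, np.ndarray]:
    frame = design.coded() if coding == "coded" else design.raw()
    return {c: frame[c].to_numpy() for c in frame.columns}


def fit_ols(design: DesignTable, spec: ModelSpec) -> FittedModel:
    """Least-squares fit of ``spec`` on ``design``.

    Raises :class:`SingularDesignError` naming the collinear terms when
    the model matrix is rank deficient, and requires more runs than
    parameters.
    """
    y = design.response(spec.response).to_numpy(dtype=float)
    values = _design_values(design, spec.coding)
    X = _model_matrix(spec.terms, values)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more runs ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the terms whose columns do not extend the rank
        labels = ["1"] + [t.label for t in spec.terms]
        bad = []
        r = 0
        for j in range(p):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(labels[j])
            r = rj
        raise SingularDesignError(f"singular design: collinear terms {bad}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    zero_var = tss == 0.0
    r2 = 1.0 if zero_var else 1.0 - rss / tss
    dof = n - p
    sigma2 = rss / dof if dof > 0 else float("nan")
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2)
    labels = ["1"] + [t.label for t in spec.terms]
    return FittedModel(
        spec=spec,
        factors=list(design.factors),
        coefficients=dict(zip(labels, beta.tolist())),
        r2=float(r2),
        training_runs=n,
        sigma2=float(sigma2),
        std_errors=dict(zip(labels, se.tolist())),
        zero_variance=zero_var,
    )


def predict(fitted: FittedModel, point: Mapping[str, float], coding: str = "raw"):
    """Module-level convenience wrapper around :meth:`FittedModel.predict`."""
    return fitted.predict(point, coding=coding)


@dataclass
class AnovaTable:
    """ANOVA rows (source, df, sum_sq, mean_sq, F, p) incl. lack-of-fit split."""

    table: pd.DataFrame
    has_pure_error: bool

    def row(self, source: str) -> pd.Series:
        hit = self.table[self.table["source"] == source]
        if hit.empty:
            raise KeyError(f"no ANOVA row {source!r}")
        return hit.iloc[0]

    def to_text(self) -> str:
        df = self.table.copy()
        for c in ("sum_sq", "mean_sq", "F"):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
        df["p"] = df["p"].map(lambda v: "" if pd.isna(v) else
                              ("<0.0001" if v < 1e-4 else f"{v:.4f}"))
        return df.to_string(index=False)


def anova(fitted: FittedModel, design: DesignTable) -> AnovaTable:
    """Sequential-SS ANOVA with lack-of-fit/pure-error decomposition.

    Per-term rows carry type-I (fit-order) sums of squares, each tested
    against the full-model residual mean square.  Pure error comes from
    replicated design points; when the design has none, the lack-of-fit
    rows are omitted (``has_pure_error`` is False).
    """
    y = design.response(fitted.spec.response).to_numpy(dtype=float)
    values = _design_values(design, fitted.spec.coding)
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())

    rss_path = [tss]
    for j in range(1, len(fitted.spec.terms) + 1):
        X = _model_matrix(fitted.spec.terms[:j], values)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss_path.append(float(r @ r))
    rss = rss_path[-1]
    p_terms = len(fitted.spec.terms)
    df_model, df_resid = p_terms, n - p_terms - 1
    ss_model = tss - rss
    ms_resid = rss / df_resid if df_resid > 0 else np.nan
    ms_model = ss_model / df_model if df_model > 0 else np.nan
    f_model = ms_model / ms_resid if df_resid > 0 and ms_resid > 0 else np.nan
    p_model = stats.f.sf(f_model, df_model, df_resid) if np.isfinite(f_model) else np.nan

    rows = [("model", df_model, ss_model, ms_model, f_model, p_model)]
    for term, prev, cur in zip(fitted.spec.terms, rss_path[:-1], rss_path[1:]):
        ss = prev - cur
        f = ss / ms_resid if df_resid > 0 and ms_resid > 0 else np.nan
        pv = stats.f.sf(f, 1, df_resid) if np.isfinite(f) else np.nan
        rows.append((term.label, 1, ss, ss, f, pv))
    rows.append(("residual", df_resid, rss, ms_resid, np.nan, np.nan))

    groups = design.replicate_groups()
    has_pe = bool(groups) and df_resid > 0
    if has_pe:
        ss_pe = 0.0
        df_pe = 0
        positions = {rid: i for i, rid in enumerate(design.data.index)}
        for grp in groups:
            vals = y[[positions[r] for r in grp]]
            ss_pe += float(((vals - vals.mean()) ** 2).sum())
            df_pe += len(vals) - 1
        df_lof = df_resid - df_pe
        ss_lof = rss - ss_pe
        ms_pe = ss_pe / df_pe if df_pe > 0 else np.nan
        ms_lof = ss_lof / df_lof if df_lof > 0 else np.nan
        f_lof = ms_lof / ms_pe if df_pe > 0 and df_lof > 0 and ms_pe > 0 else np.nan
        p_lof = stats.f.sf(f_lof, df_lof, df_pe) if np.isfinite(f_lof) else np.nan
        rows.append(("lack_of_fit", df_lof, ss_lof, ms_lof, f_lof, p_lof))
        rows.append(("pure_error", df_pe, ss_pe, ms_pe, np.nan, np.nan))
    rows.append(("total", n - 1, tss, np.nan, np.nan, np.nan))

    table = pd.DataFrame(rows, columns=["source", "df", "sum_sq", "mean_sq", "F", "p"])
    return AnovaTable(table, has_pe)


# --------------------------------------------------------------- selection

def _fit_rss(y: np.ndarray, values: Mapping[str, np.ndarray],
             terms: Sequence[Term]) -> float:
    X = _model_matrix(terms, values)
    if X.shape[0] <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
        return np.inf
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _criterion(rss: float, n: int, n_slopes: int, m: int, which: str) -> float:
    """Information criterion for a model with ``n_slopes`` non-intercept terms.

    ``ebic`` (extended BIC) adds a 2*log C(m, n_slopes) term charging for
    the search over the ``m``-term candidate set — the familywise control
    that keeps small-n stepwise selection from picking up noise terms.
    """
    if rss <= 0:
        rss = 1e-300
    p = n_slopes + 1
    ll = n * np.log(rss / n)
    if which == "bic":
        return ll + p * np.log(n)
    if which == "ebic":
        # k*log(m) is the monotone small-k form of log C(m, k); the exact
        # binomial term collapses to 0 at the saturated model, which on a
        # 17-run design would paradoxically favour it
        return ll + p * np.log(n) + 2.0 * n_slopes * np.log(max(m, 2))
    if which == "aic":
        return ll + 2 * p
    if which == "aicc":
        k = p + 1  # + error variance
        if n - k - 1 <= 0:
            return np.inf
        return ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    raise ValueError(f"unknown criterion {which!r}")


def stepwise_select(design: DesignTable, response: str,
                    candidate_terms: Sequence[Term | str] | None = None,
                    criterion: str = "bonferroni",
                    p_enter: float = 0.10, p_exit: float = 0.10,
                    coding: str = "coded") -> ModelSpec:
    """Bidirectional stepwise search over the quadratic candidate set.

    Heredity is enforced structurally: adding an interaction or
    quadratic term brings its missing parent(s) in with it (the move is
    scored with the whole group), and a parent cannot leave while one of
    its children remains.

    ``criterion`` picks the entry/exit rule.  ``bonferroni`` (default)
    enters on partial F tests at threshold ``p_enter / m`` where m is
    the candidate count, controlling the familywise rate of spurious
    entries — the right default for *discovery* on small designs.
    ``pvalue`` is the classical stepwise rule (enter at ``p_enter``,
    drop at ``p_exit``, uncorrected) that admits any conventionally
    significant effect; it is the mode that reproduces term sets chosen
    by the usual DOE software.  ``ebic`` (BIC plus a 2*k*log(m)
    multiplicity charge), ``bic``, ``aic`` and ``aicc`` are also offered.
    """
    if candidate_terms is None:
        candidate_terms = full_quadratic_terms(design.factor_names)
    candidates = parse_terms(candidate_terms)
    if not candidates:
        raise ValueError("empty candidate set")
    y = design.response(response).to_numpy(dtype=float)
    values = _design_values(design, coding)
    n = len(y)
    use_pval = criterion in ("pvalue", "bonferroni")
    m = len(candidates)
    # familywise control of spurious entry: Bonferroni-divide the entry
    # threshold by the candidate-set size
    eff_enter = p_enter / m if criterion == "bonferroni" else p_enter

    current: list[Term] = []
    current_rss = _fit_rss(y, values, current)

    def children_of(parent: Term, terms: Sequence[Term]) -> list[Term]:
        return [t for t in terms if parent in t.parents()]

    while True:
        best_move = None  # (score_gain_key, new_terms, new_rss)
        cur_score = (np.nan if use_pval
                     else _criterion(current_rss, n, len(current), m, criterion))
        # additions (with heredity group)
        for cand in candidates:
            if cand in current:
                continue
            group = [p for p in cand.parents()
                     if p not in current and p in candidates] + [cand]
            new_terms = current + [g for g in group if g not in current]
            rss_new = _fit_rss(y, values, new_terms)
            if not np.isfinite(rss_new):
                continue
            added = len(new_terms) - len(current)
            if use_pval:
                df2 = n - len(new_terms) - 1
                if df2 <= 0 or rss_new <= 0:
                    continue
                f = ((current_rss - rss_new) / added) / (rss_new / df2)
                pv = stats.f.sf(f, added, df2)
                if pv < eff_enter:
                    key = pv
                    if best_move is None or key < best_move[0]:
                        best_move = (key, new_terms, rss_new)
            else:
                score = _criterion(rss_new, n, len(new_terms), m, criterion)
                if score < cur_score - 1e-10:
                    key = score
                    if best_move is None or key < best_move[0]:
                        best_move = (key, new_terms, rss_new)
        # removals (protect parents of remaining children)
        for t in current:
            if t.kind == "main" and children_of(t, [u for u in current if u != t]):
                continue
            new_terms = [u for u in current if u != t]
            rss_new = _fit_rss(y, values, new_terms)
            if not np.isfinite(rss_new):
                continue
            if use_pval:
                df2 = n - len(current) - 1
                if df2 <= 0 or current_rss <= 0:
                    continue
                f = (rss_new - current_rss) / (current_rss / df2)
                pv = stats.f.sf(f, 1, df2)
                if pv > p_exit:
                    key = -pv  # drop the least significant first
                    if best_move is None or key < best_move[0]:
                        best_move = (key, new_terms, rss_new)
            else:
                score = _criterion(rss_new, n, len(new_terms), m, criterion)
                if score < cur_score - 1e-10:
                    if best_move is None or score < best_move[0]:
                        best_move = (score, new_terms, rss_new)
        if best_move is None:
            break
        _, current, current_rss = best_move

    # deterministic presentation: mains, then interactions, then quadratics
    ordered = ([t for t in current if t.kind == "main"]
               + [t for t in current if t.kind == "interaction"]
               + [t for t in current if t.kind == "quadratic"])
    return ModelSpec(response, tuple(ordered), coding)


# -------------------------------------------------------------- validation

@dataclass
class FitStats:
    r2_train: float
    q2_test: float | None = None
    cv_rmse: float | None = None


def kfold_cv(design: DesignTable, spec: ModelSpec, k: int = 5,
             seed: int = 0) -> float:
    """Root-mean-square error of held-out predictions under a seeded k-fold split."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = design.n_runs
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} runs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    run_ids = design.data.index.to_numpy()
    se_sum, count = 0.0, 0
    for fold in folds:
        test_ids = run_ids[fold]
        train_ids = run_ids[np.setdiff1d(order, fold, assume_unique=False)]
        fitted = fit_ols(design.subset(train_ids), spec)
        held = design.subset(test_ids)
        yhat = fitted.predict({c: held.raw()[c].to_numpy()
                               for c in held.factor_names}, coding="raw")
        y = held.response(spec.response).to_numpy(dtype=float)
        se_sum += float(((y - yhat) ** 2).sum())
        count += len(y)
    return float(np.sqrt(se_sum / count))


def test_set_q2(fitted: FittedModel, test: DesignTable,
                method: str = "correlation") -> float:
    """Out-of-sample predictivity Q^2 on an independent test set.

    ``method="correlation"`` (default) returns the squared Pearson
    correlation between measured and model-predicted responses — the
    slope-and-intercept-free agreement a measured-vs-predicted
    regression plot reports.  ``method="press"`` returns the stricter
    1 - sum((y - yhat)^2) / sum((y - mean(y))^2), which also penalizes
    calibration offsets and can be negative.
    """
    y = test.response(fitted.spec.response).to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("zero-variance test responses")
    yhat = fitted.predict({c: test.raw()[c].to_numpy()
                           for c in test.factor_names}, coding="raw")
    if method == "press":
        return float(1.0 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    if method == "correlation":
        if np.ptp(yhat) == 0:
            return 0.0
        return float(np.corrcoef(y, yhat)[0, 1] ** 2)
    raise ValueError(f"unknown method {method!r}")
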