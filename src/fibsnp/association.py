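"""Covariate-adjusted association and gene-environment interaction models.

Three analysis phases over a phenotype/covariate table:

1. per-SNP group comparisons of each outcome by ANCOVA (OLS with group
   indicators plus covariates; group effect from a partial F test;
   adjusted means at covariate means),
2. outcome differences across IL-6 quartiles with Tukey
   honest-significant-difference post-hoc comparisons,
3. full-factorial genotype x IL-6 interaction models with per-genotype
   IL-6 slopes (simple within-group regressions with 95% CIs),
   Benjamini-Hochberg adjustment across SNPs, mediator (fibrinogen)
   re-adjustment, and the high-IL-6 sensitivity filter.

All models are complete-case per fit, so the analyzable n differs
between outcomes when values are missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_COVARIATES = ("age", "gender", "bmi", "hiv", "hba1c", "hdl")


class AliasingError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""


class DegenerateCutError(ValueError):
    """Ties leave an empty IL-6 quartile."""


class MediatorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    outcome: str
    terms: pd.DataFrame  # term, coef, se, t, p
    adjusted_means: pd.DataFrame  # group, mean, se, n
    p_group: float
    n: int
    r2: float
    covariates: tuple


@dataclass
class QuartileResult:
    outcome: str
    bounds: tuple  # 25/50/75 percentiles
    means: pd.DataFrame  # quartile, mean, se, n
    p: float
    tukey: pd.DataFrame  # group_i, group_j, diff, q, p
    n: int
    covariates: tuple


@dataclass
class InteractionResult:
    snp: str
    outcome: str
    interaction_p: float
    slopes: pd.DataFrame  # group, n, slope, ci_lo, ci_hi
    interaction_p_bh: float = np.nan
    interaction_p_adjusted: float = np.nan  # mediator-adjusted refit
    mediators: tuple = ()
    dropped_groups: list = field(default_factory=list)
    covariates: tuple = ()
    n: int = 0
    il6_col: str = "il6"
    group_labels: pd.Series | None = None  # retained for mediator refits


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by incremental QR
        aliased = []
        keep: list[str] = []
        for col in X.columns:
            sub = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(sub) == len(keep) + 1:
                keep.append(col)
            else:
                aliased.append(col)
        raise AliasingError(f"design is rank deficient; aliased terms: {aliased}")


def _ols(y: np.ndarray, X: pd.DataFrame):
    _check_rank(X)
    return sm.OLS(y, X).fit()


def _group_design(groups: pd.Series) -> tuple[pd.DataFrame, list]:
    """Treatment-coded indicators, reference = lowest group label."""
    levels = sorted(pd.unique(groups.dropna()))
    dummies = pd.DataFrame(
        {f"g[{lv}]": (groups == lv).astype(float) for lv in levels[1:]},
        index=groups.index,
    )
    return dummies, levels


def _partial_f(full, restricted) -> float:
    if full.ssr <= 1e-12:  # perfect fit: interaction removes all residual
        return 0.0 if restricted.ssr > full.ssr + 1e-12 else 1.0
    fstat, pval, _ = full.compare_f_test(restricted)
    return float(pval)


def _simple_slope(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """OLS slope of y on x with a 95% CI (slope, lo, hi)."""
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    lo, hi = res.conf_int()[1]
    return float(res.params[1]), float(lo), float(hi)


# ---------------------------------------------------------------------------
# phase 1: ANCOVA
# ---------------------------------------------------------------------------


def fit_ancova(
    data: pd.DataFrame,
    outcome: str,
    group: str | pd.Series,
    covariates: tuple = (),
) -> LinearFit:
    """OLS of ``outcome`` on group indicators + covariates.

    The group-effect p-value comes from the partial F test of the group
    indicators; adjusted group means are evaluated at the covariate
    means of the analyzed cases. Requires >= 2 groups with >= 2
    complete cases each; a rank-deficient design raises
    :class:`AliasingError` naming the aliased terms.
    """
    g = data[group] if isinstance(group, str) else group
    df = pd.DataFrame({"__y": data[outcome], "__g": g})
    for c in covariates:
        df[c] = data[c]
    df = df.dropna()
    counts = df["__g"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 complete cases each")

    dummies, levels = _group_design(df["__g"])
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    X = pd.concat([X, dummies, df[list(covariates)]], axis=1)
    res = _ols(df["__y"].to_numpy(), X)

    X0 = X.drop(columns=dummies.columns)
    res0 = sm.OLS(df["__y"].to_numpy(), X0).fit()
    p_group = _partial_f(res, res0)

    cov_means = df[list(covariates)].mean() if covariates else pd.Series(dtype=float)
    rows = []
    for lv in levels:
        v = pd.Series(0.0, index=X.columns)
        v["const"] = 1.0
        key = f"g[{lv}]"
        if key in v.index:
            v[key] = 1.0
        for c in covariates:
            v[c] = cov_means[c]
        mean = float(v @ res.params)
        se = float(np.sqrt(v @ res.cov_params() @ v))
        rows.append(
            {"group": lv, "mean": mean, "se": se, "n": int(counts[lv])}
        )

    terms = pd.DataFrame(
        {
            "term": X.columns,
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    return LinearFit(
        outcome=outcome,
        terms=terms,
        adjusted_means=pd.DataFrame(rows),
        p_group=p_group,
        n=len(df),
        r2=float(res.rsquared),
        covariates=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# phase 2: IL-6 quartiles with Tukey HSD
# ---------------------------------------------------------------------------


def assign_quartiles(il6: pd.Series) -> tuple[pd.Series, tuple]:
    """Quartile labels 1-4 from the 25/50/75 sample percentiles of the
    analyzed cases; boundary values go to the lower quartile."""
    x = il6.dropna()
    bounds = tuple(np.percentile(x, [25, 50, 75]))
    # value == bound -> lower quartile
    q = pd.Series(np.searchsorted(bounds, il6, side="left") + 1, index=il6.index)
    q[il6.isna()] = np.nan
    counts = q.value_counts()
    for k in range(1, 5):
        if counts.get(k, 0) == 0:
            raise DegenerateCutError(
                f"quartile {k} is empty: tied IL-6 values at bounds {bounds}"
            )
    return q, bounds


def quartile_analysis(
    data: pd.DataFrame,
    outcome: str,
    il6: str = "il6",
    covariates: tuple = (),
) -> QuartileResult:
    """Outcome means across IL-6 quartiles with ANOVA/ANCOVA p and
    Tukey HSD pairwise comparisons on the model residual variance."""
    cols = [outcome, il6, *covariates]
    df = data[cols].dropna()
    if len(df) < 8:
        raise ValueError("need >= 8 complete cases")
    q, bounds = assign_quartiles(df[il6])
    fit = fit_ancova(
        df.assign(__q=q), outcome, "__q", covariates=tuple(covariates)
    )
    dummies, levels = _group_design(q)
    X = pd.concat(
        [pd.DataFrame({"const": 1.0}, index=df.index), dummies, df[list(covariates)]],
        axis=1,
    )
    res = sm.OLS(df[outcome].to_numpy(), X).fit()
    mse = res.ssr / res.df_resid
    k = len(levels)
    rows = []
    am = fit.adjusted_means.set_index("group")
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            na, nb = int(am.loc[a, "n"]), int(am.loc[b, "n"])
            diff = float(am.loc[b, "mean"] - am.loc[a, "mean"])
            se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            qstat = abs(diff) / se
            p = float(stats.studentized_range.sf(qstat, k, res.df_resid))
            rows.append(
                {"group_i": a, "group_j": b, "diff": diff, "q": qstat, "p": p}
            )
    return QuartileResult(
        outcome=outcome,
        bounds=bounds,
        means=fit.adjusted_means.rename(columns={"group": "quartile"}),
        p=fit.p_group,
        tukey=pd.DataFrame(rows),
        n=len(df),
        covariates=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# phase 3: genotype x IL-6 interaction
# ---------------------------------------------------------------------------


def fit_interaction(
    data: pd.DataFrame,
    outcome: str,
    group_labels: pd.Series,
    il6: str = "il6",
    covariates: tuple = (),
    min_group_n: int = 10,
    snp: str = "",
    mediators: tuple = (),
) -> InteractionResult:
    """Full-factorial model: covariates + group + IL-6 + group x IL-6.

    The interaction p-value is the partial F test of the product terms;
    per-group slopes (with 95% CIs) are simple within-group regressions
    of the outcome on IL-6, the form in which stratified interaction
    effects are reported. Groups with fewer than ``min_group_n``
    complete cases are dropped with a warning and recorded. Optional
    ``mediators`` are added as covariates (used by
    :func:`adjust_for_mediators`).
    """
    for m in mediators:
        if m == outcome:
            raise MediatorError(f"mediator {m!r} is identical to the outcome")
    if isinstance(group_labels, pd.Series):
        g = group_labels.reindex(data.index)
    else:
        g = pd.Series(np.asarray(group_labels, dtype=float), index=data.index)
    df = pd.DataFrame({"__y": data[outcome], "__g": g, "__x": data[il6]})
    for c in (*covariates, *mediators):
        df[c] = data[c]
    df = df.dropna()

    counts = df["__g"].value_counts()
    dropped = [
        {"group": lv, "n": int(cnt)}
        for lv, cnt in counts.items()
        if cnt < min_group_n
    ]
    if dropped:
        warnings.warn(
            f"dropping degenerate groups {[d['group'] for d in dropped]} "
            f"(n < {min_group_n})",
            stacklevel=2,
        )
        df = df[~df["__g"].isin([d["group"] for d in dropped])]
    counts = df["__g"].value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 analyzable genotype groups")

    dummies, levels = _group_design(df["__g"])
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    X = pd.concat([X, df[list(covariates) + list(mediators)], dummies], axis=1)
    X["__x"] = df["__x"]
    inter_cols = []
    for col in dummies.columns:
        name = f"{col}:x"
        X[name] = dummies[col] * df["__x"]
        inter_cols.append(name)
    res = _ols(df["__y"].to_numpy(), X)
    res0 = sm.OLS(df["__y"].to_numpy(), X.drop(columns=inter_cols)).fit()
    p_int = _partial_f(res, res0)

    rows = []
    for lv in levels:
        sub = df[df["__g"] == lv]
        m, lo, hi = _simple_slope(sub["__y"].to_numpy(), sub["__x"].to_numpy())
        rows.append(
            {"group": lv, "n": len(sub), "slope": m, "ci_lo": lo, "ci_hi": hi}
        )
    return InteractionResult(
        snp=snp,
        outcome=outcome,
        interaction_p=p_int,
        slopes=pd.DataFrame(rows),
        mediators=tuple(mediators),
        dropped_groups=dropped,
        covariates=tuple(covariates),
        n=len(df),
        il6_col=il6,
        group_labels=g,
    )


def adjust_for_mediators(
    results: list[InteractionResult],
    data: pd.DataFrame,
    mediators: tuple = ("fibrinogen_total", "fibrinogen_gamma"),
    min_group_n: int = 10,
) -> list[InteractionResult]:
    """Refit each interaction model with mediator covariates added and
    store the adjusted interaction p next to the raw one.

    Used after a clot-property outcome shows genotype or interaction
    effects: loss of significance under fibrinogen adjustment indicates
    mediation through fibrinogen concentration rather than a direct
    genotype effect on the clot phenotype. Refuses a mediator equal to
    the outcome.
    """
    out = []
    for r in results:
        meds = tuple(m for m in mediators if m in data.columns)
        for m in meds:
            if m == r.outcome:
                raise MediatorError(
                    f"mediator {m!r} is identical to outcome {r.outcome!r}"
                )
        try:
            refit = fit_interaction(
                data,
                r.outcome,
                r.group_labels,
                il6=r.il6_col,
                covariates=r.covariates,
                min_group_n=min_group_n,
                snp=r.snp,
                mediators=meds,
            )
            r.interaction_p_adjusted = refit.interaction_p
        except ValueError:
            # mediator complete cases leave < 2 analyzable groups
            r.interaction_p_adjusted = np.nan
        r.mediators = meds
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# multiplicity and sensitivity
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, p'_(i) = min_{j >= i} min(1, m p_(j) / j);
    order-preserving and never smaller than the raw p.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def apply_bh(results: list[InteractionResult]) -> list[InteractionResult]:
    """BH family: one outcome across SNPs (the conservative reading)."""
    adj = bh_adjust([r.interaction_p for r in results])
    for r, a in zip(results, adj):
        r.interaction_p_bh = float(a)
    return results


def sensitivity_filter(
    data: pd.DataFrame, il6_cutoff: float = 100.0, il6: str = "il6"
) -> tuple[pd.DataFrame, int]:
    """Drop samples with IL-6 above the cutoff (pg/mL); returns the
    filtered table and the removed count, for re-running the models."""
    keep = ~(data[il6] > il6_cutoff)
    return data[keep].copy(), int((~keep).sum())


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------


class _ParamsMixin:
    _param_names: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


class AncovaModel(_ParamsMixin):
    """Group-comparison ANCOVA as an estimator: ``fit(data)`` exposes
    ``fit_`` (:class:`LinearFit`), ``p_group_``, ``adjusted_means_``."""

    _param_names = ("outcome", "group", "covariates")

    def __init__(self, outcome: str, group: str, covariates: tuple = ()):
        self.outcome = outcome
        self.group = group
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_ = fit_ancova(X, self.outcome, self.group, tuple(self.covariates))
        self.p_group_ = self.fit_.p_group
        self.adjusted_means_ = self.fit_.adjusted_means
        self.n_ = self.fit_.n
        return self


class QuartileModel(_ParamsMixin):
    _param_names = ("outcome", "il6", "covariates")

    def __init__(self, outcome: str, il6: str = "il6", covariates: tuple = ()):
        self.outcome = outcome
        self.il6 = il6
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_ = quartile_analysis(X, self.outcome, self.il6, tuple(self.covariates))
        self.p_ = self.fit_.p
        self.tukey_ = self.fit_.tukey
        self.bounds_ = self.fit_.bounds
        return self


class InteractionModel(_ParamsMixin):
    """Genotype x IL-6 full-factorial ANCOVA as an estimator.

    ``group_col`` names a column of collapsed genotype-group labels in
    the fitted frame. After ``fit``: ``interaction_p_``, ``slopes_``
    and, when mediators are set, ``interaction_p_adjusted_``.
    """

    _param_names = (
        "outcome", "group_col", "il6", "covariates", "mediators", "min_group_n",
    )

    def __init__(
        self,
        outcome: str,
        group_col: str,
        il6: str = "il6",
        covariates: tuple = DEFAULT_COVARIATES,
        mediators: tuple = (),
        min_group_n: int = 10,
    ):
        self.outcome = outcome
        self.group_col = group_col
        self.il6 = il6
        self.covariates = covariates
        self.mediators = mediators
        self.min_group_n = min_group_n

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_ = fit_interaction(
            X,
            self.outcome,
            X[self.group_col],
            il6=self.il6,
            covariates=tuple(self.covariates),
            min_group_n=self.min_group_n,
            mediators=tuple(self.mediators),
        )
        self.interaction_p_ = self.fit_.interaction_p
        self.slopes_ = self.fit_.slopes
        self.n_ = self.fit_.n
        if self.mediators:
            self.interaction_p_adjusted_ = self.fit_.interaction_p
        return self
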