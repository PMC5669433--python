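"""Cumulative minor-allele risk score and its IL-6 interaction.

The score sums per-SNP codes over a chosen SNP set: 0 for major-allele
homozygotes, 1 for heterozygotes and 2 for minor-allele homozygotes
under three-level coding, or 0/1 under carrier coding for low-MAF SNPs
whose minor-homozygote group is underpowered. The coding per SNP is
derived from the same minimum-group-size rule used to collapse
genotype groups in the single-SNP analyses.

The score x IL-6 interaction is tested in a full-factorial ANCOVA with
the score as a categorical factor; per-score IL-6 slopes come from
within-score regressions, and pairwise slope equality is tested by
Wald contrasts on the interaction coefficients. Score levels with too
few samples are excluded (and reported) before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import DEFAULT_COVARIATES, _check_rank, _simple_slope
from .popgen import GenotypeTable, collapse_genotype_groups


@dataclass
class RiskScoreResult:
    scores: pd.Series  # per-sample score (NaN: incomplete genotypes)
    coding: dict  # snp -> 'carrier' | 'additive'
    group_table: pd.DataFrame  # score, n, slope, ci_lo, ci_hi, excluded
    interaction_p: float
    pairwise_p: pd.DataFrame  # score x score matrix of slope-equality p
    excluded_levels: list
    min_group_n: int
    n_excluded_samples: int = 0
    covariates: tuple = ()


def build_risk_score(
    genotypes: GenotypeTable,
    snp_ids: list[str],
    codings: dict | None = None,
    collapse_threshold: int = 71,
) -> tuple[pd.Series, dict]:
    """Per-sample cumulative score over ``snp_ids``.

    ``codings`` maps snp -> 'carrier' (0/1) or 'additive' (0/1/2); by
    default the coding is derived per SNP from the minor-homozygote
    group-size rule: carrier coding whenever that group is below
    ``collapse_threshold``. Samples missing any contributing genotype
    get a missing score (excluded and counted downstream).
    """
    if not snp_ids:
        raise ValueError("empty SNP list")
    if codings is None:
        codings = {}
        for sid in snp_ids:
            grouping = collapse_genotype_groups(
                genotypes.column(sid), threshold=collapse_threshold
            )
            codings[sid] = "carrier" if grouping.mode == "carrier" else "additive"
    total = np.zeros(genotypes.n_samples)
    missing = np.zeros(genotypes.n_samples, dtype=bool)
    for sid in snp_ids:
        g = genotypes.column(sid)
        missing |= np.isnan(g)
        coded = np.where(g > 0, 1.0, 0.0) if codings[sid] == "carrier" else g
        total = total + np.where(np.isnan(g), 0.0, coded)
    total[missing] = np.nan
    return (
        pd.Series(total, index=genotypes.sample_ids, name="risk_score"),
        dict(codings),
    )


def score_interaction_analysis(
    data: pd.DataFrame,
    scores: pd.Series,
    outcome: str = "fibrinogen_total",
    il6: str = "il6",
    covariates: tuple = DEFAULT_COVARIATES,
    min_group_n: int = 71,
) -> RiskScoreResult:
    """Full-factorial score x IL-6 model with per-score slopes.

    Model: covariates + score (categorical) + IL-6 + score x IL-6;
    the interaction p is the partial F test of the product terms.
    Per-score slopes and 95% CIs come from within-score regressions of
    the outcome on IL-6; pairwise slope equality is a Wald z test on
    contrasts of the interaction coefficients (each score level's slope
    offset against the reference level). Score levels with fewer than
    ``min_group_n`` complete cases are excluded and reported.
    """
    s = scores.to_numpy() if len(scores) == len(data) else scores.reindex(
        data["sample_id"]
    ).to_numpy()
    df = pd.DataFrame({"__y": data[outcome].to_numpy(), "__x": data[il6].to_numpy(),
                       "__s": s})
    for c in covariates:
        df[c] = data[c].to_numpy()
    n_all = len(df)
    df = df.dropna()
    n_excluded_samples = n_all - len(df)

    counts = df["__s"].value_counts().sort_index()
    levels_all = [int(v) for v in counts.index]
    excluded = [
        {"score": lv, "n": int(counts[lv])}
        for lv in levels_all
        if counts[lv] < min_group_n
    ]
    if excluded:
        warnings.warn(
            f"excluding score levels {[e['score'] for e in excluded]} "
            f"(n < {min_group_n})",
            stacklevel=2,
        )
    retained = [lv for lv in levels_all if counts[lv] >= min_group_n]
    if len(retained) < 2:
        raise ValueError("fewer than 2 retained score levels")
    df = df[df["__s"].isin(retained)]

    ref = retained[0]
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for c in covariates:
        X[c] = df[c]
    inter_cols = {}
    for lv in retained[1:]:
        ind = (df["__s"] == lv).astype(float)
        X[f"s[{lv}]"] = ind
        X[f"s[{lv}]:x"] = ind * df["__x"]
        inter_cols[lv] = f"s[{lv}]:x"
    X["__x"] = df["__x"]
    _check_rank(X)
    res = sm.OLS(df["__y"].to_numpy(), X).fit()
    res0 = sm.OLS(
        df["__y"].to_numpy(), X.drop(columns=list(inter_cols.values()))
    ).fit()
    if res.ssr <= 1e-12:
        p_int = 0.0 if res0.ssr > res.ssr + 1e-12 else 1.0
    else:
        _, p_int, _ = res.compare_f_test(res0)

    # per-score slopes from within-group regressions
    rows = []
    for lv in levels_all:
        sub = df[df["__s"] == lv]
        if lv in retained:
            m, lo, hi = _simple_slope(sub["__y"].to_numpy(), sub["__x"].to_numpy())
        else:
            m = lo = hi = np.nan
        rows.append(
            {
                "score": lv,
                "n": int(counts[lv]),
                "slope": m,
                "ci_lo": lo,
                "ci_hi": hi,
                "excluded": lv not in retained,
            }
        )

    # Wald contrasts on the interaction coefficients: slope(lv) - slope(lw)
    cov = res.cov_params()
    params = res.params
    pw = pd.DataFrame(np.nan, index=retained, columns=retained)
    for i, lv in enumerate(retained):
        for lw in retained[i + 1 :]:
            vec = pd.Series(0.0, index=X.columns)
            if lv != ref:
                vec[inter_cols[lv]] = 1.0
            if lw != ref:
                vec[inter_cols[lw]] -= 1.0
            est = float(vec @ params)
            se = float(np.sqrt(vec @ cov @ vec))
            z = est / se if se > 0 else np.inf
            p = float(2 * stats.t.sf(abs(z), res.df_resid))
            pw.loc[lv, lw] = pw.loc[lw, lv] = p

    return RiskScoreResult(
        scores=scores,
        coding={},
        group_table=pd.DataFrame(rows),
        interaction_p=float(p_int),
        pairwise_p=pw,
        excluded_levels=excluded,
        min_group_n=min_group_n,
        n_excluded_samples=n_excluded_samples,
        covariates=tuple(covariates),
    )


class RiskScoreModel:
    """Estimator combining score construction and interaction analysis.

    fit(X) expects a phenotype frame whose rows align with the genotype
    table passed at construction; fitted attributes: ``scores_``,
    ``coding_``, ``interaction_p_``, ``group_table_``, ``pairwise_p_``.
    """

    def __init__(
        self,
        genotypes: GenotypeTable,
        snp_ids: list[str],
        outcome: str = "fibrinogen_total",
        il6: str = "il6",
        covariates: tuple = DEFAULT_COVARIATES,
        min_group_n: int = 71,
        collapse_threshold: int = 71,
    ):
        self.genotypes = genotypes
        self.snp_ids = snp_ids
        self.outcome = outcome
        self.il6 = il6
        self.covariates = covariates
        self.min_group_n = min_group_n
        self.collapse_threshold = collapse_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "genotypes", "snp_ids", "outcome", "il6", "covariates",
                "min_group_n", "collapse_threshold",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        scores, coding = build_risk_score(
            self.genotypes, self.snp_ids, collapse_threshold=self.collapse_threshold
        )
        result = score_interaction_analysis(
            X,
            scores,
            outcome=self.outcome,
            il6=self.il6,
            covariates=tuple(self.covariates),
            min_group_n=self.min_group_n,
        )
        result.coding = coding
        self.scores_ = scores
        self.coding_ = coding
        self.interaction_p_ = result.interaction_p
        self.group_table_ = result.group_table
        self.pairwise_p_ = result.pairwise_p
        self.result_ = result
        return self


def write_score_table(result: RiskScoreResult, path) -> None:
    result.group_table.to_csv(path, sep="\t", index=False)


def pairwise_to_json(result: RiskScoreResult, path) -> None:
    import json

    payload = {
        f"{int(i)}-{int(j)}": float(result.pairwise_p.loc[i, j])
        for i in result.pairwise_p.index
        for j in result.pairwise_p.columns
        if i < j and np.isfinite(result.pairwise_p.loc[i, j])
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
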