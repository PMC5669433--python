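"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a cross-sectional cohort in which circulating
IL-6 drives total fibrinogen with a genotype-dependent slope:

    fibrinogen_i = c0 + sum_s c_g(s) + [m0 + sum_s m_g(s)] * IL6_i
                   + covariate effects + noise

where ``c_g``/``m_g`` are per-SNP per-genotype intercept and slope
contributions from the effect map. IL-6 is log-normal (heavy-tailed,
moment-matched to a target mean/SD); gamma' fibrinogen is a uniform
fraction of total; clot phenotypes derive from total fibrinogen (and
PAI-1 activity for lysis time) through a configurable monotone linear
forward model; turbidity curves are double-logistic rise-and-fall
kinetics parameterised by those phenotypes.

Linked SNP groups are sampled as two-state haplotype Markov chains that
hit the configured pairwise D' targets exactly in expectation; unlinked
SNPs are drawn independently under Hardy-Weinberg proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .popgen import GenotypeTable, SNPMeta
from .turbidity import CurveFeatures, InvalidKineticsError, TurbidityCurve


class LDFeasibilityError(ValueError):
    pass


class EffectMapError(KeyError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SNPSpec:
    id: str
    gene: str = ""
    major: str = "G"
    minor: str = "A"
    maf: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.id}: MAF must be in [0, 0.5]")


@dataclass
class LDPairSpec:
    snp_i: str
    snp_j: str
    d_prime: float
    r2: float | None = None  # optional joint-feasibility check target


@dataclass
class CovariateSpec:
    """One generated covariate: sampling distribution + additive effect
    on total fibrinogen (g/L per unit of the covariate)."""

    dist: str  # 'normal' | 'bernoulli' | 'lognormal' | 'uniform'
    params: tuple
    effect: float = 0.0


def default_covariates() -> dict[str, CovariateSpec]:
    """Age, gender, BMI, HIV status, HbA1c, HDL-c, PAI-1 activity with
    small additive fibrinogen effects; distributions are plausible for a
    middle-aged African cohort and are config, not inference."""
    return {
        "age": CovariateSpec("uniform", (35.0, 70.0), 0.01),
        "gender": CovariateSpec("bernoulli", (0.6,), 0.15),
        "bmi": CovariateSpec("normal", (26.0, 6.0), 0.02),
        "hiv": CovariateSpec("bernoulli", (0.15,), 0.3),
        "hba1c": CovariateSpec("normal", (5.8, 1.0), 0.05),
        "hdl": CovariateSpec("normal", (1.5, 0.5), -0.2),
        "pai1_act": CovariateSpec("normal", (7.0, 3.0), 0.0),
    }


@dataclass
class CurveModel:
    """Monotone linear forward map from phenotypes to clot features.

    maxabs rises with fibrinogen (fibre diameter), slope rises with
    fibrinogen (lateral aggregation), CLT rises with fibrinogen and
    with PAI-1 activity (slower lysis under inhibition). Coefficients
    are config: the source analysis reports associations, not a
    mechanistic forward model.
    """

    baseline_au: float = 0.10
    maxabs_intercept: float = 0.25
    maxabs_per_fib: float = 0.05
    slope_e3_intercept: float = 4.0
    slope_e3_per_fib: float = 1.5
    lag_intercept_min: float = 6.0
    lag_per_fib: float = 0.12
    clt_intercept_min: float = 38.0
    clt_per_fib: float = 2.0
    clt_per_pai1: float = 1.6
    t_form_mid_min: float = 10.0


DEFAULT_NOISE_SD = {
    "fibrinogen_total": 2.0,
    "fibrinogen_gamma": 0.05,
    "lag_min": 1.9,
    "slope_e3_au_s": 4.0,
    "maxabs_au": 0.13,
    "clt_min": 8.0,
}


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort.

    effect_map: snp id -> {genotype (0/1/2): (intercept g/L, slope g/L
    per pg/mL)} contributions, additive across SNPs on top of
    ``base_intercept``/``base_slope``. For a single-SNP effect map the
    population regression slope of fibrinogen on IL-6 within a genotype
    stratum is exactly ``base_slope + m(genotype)``.
    """

    n_samples: int = 2000
    snps: list[SNPSpec] = field(default_factory=list)
    ld_pairs: list[LDPairSpec] = field(default_factory=list)
    il6_log_mean: float = 0.6536
    il6_log_sd: float = 1.5610
    base_intercept: float = 3.0
    base_slope: float = 0.0
    effect_map: dict = field(default_factory=dict)
    gammaprime_fraction_range: tuple[float, float] = (0.08, 0.15)
    covariates: dict = field(default_factory=default_covariates)
    curve_model: CurveModel = field(default_factory=CurveModel)
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    missing_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.gammaprime_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("gamma' fraction range must be within [0, 1]")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        by_id = {s.id: s for s in self.snps}
        for pair in self.ld_pairs:
            for sid in (pair.snp_i, pair.snp_j):
                if sid not in by_id:
                    raise ValueError(f"LD pair references unknown SNP {sid!r}")
            a, b = by_id[pair.snp_i], by_id[pair.snp_j]
            # raises LDFeasibilityError on an infeasible (MAF, D') combination
            freqs = simulate_haplotype_pool(a.maf, b.maf, pair.d_prime)
            if pair.r2 is not None:
                got = implied_r2(a.maf, b.maf, pair.d_prime)
                if abs(got - pair.r2) > 0.05:
                    raise LDFeasibilityError(
                        f"({pair.snp_i},{pair.snp_j}): target r2={pair.r2} "
                        f"is not jointly feasible with D'={pair.d_prime} at "
                        f"these MAFs (implied r2={got:.3f})"
                    )
            del freqs
        for rate in self.missing_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must be in [0, 1]")
        for sid in self.effect_map:
            if sid not in by_id:
                raise EffectMapError(f"effect map references unknown SNP {sid!r}")

    @classmethod
    def il6_params_from_moments(cls, mean: float, sd: float) -> tuple[float, float]:
        """Log-normal (mu, sigma) matching a target mean and SD."""
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


@dataclass
class Cohort:
    genotypes: GenotypeTable
    phenotypes: pd.DataFrame
    curves: list[TurbidityCurve] | None
    truth: CohortConfig


# ---------------------------------------------------------------------------
# haplotype pools and genotypes
# ---------------------------------------------------------------------------


def simulate_haplotype_pool(
    maf_a: float, maf_b: float, d_prime: float
) -> np.ndarray:
    """Four haplotype frequencies hitting the target MAFs and D' exactly.

    Order matches :data:`fibsnp.popgen.HAPLOTYPE_ORDER`:
    (major-major, major-minor, minor-major, minor-minor), with D > 0
    coupling the two minor alleles. Raises :class:`LDFeasibilityError`
    with the admissible D' range when the combination is infeasible.
    """
    for name, maf in (("maf_a", maf_a), ("maf_b", maf_b)):
        if not 0.0 < maf <= 0.5:
            raise LDFeasibilityError(
                f"{name}={maf}: MAF must be in (0, 0.5]; admissible D' "
                "range is empty for a monomorphic locus"
            )
    if not 0.0 <= d_prime <= 1.0:
        raise LDFeasibilityError(
            f"d_prime={d_prime} outside the admissible range [0, 1]"
        )
    p, q = maf_a, maf_b
    dmax = min(p * (1 - q), (1 - p) * q)
    D = d_prime * dmax
    f = np.array(
        [
            (1 - p) * (1 - q) + D,
            (1 - p) * q - D,
            p * (1 - q) - D,
            p * q + D,
        ]
    )
    assert abs(f.sum() - 1.0) < 1e-12
    return f


def implied_r2(maf_a: float, maf_b: float, d_prime: float) -> float:
    """r^2 implied by (MAFs, D'); r^2 is fully determined by them."""
    f = simulate_haplotype_pool(maf_a, maf_b, d_prime)
    D = f[3] - maf_a * maf_b
    return float(
        D * D / (maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
    )


def _ld_groups(config: CohortConfig) -> list[list[str]]:
    """Connected components of the LD-pair graph, each ordered as a
    chain following the configured SNP order."""
    order = {s.id: k for k, s in enumerate(config.snps)}
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in config.ld_pairs:
        a, b = find(pair.snp_i), find(pair.snp_j)
        if a != b:
            parent[a] = b
    groups: dict[str, list[str]] = {}
    for pair in config.ld_pairs:
        for sid in (pair.snp_i, pair.snp_j):
            groups.setdefault(find(sid), [])
            if sid not in groups[find(sid)]:
                groups[find(sid)].append(sid)
    out = []
    for members in groups.values():
        members.sort(key=lambda s: order[s])
        out.append(members)
    out.sort(key=lambda g: order[g[0]])
    return out


def _pair_target(config: CohortConfig, a: str, b: str) -> float:
    for pair in config.ld_pairs:
        if {pair.snp_i, pair.snp_j} == {a, b}:
            return pair.d_prime
    raise LDFeasibilityError(
        f"LD group members {a!r},{b!r} are adjacent in the chain but have "
        "no configured pairwise D' target"
    )


def simulate_genotypes(
    config: CohortConfig, seed: int | None = None, rng=None
) -> GenotypeTable:
    """Diploid 0/1/2 genotypes for every configured SNP.

    Each LD group is sampled as a haplotype Markov chain along the
    configured SNP order (two independent haplotypes per individual),
    so adjacent pairwise D' targets are hit exactly in expectation;
    SNPs outside any group are independent binomial draws under HWE.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    mafs = {s.id: s.maf for s in config.snps}
    calls = {}

    grouped: set[str] = set()
    for members in _ld_groups(config):
        grouped.update(members)
        hap = np.zeros((2 * n, len(members)), dtype=np.int8)
        first = members[0]
        hap[:, 0] = rng.random(2 * n) < mafs[first]
        for k in range(1, len(members)):
            prev_id, cur_id = members[k - 1], members[k]
            f = simulate_haplotype_pool(
                mafs[prev_id], mafs[cur_id], _pair_target(config, prev_id, cur_id)
            )
            p_prev = mafs[prev_id]
            # P(minor at current | haplotype state at previous locus)
            p_given_minor = f[3] / p_prev
            p_given_major = f[1] / (1 - p_prev)
            u = rng.random(2 * n)
            hap[:, k] = np.where(
                hap[:, k - 1] == 1, u < p_given_minor, u < p_given_major
            )
        geno = hap[:n] + hap[n:]
        for k, sid in enumerate(members):
            calls[sid] = geno[:, k].astype(float)

    for s in config.snps:
        if s.id in grouped:
            continue
        if s.maf == 0.0:
            calls[s.id] = np.zeros(n)
        else:
            calls[s.id] = rng.binomial(2, s.maf, size=n).astype(float)

    if config.snps:
        mat = np.column_stack([calls[s.id] for s in config.snps])
    else:
        mat = np.zeros((n, 0))
    rate = config.missing_rates.get("genotypes", 0.0)
    if rate > 0:
        mat[rng.random(mat.shape) < rate] = np.nan
    return GenotypeTable(
        snps=[
            SNPMeta(id=s.id, gene=s.gene, major=s.major, minor=s.minor, order=k)
            for k, s in enumerate(config.snps)
        ],
        calls=mat,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _sample_covariate(spec: CovariateSpec, n: int, rng) -> np.ndarray:
    if spec.dist == "normal":
        return rng.normal(spec.params[0], spec.params[1], n)
    if spec.dist == "lognormal":
        return rng.lognormal(spec.params[0], spec.params[1], n)
    if spec.dist == "bernoulli":
        return (rng.random(n) < spec.params[0]).astype(float)
    if spec.dist == "uniform":
        return rng.uniform(spec.params[0], spec.params[1], n)
    raise ValueError(f"unknown covariate distribution {spec.dist!r}")


def simulate_phenotypes(
    genotypes: GenotypeTable,
    config: CohortConfig,
    seed: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Phenotype/covariate records matched to the genotype table rows.

    Raises :class:`EffectMapError` when a genotype present in the data
    has no entry in the effect map of a listed SNP.
    """
    if rng is None:
        rng = np.random.default_rng(
            config.seed + 1 if seed is None else seed
        )
    n = genotypes.n_samples
    if n != config.n_samples:
        raise ValueError("genotype table size does not match config")

    il6 = rng.lognormal(config.il6_log_mean, config.il6_log_sd, n)

    cov_vals = {}
    cov_effect = np.zeros(n)
    for name, spec in config.covariates.items():
        x = _sample_covariate(spec, n, rng)
        cov_vals[name] = x
        cov_effect += spec.effect * (x - np.mean(x))

    intercept = np.full(n, config.base_intercept, dtype=float)
    slope = np.full(n, config.base_slope, dtype=float)
    for sid, per_geno in config.effect_map.items():
        g = genotypes.column(sid)
        obs = np.unique(g[~np.isnan(g)]).astype(int)
        for lvl in obs:
            if lvl not in per_geno:
                raise EffectMapError(
                    f"effect map for {sid!r} lacks genotype level {lvl}"
                )
        c = np.zeros(n)
        m = np.zeros(n)
        for lvl, (ci, mi) in per_geno.items():
            mask = g == lvl
            c[mask] = ci
            m[mask] = mi
        intercept += c
        slope += m

    nsd = config.noise_sd
    fib = intercept + slope * il6 + cov_effect + rng.normal(
        0.0, nsd.get("fibrinogen_total", 0.0), n
    )
    lo, hi = config.gammaprime_fraction_range
    frac = rng.uniform(lo, hi, n)
    gamma = frac * fib + rng.normal(0.0, nsd.get("fibrinogen_gamma", 0.0), n)

    cm = config.curve_model
    pai1 = cov_vals.get("pai1_act", np.zeros(n))
    maxabs = (
        cm.maxabs_intercept
        + cm.maxabs_per_fib * fib
        + rng.normal(0.0, nsd.get("maxabs_au", 0.0), n)
    )
    slope_e3 = (
        cm.slope_e3_intercept
        + cm.slope_e3_per_fib * fib
        + rng.normal(0.0, nsd.get("slope_e3_au_s", 0.0), n)
    )
    lag = (
        cm.lag_intercept_min
        + cm.lag_per_fib * fib
        + rng.normal(0.0, nsd.get("lag_min", 0.0), n)
    )
    clt = (
        cm.clt_intercept_min
        + cm.clt_per_fib * fib
        + cm.clt_per_pai1 * pai1
        + rng.normal(0.0, nsd.get("clt_min", 0.0), n)
    )

    df = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "il6": il6,
            "fibrinogen_total": fib,
            "fibrinogen_gamma": gamma,
            "gamma_pct": 100.0 * gamma / fib,
            "lag_min": lag,
            "slope_e3_au_s": slope_e3,
            "maxabs_au": maxabs,
            "clt_min": clt,
            **cov_vals,
        }
    )
    for col, rate in config.missing_rates.items():
        if col in df.columns and col != "sample_id" and rate > 0:
            df.loc[rng.random(n) < rate, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


def double_logistic(
    t: np.ndarray,
    baseline: float,
    amplitude: float,
    t_form_s: float,
    s_form_s: float,
    t_lys_s: float,
    s_lys_s: float,
) -> np.ndarray:
    """Rise-and-fall kinetics: logistic formation times logistic decay."""
    rise = 1.0 / (1.0 + np.exp(-(t - t_form_s) / s_form_s))
    fall = 1.0 / (1.0 + np.exp(-(t - t_lys_s) / s_lys_s))
    return baseline + amplitude * rise * (1.0 - fall)


def simulate_curve(
    features: CurveFeatures,
    sampling_step: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng=None,
    s_lys_s: float | None = None,
    duration_s: float | None = None,
    sample_id: str = "",
) -> TurbidityCurve:
    """Double-logistic curve whose extracted features match the input.

    The formation shape parameter is chosen so the analytic maximum
    rate amplitude/(4*s_form) equals the requested slope; the lysis
    midpoint sits CLT minutes after the formation midpoint. Requires a
    positive CLT (:class:`InvalidKineticsError` otherwise).
    """
    if sampling_step <= 0:
        raise ValueError("sampling_step must be positive")
    amp = features.max_absorbance
    if amp < 0:
        raise ValueError("amplitude must be nonnegative")
    t_form = features.t_form_mid_min * 60.0
    clt_s = features.clt_min * 60.0
    if not clt_s > 0:
        raise InvalidKineticsError("lysis midpoint must follow formation")
    t_lys = t_form + clt_s
    if amp > 0 and features.slope_au_s > 0:
        s_form = amp / (4.0 * features.slope_au_s)
    else:
        s_form = 60.0
    if s_lys_s is None:
        s_lys_s = 1.5 * s_form
    if duration_s is None:
        duration_s = t_lys + 12.0 * s_lys_s
    t = np.arange(0.0, duration_s + sampling_step / 2, sampling_step)
    if amp == 0:
        y = np.full_like(t, features.baseline)
    else:
        y = double_logistic(t, features.baseline, amp, t_form, s_form, t_lys, s_lys_s)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, t.size)
    return TurbidityCurve(t, y, sample_id=sample_id)


def control_curve_features() -> CurveFeatures:
    """External-control kinetics: pooled-plasma reagents titrated so the
    control lysis time lands between 60 and 100 minutes."""
    return CurveFeatures(
        lag_min=6.5,
        slope_au_s=9.6e-3,
        max_absorbance=0.40,
        clt_min=80.0,
        baseline=0.10,
        plateau=0.50,
        t_form_mid_min=10.0,
        t_lys_mid_min=90.0,
    )


def features_from_phenotypes(row: pd.Series, cm: CurveModel) -> CurveFeatures:
    return CurveFeatures(
        lag_min=row["lag_min"],
        slope_au_s=row["slope_e3_au_s"] * 1e-3,
        max_absorbance=row["maxabs_au"],
        clt_min=row["clt_min"],
        baseline=cm.baseline_au,
        plateau=cm.baseline_au + row["maxabs_au"],
        t_form_mid_min=cm.t_form_mid_min,
        t_lys_mid_min=cm.t_form_mid_min + row["clt_min"],
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: CohortConfig,
    seed: int | None = None,
    include_curves: bool = False,
    curve_sampling_step: float = 2.0,
    curve_noise_sd: float = 0.0,
) -> Cohort:
    """Generate genotypes, phenotypes and (optionally) turbidity curves.

    A fixed seed reproduces the cohort bit-for-bit; per-stage child
    streams are derived from one SeedSequence so stages stay decoupled.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    ss_geno, ss_pheno, ss_curve = root.spawn(3)
    genotypes = simulate_genotypes(config, rng=np.random.default_rng(ss_geno))
    phenotypes = simulate_phenotypes(
        genotypes, config, rng=np.random.default_rng(ss_pheno)
    )
    curves = None
    if include_curves:
        rng = np.random.default_rng(ss_curve)
        curves = []
        for _, row in phenotypes.iterrows():
            if row[["maxabs_au", "clt_min", "slope_e3_au_s"]].isna().any():
                continue
            feats = features_from_phenotypes(row, config.curve_model)
            if feats.clt_min <= 0 or feats.max_absorbance <= 0:
                continue
            curves.append(
                simulate_curve(
                    feats,
                    sampling_step=curve_sampling_step,
                    noise_sd=curve_noise_sd,
                    rng=rng,
                    sample_id=row["sample_id"],
                )
            )
    return Cohort(genotypes, phenotypes, curves, truth=config)


# ---------------------------------------------------------------------------
# calibrated scenario configurations
# ---------------------------------------------------------------------------

#: 14 fibrinogen-cluster SNPs in genomic order. MAFs follow the printed
#: values where available and are otherwise derived from collapsed
#: genotype-group counts; the novel promoter SNP rs2227385 is assigned
#: a MAF between its strongly linked neighbours.
STUDY_SNPS = [
    ("rs7439150", "FGB", 0.0695),
    ("rs2227385", "FGB", 0.0686),
    ("rs1800789", "FGB", 0.0678),
    ("rs2227388", "FGB", 0.100),
    ("rs1800791", "FGB", 0.050),
    ("rs1800790", "FGB", 0.0332),
    ("rs1800788", "FGB", 0.050),
    ("rs1800787", "FGB", 0.059),
    ("rs4220", "FGB", 0.087),
    ("rs4463047", "FGB", 0.114),
    ("rs6050", "FGA", 0.296),
    ("rs2070011", "FGA", 0.168),
    ("rs2066865", "FGG", 0.261),
    ("rs1049636", "FGG", 0.149),
]

#: Within-block D' targets. Within-block pairwise D' sits near (but
#: below) complete coupling, the pattern the blocks were called from;
#: chaining the FGB promoter trio at adjacent D' = 0.985 implies
#: D' ~ 0.97 / r^2 ~ 0.92 for its outer pair, and the FGG 3'UTR pair's
#: unequal MAFs keep its r^2 well below 1 despite D' = 0.99.
STUDY_LD_PAIRS = [
    LDPairSpec("rs7439150", "rs2227385", 0.985),
    LDPairSpec("rs2227385", "rs1800789", 0.985),
    LDPairSpec("rs2066865", "rs1049636", 0.99),
]


def carrier_effect(m_major: float, m_carrier: float, c_major: float = 0.0,
                   c_carrier: float = 0.0) -> dict:
    """Effect-map entry under minor-allele-carrier coding."""
    return {
        0: (c_major, m_major),
        1: (c_carrier, m_carrier),
        2: (c_carrier, m_carrier),
    }


#: Carrier-coded IL-6 slope contributions (g/L per pg/mL) relative to a
#: shared base slope, for the SNPs with reported genotype-dependent
#: IL-6 response; slopes for the remaining SNPs are flat.
STUDY_SLOPE_EFFECTS = {
    "rs7439150": carrier_effect(0.0, 0.057),
    "rs1800789": carrier_effect(0.0, 0.059),
    "rs1800788": carrier_effect(0.0, 0.066),
    "rs1800787": carrier_effect(0.0, 0.061),
    "rs4220": carrier_effect(0.0, 0.045),
    "rs2070011": carrier_effect(0.0, 0.027),
    "rs1049636": carrier_effect(0.0, 0.096),
}


def study_config(n_samples: int = 2010, seed: int = 0,
                 with_missingness: bool = True) -> CohortConfig:
    """Full 14-SNP cohort mirroring the study conditions: printed MAFs,
    the two LD blocks, heavy-tailed IL-6 (mean 6.5, SD 21 pg/mL),
    carrier-coded genotype-dependent IL-6 slopes, and per-variable
    missingness producing differing analyzable n per outcome."""
    missing = (
        {
            "fibrinogen_total": 0.20,
            "fibrinogen_gamma": 0.20,
            "gamma_pct": 0.24,
            "lag_min": 0.26,
            "slope_e3_au_s": 0.25,
            "maxabs_au": 0.28,
            "clt_min": 0.20,
            "genotypes": 0.08,
        }
        if with_missingness
        else {}
    )
    return CohortConfig(
        n_samples=n_samples,
        snps=[SNPSpec(id=i, gene=g, maf=m) for i, g, m in STUDY_SNPS],
        ld_pairs=list(STUDY_LD_PAIRS),
        base_slope=0.014,
        effect_map=dict(STUDY_SLOPE_EFFECTS),
        missing_rates=missing,
        seed=seed,
    )


def interaction_recovery_config(n_samples: int = 1346, seed: int = 0) -> CohortConfig:
    """Single-SNP cohort with the reported carrier-stratified IL-6
    slopes 0.014 (major homozygotes) and 0.110 (minor-allele carriers)
    for the FGG 3'UTR variant, at its analyzed sample size."""
    return CohortConfig(
        n_samples=n_samples,
        snps=[SNPSpec(id="rs1049636", gene="FGG", maf=0.149)],
        effect_map={"rs1049636": carrier_effect(0.014, 0.110)},
        seed=seed,
    )


def mediation_config(kind: str = "full", n_samples: int = 2010,
                     seed: int = 0) -> CohortConfig:
    """Clot-property mediation scenarios.

    'full': maximum absorbance depends on IL-6 and genotype solely
    through total fibrinogen — adjusting for fibrinogen should remove
    the genotype x IL-6 interaction on maxabs. 'direct': an additional
    genotype x IL-6 effect on maxabs beyond fibrinogen, which should
    survive adjustment. 'none': maxabs independent of fibrinogen.

    The fibrinogen-to-maxabs coupling and residual SDs are sized so the
    unadjusted interaction carries the decisive significance the
    mediated signature requires (its stratified maxabs slopes stay
    close to the printed ones).
    """
    cfg = CohortConfig(
        n_samples=n_samples,
        snps=[SNPSpec(id="rs1800789", gene="FGB", maf=0.0678)],
        effect_map={"rs1800789": carrier_effect(0.012, 0.071)},
        noise_sd={**DEFAULT_NOISE_SD, "fibrinogen_total": 1.5,
                  "maxabs_au": 0.06},
        seed=seed,
    )
    cm = replace(cfg.curve_model, maxabs_intercept=0.28, maxabs_per_fib=0.05)
    if kind == "none":
        cm = replace(cm, maxabs_per_fib=0.0)
    elif kind not in ("full", "direct"):
        raise ValueError("kind must be 'full', 'direct' or 'none'")
    cfg.curve_model = cm
    return cfg


def apply_direct_maxabs_effect(
    cohort_phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    snp: str = "rs1800789",
    extra_slope: float = 0.003,
) -> pd.DataFrame:
    """Add a genotype x IL-6 effect on maximum absorbance that does not
    pass through fibrinogen ('direct' mediation scenario)."""
    df = cohort_phenotypes.copy()
    carrier = genotypes.column(snp) > 0
    df.loc[carrier, "maxabs_au"] += extra_slope * df.loc[carrier, "il6"]
    return df


def score_config(n_samples: int = 1800, seed: int = 0) -> CohortConfig:
    """Seven carrier-coded risk-allele SNPs, carrier probability 0.25
    each, so the carrier-count score ranges 0-6 with the top levels too
    small to analyse (matching the study's excluded score groups)."""
    maf = 1.0 - math.sqrt(0.75)  # carrier probability 0.25
    snps = [SNPSpec(id=f"rscum{k}", gene="FGB", maf=maf) for k in range(7)]
    return CohortConfig(
        n_samples=n_samples,
        snps=snps,
        base_slope=0.01,
        noise_sd={**DEFAULT_NOISE_SD, "fibrinogen_total": 1.5},
        seed=seed,
    )


def simulate_score_cohort(
    pattern: str = "monotone",
    n_samples: int = 1800,
    seed: int = 0,
    increment: float = 0.04,
    threshold_cap: int = 3,
) -> tuple[GenotypeTable, pd.DataFrame, CohortConfig]:
    """Cohort whose IL-6->fibrinogen slope is a function of the number
    of risk-allele groups carried (the cumulative score itself, which an
    additive per-SNP effect map cannot express beyond the linear case).

    'monotone': slope = base + increment * score;
    'threshold': slope rises with the score up to ``threshold_cap``
    risk-allele groups and is flat beyond;
    'null': identical slopes at every score.
    """
    if pattern not in ("monotone", "threshold", "null"):
        raise ValueError("pattern must be 'monotone', 'threshold' or 'null'")
    cfg = score_config(n_samples=n_samples, seed=seed)
    root = np.random.SeedSequence(seed)
    ss_geno, ss_pheno, ss_noise = root.spawn(3)
    genotypes = simulate_genotypes(cfg, rng=np.random.default_rng(ss_geno))
    phen = simulate_phenotypes(
        genotypes, cfg, rng=np.random.default_rng(ss_pheno)
    )
    score = (genotypes.calls > 0).sum(axis=1).astype(float)
    if pattern == "null":
        slope = np.full(n_samples, cfg.base_slope)
    elif pattern == "monotone":
        slope = cfg.base_slope + increment * score
    else:
        slope = cfg.base_slope + increment * np.minimum(score, threshold_cap)
    rng = np.random.default_rng(ss_noise)
    phen = phen.copy()
    phen["fibrinogen_total"] = (
        cfg.base_intercept
        + slope * phen["il6"].to_numpy()
        + rng.normal(0.0, cfg.noise_sd["fibrinogen_total"], n_samples)
    )
    return genotypes, phen, cfg


def blocks_config(n_samples: int = 2010, seed: int = 0) -> CohortConfig:
    """Genotype-only configuration with the two-block LD structure."""
    cfg = study_config(n_samples=n_samples, seed=seed, with_missingness=False)
    cfg.effect_map = {}
    return cfg


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_vcf(table: GenotypeTable, path) -> None:
    """Minimal VCF v4.2, GT field only, unphased, missing as ./. —
    positions are synthetic 1-based offsets in configured order."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        gt_for = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, meta in enumerate(table.snps):
            calls = table.calls[:, j]
            gts = [
                "./." if np.isnan(v) else gt_for[v] for v in calls
            ]
            fh.write(
                f"4\t{1000 + 100 * j}\t{meta.id}\t{meta.major}\t{meta.minor}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def config_to_yaml(config: CohortConfig, path) -> None:
    payload = {
        "n_samples": config.n_samples,
        "seed": config.seed,
        "il6_log_mean": config.il6_log_mean,
        "il6_log_sd": config.il6_log_sd,
        "base_intercept": config.base_intercept,
        "base_slope": config.base_slope,
        "gammaprime_fraction_range": list(config.gammaprime_fraction_range),
        "snps": [
            {"id": s.id, "gene": s.gene, "major": s.major, "minor": s.minor,
             "maf": s.maf}
            for s in config.snps
        ],
        "ld_pairs": [
            {"snp_i": p.snp_i, "snp_j": p.snp_j, "d_prime": p.d_prime,
             "r2": p.r2}
            for p in config.ld_pairs
        ],
        "effect_map": {
            sid: {int(g): list(cm) for g, cm in per.items()}
            for sid, per in config.effect_map.items()
        },
        "noise_sd": dict(config.noise_sd),
        "missing_rates": dict(config.missing_rates),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = CohortConfig(
        n_samples=raw["n_samples"],
        snps=[SNPSpec(**s) for s in raw.get("snps", [])],
        ld_pairs=[LDPairSpec(**p) for p in raw.get("ld_pairs", [])],
        il6_log_mean=raw.get("il6_log_mean", 0.6536),
        il6_log_sd=raw.get("il6_log_sd", 1.5610),
        base_intercept=raw.get("base_intercept", 3.0),
        base_slope=raw.get("base_slope", 0.0),
        effect_map={
            sid: {int(g): tuple(cm) for g, cm in per.items()}
            for sid, per in raw.get("effect_map", {}).items()
        },
        gammaprime_fraction_range=tuple(
            raw.get("gammaprime_fraction_range", (0.08, 0.15))
        ),
        noise_sd=raw.get("noise_sd", dict(DEFAULT_NOISE_SD)),
        missing_rates=raw.get("missing_rates", {}),
        seed=raw.get("seed", 0),
    )
    return cfg
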