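"""Population-genetic QC and two-locus LD structure.

Minor allele frequencies, the exact conditional Hardy-Weinberg test,
EM haplotype-frequency estimation from unphased two-locus genotypes,
normalised LD coefficients (D, D', r^2) with profile-likelihood
confidence bounds on D', Gabriel-style haplotype blocks, the
noncentral-t minimum-group-size power rule, and the genotype-group
collapsing rule driven by it.

Genotypes are coded 0/1/2 as counts of the declared minor allele;
``nan`` marks a missing call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp


class MonomorphicError(ValueError):
    """LD statistics are undefined when a locus has a fixed allele."""


class PowerUnreachableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SNPMeta:
    """Annotation for one biallelic SNP.

    ``order`` is the genomic order index used for block finding; it
    defaults to the position of the SNP in the table.
    """

    id: str
    gene: str = ""
    major: str = "A"
    minor: str = "a"
    order: int | None = None


@dataclass
class GenotypeTable:
    """Sample x SNP matrix of unphased minor-allele counts.

    calls: float array, entries in {0, 1, 2, nan}; one column per SNP.
    """

    snps: list[SNPMeta]
    calls: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2 or self.calls.shape[1] != len(self.snps):
            raise ValueError("calls must be (n_samples, n_snps)")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(self.calls.shape[0])]
        for i, s in enumerate(self.snps):
            if s.order is None:
                s.order = i

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_ids.index(snp_id)]

    def maf(self) -> pd.Series:
        return pd.Series(
            [compute_maf(self.calls[:, j]) for j in range(len(self.snps))],
            index=self.snp_ids,
            name="maf",
        )

    def missingness(self) -> pd.Series:
        return pd.Series(
            np.isnan(self.calls).mean(axis=0), index=self.snp_ids, name="f_missing"
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.snp_ids)


@dataclass
class LDPair:
    snp_i: str
    snp_j: str
    D: float
    d_prime: float
    r2: float
    d_prime_ci: tuple[float, float] = (np.nan, np.nan)
    n_informative: int = 0


@dataclass
class HaploBlock:
    snp_ids: list[str]
    strong_fraction: float

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class PowerSpec:
    """Settings for the minimum-group-size calculation.

    effect_size_d : standardized mean difference to detect (Cohen's d)
    reference_group : 'asymptotic' (the comparison group is effectively
        unlimited, a one-sample noncentral-t formulation) or 'equal'
        (two groups of equal size n, two-sample formulation).
    """

    effect_size_d: float = 0.3
    power: float = 0.80
    alpha: float = 0.05
    sidedness: str = "one"  # 'one' | 'two'
    reference_group: str = "asymptotic"  # 'asymptotic' | 'equal'

    def __post_init__(self) -> None:
        if not 0 < self.power < 1 or not 0 < self.alpha < 1:
            raise ValueError("power and alpha must be in (0,1)")
        if self.effect_size_d <= 0:
            raise ValueError("effect size must be positive")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")
        if self.reference_group not in ("asymptotic", "equal"):
            raise ValueError("reference_group must be 'asymptotic' or 'equal'")


@dataclass
class GenotypeGrouping:
    """Result of the minor-homozygote collapsing rule."""

    mode: str  # 'three-level' | 'carrier' | 'monomorphic'
    labels: np.ndarray  # per-sample group codes (nan where call missing)
    counts: dict[int, int]
    threshold: int

    @property
    def analyzable(self) -> bool:
        return self.mode != "monomorphic"


# ---------------------------------------------------------------------------
# allele frequencies and HWE
# ---------------------------------------------------------------------------


def compute_maf(calls: np.ndarray) -> float:
    """Minor allele frequency of one SNP from 0/1/2 calls.

    Missing calls are dropped from the denominator. Returns
    ``min(p, 1-p)`` of the counted allele, i.e. always in [0, 0.5].
    """
    calls = np.asarray(calls, dtype=float)
    obs = calls[~np.isnan(calls)]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: all calls missing")
    p = obs.sum() / (2 * obs.size)
    return float(min(p, 1.0 - p))


def genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """(n_major_hom, n_het, n_minor_hom) ignoring missing calls."""
    calls = np.asarray(calls, dtype=float)
    obs = calls[~np.isnan(calls)].astype(int)
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed configuration (two-sided, the usual
    exact formulation for small minor-homozygote counts).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_rare = 2 * min(n_aa, n_bb) + n_ab  # rare allele count
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | allele counts) up to a shared constant: 2^h / (r! h! c!)
    logp = hets * math.log(2.0) - (
        gammaln(hom_rare + 1) + gammaln(hets + 1) + gammaln(hom_common + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[hets == n_ab][0]
    pval = float(np.exp(logsumexp(logp[logp <= p_obs + 1e-12])))
    return min(1.0, pval)


# ---------------------------------------------------------------------------
# two-locus EM and LD coefficients
# ---------------------------------------------------------------------------

# haplotype order used throughout: (ab, aB, Ab, AB) where lowercase is the
# minor allele at each locus -> index = 2*(allele_i) + allele_j with minor=1:
# [MAJ-MAJ, MAJ-min, min-MAJ, min-min]
HAPLOTYPE_ORDER = ("MM", "Mm", "mM", "mm")


def _two_locus_counts(calls_i: np.ndarray, calls_j: np.ndarray) -> np.ndarray:
    """3x3 table of pairwise-complete genotype counts."""
    gi = np.asarray(calls_i, dtype=float)
    gj = np.asarray(calls_j, dtype=float)
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    if not ok.any():
        raise ValueError("no pairwise-complete samples")
    idx = (3 * gi[ok] + gj[ok]).astype(int)
    return np.bincount(idx, minlength=9).reshape(3, 3)


_HAP_ALLELES = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
# tensor T[class, a, b] = 1 when gametes a,b produce genotype class
_CLASS_TENSOR = np.zeros((9, 4, 4))
for _a in range(4):
    for _b in range(4):
        _gi = _HAP_ALLELES[_a, 0] + _HAP_ALLELES[_b, 0]
        _gj = _HAP_ALLELES[_a, 1] + _HAP_ALLELES[_b, 1]
        _CLASS_TENSOR[3 * _gi + _gj, _a, _b] = 1.0


def _class_probs(f: np.ndarray) -> np.ndarray:
    """Genotype-class probabilities (3x3) from haplotype freqs under
    random union of gametes. f order: [MM, Mm, mM, mm] (minor=1)."""
    return np.einsum("iab,a,b->i", _CLASS_TENSOR, f, f).reshape(3, 3)


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    p = _class_probs(np.maximum(f, 0.0))
    with np.errstate(divide="ignore"):
        lp = np.log(p)
    lp[counts == 0] = 0.0  # 0*log(0) := 0
    if np.any((counts > 0) & ~np.isfinite(lp)):
        return -np.inf
    return float((counts * np.where(np.isfinite(lp), lp, 0.0)).sum())


def em_haplotype_freqs(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 2000
) -> tuple[np.ndarray, float, int]:
    """EM estimate of the four haplotype frequencies from a 3x3 table of
    unphased two-locus genotype counts.

    Only the double-heterozygote class (1,1) is phase-ambiguous; every
    other class contributes haplotypes deterministically. Returns
    (frequencies in HAPLOTYPE_ORDER, final log-likelihood, iterations).
    The log-likelihood is non-decreasing across iterations.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("expected a 3x3 genotype count table")
    n = counts.sum()
    if n < 1:
        raise ValueError("no informative samples")

    # fixed haplotype contributions from unambiguous classes
    base = np.zeros(4)  # MM, Mm, mM, mm
    contrib = {
        (0, 0): {0: 2},
        (0, 1): {0: 1, 1: 1},
        (0, 2): {1: 2},
        (1, 0): {0: 1, 2: 1},
        (1, 2): {1: 1, 3: 1},
        (2, 0): {2: 2},
        (2, 1): {2: 1, 3: 1},
        (2, 2): {3: 2},
    }
    for (gi, gj), haps in contrib.items():
        for h, k in haps.items():
            base[h] += k * counts[gi, gj]
    n_dh = counts[1, 1]

    f = np.full(4, 0.25)
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # E step: split double heterozygotes between MM/mm and Mm/mM phase
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        hap_counts = base.copy()
        hap_counts[[0, 3]] += n_dh * w
        hap_counts[[1, 2]] += n_dh * (1 - w)
        f_new = hap_counts / (2 * n)
        ll = _loglik(counts, f_new)
        f = f_new
        if ll - ll_prev < tol and it > 1:
            ll_prev = ll
            break
        ll_prev = ll
    return f, ll_prev, it


def em_haplotype_freqs_from_calls(
    calls_i: np.ndarray, calls_j: np.ndarray, **kw
) -> tuple[np.ndarray, float, int]:
    return em_haplotype_freqs(_two_locus_counts(calls_i, calls_j), **kw)


def ld_stats(freqs: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) from four haplotype frequencies in HAPLOTYPE_ORDER.

    D is the covariance of the two minor-allele indicators;
    D' = |D| / Dmax with Dmax the bound imposed by the marginals on the
    side of the observed sign; r^2 = D^2 / (pA qA pB qB).
    """
    f = np.asarray(freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-8 or (f < -1e-12).any():
        raise ValueError("haplotype frequencies must be nonnegative and sum to 1")
    p_i = f[2] + f[3]  # minor allele freq, locus i
    p_j = f[1] + f[3]
    for p in (p_i, p_j):
        if p <= 0 or p >= 1:
            raise MonomorphicError("LD undefined for a monomorphic locus")
    D = f[3] - p_i * p_j
    if D >= 0:
        dmax = min(p_i * (1 - p_j), (1 - p_i) * p_j)
    else:
        dmax = min(p_i * p_j, (1 - p_i) * (1 - p_j))
    d_prime = 0.0 if dmax == 0 else abs(D) / dmax
    r2 = D * D / (p_i * (1 - p_i) * p_j * (1 - p_j))
    return float(D), float(min(d_prime, 1.0)), float(min(r2, 1.0))


def d_prime_profile_ci(
    counts: np.ndarray, grid: int = 1000
) -> tuple[float, float]:
    """One-sided 95% bounds on |D'| by profile likelihood.

    Allele frequencies are fixed at their sample estimates; the
    likelihood of the 3x3 genotype table is evaluated on a grid of
    |D'| values in [0, 1] (sign taken from the EM point estimate),
    normalised, and the 5th / 95th percentiles of the resulting
    cumulative mass are returned. This mirrors the confidence-bound
    construction used for block finding in Haploview.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_i = (counts[1, :].sum() + 2 * counts[2, :].sum()) / (2 * n)
    p_j = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n)
    if min(p_i, 1 - p_i, p_j, 1 - p_j) <= 0:
        raise MonomorphicError("D' CI undefined for a monomorphic locus")
    f_hat, _, _ = em_haplotype_freqs(counts)
    D_hat = f_hat[3] - (f_hat[2] + f_hat[3]) * (f_hat[1] + f_hat[3])
    sign = 1.0 if D_hat >= 0 else -1.0
    if sign > 0:
        dmax = min(p_i * (1 - p_j), (1 - p_i) * p_j)
    else:
        dmax = min(p_i * p_j, (1 - p_i) * (1 - p_j))

    dp = (np.arange(grid) + 0.5) / grid
    D = sign * dp * dmax
    F = np.stack(
        [
            (1 - p_i) * (1 - p_j) + D,
            (1 - p_i) * p_j - D,
            p_i * (1 - p_j) - D,
            p_i * p_j + D,
        ],
        axis=1,
    )
    F = np.clip(F, 0.0, None)
    F /= F.sum(axis=1, keepdims=True)
    probs = np.einsum("iab,ga,gb->gi", _CLASS_TENSOR, F, F)  # (grid, 9)
    cnt = counts.reshape(-1)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = cnt > 0
    bad = (probs[:, mask] <= 0).any(axis=1)
    lls = np.where(bad, -np.inf, (cnt[mask] * logp[:, mask]).sum(axis=1))
    w = np.exp(lls - lls.max())
    cum = np.cumsum(w) / w.sum()
    lo = float(dp[np.searchsorted(cum, 0.05)])
    hi = float(dp[min(np.searchsorted(cum, 0.95), grid - 1)])
    return lo, hi


def ld_pair(calls_i, calls_j, snp_i: str = "i", snp_j: str = "j") -> LDPair:
    """Full LD summary for one SNP pair from unphased calls."""
    counts = _two_locus_counts(calls_i, calls_j)
    f, _, _ = em_haplotype_freqs(counts)
    D, dp, r2 = ld_stats(f)
    ci = d_prime_profile_ci(counts)
    return LDPair(snp_i, snp_j, D, dp, r2, ci, int(counts.sum()))


def ld_matrix(table: GenotypeTable) -> pd.DataFrame:
    """Long-format pairwise LD table for all ordered SNP pairs."""
    rows = []
    ids = table.snp_ids
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            try:
                pair = ld_pair(
                    table.calls[:, a], table.calls[:, b], ids[a], ids[b]
                )
            except (MonomorphicError, ValueError):
                continue
            rows.append(
                {
                    "snp_i": pair.snp_i,
                    "snp_j": pair.snp_j,
                    "D": pair.D,
                    "Dprime": pair.d_prime,
                    "r2": pair.r2,
                    "ci_lo": pair.d_prime_ci[0],
                    "ci_hi": pair.d_prime_ci[1],
                    "n": pair.n_informative,
                }
            )
    return pd.DataFrame(
        rows, columns=["snp_i", "snp_j", "D", "Dprime", "r2", "ci_lo", "ci_hi", "n"]
    )


# ---------------------------------------------------------------------------
# Gabriel-style blocks
# ---------------------------------------------------------------------------


def gabriel_blocks(
    ld: pd.DataFrame,
    snp_order: list[str],
    strong_lo: float = 0.70,
    strong_hi: float = 0.98,
    recomb_hi: float = 0.90,
    min_strong_fraction: float = 0.95,
) -> list[HaploBlock]:
    """Contiguous haplotype blocks from pairwise D' confidence bounds.

    A pair is in *strong LD* when the lower bound of its one-sided 95%
    D' CI exceeds ``strong_lo`` and the upper bound reaches
    ``strong_hi``; it shows *strong evidence of recombination* when the
    upper bound falls below ``recomb_hi``. Pairs in neither category are
    uninformative. A contiguous run of >=2 SNPs is a block when at least
    ``min_strong_fraction`` of its informative pairs are strong (and it
    has at least one informative pair). Maximal non-overlapping blocks
    are returned longest-first.
    """
    pos = {s: k for k, s in enumerate(snp_order)}
    m = len(snp_order)
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for row in ld.itertuples(index=False):
        if row.snp_i not in pos or row.snp_j not in pos:
            continue
        a, b = pos[row.snp_i], pos[row.snp_j]
        is_strong = row.ci_lo > strong_lo and row.ci_hi >= strong_hi
        is_recomb = row.ci_hi < recomb_hi
        strong[a, b] = strong[b, a] = is_strong
        informative[a, b] = informative[b, a] = is_strong or is_recomb

    candidates = []
    for a in range(m):
        for b in range(a + 1, m):
            pairs = [(i, j) for i in range(a, b + 1) for j in range(i + 1, b + 1)]
            n_inf = sum(informative[i, j] for i, j in pairs)
            if n_inf == 0:
                continue
            n_str = sum(strong[i, j] for i, j in pairs)
            frac = n_str / n_inf
            if frac >= min_strong_fraction and n_str >= 1:
                candidates.append((b - a + 1, a, b, frac))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for _, a, b, frac in candidates:
        if taken[a : b + 1].any():
            continue
        taken[a : b + 1] = True
        blocks.append(HaploBlock(snp_order[a : b + 1], float(frac)))
    blocks.sort(key=lambda blk: pos[blk.snp_ids[0]])
    return blocks


def blocks_to_json(blocks: list[HaploBlock], path) -> None:
    payload = [
        {"snps": b.snp_ids, "strong_fraction": b.strong_fraction} for b in blocks
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# power rule and group collapsing
# ---------------------------------------------------------------------------


def _power_at_n(n: int, spec: PowerSpec) -> float:
    d = spec.effect_size_d
    if spec.reference_group == "asymptotic":
        df = n - 1
        nc = d * math.sqrt(n)
    else:  # equal groups of size n
        df = 2 * n - 2
        nc = d * math.sqrt(n / 2.0)
    if spec.sidedness == "one":
        tcrit = stats.t.ppf(1 - spec.alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def min_group_size_for_power(spec: PowerSpec | None = None, **kw) -> int:
    """Smallest group size n whose noncentral-t power meets the target.

    With an asymptotically large reference group the comparison reduces
    to a one-sample t test with noncentrality d*sqrt(n); with
    ``reference_group='equal'`` it is the per-group n of a balanced
    two-sample test. The floor is n = 2 (one residual df).
    """
    if spec is None:
        spec = PowerSpec(**kw)
    n_max = 1_000_000
    for n in range(2, n_max + 1):
        if _power_at_n(n, spec) >= spec.power:
            return n
    raise PowerUnreachableError(
        f"target power {spec.power} not reachable below n={n_max}"
    )


def collapse_genotype_groups(
    calls: np.ndarray, threshold: int = 71
) -> GenotypeGrouping:
    """Collapse the three genotype groups when the minor-homozygote
    group is underpowered.

    If the minor-allele homozygote count is below ``threshold`` the
    heterozygote and minor-homozygote groups are merged into a single
    carrier group (labels 0 vs 1); otherwise the three-level coding is
    kept. A monomorphic SNP is flagged non-analyzable.
    """
    calls = np.asarray(calls, dtype=float)
    n0, n1, n2 = genotype_counts(calls)
    labels = calls.copy()
    if n1 + n2 == 0 or n0 + n1 == 0:
        return GenotypeGrouping(
            "monomorphic", labels, {0: n0, 1: n1, 2: n2}, threshold
        )
    if n2 < threshold:
        labels = np.where(np.isnan(calls), np.nan, (calls > 0).astype(float))
        return GenotypeGrouping(
            "carrier", labels, {0: n0, 1: n1 + n2}, threshold
        )
    return GenotypeGrouping(
        "three-level", labels, {0: n0, 1: n1, 2: n2}, threshold
    )


# ---------------------------------------------------------------------------
# summaries and IO
# ---------------------------------------------------------------------------


def qc_summary(table: GenotypeTable) -> pd.DataFrame:
    """Per-SNP MAF, missingness, genotype counts and exact HWE p."""
    rows = []
    for j, meta in enumerate(table.snps):
        calls = table.calls[:, j]
        n0, n1, n2 = genotype_counts(calls)
        rows.append(
            {
                "snp": meta.id,
                "gene": meta.gene,
                "maf": compute_maf(calls),
                "f_missing": float(np.isnan(calls).mean()),
                "n_major_hom": n0,
                "n_het": n1,
                "n_minor_hom": n2,
                "hwe_p": hwe_exact_test(n0, n1, n2),
            }
        )
    return pd.DataFrame(rows)


def read_genotypes_tsv(path) -> GenotypeTable:
    """Read a sample x SNP table of 0/1/2 calls ('.' or empty missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    return GenotypeTable(
        snps=[SNPMeta(id=c, order=k) for k, c in enumerate(df.columns)],
        calls=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
    )


def write_genotypes_tsv(table: GenotypeTable, path) -> None:
    df = table.to_dataframe()
    out = df.map(lambda v: "." if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
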