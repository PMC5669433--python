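"""Population-genetic statistics against enumeration / scan oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from fibsnp import popgen as pg
from fibsnp import simulate as sim
from fibsnp.popgen import _power_at_n


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact conditional HWE p by full integer enumeration."""
    n = n_aa + n_ab + n_bb
    rare = 2 * min(n_aa, n_bb) + n_ab
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            continue
        weights[h] = (
            2**h
            * math.factorial(n)
            // (math.factorial(hr) * math.factorial(h) * math.factorial(hc))
        )
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total


def em_scan_oracle(counts):
    """Global ML haplotype frequencies by a 1-D likelihood scan over the
    double-heterozygote phase fraction (the only free parameter)."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    base = np.zeros(4)
    contrib = {
        (0, 0): {0: 2}, (0, 1): {0: 1, 1: 1}, (0, 2): {1: 2},
        (1, 0): {0: 1, 2: 1}, (1, 2): {1: 1, 3: 1},
        (2, 0): {2: 2}, (2, 1): {2: 1, 3: 1}, (2, 2): {3: 2},
    }
    for (gi, gj), haps in contrib.items():
        for h, k in haps.items():
            base[h] += k * counts[gi, gj]
    dh = counts[1, 1]

    def freqs(t):
        hap = base.copy()
        hap[[0, 3]] += dh * t
        hap[[1, 2]] += dh * (1 - t)
        return hap / (2 * n)

    def negll(t):
        return -pg._loglik(counts, freqs(t))

    ts = np.linspace(0, 1, 2001)
    t0 = ts[np.argmin([negll(t) for t in ts])]
    res = minimize_scalar(
        negll, bounds=(max(0, t0 - 0.002), min(1, t0 + 0.002)), method="bounded",
        options={"xatol": 1e-12},
    )
    return freqs(res.x), -res.fun


def random_hwe_table(rng):
    n = int(rng.integers(10, 201))
    p = rng.uniform(0.02, 0.5)
    g = rng.choice(3, size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


# ---------------------------------------------------------------------------
# MAF and HWE
# ---------------------------------------------------------------------------


class TestMaf:
    def test_monomorphic_zero(self):
        assert pg.compute_maf(np.zeros(4)) == 0.0

    def test_direct_count(self):
        calls = np.array([0] * 8 + [1] * 4, dtype=float)
        assert pg.compute_maf(calls) == pytest.approx(4 / 24)

    def test_missing_excluded_and_folding(self):
        calls = np.array([2, 2, 2, 1, np.nan])
        # counted allele at freq 7/8 folds to 1/8
        assert pg.compute_maf(calls) == pytest.approx(1 / 8)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            pg.compute_maf(np.array([np.nan, np.nan]))

    def test_generator_hits_target(self):
        cfg = sim.CohortConfig(
            n_samples=100_000, snps=[sim.SNPSpec(id="s", maf=0.0695)], seed=4
        )
        gt = sim.simulate_genotypes(cfg, seed=4)
        assert pg.compute_maf(gt.calls[:, 0]) == pytest.approx(0.0695, abs=0.002)


class TestHweExact:
    @pytest.mark.parametrize(
        "table", [(25, 50, 25), (0, 2, 0), (5, 1, 1), (57, 14, 50)]
    )
    def test_matches_enumeration(self, table):
        assert pg.hwe_exact_test(*table) == pytest.approx(
            hwe_oracle(*table), abs=1e-12
        )

    def test_modal_configuration_gives_one(self):
        assert pg.hwe_exact_test(25, 50, 25) == 1.0

    def test_monomorphic(self):
        assert pg.hwe_exact_test(50, 0, 0) == 1.0

    def test_random_tables_match_oracle(self, rng):
        for _ in range(60):
            table = random_hwe_table(rng)
            assert pg.hwe_exact_test(*table) == pytest.approx(
                hwe_oracle(*table), abs=1e-10
            )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            pg.hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            pg.hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# EM and LD statistics
# ---------------------------------------------------------------------------


class TestEmHaplotypes:
    def test_no_double_het_is_direct_counting(self):
        counts = np.array([[30, 10, 2], [8, 0, 1], [3, 2, 4]])
        f, ll, _ = pg.em_haplotype_freqs(counts)
        oracle, _ = em_scan_oracle(counts)
        assert np.allclose(f, oracle, atol=1e-9)
        assert f.sum() == pytest.approx(1.0)

    def test_crafted_table_matches_scan(self):
        counts = np.array([[3, 1, 0], [1, 4, 1], [0, 1, 1]])
        f, ll, _ = pg.em_haplotype_freqs(counts)
        oracle, ll_o = em_scan_oracle(counts)
        assert np.allclose(f, oracle, atol=1e-6)
        assert ll == pytest.approx(ll_o, abs=1e-8)

    def test_loglik_monotone(self):
        counts = np.array([[10, 5, 1], [6, 8, 2], [1, 3, 4]], dtype=float)
        lls = []
        # re-run EM capturing intermediate log-likelihoods
        f = np.full(4, 0.25)
        for _ in range(50):
            cis, trans = f[0] * f[3], f[1] * f[2]
            w = cis / (cis + trans) if cis + trans > 0 else 0.5
            base = np.zeros(4)
            contrib = {
                (0, 0): {0: 2}, (0, 1): {0: 1, 1: 1}, (0, 2): {1: 2},
                (1, 0): {0: 1, 2: 1}, (1, 2): {1: 1, 3: 1},
                (2, 0): {2: 2}, (2, 1): {2: 1, 3: 1}, (2, 2): {3: 2},
            }
            for (gi, gj), haps in contrib.items():
                for h, k in haps.items():
                    base[h] += k * counts[gi, gj]
            base[[0, 3]] += counts[1, 1] * w
            base[[1, 2]] += counts[1, 1] * (1 - w)
            f = base / (2 * counts.sum())
            lls.append(pg._loglik(counts, f))
        assert np.all(np.diff(lls) >= -1e-9)

    def test_simulation_consistency(self, rng):
        freqs = np.array([0.7, 0.1, 0.1, 0.1])
        hap = rng.choice(4, size=(50_000, 2), p=freqs)
        gi = (hap >= 2).sum(axis=1)
        gj = (hap % 2).sum(axis=1)
        counts = np.bincount(3 * gi + gj, minlength=9).reshape(3, 3)
        est, _, _ = pg.em_haplotype_freqs(counts)
        assert np.allclose(est, freqs, atol=0.01)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pg.em_haplotype_freqs(np.zeros((3, 3)))


class TestLdStats:
    def test_complete_coupling(self):
        D, dp, r2 = pg.ld_stats(np.array([0.5, 0, 0, 0.5]))
        assert (dp, r2) == (1.0, 1.0)

    def test_independence(self):
        p, q = 0.3, 0.2
        f = np.array([(1 - p) * (1 - q), (1 - p) * q, p * (1 - q), p * q])
        D, dp, r2 = pg.ld_stats(f)
        assert abs(D) < 1e-15 and dp < 1e-12 and r2 < 1e-15

    def test_fgb_pair_closed_form(self):
        # algebraic oracle: D = D' * Dmax, r2 = D^2/(pA qA pB qB)
        p, q, dprime = 0.0695, 0.0678, 0.95
        dmax = min(p * (1 - q), (1 - p) * q)
        r2_expected = (dprime * dmax) ** 2 / (p * (1 - p) * q * (1 - q))
        f = sim.simulate_haplotype_pool(p, q, dprime)
        D, dp, r2 = pg.ld_stats(f)
        assert dp == pytest.approx(dprime, abs=1e-9)
        assert r2 == pytest.approx(r2_expected, abs=1e-12)
        assert r2 == pytest.approx(0.879, abs=0.001)  # prints as ~0.88-0.89

    @pytest.mark.parametrize("maf_a", [0.05, 0.0695, 0.25, 0.5])
    @pytest.mark.parametrize("d_prime", [0.0, 0.3, 0.95, 1.0])
    def test_pool_ld_identity(self, maf_a, d_prime):
        f = sim.simulate_haplotype_pool(maf_a, 0.21, d_prime)
        _, dp, _ = pg.ld_stats(f)
        assert dp == pytest.approx(d_prime, abs=1e-9)
        assert f[2] + f[3] == pytest.approx(maf_a, abs=1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_error(self):
        with pytest.raises(pg.MonomorphicError):
            pg.ld_stats(np.array([1.0, 0.0, 0.0, 0.0]))


class TestDPrimeCI:
    def test_bounds_bracket_estimate(self, rng):
        f = sim.simulate_haplotype_pool(0.2, 0.3, 0.9)
        hap = rng.choice(4, size=(2000, 2), p=f)
        gi = (hap >= 2).sum(axis=1)
        gj = (hap % 2).sum(axis=1)
        counts = np.bincount(3 * gi + gj, minlength=9).reshape(3, 3)
        lo, hi = pg.d_prime_profile_ci(counts)
        _, dp, _ = pg.ld_stats(pg.em_haplotype_freqs(counts)[0])
        assert 0.0 <= lo <= hi <= 1.0
        assert lo - 0.05 <= dp <= hi + 0.05


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


def _ld_row(i, j, dp, lo, hi):
    return {"snp_i": i, "snp_j": j, "D": 0.1, "Dprime": dp, "r2": 0.5,
            "ci_lo": lo, "ci_hi": hi, "n": 1000}


class TestGabrielBlocks:
    def test_two_coupled_snps_form_block(self):
        ld = pd.DataFrame([_ld_row("a", "b", 1.0, 0.9, 1.0)])
        blocks = pg.gabriel_blocks(ld, ["a", "b"])
        assert len(blocks) == 1 and blocks[0].snp_ids == ["a", "b"]

    def test_independent_snps_no_block(self):
        ld = pd.DataFrame([_ld_row("a", "b", 0.05, 0.0, 0.3)])
        assert pg.gabriel_blocks(ld, ["a", "b"]) == []

    def test_uninformative_middle_pair_kept_inside_block(self):
        ld = pd.DataFrame(
            [
                _ld_row("a", "b", 0.99, 0.9, 1.0),
                _ld_row("b", "c", 0.99, 0.9, 1.0),
                _ld_row("a", "c", 0.95, 0.8, 0.97),  # uninformative
            ]
        )
        blocks = pg.gabriel_blocks(ld, ["a", "b", "c"])
        assert len(blocks) == 1 and blocks[0].snp_ids == ["a", "b", "c"]

    def test_recombination_pair_splits_run(self):
        ld = pd.DataFrame(
            [
                _ld_row("a", "b", 0.99, 0.9, 1.0),
                _ld_row("b", "c", 0.99, 0.9, 1.0),
                _ld_row("a", "c", 0.2, 0.05, 0.5),  # strong recombination
            ]
        )
        blocks = pg.gabriel_blocks(ld, ["a", "b", "c"])
        assert all(len(b) == 2 for b in blocks)

    def test_relabeling_minor_major_invariance(self):
        cfg = sim.blocks_config(n_samples=1200, seed=7)
        gt = sim.simulate_genotypes(cfg, seed=7)
        ld = pg.ld_matrix(gt)
        blocks = pg.gabriel_blocks(ld, gt.snp_ids)
        flipped = gt.calls.copy()
        flipped[:, 0] = 2 - flipped[:, 0]  # swap allele labels at one SNP
        gt2 = pg.GenotypeTable(gt.snps, flipped, list(gt.sample_ids))
        ld2 = pg.ld_matrix(gt2)
        blocks2 = pg.gabriel_blocks(ld2, gt2.snp_ids)
        assert [b.snp_ids for b in blocks] == [b.snp_ids for b in blocks2]


# ---------------------------------------------------------------------------
# power rule and collapsing
# ---------------------------------------------------------------------------


class TestPowerRule:
    def test_medium_effect_returns_71(self):
        n = pg.min_group_size_for_power(pg.PowerSpec(
            effect_size_d=0.3, power=0.80, alpha=0.05,
            sidedness="one", reference_group="asymptotic",
        ))
        assert n == 71

    def test_huge_effect_hits_floor(self):
        assert pg.min_group_size_for_power(pg.PowerSpec(effect_size_d=10.0)) == 2

    def test_two_sided_equal_groups_bracketed(self):
        spec = pg.PowerSpec(effect_size_d=0.5, sidedness="two",
                            reference_group="equal")
        n = pg.min_group_size_for_power(spec)
        assert _power_at_n(n, spec) >= 0.80 > _power_at_n(n - 1, spec)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            pg.PowerSpec(power=1.2)


class TestCollapse:
    def test_small_minor_hom_collapses_to_carrier(self):
        calls = np.array([0] * 500 + [1] * 100 + [2] * 30, dtype=float)
        g = pg.collapse_genotype_groups(calls)
        assert g.mode == "carrier"
        assert g.counts == {0: 500, 1: 130}

    def test_boundary_exactly_threshold_keeps_three(self):
        calls = np.array([0] * 500 + [1] * 150 + [2] * 71, dtype=float)
        assert pg.collapse_genotype_groups(calls).mode == "three-level"

    def test_monomorphic_flagged(self):
        g = pg.collapse_genotype_groups(np.zeros(100))
        assert g.mode == "monomorphic" and not g.analyzable


class TestTableIO:
    def test_tsv_roundtrip_with_missing(self, tmp_path, rng):
        calls = rng.choice([0.0, 1.0, 2.0, np.nan], size=(30, 3))
        gt = pg.GenotypeTable([pg.SNPMeta(id=f"s{i}") for i in range(3)], calls)
        path = tmp_path / "g.tsv"
        pg.write_genotypes_tsv(gt, path)
        back = pg.read_genotypes_tsv(path)
        assert back.snp_ids == gt.snp_ids
        assert np.array_equal(back.calls, gt.calls, equal_nan=True)

    def test_qc_summary_columns(self, small_cohort):
        summary = pg.qc_summary(small_cohort.genotypes)
        assert {"snp", "maf", "hwe_p", "n_het"} <= set(summary.columns)
        assert (summary["hwe_p"] > 0).all()
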