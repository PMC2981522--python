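"""Phasing enumeration, EM frequency estimation, LD and the haplotype TDT."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from trioassoc import (
    SnpRecord,
    best_two_marker_scan,
    em_phase,
    enumerate_configs,
    hap_tdt,
    ld_measures,
)
from trioassoc.simulate import SimConfig, default_config, simulate_trios

from conftest import make_trio


class TestEnumerateConfigs:
    def test_double_het_trio_has_four_configs(self, two_snps):
        trio = make_trio("f", two_snps, ["AG", "GT"], ["AG", "GT"], ["AG", "GT"])
        cfgs = enumerate_configs(trio)
        assert len(cfgs) == 4

    def test_child_homozygous_forces_transmissions(self, two_snps):
        trio = make_trio("f", two_snps, ["AG", "GT"], ["AG", "GT"], ["AA", "GG"])
        cfgs = enumerate_configs(trio)
        # transmitted haplotype is AG (index 0b01 -> A=0,G=0 -> 0) per parent
        assert len(cfgs) >= 1
        assert (cfgs[:, 0] == cfgs[0, 0]).all() and (cfgs[:, 2] == cfgs[0, 2]).all()

    def test_missing_genotype_is_union_over_fills(self, two_snps):
        base = make_trio("f", two_snps, ["AG", "--"], ["GG", "TT"], ["AG", "GT"])
        union = set()
        for fill in ("GG", "GT", "TT"):
            t = make_trio("f", two_snps, ["AG", fill], ["GG", "TT"], ["AG", "GT"])
            union |= {tuple(c) for c in enumerate_configs(t)}
        assert {tuple(c) for c in enumerate_configs(base)} == union

    def test_inconsistent_trio_has_no_configs(self, two_snps):
        trio = make_trio("f", two_snps, ["AA", "GG"], ["AA", "GG"], ["GG", "TT"])
        assert len(enumerate_configs(trio)) == 0


def brute_force_ml(trios, snps, snp_subset):
    """Exhaustive ML over haplotype frequencies by direct likelihood
    maximisation with a softmax parameterisation (independent of EM)."""
    cfg_sets = [enumerate_configs(t, [0, 1]) for t in trios]
    H = 4

    def negll(theta):
        f = np.exp(theta - theta.max())
        f = f / f.sum()
        ll = 0.0
        for cfgs in cfg_sets:
            ll += np.log(f[cfgs].prod(axis=1).sum() + 1e-300)
        return -ll

    best = None
    for start in range(5):
        rng = np.random.default_rng(start)
        res = minimize(negll, rng.normal(0, 0.5, H), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    f = np.exp(best.x - best.x.max())
    return f / f.sum(), -best.fun


class TestEmPhase:
    def test_unambiguous_equals_direct_counting(self, two_snps):
        trios = [
            make_trio("a", two_snps, ["AA", "GG"], ["GG", "TT"], ["AG", "GT"]),
            make_trio("b", two_snps, ["AA", "GG"], ["AA", "GG"], ["AA", "GG"]),
        ]
        res = em_phase(trios, two_snps, ["snp1", "snp2"])
        # founders: a: AG,AG,GT,GT; b: AG x4 -> AG 6/8, GT 2/8
        assert res.freq_dict()["AG"] == pytest.approx(0.75)
        assert res.freq_dict()["GT"] == pytest.approx(0.25)
        assert res.n_iter <= 3  # counting, then a no-gain confirmation pass

    def test_single_double_het_trio_symmetric_weights(self, two_snps):
        """With every member doubly heterozygous, coupling and repulsion are
        equally supported and the EM stays at the symmetric fixed point."""
        trio = make_trio("f", two_snps, ["AG", "GT"], ["AG", "GT"], ["AG", "GT"])
        res = em_phase([trio], two_snps, ["snp1", "snp2"])
        pt = res.trios[0]
        assert len(pt.configs) == 4
        assert pt.weights == pytest.approx([0.25] * 4)
        strings = res.hap_strings
        coupling = sum(
            w for cfg, w in zip(pt.configs, pt.weights)
            if strings[cfg[0]] in ("AG", "GT"))
        assert coupling == pytest.approx(0.5)

    def test_loglik_nondecreasing(self, study_sample):
        snps, trios, _, _ = study_sample
        lls = [em_phase(trios[:150], snps, ["rs12970134", "rs1943229"],
                        tol=0.0, max_iter=k).loglik for k in (1, 2, 3, 5, 10)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_matches_brute_force_ml_on_tiny_instances(self, two_snps):
        trios = [
            make_trio("a", two_snps, ["AG", "GT"], ["AG", "GT"], ["AG", "GT"]),
            make_trio("b", two_snps, ["AG", "GG"], ["GG", "GT"], ["AG", "GT"]),
            make_trio("c", two_snps, ["AA", "GT"], ["AG", "TT"], ["AA", "GT"]),
        ]
        em = em_phase(trios, two_snps, ["snp1", "snp2"], tol=1e-12,
                      n_restarts=10, seed=0)
        f_ml, ll_ml = brute_force_ml(trios, two_snps, ["snp1", "snp2"])
        assert em.loglik == pytest.approx(ll_ml, abs=1e-5)

    def test_frequency_recovery(self):
        """Founder frequencies estimated from 500 null trios are within
        Monte-Carlo error of the generating pool."""
        cfg = default_config(n_trios=500, seed=42, with_variants=False)
        cfg.hrr = 1.0
        cfg.risk_haplotype = None
        trios, _, truth = simulate_trios(cfg)
        res = em_phase(trios, cfg.snp_map, ["rs12970134", "rs1943229"])
        fd = res.freq_dict()
        for hap, f_true in cfg.haplotype_pool:
            se = np.sqrt(f_true * (1 - f_true) / (4 * 500))
            assert abs(fd[hap] - f_true) < 4 * se

    def test_mendelian_escapee_flagged(self, two_snps):
        good = make_trio("g", two_snps, ["AG", "GT"], ["GG", "TT"], ["AG", "GT"])
        bad = make_trio("x", two_snps, ["AA", "GG"], ["AA", "GG"], ["GG", "TT"])
        res = em_phase([good, bad], two_snps, ["snp1", "snp2"])
        assert res.flagged_families == ["x"]
        assert len(res.trios) == 1


class TestLdMeasures:
    def test_independent_snps(self):
        f = np.outer([0.7, 0.3], [0.6, 0.4]).ravel()
        d, r2 = ld_measures(f)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_coupling(self):
        d, r2 = ld_measures([0.5, 0.0, 0.0, 0.5])
        assert (d, r2) == (1.0, 1.0)

    def test_random_tables_match_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            pa, pb = f[2] + f[3], f[1] + f[3]
            if min(pa, 1 - pa, pb, 1 - pb) < 1e-3:
                continue
            D = f[3] - pa * pb
            dmax = min(pa * (1 - pb), (1 - pa) * pb) if D >= 0 else min(
                pa * pb, (1 - pa) * (1 - pb))
            d, r2 = ld_measures(f)
            assert d == pytest.approx(abs(D) / dmax)
            assert r2 == pytest.approx(D * D / (pa * (1 - pa) * pb * (1 - pb)))

    def test_monomorphic_is_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_measures([0.6, 0.4, 0.0, 0.0])


class TestHapTdt:
    def test_fractional_counts_balance(self, study_sample):
        """Every meiosis contributes weight one to each side."""
        snps, trios, _, _ = study_sample
        res = hap_tdt(trios, snps, ["rs12970134", "rs1943229"],
                      n_perm=200, seed=0, compute_hrr=False)
        assert res.table["T"].sum() == pytest.approx(res.table["U"].sum())

    def test_balanced_dataset_stat_zero(self, two_snps):
        # two mirror-image families: transmissions cancel exactly
        trios = [
            make_trio("a", two_snps, ["AG", "GT"], ["GG", "TT"], ["AG", "GT"]),
            make_trio("b", two_snps, ["AG", "GT"], ["GG", "TT"], ["GG", "TT"]),
        ]
        res = hap_tdt(trios, two_snps, ["snp1", "snp2"], n_perm=100,
                      seed=0, compute_hrr=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_perm == 1.0

    def test_risk_haplotype_overtransmitted(self, study_sample):
        snps, trios, _, _ = study_sample
        res = hap_tdt(trios, snps, ["rs12970134", "rs1943229"],
                      n_perm=999, seed=1)
        tab = res.table.set_index("haplotype")
        assert tab.loc["AG", "transmission_ratio"] > 1.2
        assert res.p_perm < 0.05
        assert tab.loc["GG", "is_reference"]


class TestBestPairScan:
    def _four_snp_sample(self, seed=0):
        snps = [SnpRecord(f"s{i}", "18", 10 * (i + 1), "A", "G") for i in range(4)]
        pool_haps = ["".join(h) for h in itertools.product("AG", repeat=4)]
        rng = np.random.default_rng(7)
        freqs = rng.dirichlet(np.ones(16))
        cfg = SimConfig(snp_map=snps,
                        haplotype_pool=list(zip(pool_haps, freqs)),
                        n_trios=150, risk_haplotype="AAAA", hrr=1.8, seed=seed)
        trios, _, _ = simulate_trios(cfg)
        return snps, trios

    def test_pair_count_and_order_invariance(self):
        snps, trios = self._four_snp_sample()
        ids = [s.snp_id for s in snps]
        tab1, _ = best_two_marker_scan(trios, snps, ids, n_perm=199, seed=5)
        tab2, _ = best_two_marker_scan(trios, snps, ids[::-1], n_perm=199, seed=5)
        assert len(tab1) == 6  # C(4,2)
        assert tab1[["snp1", "snp2", "p_perm"]].equals(
            tab2[["snp1", "snp2", "p_perm"]])
        assert (tab1["p_bonferroni"] >= tab1["p_perm"]).all()

    def test_two_snps_single_pair(self, study_sample):
        snps, trios, _, _ = study_sample
        tab, results = best_two_marker_scan(
            trios, snps, ["rs12970134", "rs1943229"], n_perm=199, seed=2)
        assert len(tab) == 1 and len(results) == 1
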