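"""Collapsing, stratified transmissions, carrier removal, joint models."""

import numpy as np
import pandas as pd
import pytest

from trioassoc import (
    FUNCTIONAL_MUTATION,
    PROTECTIVE_POLYMORPHISM,
    CodingVariantTable,
    carrier_removal_analysis,
    collapse,
    hap_tdt,
    joint_models,
    stratified_transmissions,
)
from trioassoc.simulate import SimConfig, VariantEffect, default_config, simulate_trios

PAIR = ["rs12970134", "rs1943229"]


def make_table(rows, classes):
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["family_id", "member"])
    return CodingVariantTable(statuses=df, classes=classes)


class TestCollapse:
    def _table(self):
        rows = {
            ("f1", "child"): {"v1": 0, "v2": 1, "v3": 0},
            ("f2", "child"): {"v1": 0, "v2": 0, "v3": 0},
            ("f3", "child"): {"v1": np.nan, "v2": 0, "v3": 1},
        }
        return make_table(rows, {"v1": "m", "v2": "m", "v3": "m"})

    def test_or_semantics(self):
        ind = collapse(self._table(), "m")
        assert ind[("f1", "child")] == 1
        assert ind[("f2", "child")] == 0
        assert ind[("f3", "child")] == 1  # missing treated as non-carrier

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError, match="no variants"):
            collapse(self._table(), "absent")

    def test_idempotent_and_monotone(self):
        t = self._table()
        base = collapse(t, "m")
        # adding a variant to the class never decreases any indicator
        t2 = make_table(
            {k: dict(v, v4=1) for k, v in t.statuses.to_dict("index").items()},
            {"v1": "m", "v2": "m", "v3": "m", "v4": "m"})
        assert (collapse(t2, "m") >= base).all()

    def test_carrier_count_matches_inclusion_exclusion(self):
        """Collapsed carrier rate in simulated children tracks
        1 - prod(1 - f_hap)^2 over the class's haplotype frequencies."""
        cfg = default_config(n_trios=4000, seed=99)
        cfg.hrr = 1.0
        cfg.risk_haplotype = None
        effects = [v for v in cfg.variant_effects
                   if v.var_class == PROTECTIVE_POLYMORPHISM]
        cfg.variant_effects = [
            VariantEffect(v.variant_id, v.var_class, v.host_haplotype,
                          v.carrier_freq_within_host, 1.0) for v in effects]
        trios, table, _ = simulate_trios(cfg)
        ind = collapse(table, PROTECTIVE_POLYMORPHISM)
        child = ind.xs("child", level="member")
        pool = dict(cfg.haplotype_pool)
        f_hap = sum(v.carrier_freq_within_host * pool[v.host_haplotype]
                    for v in cfg.variant_effects)
        expected = 1 - (1 - f_hap) ** 2
        se = np.sqrt(expected * (1 - expected) / len(child))
        assert abs(child.mean() - expected) < 4 * se


class TestStratifiedTransmissions:
    def test_margins_reproduce_unstratified_table(self, study_sample):
        snps, trios, table, _ = study_sample
        st = stratified_transmissions(trios, snps, PAIR, table,
                                      PROTECTIVE_POLYMORPHISM)
        cells = st.table.groupby("haplotype")[["T", "U"]].sum()
        marg = st.marginal.set_index("haplotype")[["T", "U"]]
        pd.testing.assert_frame_equal(cells, marg, check_like=True)
        # each meiosis contributes one transmitted and one untransmitted
        assert st.table["T"].sum() == pytest.approx(st.table["U"].sum())

    def test_expected_frequency_is_product_of_marginals(self, study_sample):
        snps, trios, table, _ = study_sample
        st = stratified_transmissions(trios, snps, PAIR, table)
        t = st.table
        hap_marg = t.groupby("haplotype")["estimated_freq"].sum()
        bg_marg = t.groupby("background")["estimated_freq"].sum()
        for _, row in t.iterrows():
            assert row["expected_freq"] == pytest.approx(
                hap_marg[row["haplotype"]] * bg_marg[row["background"]])

    def test_empty_cell_ratio_undefined(self, study_sample):
        snps, trios, table, _ = study_sample
        st = stratified_transmissions(trios, snps, PAIR, table)
        empty = st.table[(st.table["T"] + st.table["U"]) == 0]
        assert empty["transmission_ratio"].isna().all()

    def test_variant_free_background_collapses_to_margins(self, study_sample):
        """With zero carriers the stratified table equals the plain
        haplotype table in its wild-type stratum."""
        snps, trios, table, _ = study_sample
        zero = CodingVariantTable(
            statuses=table.statuses.copy() * 0,
            classes=table.classes)
        st = stratified_transmissions(trios, snps, PAIR, zero,
                                      FUNCTIONAL_MUTATION)
        wt = st.table[st.table["background"] == "wild_type"].set_index("haplotype")
        res = hap_tdt(trios, snps, PAIR, n_perm=100, seed=0, compute_hrr=False)
        plain = res.table.set_index("haplotype")
        for hap in plain.index:
            assert wt.loc[hap, "T"] == pytest.approx(plain.loc[hap, "T"])
            assert wt.loc[hap, "U"] == pytest.approx(plain.loc[hap, "U"])

    def test_variant_on_risk_haplotype_strengthens_its_cell(self):
        """A risk variant exclusive to the risk haplotype makes the
        variant-bearing cell over-transmitted relative to wild-type."""
        wins = 0
        for i in range(25):
            cfg = default_config(n_trios=500, seed=4000 + i, with_variants=False)
            cfg.hrr = 1.0
            cfg.risk_haplotype = None
            cfg.variant_effects = [
                VariantEffect("mut", FUNCTIONAL_MUTATION, "AG", 0.25, 3.0)]
            trios, table, _ = simulate_trios(cfg)
            st = stratified_transmissions(trios, cfg.snp_map, PAIR, table,
                                          FUNCTIONAL_MUTATION)
            t = st.table.set_index(["haplotype", "background"])
            r_var = t.loc[("AG", "variant"), "T"] / max(
                t.loc[("AG", "variant"), "U"], 1e-9)
            r_wt = t.loc[("AG", "wild_type"), "T"] / max(
                t.loc[("AG", "wild_type"), "U"], 1e-9)
            wins += r_var > r_wt
        assert wins / 25 > 0.9


class TestCarrierRemoval:
    def test_no_carriers_identical(self, study_sample):
        snps, trios, table, _ = study_sample
        zero = CodingVariantTable(statuses=table.statuses * 0,
                                  classes=table.classes)
        res = carrier_removal_analysis(trios, snps, PAIR, zero,
                                       n_perm=100, seed=0)
        assert res.n_removed == 0
        assert (res.snp_table["rr_before"] == res.snp_table["rr_after"]).all()

    def test_any_member_removes_more_than_child(self, study_sample):
        snps, trios, table, _ = study_sample
        child = carrier_removal_analysis(trios, snps, PAIR, table,
                                         member="child", n_perm=100, seed=0)
        anym = carrier_removal_analysis(trios, snps, PAIR, table,
                                        member="any", n_perm=100, seed=0)
        assert anym.n_removed >= child.n_removed > 0

    def test_removing_everyone_is_error(self, two_snps):
        from conftest import make_trio

        trios = [make_trio("f1", two_snps, ["AG", "GT"], ["GG", "TT"],
                           ["AG", "GT"])]
        tab = make_table({("f1", "child"): {"v": 1}}, {"v": FUNCTIONAL_MUTATION})
        with pytest.raises(ValueError, match="no trios"):
            carrier_removal_analysis(trios, two_snps, ["snp1", "snp2"], tab,
                                     n_perm=100)


class TestJointModels:
    def test_recovers_both_effects_jointly(self):
        cfg = SimConfig(
            snp_map=default_config().snp_map,
            haplotype_pool=[("GG", 0.646), ("AG", 0.157), ("AT", 0.134),
                            ("GT", 0.063)],
            n_trios=900, risk_haplotype="A*", hrr=1.5,
            variant_effects=[
                VariantEffect("mut", FUNCTIONAL_MUTATION, "AG", 0.08, 2.6)],
            seed=21)
        trios, table, _ = simulate_trios(cfg)
        jm = joint_models(trios, cfg.snp_map, PAIR, table,
                          effect_alleles={"rs12970134": "A", "rs1943229": "G"})
        t3 = jm.model3.table.set_index("covariate")
        assert (t3.loc["functional_mutation:variant", "ci_low"] <= 2.6
                <= t3.loc["functional_mutation:variant", "ci_high"])
        assert (t3.loc["rs12970134:A", "ci_low"] <= 1.5
                <= t3.loc["rs12970134:A", "ci_high"])

    def test_null_coding_variants_leave_snp_effects_alone(self):
        """With variants of no effect, model-3 SNP coefficients track
        model 1."""
        deltas = []
        for i in range(15):
            cfg = default_config(n_trios=500, seed=8000 + i, with_variants=False)
            cfg.variant_effects = [
                VariantEffect("null_mut", FUNCTIONAL_MUTATION, "GG", 0.05, 1.0)]
            trios, table, _ = simulate_trios(cfg)
            jm = joint_models(trios, cfg.snp_map, PAIR, table,
                              effect_alleles={"rs12970134": "A",
                                              "rs1943229": "G"})
            deltas.append(abs(jm.model3.beta[0] - jm.model1.beta[0]))
        assert np.median(deltas) < 0.02

    def test_zero_carriers_degrades_gracefully(self, study_sample):
        snps, trios, table, _ = study_sample
        zero = CodingVariantTable(statuses=table.statuses * 0,
                                  classes=table.classes)
        jm = joint_models(trios, snps, PAIR, zero)
        assert jm.model2 is None and jm.model2_error is not None
        assert jm.model3 is jm.model1
        assert any("model 1" in n for n in jm.notes)
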