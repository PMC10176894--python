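"""Ct-to-quantity conversions: ddCt, standards, GCN, decay, plasma chain."""

import numpy as np
import pandas as pd
import pytest

from circkit import quant as qnt
from circkit.quant import CtTable, RnaStandard, VolumeChain
from circkit.simulate import SimConfig, gen_qpcr, gen_standard_series

from oracles import molar_mass_bruteforce


def ct_table(rows):
    return CtTable(pd.DataFrame(rows, columns=["sample", "target", "replicate", "ct"]))


# ---------------------------------------------------------------------------
# relative expression


class TestRelativeExpression:
    def test_calibrator_fold_is_exactly_one(self):
        rng = np.random.default_rng(0)
        rows = [(s, t, r, float(rng.uniform(15, 30)))
                for s in ("cal", "a", "b") for t in ("tgt", "ref") for r in (1, 2)]
        fold, _ = qnt.relative_expression(ct_table(rows), "tgt", "ref", "cal")
        assert fold["cal"] == 1.0

    def test_ddct_minus_two_gives_fold_four(self):
        rows = [("cal", "tgt", 1, 25.0), ("cal", "ref", 1, 20.0),
                ("s1", "tgt", 1, 24.0), ("s1", "ref", 1, 21.0)]
        fold, _ = qnt.relative_expression(ct_table(rows), "tgt", "ref", "cal")
        assert fold["s1"] == pytest.approx(4.0)

    def test_replicates_averaged_before_ddct(self):
        """Three samples with duplicate wells match a spreadsheet-style
        mean-then-ddCt recomputation."""
        rows = [
            ("cal", "tgt", 1, 25.0), ("cal", "tgt", 2, 25.4),
            ("cal", "ref", 1, 20.0), ("cal", "ref", 2, 20.2),
            ("s1", "tgt", 1, 23.0), ("s1", "tgt", 2, 23.6),
            ("s1", "ref", 1, 20.1), ("s1", "ref", 2, 19.9),
            ("s2", "tgt", 1, 27.5), ("s2", "tgt", 2, 27.9),
            ("s2", "ref", 1, 21.0), ("s2", "ref", 2, 21.4),
        ]
        fold, _ = qnt.relative_expression(ct_table(rows), "tgt", "ref", "cal")
        dct_cal = 25.2 - 20.1
        for sample, tgt_mean, ref_mean in (("s1", 23.3, 20.0), ("s2", 27.7, 21.2)):
            expect = 2.0 ** -((tgt_mean - ref_mean) - dct_cal)
            assert fold[sample] == pytest.approx(expect)

    def test_missing_reference_sample_skipped_and_reported(self):
        rows = [("cal", "tgt", 1, 25.0), ("cal", "ref", 1, 20.0),
                ("s1", "tgt", 1, 24.0)]
        fold, skipped = qnt.relative_expression(ct_table(rows), "tgt", "ref", "cal")
        assert "s1" not in fold.index
        assert any("s1" in msg for msg in skipped)

    def test_undetermined_policy(self):
        df = pd.DataFrame(
            [("cal", "tgt", 1, 25.0, "ok"), ("cal", "ref", 1, 20.0, "ok"),
             ("s1", "tgt", 1, 38.0, "undetermined"), ("s1", "ref", 1, 20.0, "ok")],
            columns=["sample", "target", "replicate", "ct", "flag"],
        )
        table = CtTable(df)
        fold_drop, _ = qnt.relative_expression(table, "tgt", "ref", "cal")
        assert "s1" not in fold_drop.index
        fold_imp, _ = qnt.relative_expression(table, "tgt", "ref", "cal",
                                              undetermined="impute_max")
        assert fold_imp["s1"] == pytest.approx(2.0 ** -(40.0 - 20.0 - 5.0))


class TestRnaseRResistance:
    def test_equal_ct_is_full_survival(self):
        rows = [("mock", "circ", 1, 20.0), ("treated", "circ", 1, 20.0)]
        frac = qnt.rnase_r_resistance(ct_table(rows), "mock", "treated")
        assert frac["circ"] == pytest.approx(1.0)

    def test_three_cycle_shift_is_one_eighth(self):
        rows = [("mock", "lin", 1, 20.0), ("treated", "lin", 1, 23.0)]
        frac = qnt.rnase_r_resistance(ct_table(rows), "mock", "treated")
        assert frac["lin"] == pytest.approx(0.125)

    def test_simulation_recovers_known_survival(self):
        """Linear target surviving 5% and circular surviving 90%, measured
        through noisy Ct pairs, recovered within 20% on the replicate mean."""
        rng = np.random.default_rng(1)
        truths = {"lin": 0.05, "circ": 0.9}
        estimates = {t: [] for t in truths}
        for _ in range(50):
            rows = []
            for target, surv in truths.items():
                ct_mock = 22.0 + rng.normal(0, 0.1)
                ct_treat = 22.0 - np.log2(surv) + rng.normal(0, 0.1)
                rows += [("mock", target, 1, ct_mock), ("treated", target, 1, ct_treat)]
            frac = qnt.rnase_r_resistance(ct_table(rows), "mock", "treated")
            for t in truths:
                estimates[t].append(frac[t])
        for t, truth in truths.items():
            assert np.mean(estimates[t]) == pytest.approx(truth, rel=0.2)


# ---------------------------------------------------------------------------
# absolute quantification


class TestMolarMass:
    def test_four_nt_circular_forced_sum(self):
        std = RnaStandard("ACGU", topology="circular")
        assert qnt.molar_mass(std) == pytest.approx(1285.77)

    def test_linear_5oh_adds_water_only(self):
        circ = qnt.molar_mass(RnaStandard("ACGU", topology="circular"))
        lin = qnt.molar_mass(RnaStandard("ACGU", topology="linear", end_group="5'-OH"))
        assert lin - circ == pytest.approx(18.02)

    def test_random_sequence_matches_dictionary_sum_oracle(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGU"), size=1000))
        got = qnt.molar_mass(RnaStandard(seq, topology="linear"))
        assert got == pytest.approx(
            molar_mass_bruteforce(seq, "linear", end_extra=159.0), abs=1e-6)

    def test_circular_lighter_than_linear_under_any_end_group(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(10, 200))))
            circ = qnt.molar_mass(RnaStandard(seq, topology="circular"))
            for group in ("5'-OH", "5'-monophosphate", "5'-triphosphate"):
                assert circ < qnt.molar_mass(
                    RnaStandard(seq, topology="linear", end_group=group))

    def test_non_acgu_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            qnt.molar_mass(RnaStandard("ACGX"))


class TestMassToCopies:
    def test_unit_identity(self):
        mm = 396_516.0
        assert qnt.mass_to_copies(mm / qnt.AVOGADRO, mm) == pytest.approx(1.0)

    def test_one_microgram_of_a_396kda_standard(self):
        # 1 ug / (396,516 g/mol) * NA = 1.5188e12 molecules
        copies = qnt.mass_to_copies(1e-6, 396_516.0)
        assert copies == pytest.approx(1.519e12, rel=1e-3)

    def test_linearity(self):
        assert qnt.mass_to_copies(2e-6, 1e5) == pytest.approx(
            2 * qnt.mass_to_copies(1e-6, 1e5))


class TestStandardCurve:
    def test_perfect_doubling_slope_and_efficiency(self):
        points = [(10.0 ** d, 40 - np.log2(10.0 ** d)) for d in (11, 10, 9, 8, 7)]
        curve = qnt.fit_standard_curve(points)
        assert curve.slope == pytest.approx(-3.321928, abs=1e-6)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_slope_minus_3_6_efficiency(self):
        points = [(10.0 ** d, 40 - 3.6 * d) for d in (7, 8, 9, 10, 11)]
        curve = qnt.fit_standard_curve(points)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-9)
        assert curve.efficiency == pytest.approx(0.8956, abs=5e-4)

    def test_noisy_recovery_rate(self):
        """Slope recovered within +-0.1 in >=95% of 200 seeded noisy series
        (sigma_Ct = 0.15, 5 points x 3 replicates)."""
        hits = 0
        for seed in range(200):
            cfg = SimConfig(seed=seed, sigma_ct=0.15)
            std = gen_standard_series(cfg)
            curve = qnt.fit_standard_curve(
                list(std[["copies", "ct"]].itertuples(index=False)))
            if abs(curve.slope - (-3.321928)) <= 0.1:
                hits += 1
        assert hits >= 190

    def test_non_amplifying_curve_rejected(self):
        with pytest.raises(ValueError, match="non-amplifying"):
            qnt.fit_standard_curve([(1e7, 20.0), (1e9, 25.0), (1e11, 30.0)])


class TestCopiesPerCell:
    def test_default_rna_yield(self):
        assert qnt.copies_per_cell(1e9) == pytest.approx(7720.0)

    def test_zero_copies(self):
        assert qnt.copies_per_cell(0.0) == 0.0

    def test_linear_in_rna_yield(self):
        assert qnt.copies_per_cell(1e9, 2 * 7.72) == pytest.approx(2 * 7720.0)


class TestExonSkip:
    def test_subtraction(self):
        assert qnt.exon_skip_abundance(1000, 600) == (400, None)

    def test_negative_clamped_with_warning(self):
        val, warning = qnt.exon_skip_abundance(500, 600)
        assert val == 0.0 and warning is not None

    def test_simulation_recovers_skip_fraction(self):
        """Planted 30% skipped fraction, 10% measurement CV, 100 replicates:
        mean recovered fraction within +-0.05."""
        rng = np.random.default_rng(4)
        total_true, frac_true = 1e6, 0.3
        fracs = []
        for _ in range(100):
            total = total_true * rng.normal(1.0, 0.1)
            canonical = total_true * (1 - frac_true) * rng.normal(1.0, 0.1)
            skipped, _ = qnt.exon_skip_abundance(total, canonical)
            fracs.append(skipped / total)
        assert abs(np.mean(fracs) - frac_true) <= 0.05


# ---------------------------------------------------------------------------
# gene copy number


class TestGcn:
    def test_parental_fold_is_one_not_amplified(self):
        rows = [("par", "met", 1, 22.0), ("par", "cen", 1, 21.0)]
        res = qnt.gcn_qpcr(ct_table(rows), "met", "cen", "par")
        assert res.loc["par", "gcn_fold"] == 1.0
        assert not res.loc["par", "amplified"]

    def test_twofold_boundary_inclusive(self):
        rows = [("par", "met", 1, 22.0), ("par", "cen", 1, 21.0),
                ("res", "met", 1, 21.0), ("res", "cen", 1, 21.0)]
        res = qnt.gcn_qpcr(ct_table(rows), "met", "cen", "par")
        assert res.loc["res", "gcn_fold"] == pytest.approx(2.0)
        assert bool(res.loc["res", "amplified"])

    def test_missing_parental_is_error(self):
        rows = [("s1", "met", 1, 21.0), ("s1", "cen", 1, 21.0)]
        with pytest.raises(ValueError, match="parental"):
            qnt.gcn_qpcr(ct_table(rows), "met", "cen", "par")

    def test_eightfold_amplification_recovered(self):
        """Simulated 8-fold amplification with sigma_Ct = 0.2: the mean
        estimate across 100 seeds lies within [6.5, 9.8]."""
        folds = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = []
            for sample, fold in (("par", 1.0), ("res", 8.0)):
                for rep in (1, 2, 3):
                    rows.append((sample, "met", rep,
                                 25.0 - np.log2(fold) + rng.normal(0, 0.2)))
                    rows.append((sample, "cen", rep, 24.0 + rng.normal(0, 0.2)))
            res = qnt.gcn_qpcr(ct_table(rows), "met", "cen", "par")
            folds.append(res.loc["res", "gcn_fold"])
        assert 6.5 <= np.mean(folds) <= 9.8


# ---------------------------------------------------------------------------
# decay and plasma


class TestDecay:
    def test_exact_two_point_half_life(self):
        hl, excluded = qnt.decay_half_life([(0, 1.0), (4, 0.5)])
        assert hl == pytest.approx(4.0)
        assert not excluded

    def test_flat_series_has_no_half_life(self):
        hl, _ = qnt.decay_half_life([(0, 1.0), (4, 1.0), (8, 1.0)])
        assert hl is None

    def test_nonpositive_fractions_excluded_with_report(self):
        hl, excluded = qnt.decay_half_life([(0, 1.0), (4, 0.5), (8, 0.0)])
        assert hl == pytest.approx(4.0)
        assert len(excluded) == 1

    def test_simulation_recovers_8h_half_life(self):
        """t1/2 = 8 h, 10% lognormal noise, 6 timepoints over 20 h:
        recovered within +-1.5 h in >=90% of 100 seeds."""
        times = (0, 4, 8, 12, 16, 20)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = [(t, 0.5 ** (t / 8.0) * rng.lognormal(0, 0.1)) for t in times]
            hl, _ = qnt.decay_half_life(pts)
            if hl is not None and abs(hl - 8.0) <= 1.5:
                hits += 1
        assert hits >= 90


class TestPlasmaConversion:
    def test_default_chain_multiplier(self):
        # 20 ul RT / (15/100 of the eluate) / 1 ml plasma
        assert VolumeChain().multiplier == pytest.approx(400.0 / 3.0)
        assert qnt.plasma_copies_per_ml(3.0) == pytest.approx(400.0)

    def test_doubling_plasma_volume_halves_result(self):
        vc2 = VolumeChain(plasma_volume_ml=2.0)
        assert qnt.plasma_copies_per_ml(3.0, vc2) == pytest.approx(200.0)

    def test_identity_chain(self):
        vc = VolumeChain(plasma_volume_ml=1.0, rna_eluate_volume_ul=1.0,
                         rna_volume_into_rt_ul=1.0, rt_final_volume_ul=7.0,
                         cdna_loaded_ul=1.0)
        assert qnt.plasma_copies_per_ml(2.0, vc) == pytest.approx(14.0)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            VolumeChain(rna_volume_into_rt_ul=150.0)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = tmp_path / "volumes.yaml"
        cfg.write_text("plasma_volume_ml: 2.0\nrna_volume_into_rt_ul: 30.0\n")
        vc = qnt.load_volume_chain(cfg)
        assert vc.plasma_volume_ml == 2.0
        assert vc.multiplier == pytest.approx(20.0 / 0.3 / 2.0)
        with pytest.raises(ValueError, match="unknown"):
            cfg.write_text("bogus_key: 1\n")
            qnt.load_volume_chain(cfg)


class TestEndToEndAbsoluteQuant:
    @pytest.mark.parametrize("truth_cpc", [10.0, 100.0, 2000.0])
    def test_recovers_planted_copies_per_cell(self, truth_cpc):
        """Dilution-series fit -> Ct interpolation -> copies/cell recovers a
        planted truth in the 10..2000 copies/cell range within +-30% at
        sigma_Ct = 0.15."""
        cfg = SimConfig(seed=17, sigma_ct=0.15)
        copies_per_ug = truth_cpc / (qnt.PG_RNA_PER_CELL * 1e-6)
        table, std = gen_qpcr(cfg, {("CELL", "circ"): copies_per_ug})
        curve = qnt.fit_standard_curve(
            list(std[["copies", "ct"]].itertuples(index=False)))
        ct_mean = table.mean_ct().query("sample == 'CELL'")["ct"].iloc[0]
        recovered = qnt.copies_per_cell(float(qnt.copies_from_ct(curve, ct_mean)))
        assert recovered == pytest.approx(truth_cpc, rel=0.30)
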