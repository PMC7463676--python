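import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from metabomap import indexes as ix
from metabomap import preprocess
from metabomap import synthetic_cohort as sc

REFERENCE_MEDIANS = {
    "g": (5.46, 9.16, 6.58),
    "i": (43.1, 318.0, 238.0),
    "c": (0.68, 2.09, 2.59),
    "f": (0.48, 0.33, 0.12),
}


class TestAucTrapezoid:
    def test_reference_glucose_medians(self):
        # rounds to the printed cohort median 928
        auc = ix.auc_trapezoid([0, 30, 120], REFERENCE_MEDIANS["g"])
        assert auc == pytest.approx(927.6)
        assert round(auc) == 928

    def test_reference_ffa_medians(self):
        assert ix.auc_trapezoid([0, 30, 120], REFERENCE_MEDIANS["f"]) == \
            pytest.approx(32.4)

    def test_constant_value(self):
        assert ix.auc_trapezoid([0, 30, 120], [3.3, 3.3, 3.3]) == \
            pytest.approx(120 * 3.3)

    @pytest.mark.parametrize("times,values", [
        ([0], [1.0]),
        ([0, 0, 120], [1, 2, 3]),
        ([0, 30, 20], [1, 2, 3]),
        ([0, 30, 120], [1, np.nan, 3]),
    ])
    def test_invalid_inputs(self, times, values):
        with pytest.raises(ValueError):
            ix.auc_trapezoid(times, values)

    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        v=st.lists(st.floats(0.1, 50), min_size=3, max_size=3),
        w=st.lists(st.floats(0.1, 50), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, a, b, v, w):
        times = [0, 30, 120]
        v, w = np.array(v), np.array(w)
        lhs = ix.auc_trapezoid(times, a * v + b * w)
        rhs = a * ix.auc_trapezoid(times, v) + b * ix.auc_trapezoid(times, w)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestBetaCell:
    def test_reference_igi_and_di(self):
        g, i, c = (REFERENCE_MEDIANS[k] for k in "gic")
        out = ix.beta_cell_indexes(g[0], g[1], i[0], i[1], c[0], c[1])
        assert out.igi == pytest.approx(274.9 / 3.7, rel=1e-12)
        assert out.di == pytest.approx(274.9 / 3.7 / 43.1, rel=1e-12)

    def test_zero_numerator(self):
        out = ix.beta_cell_indexes(5.0, 8.0, 50.0, 50.0, 0.6, 1.8)
        assert out.igi == 0.0

    def test_flat_glucose_flagged_undefined(self):
        out = ix.beta_cell_indexes(5.0, 5.0, 50.0, 200.0, 0.6, 1.8)
        assert np.isnan(out.igi) and np.isnan(out.delta_cpep_glu_030)
        assert np.isnan(out.di)

    def test_sum_ratios(self):
        out = ix.beta_cell_indexes(5.0, 9.0, 40.0, 300.0, 0.6, 2.0)
        assert out.ratio_cpep_glu_030 == pytest.approx(2.6 / 14.0)
        assert out.ratio_ins_glu_030 == pytest.approx(340.0 / 14.0)


class TestHoma:
    def test_closed_form_scale(self):
        _, hir = ix.homa_indexes(5.46, 43.1, 0.68)
        assert hir == pytest.approx(5.46 * (43.1 / 6.0) / 22.5, rel=1e-12)

    def test_linearity_in_insulin(self):
        _, h1 = ix.homa_indexes(5.0, 60.0, 0.7)
        _, h2 = ix.homa_indexes(5.0, 120.0, 0.7)
        assert h2 == pytest.approx(2 * h1, rel=1e-12)

    def test_beta_cell_floor(self):
        hb, _ = ix.homa_indexes(3.5, 60.0, 0.7)
        assert np.isnan(hb)

    def test_passthrough_backend(self):
        backend = lambda g0, i0, c0: (123.0, 0.81)
        hb, hir = ix.homa_indexes(5.46, 43.1, 0.68, backend=backend)
        assert (hb, hir) == (123.0, 0.81)


class TestMatsuda:
    def test_reference_medians(self):
        got = ix.matsuda(
            np.array(REFERENCE_MEDIANS["g"]), np.array(REFERENCE_MEDIANS["i"])
        )
        expected = oracles.matsuda_ref(REFERENCE_MEDIANS["g"],
                                       REFERENCE_MEDIANS["i"])
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(5.779, abs=1e-3)

    def test_square_root_homogeneity(self):
        # index ~ (I0 * Imean)^(-1/2): scaling every insulin by s scales
        # the index by 1/s
        g = np.array([5.0, 9.0, 7.0])
        i = np.array([40.0, 300.0, 200.0])
        assert ix.matsuda(g, 4 * i) == pytest.approx(ix.matsuda(g, i) / 4)

    def test_degenerate_constant_curves(self):
        g = np.array([5.0, 5.0, 5.0])
        i = np.array([60.0, 60.0, 60.0])
        g0_mgdl, i0_miu = 5.0 * 18.016, 10.0
        assert ix.matsuda(g, i) == pytest.approx(10000 / (g0_mgdl * i0_miu))


class TestTissueIR:
    def test_reference_adipo(self):
        out = ix.tissue_ir(3e4, 219.3, 5416.5, 30, 55, 27, 0.48, 43.1, 3e4, 32.4)
        assert out.adipo_ir == pytest.approx(0.48 * 43.1, rel=1e-12)

    def test_reference_hepatic(self):
        out = ix.tissue_ir(3e4, 219.3, 5416.5, 30, 55, 27, 0.48, 43.1, 3e4, 32.4)
        assert out.hepatic_ir == pytest.approx(5416.5 * 219.3, rel=1e-12)
        assert out.hepatic_ir == pytest.approx(1.188e6, rel=1e-3)

    def test_isi_ffa_fixed_point(self):
        # scaled AUC product of 1 is the fixed point of 2/(x+1)
        out = ix.tissue_ir(3e4, 1, 1, 30, 55, 27, 0.5, 50, 1e4, 30.0)
        assert out.isi_ffa == pytest.approx(1.0, rel=1e-12)

    def test_log_of_nonpositive_flagged(self):
        out = ix.tissue_ir(3e4, 1, 1, -1.0, 55, 27, 0.5, 50, 1e4, 30.0)
        assert np.isnan(out.liver_ir)


class TestInsulinClearance:
    def test_reference_fast(self):
        out = ix.insulin_clearance(0.68, 2.09, 2.59, 43.1, 318, 238)
        assert out.ic_fast == pytest.approx(0.68 / 43.1, rel=1e-12)

    def test_reference_120(self):
        out = ix.insulin_clearance(0.68, 2.09, 2.59, 43.1, 318, 238)
        assert out.ic_120 == pytest.approx(4.68 / 556, rel=1e-12)

    def test_flat_trajectory_zero_slope(self):
        out = ix.insulin_clearance(0.7, 0.7, 0.7, 60, 60, 60)
        assert out.ic_delta_030 == pytest.approx(0.0, abs=1e-15)


class TestFattyLiver:
    def test_reference_nafld(self):
        out = ix.fatty_liver_scores(False, False, 43.1, 100, 27, 96)
        assert out.nafld_fls == pytest.approx(-2.889 + 0.145 * 43.1 / 6.0,
                                              rel=1e-12)

    def test_fli_midpoint(self):
        # linear predictor 0  <=>  fli 50; invert for TG given bmi/waist
        bmi, waist = 27.0, 96.0
        tg = math.exp((15.745 - 0.139 * bmi - 0.053 * waist) / 0.953)
        out = ix.fatty_liver_scores(False, False, 43.1, tg, bmi, waist)
        assert out.fli == pytest.approx(50.0, rel=1e-9)

    def test_fli_hand_evaluated(self):
        out = ix.fatty_liver_scores(False, False, 43.1, 100, 27, 96)
        assert out.fli == pytest.approx(oracles.fli_ref(100, 27, 96), rel=1e-12)

    @given(tg=st.floats(10, 2000), bmi=st.floats(15, 55),
           waist=st.floats(50, 180))
    @settings(max_examples=100, deadline=None)
    def test_fli_bounds(self, tg, bmi, waist):
        out = ix.fatty_liver_scores(False, False, 50.0, tg, bmi, waist)
        assert 0.0 <= out.fli <= 100.0


class TestEgfr:
    def test_female_at_knot(self):
        got = ix.egfr_ckd_epi(0.7, 62, "female")
        assert got == pytest.approx(141 * 1.018 * 0.993**62, rel=1e-12)

    def test_male_at_knot(self):
        got = ix.egfr_ckd_epi(0.9, 62, "male")
        assert got == pytest.approx(141 * 0.993**62, rel=1e-12)
        assert got == pytest.approx(91.2, abs=0.05)

    def test_monotone_decreasing_in_creatinine(self):
        values = [ix.egfr_ckd_epi(c, 60, "male")
                  for c in np.linspace(0.4, 4.0, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_nonpositive_flagged(self):
        assert np.isnan(ix.egfr_ckd_epi(0.0, 60, "male"))


class TestClassifyGlycemia:
    @pytest.mark.parametrize("g0,g120,expected", [
        (5.46, 6.58, "NG"),
        (7.0, 5.0, "DM"),
        (5.0, 11.1, "DM"),
        (6.5, 8.0, "IFG+IGT"),
        (6.1, 5.0, "IFG"),
        (5.0, 7.8, "IGT"),
        (6.9, 7.7, "IFG"),
    ])
    def test_cutoffs(self, g0, g120, expected):
        assert ix.classify_glycemia(g0, g120) == expected

    def test_missing_g120_cannot_be_igt(self):
        assert ix.classify_glycemia(5.0) == "NG"
        assert ix.classify_glycemia(6.5) == "IFG"

    def test_missing_g0_raises(self):
        with pytest.raises(ValueError):
            ix.classify_glycemia(np.nan, 8.0)

    @given(g0=st.floats(3.0, 15.0), g120=st.floats(2.0, 20.0))
    @settings(max_examples=200, deadline=None)
    def test_partition_exactly_one_class(self, g0, g120):
        assert ix.classify_glycemia(g0, g120) in ix.GLYCEMIA_CLASSES


class TestBmi:
    def test_direct(self):
        assert ix.bmi(70, 1.75) == pytest.approx(22.857, abs=1e-3)

    def test_inverse_construction_to_reference_median(self):
        assert ix.bmi(81, 1.732) == pytest.approx(27.0, abs=0.01)

    def test_linearity(self):
        assert ix.bmi(140, 1.75) == pytest.approx(2 * ix.bmi(70, 1.75))

    def test_zero_height(self):
        with pytest.raises(ValueError):
            ix.bmi(70, 0.0)


def _random_valid_inputs(rng, n):
    return {
        "g": rng.uniform(3.6, 15.0, (n, 3)),
        "i": rng.uniform(10.0, 1200.0, (n, 3)),
        "c": rng.uniform(0.2, 6.0, (n, 3)),
        "f": rng.uniform(0.05, 1.5, (n, 3)),
        "fat": rng.uniform(8, 55, n),
        "hdl": rng.uniform(25, 95, n),
        "bmi": rng.uniform(17, 45, n),
        "tg": rng.uniform(40, 600, n),
        "waist": rng.uniform(60, 140, n),
        "age": rng.uniform(20, 90, n),
        "creat": rng.uniform(0.4, 3.0, n),
    }


N_ORACLE = 1000


@pytest.fixture(scope="module")
def inputs():
    return _random_valid_inputs(np.random.default_rng(123), N_ORACLE)


class TestOracleEquivalence:
    """Every composite index equals a straight-line re-evaluation of its
    formula on 1000 random valid inputs (rel err <= 1e-10)."""

    N = N_ORACLE

    def test_auc(self, inputs):
        for row in inputs["g"][:200]:
            got = ix.auc_trapezoid([0, 30, 120], row)
            ref = oracles.auc_trapz([0, 30, 120], list(row))
            assert got == pytest.approx(ref, rel=1e-10)

    def test_igi(self, inputs):
        g, i = inputs["g"], inputs["i"]
        out = ix.beta_cell_indexes(g[:, 0], g[:, 1], i[:, 0], i[:, 1],
                                   inputs["c"][:, 0], inputs["c"][:, 1])
        for k in range(self.N):
            ref = oracles.igi(g[k, 0], g[k, 1], i[k, 0], i[k, 1])
            assert out.igi[k] == pytest.approx(ref, rel=1e-10)

    def test_matsuda(self, inputs):
        out = ix.matsuda(inputs["g"], inputs["i"])
        for k in range(self.N):
            ref = oracles.matsuda_ref(inputs["g"][k], inputs["i"][k])
            assert out[k] == pytest.approx(ref, rel=1e-10)

    def test_liver_ir(self, inputs):
        auc_i = np.array([oracles.auc_trapz([0, 30, 120], r)
                          for r in inputs["i"]])
        out = ix.tissue_ir(auc_i, 1, 1, inputs["fat"], inputs["hdl"],
                           inputs["bmi"], 0.5, 50, auc_i, 30.0)
        for k in range(self.N):
            ref = oracles.liver_ir_ref(auc_i[k], inputs["fat"][k],
                                       inputs["hdl"][k], inputs["bmi"][k])
            assert out.liver_ir[k] == pytest.approx(ref, rel=1e-10)

    def test_isi_ffa(self, inputs):
        auc_i = np.array([oracles.auc_trapz([0, 30, 120], r)
                          for r in inputs["i"]])
        auc_f = np.array([oracles.auc_trapz([0, 30, 120], r)
                          for r in inputs["f"]])
        out = ix.tissue_ir(auc_i, 1, 1, inputs["fat"], inputs["hdl"],
                           inputs["bmi"], 0.5, 50, auc_i, auc_f)
        for k in range(self.N):
            ref = oracles.isi_ffa_ref(auc_i[k], auc_f[k])
            assert out.isi_ffa[k] == pytest.approx(ref, rel=1e-10)
            assert 0.0 < out.isi_ffa[k] <= 2.0

    def test_fli_and_nafld(self, inputs):
        out = ix.fatty_liver_scores(
            np.zeros(self.N), np.zeros(self.N), inputs["i"][:, 0],
            inputs["tg"], inputs["bmi"], inputs["waist"],
        )
        for k in range(self.N):
            assert out.fli[k] == pytest.approx(
                oracles.fli_ref(inputs["tg"][k], inputs["bmi"][k],
                                inputs["waist"][k]), rel=1e-10)
            assert out.nafld_fls[k] == pytest.approx(
                oracles.nafld_fls_ref(False, False, inputs["i"][k, 0]),
                rel=1e-10)

    def test_egfr(self, inputs):
        for sex in ("male", "female"):
            out = ix.egfr_ckd_epi(inputs["creat"], inputs["age"], sex)
            for k in range(self.N):
                ref = oracles.egfr_ref(inputs["creat"][k], inputs["age"][k], sex)
                assert out[k] == pytest.approx(ref, rel=1e-10)


class TestUnitSanity:
    def test_insulin_unit_roundtrip(self):
        """Re-declaring insulin in mIU/L and converting back is lossless,
        so every insulin-consuming index is unchanged."""
        rng = np.random.default_rng(5)
        i_pmol = rng.uniform(20, 900, 100)
        i_round_trip = ix.insulin_to_miu(i_pmol) * ix.INSULIN_PMOL_PER_MIU
        np.testing.assert_allclose(i_round_trip, i_pmol, rtol=1e-14)
        g = np.tile([5.2, 9.0, 7.0], (100, 1))
        i3 = np.column_stack([i_pmol, i_pmol * 4, i_pmol * 3])
        np.testing.assert_allclose(
            ix.matsuda(g, i3), ix.matsuda(g, i_round_trip[:, None] * i3 / i_pmol[:, None]),
            rtol=1e-12,
        )


@pytest.fixture(scope="module")
def panel_and_cohort(default_cohort):
    retained, _ = preprocess.apply_exclusions(default_cohort)
    return ix.compute_panel(retained), retained


class TestComputePanel:

    def test_one_row_per_subject(self, panel_and_cohort):
        panel, cohort = panel_and_cohort
        assert len(panel) == len(cohort)

    def test_no_infinities(self, panel_and_cohort):
        panel, _ = panel_and_cohort
        numeric = panel.select_dtypes(include=[float]).to_numpy()
        assert not np.isinf(numeric).any()

    def test_idempotent(self, panel_and_cohort):
        panel, cohort = panel_and_cohort
        again = ix.compute_panel(cohort)
        pd.testing.assert_frame_equal(panel, again)

    def test_missingness_propagation(self):
        cfg = sc.GeneratorConfig(
            n_subjects=30, archetypes=tuple(sc.default_archetypes()), seed=2
        )
        cohort = sc.generate_cohort(cfg)
        cohort.loc[0, "insulin_30"] = np.nan
        panel = ix.compute_panel(cohort)
        for col in ("auc_insulin", "igi", "ratio_ins_glu_030", "matsuda",
                    "hepatic_ir", "ic_delta_030"):
            assert np.isnan(panel.loc[0, col]), col
        assert not np.isnan(panel.loc[0, "auc_ffa"])
        assert not np.isnan(panel.loc[0, "homa_ir"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ix.compute_panel(pd.DataFrame(columns=sc.COHORT_COLUMNS))

    def test_units_manifest_written(self, panel_and_cohort, tmp_path):
        panel, _ = panel_and_cohort
        ix.write_panel(panel, tmp_path / "p.csv", tmp_path / "units.tsv")
        lines = (tmp_path / "units.tsv").read_text().splitlines()
        assert len(lines) == len(panel.columns)
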