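"""Biomarker scoring chain: eligibility, bTMB, mean AF, ctDNA mass, adjustment."""

import math

import numpy as np
import pytest

from btmbkit.errors import ConfigurationError, ValidationError
from btmbkit.io import ClinicalRecord, PlasmaSample, VariantCall
from btmbkit.scoring import (EligibilityPolicy, adjust_btmb, classify_dcb,
                             compute_btmb, compute_mean_af, estimate_ctdna_mass,
                             filter_eligible_variants, score_cohort)


def call(af, pid="P1", germline=False, driver=False, vclass="SNV", pos=100):
    return VariantCall(patient_id=pid, chrom="chr1", pos=pos, ref="A", alt="T",
                       allele_fraction=af, depth=1000, variant_class=vclass,
                       driver_flag=driver, germline_flag=germline)


class TestEligibility:
    def test_af_floor_drops_subthreshold_call(self):
        calls = [call(0.002), call(0.01), call(0.05), call(0.20), call(0.30)]
        btmb_set, af_set = filter_eligible_variants(calls, EligibilityPolicy())
        assert len(btmb_set) == 4  # the 0.002 call drops
        assert len(af_set) == 5   # mean AF uses all somatic calls

    def test_germline_excluded_from_both_sets(self):
        calls = [call(0.01), call(0.5, germline=True)]
        btmb_set, af_set = filter_eligible_variants(calls, EligibilityPolicy())
        assert len(btmb_set) == 1
        assert len(af_set) == 1

    def test_driver_exclusion_only_affects_btmb_set(self):
        calls = [call(0.05, driver=True), call(0.06, driver=True)] + \
                [call(0.01 * k, pos=200 + k) for k in range(1, 5)]
        pol = EligibilityPolicy(exclude_drivers_from_btmb=True)
        btmb_set, af_set = filter_eligible_variants(calls, pol)
        assert len(btmb_set) == 4
        assert len(af_set) == 6

    def test_empty_input(self):
        assert filter_eligible_variants([], EligibilityPolicy()) == ([], [])

    def test_multi_patient_calls_rejected(self):
        with pytest.raises(ValidationError):
            filter_eligible_variants([call(0.1, pid="A"), call(0.1, pid="B")],
                                     EligibilityPolicy())


class TestScoreArithmetic:
    @pytest.mark.parametrize("n, panel, expected", [(12, 1.0, 12.0), (11, 1.1, 10.0), (0, 1.0, 0.0)])
    def test_btmb_is_count_per_megabase(self, n, panel, expected):
        calls = [call(0.05, pos=100 + k) for k in range(n)]
        assert compute_btmb(calls, panel) == pytest.approx(expected)

    def test_nonpositive_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_btmb([], 0.0)

    def test_mean_af(self):
        assert compute_mean_af([call(0.05), call(0.15)]) == pytest.approx(0.10)
        assert compute_mean_af([call(0.08)]) == pytest.approx(0.08)
        assert compute_mean_af([]) == 0.0

    @pytest.mark.parametrize("cfdna, af, expected", [(25, 0.08, 2.0), (30, 0.0, 0.0), (10, 0.5, 5.0)])
    def test_ctdna_mass_is_product(self, cfdna, af, expected):
        assert estimate_ctdna_mass(cfdna, af) == pytest.approx(expected)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValidationError):
            estimate_ctdna_mass(-1.0, 0.1)

    def test_adjustment_divides_by_ctdna_mass(self):
        assert adjust_btmb(16.0, 2.0) == pytest.approx(8.0)
        assert adjust_btmb(0.0, 1.5) == 0.0

    def test_zero_mass_undefined_by_default(self):
        assert math.isnan(adjust_btmb(10.0, 0.0))

    def test_zero_mass_epsilon_floor_policy(self):
        pol = EligibilityPolicy(zero_mass_policy="epsilon_floor", epsilon_floor_ng=0.5)
        assert adjust_btmb(10.0, 0.0, pol) == pytest.approx(20.0)


class TestDCB:
    @pytest.mark.parametrize("months, event, expected", [
        (7.2, True, "DCB"),
        (6.0, True, "DCB"),        # boundary: six months or more
        (6.0, False, "DCB"),
        (4.0, True, "NDB"),
        (4.0, False, "indeterminate"),
    ])
    def test_default_policy(self, months, event, expected):
        assert classify_dcb(months, event) == expected

    def test_indeterminate_as_ndb_policy(self):
        pol = EligibilityPolicy(dcb_indeterminate="ndb")
        assert classify_dcb(4.0, False, pol) == "NDB"

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            classify_dcb(-1.0, True)


def _clin(pid):
    return ClinicalRecord(patient_id=pid, arm="ICI", os_months=10.0, os_event=True,
                          pfs_months=5.0, pfs_event=True, best_response="SD")


class TestScoreCohort:
    def test_three_patient_fixture_invariants(self):
        clinical = [_clin("A"), _clin("B"), _clin("C")]
        variants = ([call(0.05, pid="A", pos=1), call(0.15, pid="A", pos=2)]
                    + [call(0.02, pid="B", pos=3)])
        plasma = [PlasmaSample("A", 20.0), PlasmaSample("B", 30.0), PlasmaSample("C", 25.0)]
        table = score_cohort(clinical, variants, plasma)
        assert len(table) == 3
        defined = table[table["undefined_reason"] == "none"]
        # adjusted x ctDNA mass == btmb, exactly as derived
        np.testing.assert_allclose(
            defined["adjusted_btmb"] * defined["ctdna_input_mass_ng"],
            defined["btmb"], atol=1e-12)
        c = table.set_index("patient_id").loc["C"]
        assert c["btmb"] == 0.0
        assert c["undefined_reason"] == "no_variants"

    def test_orphan_variant_rejected(self):
        with pytest.raises(ValidationError, match="X"):
            score_cohort([_clin("A")], [call(0.1, pid="X")], [PlasmaSample("A", 20.0)])

    def test_missing_plasma_reason(self):
        table = score_cohort([_clin("A")], [call(0.1, pid="A")], [])
        assert table.iloc[0]["undefined_reason"] == "missing_plasma"

    def test_matches_independent_recomputation(self, small_cohort):
        """Row-by-row recompute from the raw tables with plain pandas."""
        import pandas as pd
        from btmbkit.io import plasma_to_frame, variants_to_frame

        table = score_cohort(small_cohort.clinical, small_cohort.variants,
                             small_cohort.plasma, panel_size_mb=1.0)
        vdf = variants_to_frame(small_cohort.variants)
        vdf = vdf[vdf["germline_flag"] == 0]
        pdf = plasma_to_frame(small_cohort.plasma).set_index("patient_id")
        for row in table.itertuples():
            mine = vdf[vdf["patient_id"] == row.patient_id]
            n_elig = int((mine["allele_fraction"] >= 0.005).sum())
            mean_af = float(mine["allele_fraction"].mean()) if len(mine) else 0.0
            assert row.n_eligible_mutations == n_elig
            assert row.btmb == pytest.approx(n_elig / 1.0)
            assert row.mean_af == pytest.approx(mean_af, abs=1e-12)
            mass = pdf.loc[row.patient_id, "cfdna_input_mass_ng"] * mean_af
            assert row.ctdna_input_mass_ng == pytest.approx(mass, rel=1e-12)
            if mass > 0:
                assert row.adjusted_btmb == pytest.approx(row.btmb / mass, rel=1e-12)
            else:
                assert math.isnan(row.adjusted_btmb)


class TestScaleEquivariance:
    def test_af_rescaling_moves_mass_not_btmb(self):
        """Scaling every AF by c scales mean AF and ctDNA mass by c and the
        adjusted score by 1/c, leaving bTMB unchanged (no floor crossings)."""
        afs = [0.02, 0.05, 0.11, 0.26]
        c = 0.5
        pol = EligibilityPolicy()
        base_b, base_af = filter_eligible_variants([call(a, pos=i) for i, a in enumerate(afs, 1)], pol)
        scaled_b, scaled_af = filter_eligible_variants(
            [call(a * c, pos=i) for i, a in enumerate(afs, 1)], pol)
        assert len(base_b) == len(scaled_b)
        m0, m1 = compute_mean_af(base_af), compute_mean_af(scaled_af)
        assert m1 == pytest.approx(c * m0)
        btmb = compute_btmb(base_b, 1.0)
        adj0 = adjust_btmb(btmb, estimate_ctdna_mass(25.0, m0))
        adj1 = adjust_btmb(btmb, estimate_ctdna_mass(25.0, m1))
        assert adj1 == pytest.approx(adj0 / c)

    def test_adding_eligible_variant_never_decreases_btmb(self):
        pol = EligibilityPolicy()
        calls = [call(0.02, pos=1), call(0.07, pos=2)]
        before = compute_btmb(filter_eligible_variants(calls, pol)[0], 1.0)
        after = compute_btmb(
            filter_eligible_variants(calls + [call(0.01, pos=3)], pol)[0], 1.0)
        assert after >= before
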