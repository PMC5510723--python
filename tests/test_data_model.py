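"""Container validation, allele harmonization and orientation."""

import numpy as np
import pandas as pd
import pytest

from mrsummary import (
    CorrelationMatrix,
    SummaryData,
    align_alleles,
    flag_palindromic,
    orient_to_exposure_increasing,
    validate_summary_data,
)
from mrsummary.exceptions import (
    CorrelationMatrixError,
    DataStructureError,
    HarmonizationError,
    StandardErrorError,
)


class TestValidate:
    def test_valid_data_returned_unchanged(self):
        d = SummaryData(bx=[0.1, 0.2, 0.3], bxse=[0.01] * 3,
                        by=[0.02, 0.05, 0.06], byse=[0.01] * 3)
        assert validate_summary_data(d) is d

    @pytest.mark.parametrize("field,bad", [("bxse", 0.0), ("byse", -0.1)])
    def test_nonpositive_se_names_variant(self, field, bad):
        kwargs = dict(bx=[0.1, 0.2], bxse=[0.01, 0.01],
                      by=[0.02, 0.05], byse=[0.01, 0.01])
        kwargs[field] = [0.01, bad]
        with pytest.raises(StandardErrorError, match="index 1"):
            validate_summary_data(SummaryData(**kwargs))

    def test_length_mismatch_names_field(self):
        d = SummaryData(bx=[0.1, 0.2, 0.3], bxse=[0.01] * 3,
                        by=[0.02, 0.05], byse=[0.01] * 3)
        with pytest.raises(DataStructureError, match="by"):
            validate_summary_data(d)

    def test_correlation_dimension_mismatch(self):
        d = SummaryData(bx=[0.1, 0.2, 0.3], bxse=[0.01] * 3,
                        by=[0.02, 0.05, 0.06], byse=[0.01] * 3,
                        correlation=CorrelationMatrix(np.eye(2)))
        with pytest.raises(CorrelationMatrixError, match="dimension"):
            validate_summary_data(d)

    def test_duplicate_ids_rejected(self):
        d = SummaryData(bx=[0.1, 0.2], bxse=[0.01] * 2, by=[0.0, 0.0],
                        byse=[0.01] * 2, variant_ids=["rs1", "rs1"])
        with pytest.raises(DataStructureError, match="unique"):
            validate_summary_data(d)


class TestCorrelationMatrix:
    def test_asymmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(CorrelationMatrixError, match="asymmetric"):
            CorrelationMatrix(m)

    def test_out_of_range_rejected(self):
        m = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(CorrelationMatrixError):
            CorrelationMatrix(m)

    def test_indefinite_rejected(self):
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(CorrelationMatrixError, match="definite"):
            CorrelationMatrix(m)

    def test_psd_boundary_admitted(self):
        # perfectly correlated pair: smallest eigenvalue exactly 0 is legal
        # (it is the *estimators* that reject the resulting singular Sigma)
        CorrelationMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestPalindromic:
    def test_flags(self, allele_data):
        # A/G -> no, C/G -> yes, A/T -> yes
        assert flag_palindromic(allele_data) == [False, True, True]

    def test_missing_alleles_indeterminate(self):
        d = SummaryData(bx=[0.1], bxse=[0.01], by=[0.0], byse=[0.01])
        assert flag_palindromic(d) == [None]


class TestOrient:
    def test_negative_bx_flips_both(self):
        d = SummaryData(bx=[-0.1], bxse=[0.02], by=[0.2], byse=[0.05])
        o = orient_to_exposure_increasing(d)
        assert o.bx[0] == pytest.approx(0.1) and o.by[0] == pytest.approx(-0.2)
        assert o.bxse[0] == 0.02 and o.byse[0] == 0.05

    def test_positive_bx_unchanged(self, small_data):
        assert orient_to_exposure_increasing(small_data) is small_data

    def test_zero_bx_unchanged(self):
        d = SummaryData(bx=[0.0, -0.1], bxse=[0.01] * 2, by=[0.3, 0.2],
                        byse=[0.01] * 2)
        o = orient_to_exposure_increasing(d)
        assert o.bx[0] == 0.0 and o.by[0] == 0.3

    def test_idempotent(self, allele_data):
        once = orient_to_exposure_increasing(allele_data)
        twice = orient_to_exposure_increasing(once)
        np.testing.assert_array_equal(once.bx, twice.bx)
        np.testing.assert_array_equal(once.by, twice.by)

    def test_eaf_complemented_and_alleles_swapped(self, allele_data):
        o = orient_to_exposure_increasing(allele_data)
        # rs2 has bx < 0
        assert o.eaf[1] == pytest.approx(0.6)
        assert (o.effect_allele[1], o.other_allele[1]) == ("G", "C")

    def test_correlation_sign_adjusted(self):
        rho = np.array([[1.0, 0.4], [0.4, 1.0]])
        d = SummaryData(bx=[0.1, -0.2], bxse=[0.01] * 2, by=[0.0, 0.0],
                        byse=[0.01] * 2, correlation=CorrelationMatrix(rho))
        o = orient_to_exposure_increasing(d)
        assert o.correlation.values[0, 1] == pytest.approx(-0.4)

    def test_ratio_invariant(self, allele_data):
        o = orient_to_exposure_increasing(allele_data)
        np.testing.assert_allclose(o.by / o.bx, allele_data.by / allele_data.bx)


def _records(rows):
    return pd.DataFrame(
        rows, columns=["snp", "beta", "se", "effect_allele", "other_allele"]
    )


class TestAlignAlleles:
    def test_swapped_alleles_flip_sign(self):
        exp = _records([["rs1", 0.1, 0.01, "A", "G"]])
        out = _records([["rs1", 0.3, 0.05, "G", "A"]])
        res = align_alleles(exp, out)
        assert res.data.by[0] == pytest.approx(-0.3)

    def test_identical_alleles_unchanged(self):
        exp = _records([["rs1", 0.1, 0.01, "A", "G"]])
        out = _records([["rs1", 0.3, 0.05, "A", "G"]])
        res = align_alleles(exp, out)
        assert res.data.by[0] == pytest.approx(0.3)

    def test_irreconcilable_pair_dropped_and_reported(self):
        exp = _records([["rs1", 0.1, 0.01, "A", "G"],
                        ["rs2", 0.2, 0.01, "C", "T"]])
        out = _records([["rs1", 0.3, 0.05, "A", "T"],
                        ["rs2", 0.1, 0.05, "C", "T"]])
        with pytest.warns(UserWarning, match="rs1"):
            res = align_alleles(exp, out)
        assert res.data.variant_ids == ("rs2",)
        assert res.dropped[0][0] == "rs1"

    def test_no_shared_variants_errors(self):
        exp = _records([["rs1", 0.1, 0.01, "A", "G"]])
        out = _records([["rs9", 0.3, 0.05, "A", "G"]])
        with pytest.raises(HarmonizationError, match="share no variants"):
            align_alleles(exp, out)

    def test_strand_flip_only_when_allowed(self):
        # outcome reported on the other strand: A/G vs T/C
        exp = _records([["rs1", 0.1, 0.01, "A", "G"]])
        out = _records([["rs1", 0.3, 0.05, "T", "C"]])
        with pytest.raises(HarmonizationError):
            align_alleles(exp, out, allow_strand_flip=False)
        res = align_alleles(exp, out, allow_strand_flip=True)
        assert res.data.by[0] == pytest.approx(0.3)
        assert res.strand_flipped == ["rs1"]

    def test_palindromic_never_strand_flipped(self):
        # A/T palindrome: complementing maps the pair onto itself, so a
        # "strand" match would be arbitrary; swapped orientation is the only
        # direct match and non-matching pairs must drop
        exp = _records([["rs1", 0.1, 0.01, "A", "T"],
                        ["rs2", 0.2, 0.01, "A", "G"]])
        out = _records([["rs1", 0.3, 0.05, "T", "A"],
                        ["rs2", 0.1, 0.05, "A", "G"]])
        res = align_alleles(exp, out, allow_strand_flip=True)
        # direct swap match still works (sign flip), no strand flip recorded
        assert res.data.by[0] == pytest.approx(-0.3)
        assert res.strand_flipped == []

    def test_orientation_invariance_of_harmonization(self):
        """Flipping the reported allele of every outcome record changes
        nothing after harmonization."""
        exp = _records([["rs1", 0.1, 0.01, "A", "G"],
                        ["rs2", 0.2, 0.01, "C", "A"]])
        out = _records([["rs1", 0.3, 0.05, "A", "G"],
                        ["rs2", -0.2, 0.05, "C", "A"]])
        flipped = out.copy()
        flipped["beta"] = -flipped["beta"]
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]].to_numpy()
        a = align_alleles(exp, out).data
        b = align_alleles(exp, flipped).data
        np.testing.assert_allclose(a.by, b.by)
        np.testing.assert_allclose(a.bx, b.bx)
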