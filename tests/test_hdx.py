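"""Uptake bookkeeping: exchangeable amides, back exchange, fractional
uptake, normalization, coverage."""

import numpy as np
import pandas as pd
import pytest

from hdxflex.hdx import (
    BackExchangeRecord,
    PeptideRecord,
    UptakeMeasurement,
    back_exchange_rate,
    compute_coverage,
    compute_uptake,
    correct_back_exchange,
    exchangeable_nh,
    fractional_hdx,
    normalize_hdx,
    read_state_table,
    write_state_table,
)
from hdxflex.envelope import IsotopeEnvelope, PROTON_MASS


def _m(pep, uptake, exposure=60.0, state="free", rep=1):
    return UptakeMeasurement(pep, state, exposure, rep, uptake)


class TestExchangeableNH:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", 3),
            ("AGPLK", 3),  # first residue and the proline excluded
            ("APPP", 0),
            ("PAAA", 3),  # N-terminal proline is excluded anyway
            ("AA", 1),
        ],
    )
    def test_counting_rule(self, seq, expected):
        assert exchangeable_nh(seq) == expected

    def test_two_residue_convention(self):
        assert exchangeable_nh("AGPLK", n_term_excluded=2) == 2

    def test_bad_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            exchangeable_nh("AAXA")

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            exchangeable_nh("")

    def test_agrees_with_per_residue_scan(self):
        # brute-force oracle: walk residues 2..N, count non-prolines
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(1000):
            n = rng.integers(2, 30)
            seq = "".join(rng.choice(aas, size=n))
            brute = sum(1 for aa in seq[1:] if aa != "P")
            assert exchangeable_nh(seq) == brute


class TestPeptideRecord:
    def test_span_must_match_sequence(self):
        with pytest.raises(ValueError):
            PeptideRecord("AAAA", 1, 3)

    def test_observed_residues_skip_nterm_and_prolines(self):
        pep = PeptideRecord("AGPLK", 10, 14)
        assert pep.observed_residues() == [11, 13, 14]


class TestBackExchange:
    def test_forty_percent(self):
        pep = PeptideRecord("AKLMNQRSTVW", 1, 11)  # 10 exchangeable
        rec = back_exchange_rate(_m(pep, 6.0))
        assert rec.be_fraction == pytest.approx(0.40)

    def test_full_uptake_means_zero_be(self):
        pep = PeptideRecord("AKLMNQRSTVW", 1, 11)
        assert back_exchange_rate(_m(pep, 10.0)).be_fraction == pytest.approx(0.0)

    def test_ratio_examples(self):
        pep = PeptideRecord("AKLMNQRSTVWYA", 1, 13)  # 12 exchangeable
        assert back_exchange_rate(_m(pep, 7.2)).be_fraction == pytest.approx(0.40)

    def test_overshoot_clamped_with_warning(self):
        pep = PeptideRecord("AAA", 1, 3)
        with pytest.warns(UserWarning, match="clamped"):
            rec = back_exchange_rate(_m(pep, 2.5))
        assert rec.be_fraction == 0.0

    def test_zero_exchangeable_error(self):
        pep = PeptideRecord("AP", 1, 2)
        with pytest.raises(ValueError, match="exchangeable"):
            back_exchange_rate(_m(pep, 0.5))


class TestCorrectBackExchange:
    def test_division_by_retained_fraction(self):
        pep = PeptideRecord("AKLMNQRSTVW", 1, 11)
        be = BackExchangeRecord(pep, 6.0, 0.40)
        assert correct_back_exchange(_m(pep, 1.2), be) == pytest.approx(2.0)
        assert correct_back_exchange(_m(pep, 3.0), BackExchangeRecord(pep, 9.0, 0.25)) == pytest.approx(4.0)

    def test_zero_be_is_identity(self):
        pep = PeptideRecord("AKLMNQRSTVW", 1, 11)
        be = BackExchangeRecord(pep, 10.0, 0.0)
        assert correct_back_exchange(_m(pep, 3.3), be) == pytest.approx(3.3)

    def test_cap_at_exchangeable(self):
        pep = PeptideRecord("AAA", 1, 3)  # 2 exchangeable
        be = BackExchangeRecord(pep, 1.0, 0.5)
        with pytest.warns(UserWarning, match="capped"):
            assert correct_back_exchange(_m(pep, 1.9), be) == 2.0

    def test_peptide_mismatch(self):
        pep = PeptideRecord("AAA", 1, 3)
        other = PeptideRecord("AKL", 5, 7)
        with pytest.raises(ValueError):
            correct_back_exchange(_m(pep, 1.0), BackExchangeRecord(other, 1.0, 0.1))


class TestFractionalHDX:
    def test_examples(self):
        pep = PeptideRecord("AKLMNQRSTVW", 1, 11)  # 10 exchangeable
        assert fractional_hdx(_m(pep, 2.0)) == pytest.approx(20.0)
        assert fractional_hdx(_m(pep, 0.0)) == pytest.approx(0.0)
        assert fractional_hdx(_m(pep, 10.0)) == pytest.approx(100.0)

    def test_monotone_in_uptake(self):
        pep = PeptideRecord("AKLMNQRSTVW", 1, 11)
        vals = [fractional_hdx(_m(pep, u)) for u in np.linspace(0, 10, 7)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestNormalizeHDX:
    def _table(self, uptakes, state="run1", exposure=60.0):
        return pd.DataFrame(
            {
                "state": state,
                "exposure_s": exposure,
                "uptake_da": uptakes,
            }
        )

    def test_unit_spaced_group(self):
        res = normalize_hdx(self._table([1.0, 2.0, 3.0]))
        assert np.allclose(res.z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_translation_invariance(self):
        a = normalize_hdx(self._table([1.0, 2.5, 4.0, 4.5]))
        b = normalize_hdx(self._table([11.0, 12.5, 14.0, 14.5]))
        assert np.allclose(a.z.to_numpy(), b.z.to_numpy())

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(7)
        res = normalize_hdx(self._table(rng.normal(3, 0.5, 50)))
        z = res.z.to_numpy()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_scale_invariance_up_to_sign(self):
        vals = [1.0, 2.0, 4.0, 5.0]
        a = normalize_hdx(self._table(vals)).z.to_numpy()
        b = normalize_hdx(self._table([-3.0 * v for v in vals])).z.to_numpy()
        assert np.allclose(a, -b)

    def test_zero_variance_group_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalize_hdx(self._table([2.0, 2.0, 2.0]))

    def test_groups_are_independent(self):
        t = pd.concat(
            [self._table([1.0, 2.0, 3.0], exposure=60.0),
             self._table([10.0, 30.0], exposure=600.0)],
            ignore_index=True,
        )
        res = normalize_hdx(t)
        assert np.allclose(res.z.to_numpy(), [-1, 0, 1, -np.sqrt(0.5), np.sqrt(0.5)])


class TestComputeUptake:
    def _env(self, mz, inten, charge=1):
        return IsotopeEnvelope(charge, np.asarray(mz, float), np.asarray(inten, float))

    def test_identical_envelopes(self):
        e = self._env([100.0, 101.0, 102.0], [1.0, 2.0, 1.0])
        assert compute_uptake(e, e) == pytest.approx(0.0)

    def test_delta_mz_times_charge(self):
        ref = self._env([500.0], [1.0], charge=2)
        lab = self._env([501.0], [1.0], charge=2)
        assert compute_uptake(lab, ref) == pytest.approx(2.0)

    def test_hand_computed_centroids(self):
        # weighted means: ref (100*1+101*2+102*1)/4 = 101.0
        #                 lab (102*2+103*1+104*1)/4 = 102.75
        ref = self._env([100.0, 101.0, 102.0], [1.0, 2.0, 1.0])
        lab = self._env([102.0, 103.0, 104.0], [2.0, 1.0, 1.0])
        assert compute_uptake(lab, ref) == pytest.approx(1.75)

    def test_charge_mismatch(self):
        with pytest.raises(ValueError, match="charge"):
            compute_uptake(self._env([100.0], [1.0], 1), self._env([100.0], [1.0], 2))


class TestCoverage:
    def test_full_coverage(self):
        peps = [PeptideRecord("A" * 165, 1, 165)]
        assert compute_coverage(peps, 165) == pytest.approx(100.0)

    def test_union_counting(self):
        peps = [PeptideRecord("A" * 10, 1, 10), PeptideRecord("A" * 10, 5, 14)]
        assert compute_coverage(peps, 20) == pytest.approx(70.0)

    def test_eighty_of_165(self):
        peps = [PeptideRecord("A" * 40, 1, 40), PeptideRecord("A" * 40, 41, 80)]
        assert compute_coverage(peps, 165) == pytest.approx(100 * 80 / 165)

    def test_empty_list(self):
        assert compute_coverage([], 100) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            compute_coverage([PeptideRecord("AA", 10, 11)], 5)


class TestStateTableIO:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "protein": ["p"] * 2,
                "sequence": ["AKLM"] * 2,
                "start": [1, 1],
                "end": [4, 4],
                "state": ["free", "bound"],
                "exposure_s": [60.0, 60.0],
                "replicate": [1, 1],
                "uptake_da": [1.25, 0.75],
            }
        )
        path = tmp_path / "t.csv"
        write_state_table(df, path)
        back = read_state_table(path)
        assert np.allclose(back["uptake_da"], df["uptake_da"])

    def test_schema_violation_reports_rows(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "protein,sequence,start,end,state,exposure_s,replicate,uptake_da\n"
            "p,AKLM,1,4,free,-1.0,1,1.0\n"
        )
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            read_state_table(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad2.csv"
        path.write_text("protein,sequence\np,AKLM\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_state_table(path)
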