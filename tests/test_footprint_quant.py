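"""Oxidation quantification, fold changes and exposure calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coldscan import footprint_quant as fq
from coldscan import synthetic_data as sd
from coldscan.errors import UndefinedControlError, UndefinedSignalError


class TestOxidationLevel:
    @pytest.mark.parametrize("oxi, naked, expected", [
        (100.0, 300.0, 0.25),
        (0.0, 50.0, 0.0),
        (50.0, 0.0, 1.0),
    ])
    def test_direct_arithmetic(self, oxi, naked, expected):
        assert fq.oxidation_level(oxi, naked) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedSignalError):
            fq.oxidation_level(0.0, 0.0)

    @given(oxi=st.floats(0.0, 1e9), naked=st.floats(1e-6, 1e9),
           c=st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, oxi, naked, c):
        """Multiplying both intensities by c>0 leaves Oxi% unchanged."""
        assert fq.oxidation_level(oxi * c, naked * c) == pytest.approx(
            fq.oxidation_level(oxi, naked), rel=1e-9)


class TestRatios:
    def test_relative_oxidation(self):
        assert fq.relative_oxidation(0.3, 0.1, 0.2) == pytest.approx(1.0)
        assert fq.relative_oxidation(0.0, 0.1, 0.2) == 0.0
        with pytest.raises(UndefinedControlError):
            fq.relative_oxidation(0.3, 0.0, 0.0)

    def test_fold_change(self):
        assert fq.fold_change(0.5, 0.4) == pytest.approx(1.25)
        assert fq.fold_change(0.7, 0.7) == pytest.approx(1.0)
        with pytest.raises(UndefinedControlError):
            fq.fold_change(0.5, 0.0)

    @given(a=st.floats(1e-3, 1e3), b=st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_fold_change_reciprocal(self, a, b):
        assert fq.fold_change(a, b) * fq.fold_change(b, a) == pytest.approx(1.0)


class TestExposureCall:
    @pytest.mark.parametrize("fc, expected", [
        (1.25, "more_exposed"),   # clearly above the +20% window
        (1.00, "unchanged"),
        (0.80, "more_buried"),    # clearly below
        (1.20, "unchanged"),      # boundary: strict inequality
        (0.83, "unchanged"),
        (0.87, "unchanged"),      # inside the window despite a buried-looking drop
    ])
    def test_default_thresholds(self, fc, expected):
        assert fq.call_exposure_change(fc) == expected

    def test_thresholds_configurable(self):
        # with a relaxed lower cutoff a mild drop becomes a buried call
        assert fq.call_exposure_change(0.87, upper=1.20, lower=0.90) == "more_buried"

    def test_nonsensical_thresholds(self):
        with pytest.raises(ValueError):
            fq.call_exposure_change(1.0, upper=0.8, lower=1.2)


class TestSingleOxidationFilter:
    def _mixed_table(self):
        rows = []
        for n_ox, res in [(0, None), (1, 5), (2, 5), (1, 7), (3, 9)]:
            rows.append({"peptide_sequence": "ACDEFGHIK", "protein_position": 1,
                         "oxidized_residue": res, "n_oxidations_on_peptide": n_ox,
                         "condition": "O", "temperature_C": 4, "replicate": 1,
                         "intensity": 100.0})
        df = pd.DataFrame(rows)
        df["oxidized_residue"] = df["oxidized_residue"].astype("Int64")
        return df

    def test_filter_matches_brute_force(self):
        table = self._mixed_table()
        out = fq.filter_single_oxidation(table)
        brute = [i for i, row in table.iterrows()
                 if row.n_oxidations_on_peptide == 0
                 or (row.n_oxidations_on_peptide == 1
                     and pd.notna(row.oxidized_residue))]
        assert sorted(out.index) == brute
        # multiply-oxidized forms are gone, unmodified partner retained
        assert (out["n_oxidations_on_peptide"] <= 1).all()
        assert (out["n_oxidations_on_peptide"] == 0).sum() == 1

    def test_identity_on_clean_table(self, noiseless_footprint):
        table = noiseless_footprint.table
        out = fq.filter_single_oxidation(table)
        pd.testing.assert_frame_equal(out, table)


class TestResidueFcTable:
    def test_noiseless_plant_recovered_exactly(self, noiseless_footprint):
        report = fq.residue_fc_table(noiseless_footprint.table)
        truth = noiseless_footprint.truth.set_index("residue")
        assert set(report["residue"]) == set(truth.index)
        for _, row in report.iterrows():
            assert row.fc_mean == pytest.approx(
                truth.loc[row.residue, "fc_true"], abs=1e-12)
        calls = dict(zip(report["residue"], report["call"]))
        assert calls[137] == "more_exposed"
        assert calls[520] == "more_buried"
        assert calls[651] == "unchanged"   # 0.87 sits inside the (0.83, 1.20) window
        assert calls[300] == "unchanged"

    def test_amino_acid_read_off_peptide(self, noiseless_footprint):
        report = fq.residue_fc_table(noiseless_footprint.table)
        seq = noiseless_footprint.protein_sequence
        for _, row in report.iterrows():
            assert row.amino_acid == seq[row.residue - 1]

    def test_single_replicate_has_no_sem(self, noiseless_footprint):
        table = noiseless_footprint.table
        one_rep = table[table["replicate"] == 1]
        report = fq.residue_fc_table(one_rep)
        assert report["n_detections"].eq(1).all()
        assert report["fc_sem"].isna().all()

    def test_row_order_invariance(self, noiseless_footprint, rng):
        table = noiseless_footprint.table
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = fq.residue_fc_table(table)
        b = fq.residue_fc_table(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_intensity_rescaling_invariance(self, noiseless_footprint):
        table = noiseless_footprint.table.copy()
        scaled = table.copy()
        scaled["intensity"] *= 3.7e4
        a = fq.residue_fc_table(table)
        b = fq.residue_fc_table(scaled)
        np.testing.assert_allclose(a["fc_mean"], b["fc_mean"], rtol=1e-12)

    def test_missing_controls_excluded_with_warning(self, noiseless_footprint, caplog):
        table = noiseless_footprint.table
        # strip every control record for residue 300
        drop = (table["condition"].isin(["C", "F"])
                & (table["oxidized_residue"].fillna(-1) == 300))
        # controls are matched through the peptide, so drop by peptide span
        pep = table.loc[table["oxidized_residue"].fillna(-1) == 300,
                        "peptide_sequence"].iloc[0]
        drop = table["condition"].isin(["C", "F"]) & (table["peptide_sequence"] == pep)
        report = fq.residue_fc_table(table[~drop])
        assert 300 not in set(report["residue"])
        assert report.attrs["excluded_residues"] == [300]

    def test_pooled_aggregation_matches_on_noiseless_data(self, noiseless_footprint):
        rep = fq.residue_fc_table(noiseless_footprint.table, aggregate="pooled")
        truth = noiseless_footprint.truth.set_index("residue")
        for _, row in rep.iterrows():
            assert row.fc_mean == pytest.approx(
                truth.loc[row.residue, "fc_true"], abs=1e-12)

    def test_noisy_fc_error_stays_inside_calling_window(self):
        """Mean |FC error| < 0.05 at CV 0.1 with 3 replicates, 100 seeds."""
        truth = {137: 1.25, 651: 0.87, 300: 1.0}
        errs = []
        for seed in range(100):
            cfg = sd.FootprintSimConfig(fc_planted=truth, noise_cv=0.1, seed=seed)
            rep = fq.residue_fc_table(sd.gen_footprint_dataset(cfg).table)
            for _, row in rep.iterrows():
                errs.append(abs(row.fc_mean - truth[row.residue]))
        assert np.mean(errs) < 0.05


class TestTableIO:
    def test_tsv_round_trip(self, noiseless_footprint, tmp_path):
        path = tmp_path / "table.tsv"
        fq.write_peptide_table(noiseless_footprint.table, path)
        back = fq.read_peptide_table(path)
        a = fq.residue_fc_table(noiseless_footprint.table)
        b = fq.residue_fc_table(back)
        pd.testing.assert_frame_equal(a, b)
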