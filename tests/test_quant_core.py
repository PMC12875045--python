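"""Report ingestion, detection filtering, centering and imputation."""

import math

import numpy as np
import pandas as pd
import pytest

from evmacro import quant_core as qc
from evmacro import synthetic_data as sd


def _mini_report(rows):
    return pd.DataFrame(
        rows,
        columns=["Run", "Protein.Group", "Genes", "Precursor.Id",
                 "Protein.Q.Value", "PG.MaxLFQ"],
    )


SHEET = pd.DataFrame(
    {
        "Run": [f"{g}_D{d}" for g in ("M1", "M2") for d in (1, 2, 3)],
        "group": ["M1"] * 3 + ["M2"] * 3,
        "donor": ["D1", "D2", "D3"] * 2,
    }
)


def _np_rows(protein, run, n_prec, q=0.001, inten=1000.0):
    return [
        (run, protein, protein, f"{protein}_p{i}", q, inten)
        for i in range(n_prec)
    ]


class TestReadValidate:
    def test_well_formed_records(self, tmp_path):
        rep = _mini_report(_np_rows("P1", "M1_D1", 3))
        path = tmp_path / "r.tsv"
        rep.to_csv(path, sep="\t", index=False)
        out = qc.read_report(path, SHEET)
        assert len(out) == 3 and out["group"].eq("M1").all()

    def test_unknown_run_named_in_error(self):
        rep = _mini_report(_np_rows("P1", "M9_D1", 1))
        with pytest.raises(ValueError, match="M9_D1"):
            qc.validate_report(rep, SHEET)

    def test_nonpositive_intensity_rejected(self):
        rep = _mini_report([("M1_D1", "P1", "P1", "p1", 0.001, -5.0)])
        with pytest.raises(ValueError, match="positive"):
            qc.validate_report(rep, SHEET)

    def test_q_out_of_range_rejected(self):
        rep = _mini_report([("M1_D1", "P1", "P1", "p1", 1.2, 5.0)])
        with pytest.raises(ValueError, match="Q.Value"):
            qc.validate_report(rep, SHEET)

    def test_round_trip(self, tmp_path, small_sim):
        _, report, _, sheet = small_sim
        path = tmp_path / "rt.tsv"
        qc.write_report(report, path)
        back = qc.read_report(path, sheet)
        got = back[qc.REQUIRED_COLUMNS].reset_index(drop=True)
        exp = report[qc.REQUIRED_COLUMNS].reset_index(drop=True)
        pd.testing.assert_frame_equal(got, exp, check_exact=False, rtol=1e-12)


class TestFilter:
    def _matrix_for(self, np_per_donor, q=0.001):
        rows = []
        for d, n in enumerate(np_per_donor, start=1):
            rows += _np_rows("P1", f"M1_D{d}", n, q=q)
        rows += _np_rows("P2", "M2_D1", 3) + _np_rows("P2", "M2_D2", 3)
        rep = qc.validate_report(_mini_report(rows), SHEET)
        return qc.filter_protein_groups(rep)

    def test_np_331_retained(self):
        assert "P1" in self._matrix_for([3, 3, 1]).proteins

    def test_np_311_dropped(self):
        assert "P1" not in self._matrix_for([3, 1, 1]).proteins

    def test_q_above_threshold_drops_protein(self):
        assert "P1" not in self._matrix_for([5, 5, 5], q=0.02).proteins

    def test_empty_report_errors(self):
        with pytest.raises(ValueError):
            qc.filter_protein_groups(
                qc.validate_report(_mini_report([]), SHEET).iloc[0:0]
            )

    def test_retained_set_matches_brute_force(self, small_sim):
        cfg, report, _, sheet = small_sim
        rep = qc.validate_report(report, sheet)
        spec = qc.FilterSpec()
        mat = qc.filter_protein_groups(rep, spec)

        # brute force, straight from the rule's wording
        ok = rep[rep["Protein.Q.Value"] < spec.q_max]
        expected = set()
        for g in cfg.groups:
            sub = ok[ok["group"] == g]
            donors = sorted(sheet.loc[sheet["group"] == g, "Run"])
            need = math.ceil(spec.min_donor_fraction * len(donors))
            for prot, grp in sub.groupby("Protein.Group"):
                n_supported = sum(
                    grp[grp["Run"] == r]["Precursor.Id"].nunique()
                    >= spec.min_precursors
                    for r in donors
                )
                if n_supported >= need:
                    expected.add(prot)
        assert set(mat.proteins) == expected

    def test_filter_monotone_in_thresholds(self, small_sim):
        cfg, report, _, sheet = small_sim
        rep = qc.validate_report(report, sheet)
        strict = set(qc.filter_protein_groups(rep, qc.FilterSpec()).proteins)
        lax_q = set(
            qc.filter_protein_groups(rep, qc.FilterSpec(q_max=0.5)).proteins
        )
        lax_np = set(
            qc.filter_protein_groups(rep, qc.FilterSpec(min_precursors=1)).proteins
        )
        assert strict <= lax_q and strict <= lax_np


class TestCenterImpute:
    def _matrix(self, values):
        idx = [f"P{i}" for i in range(values.shape[0])]
        cols = SHEET["Run"].tolist()[: values.shape[1]]
        vals = pd.DataFrame(values, index=idx, columns=cols)
        samples = SHEET.set_index("Run").loc[cols]
        return qc.ProteinQuantMatrix(
            values=vals,
            mask=pd.DataFrame(False, index=idx, columns=cols),
            np_table=pd.DataFrame(3, index=idx, columns=cols),
            samples=samples,
        )

    def test_median_center_shifts_back_exactly(self):
        # column 5 already has the largest median, so a further +2 leaves
        # the grand median (median of column medians) unchanged and must be
        # undone exactly
        rng = np.random.default_rng(0)
        base = rng.normal(20, 2, size=(51, 6)) + np.arange(6) * 3.0
        shifted = base.copy()
        shifted[:, 5] += 2.0
        c_base = qc.median_center(self._matrix(base)).values
        c_shift = qc.median_center(self._matrix(shifted)).values
        np.testing.assert_allclose(
            c_shift.iloc[:, 5], c_base.iloc[:, 5], atol=1e-12
        )

    def test_all_column_medians_equal_after_centering(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(18, 3, size=(200, 6))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        out = qc.median_center(self._matrix(vals)).values
        med = out.median(axis=0, skipna=True)
        assert np.ptp(med.to_numpy()) < 1e-12

    def test_median_center_idempotent_and_preserves_differences(self):
        rng = np.random.default_rng(2)
        m = self._matrix(rng.normal(20, 2, size=(80, 6)))
        once = qc.median_center(m)
        twice = qc.median_center(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        diffs_before = m.values.iloc[:, 0] - m.values.iloc[10, 0]
        diffs_after = once.values.iloc[:, 0] - once.values.iloc[10, 0]
        np.testing.assert_allclose(diffs_before, diffs_after, atol=1e-12)

    def test_empty_column_rejected(self):
        vals = np.full((5, 6), np.nan)
        vals[:, :5] = 1.0
        with pytest.raises(ValueError, match="zero observed"):
            qc.median_center(self._matrix(vals))

    def test_impute_no_missing_is_identity(self):
        m = self._matrix(np.ones((10, 6)) * 20)
        out = qc.impute_missing(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert not out.mask.any().any()

    def test_impute_deterministic_and_mask_exact(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 2, size=(100, 6))
        miss = rng.random(vals.shape) < 0.15
        vals[miss] = np.nan
        m = self._matrix(vals)
        out1 = qc.impute_missing(m, seed=5)
        out2 = qc.impute_missing(m, seed=5)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        np.testing.assert_array_equal(out1.mask.to_numpy(), miss)
        # observed cells untouched
        np.testing.assert_array_equal(
            out1.values.to_numpy()[~miss], vals[~miss]
        )

    def test_imputed_mean_matches_downshift_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 2, size=(20_000, 6))
        miss = np.zeros_like(vals, bool)
        miss[: 10_000, 0] = True
        vals_miss = vals.copy()
        vals_miss[miss] = np.nan
        obs = vals_miss[~np.isnan(vals_miss[:, 0]), 0]
        mu, sdev = obs.mean(), obs.std(ddof=1)
        out = qc.impute_missing(self._matrix(vals_miss), seed=6)
        imputed = out.values.to_numpy()[miss]
        target = mu - 1.8 * sdev
        assert abs(imputed.mean() - target) < 3 * (0.3 * sdev) / np.sqrt(10_000)


class TestDetectionSets:
    def test_core_and_merged_set_algebra(self, small_sim):
        cfg, report, _, sheet = small_sim
        rep = qc.validate_report(report, sheet)
        mat = qc.filter_protein_groups(rep)
        sets = qc.detection_sets(mat)
        groups = list(cfg.groups)
        brute_core = set(mat.detected.index)
        brute_merged = set()
        for g in groups:
            got = {p for p in mat.detected.index if mat.detected.loc[p, g]}
            assert sets[g] == got
            brute_core &= got
            brute_merged |= got
        assert sets["core"] == brute_core
        assert sets["merged"] == brute_merged
        for g in groups:
            assert sets["core"] <= sets[g] <= sets["merged"]

    def test_identical_groups_core_equals_merged(self):
        rows = []
        for g in ("M1", "M2"):
            for d in (1, 2, 3):
                rows += _np_rows("P1", f"{g}_D{d}", 3)
        mat = qc.filter_protein_groups(
            qc.validate_report(_mini_report(rows), SHEET)
        )
        sets = qc.detection_sets(mat)
        assert sets["core"] == sets["merged"] == {"P1"}

    def test_disjoint_groups_empty_core(self):
        rows = []
        for d in (1, 2, 3):
            rows += _np_rows("P1", f"M1_D{d}", 3)
            rows += _np_rows("P2", f"M2_D{d}", 3)
        sets = qc.detection_sets(
            qc.filter_protein_groups(qc.validate_report(_mini_report(rows), SHEET))
        )
        assert sets["core"] == set()
        assert sets["merged"] == {"P1", "P2"}
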