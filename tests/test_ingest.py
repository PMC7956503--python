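"""Reading, alignment, normalization, frequency filter and replicate handling."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_run_table
from uvep import (
    FormatError,
    ValidationError,
    align_runs,
    average_replicates,
    filter_by_frequency,
    normalize_total_spc,
    read_run_table,
    replicate_qc,
)
from uvep.matrix import read_matrix_tsv


def write_long_tsv(path, rows):
    header = "run_id\tsubject_id\treplicate\taccession\tgene_symbol\tspc\n"
    path.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))


class TestReadRunTable:
    def test_long_tsv_identity(self, tmp_path):
        p = tmp_path / "runs.tsv"
        write_long_tsv(p, [("r1", "s1", 1, "P1", "G1", 5),
                           ("r1", "s1", 1, "P2", "G2", 3),
                           ("r1", "s1", 1, "P3", "G3", 1)])
        table = read_run_table(p, "long_tsv")
        assert len(table) == 3
        assert table.run_ids == ["r1"]
        assert table.gene_symbols()["P2"] == "G2"

    def test_wide_csv_keeps_explicit_zeros(self, tmp_path):
        wide = tmp_path / "wide.csv"
        wide.write_text("accession,r1,r2\nP1,5,0\nP2,,3\n")
        sidecar = tmp_path / "meta.tsv"
        sidecar.write_text("run_id\tsubject_id\treplicate\nr1\ts1\t1\nr2\ts1\t2\n")
        table = read_run_table(wide, "wide_csv", sidecar=sidecar)
        assert len(table) == 4  # zeros (incl. the empty cell) kept as records
        spc = dict(zip(zip(table.records["run_id"], table.records["accession"]),
                       table.records["spc"]))
        assert spc[("r2", "P1")] == 0.0 and spc[("r1", "P2")] == 0.0
        assert any("empty cell" in line for line in table.provenance)

    def test_negative_spc_reports_row(self, tmp_path):
        p = tmp_path / "runs.tsv"
        write_long_tsv(p, [("r1", "s1", 1, "P1", "G1", 5),
                           ("r1", "s1", 1, "P2", "G2", -1)])
        with pytest.raises(ValidationError, match="line 3"):
            read_run_table(p, "long_tsv")

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "runs.tsv"
        p.write_text("run_id\tsubject_id\taccession\tspc\nr1\ts1\tP1\t5\n")
        with pytest.raises(FormatError, match="replicate"):
            read_run_table(p, "long_tsv")

    def test_duplicate_run_accession_rejected(self, tmp_path):
        p = tmp_path / "runs.tsv"
        write_long_tsv(p, [("r1", "s1", 1, "P1", "G1", 5),
                           ("r1", "s1", 1, "P1", "G1", 6)])
        with pytest.raises(ValidationError, match="duplicate"):
            read_run_table(p, "long_tsv")


class TestAlignRuns:
    def test_disjoint_union(self):
        table = make_run_table({"r1": {"P1": 5}, "r2": {"P2": 3}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        m = align_runs(table)
        assert m.values.to_numpy().tolist() == [[5.0, 0.0], [0.0, 3.0]]
        assert m.protein_index == ["P1", "P2"]

    def test_identical_runs_identical_columns(self):
        table = make_run_table({"r1": {"P1": 5, "P2": 2}, "r2": {"P1": 5, "P2": 2}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        m = align_runs(table)
        assert (m.values["r1"] == m.values["r2"]).all()

    def test_union_row_count_matches_set_oracle(self):
        rng = np.random.default_rng(3)
        pool = [f"P{i}" for i in range(30)]
        runs = {f"r{j}": {a: 1.0 for a in rng.choice(pool, 12, replace=False)}
                for j in range(3)}
        meta = {"r0": ("s1", 1), "r1": ("s1", 2), "r2": ("s2", 1)}
        m = align_runs(make_run_table(runs, meta))
        oracle = set()
        for prot in runs.values():
            oracle |= set(prot)
        assert m.n_proteins == len(oracle)

    def test_column_order_equivariance(self, two_subject_runs):
        m = align_runs(two_subject_runs)
        rev = two_subject_runs.records.iloc[::-1].reset_index(drop=True)
        m2 = align_runs(type(two_subject_runs)(records=rev))
        assert m2.column_index == m.column_index[::-1]
        pd.testing.assert_frame_equal(m2.values[m.column_index], m.values)


class TestNormalize:
    def test_totals_scale_to_grand_mean(self):
        table = make_run_table({"r1": {"P1": 60, "P2": 40}, "r2": {"P1": 150, "P2": 50}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        m = normalize_total_spc(align_runs(table))
        totals = m.values.sum(axis=0)
        assert totals.tolist() == pytest.approx([150.0, 150.0])
        # scale factors 1.5 and 0.75
        assert m.values.loc["P1", "r1"] == pytest.approx(90.0)
        assert m.values.loc["P1", "r2"] == pytest.approx(112.5)

    def test_equal_totals_is_identity_and_idempotent(self, two_subject_runs):
        m = align_runs(two_subject_runs)
        once = normalize_total_spc(m)
        twice = normalize_total_spc(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)
        # within-column protein ranking untouched
        for col in m.column_index:
            assert (m.values[col].rank() == once.values[col].rank()).all()

    def test_single_column_unchanged(self):
        table = make_run_table({"r1": {"P1": 5}, "r2": {"P1": 5}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        m = align_runs(table)
        np.testing.assert_allclose(normalize_total_spc(m).values, m.values)

    def test_zero_total_column_names_run(self):
        table = make_run_table({"r1": {"P1": 5}, "r2": {"P1": 0}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        with pytest.raises(ValidationError, match="r2"):
            normalize_total_spc(align_runs(table))


class TestFrequencyFilter:
    @staticmethod
    def _matrix_42_runs(n_detected: int):
        runs = {}
        meta = {}
        for j in range(42):
            rid = f"r{j:02d}"
            prot = {"Pkeep": 1.0} if j < n_detected else {}
            prot["Panchor"] = 1.0  # detected everywhere, keeps runs non-empty
            runs[rid] = prot
            meta[rid] = (f"s{j // 2:02d}", j % 2 + 1)
        return align_runs(make_run_table(runs, meta))

    def test_11_of_42_is_retained_10_dropped(self):
        kept = filter_by_frequency(self._matrix_42_runs(11), 0.25)
        assert "Pkeep" in kept.protein_index  # 11/42 = 26.2% > 25%
        dropped = filter_by_frequency(self._matrix_42_runs(10), 0.25)
        assert "Pkeep" not in dropped.protein_index  # 10/42 = 23.8%

    def test_min_frac_zero_keeps_any_detection(self):
        m = self._matrix_42_runs(1)
        assert filter_by_frequency(m, 0.0).n_proteins == m.n_proteins

    def test_detection_judged_on_raw_counts(self, two_subject_runs):
        m = align_runs(two_subject_runs)
        before = filter_by_frequency(m, 0.25).protein_index
        after = filter_by_frequency(normalize_total_spc(m), 0.25).protein_index
        assert before == after

    def test_empty_result_warns(self):
        m = self._matrix_42_runs(1)
        with pytest.warns(UserWarning, match="every protein"):
            out = filter_by_frequency(m.with_values(m.values.loc[["Pkeep"]], "sub"), 0.5)
        assert out.n_proteins == 0


class TestReplicateQc:
    def test_identical_replicates_pass(self):
        table = make_run_table({"r1": {"P1": 4, "P2": 9}, "r2": {"P1": 4, "P2": 9}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        (qc,) = replicate_qc(align_runs(table), table.pairing())
        assert qc.correlation == pytest.approx(1.0)
        assert qc.slope == pytest.approx(1.0)
        assert qc.passed

    def test_doubled_replicate_fails_slope_window(self):
        table = make_run_table({"r1": {"P1": 4, "P2": 9}, "r2": {"P1": 8, "P2": 18}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        (qc,) = replicate_qc(align_runs(table), table.pairing())
        assert qc.correlation == pytest.approx(1.0)
        assert qc.slope == pytest.approx(2.0)
        assert not qc.passed

    def test_degenerate_vector_is_nan_fail(self):
        table = make_run_table({"r1": {"P1": 3, "P2": 3}, "r2": {"P1": 5, "P2": 5}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        (qc,) = replicate_qc(align_runs(table), table.pairing())
        assert np.isnan(qc.correlation) and not qc.passed

    def test_subject_without_two_runs_is_error(self, two_subject_runs):
        bad = two_subject_runs.records[two_subject_runs.records["run_id"] != "r2b"]
        with pytest.raises(ValidationError, match="exactly 2"):
            type(two_subject_runs)(records=bad.reset_index(drop=True)).pairing()


class TestAverageReplicates:
    def test_simple_means(self):
        table = make_run_table({"r1": {"P1": 4, "P2": 0}, "r2": {"P1": 6, "P2": 0}},
                               {"r1": ("s1", 1), "r2": ("s1", 2)})
        m = average_replicates(align_runs(table), table.pairing())
        assert m.level == "subject"
        assert m.values.loc["P1", "s1"] == 5.0
        assert m.values.loc["P2", "s1"] == 0.0

    def test_matches_elementwise_mean_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.poisson(6, 5).astype(float), rng.poisson(6, 5).astype(float)
        a[0] = b[0] = max(a[0], 1)  # keep the run non-empty
        table = make_run_table(
            {"r1": {f"P{i}": a[i] for i in range(5) if a[i] > 0},
             "r2": {f"P{i}": b[i] for i in range(5) if b[i] > 0}},
            {"r1": ("s1", 1), "r2": ("s1", 2)},
        )
        m = align_runs(table)
        out = average_replicates(m, table.pairing())
        expected = (m.values["r1"] + m.values["r2"]) / 2
        np.testing.assert_allclose(out.values["s1"], expected)

    def test_total_mass_halved(self, two_subject_runs):
        m = align_runs(two_subject_runs)
        out = average_replicates(m, two_subject_runs.pairing())
        assert out.values.to_numpy().sum() == pytest.approx(m.values.to_numpy().sum() / 2)


def test_matrix_tsv_round_trip(tmp_path, two_subject_runs):
    m = normalize_total_spc(align_runs(two_subject_runs))
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = read_matrix_tsv(path)
    assert back.level == "run" and back.normalized
    np.testing.assert_allclose(back.values, m.values)
    assert back.provenance == m.provenance
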