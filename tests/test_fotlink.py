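"""Kruskal–Wallis, Dunn/Holm post-hoc, Yates chi-squared and cohort tables."""

import numpy as np
import pytest
from scipy import stats

from uvep import (
    FOT_VARIABLES,
    FotRecord,
    ValidationError,
    chi2_yates,
    cohort_table,
    compare_groups_fot,
    dunn_posthoc,
    kruskal_wallis,
    read_fot_table,
)
from uvep.fotlink import fot_frame
from uvep.stratify import GroupAssignment


def make_records(z_by_subject, covariates=None, birth=None):
    records = []
    for sid, z in z_by_subject.items():
        records.append(
            FotRecord(
                subject_id=sid,
                z_scores=dict(zip(FOT_VARIABLES, map(float, z))),
                covariates=(covariates or {}).get(sid, {}),
                birth_group=(birth or {}).get(sid),
            )
        )
    return records


class TestKruskalWallis:
    def test_hand_rank_example(self):
        values = [("A", v) for v in (1, 2, 3)] + [("B", v) for v in (4, 5, 6)] + [
            ("C", v) for v in (7, 8, 9)
        ]
        h, p = kruskal_wallis(values)
        # rank sums 6, 15, 24 over N=9: H = 12/(9*10) * (12+75+192) - 30 = 7.2
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(stats.chi2.sf(7.2, df=2))

    def test_all_equal_values(self):
        h, p = kruskal_wallis([("A", 5.0), ("A", 5.0), ("B", 5.0), ("B", 5.0)])
        assert h == 0.0 and p == 1.0

    def test_single_group_is_error(self):
        with pytest.raises(ValidationError, match="2 groups"):
            kruskal_wallis([("A", 1.0), ("A", 2.0)])

    def test_two_groups_consistent_with_rank_sum(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        values = [("A", v) for v in a] + [("B", v) for v in b]
        _, p_kw = kruskal_wallis(values)
        p_mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                  use_continuity=False).pvalue
        assert p_kw == pytest.approx(p_mw, rel=1e-6)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        vals = [(g, float(v)) for g in "ABC" for v in rng.uniform(0.1, 5, 6)]
        h1, _ = kruskal_wallis(vals)
        h2, _ = kruskal_wallis([(g, np.log(v)) for g, v in vals])
        assert h1 == pytest.approx(h2)


class TestDunnPosthoc:
    def test_identical_groups_all_one(self):
        values = [(g, float(v)) for g in "ABC" for v in (1, 2, 3)]
        assert all(p == pytest.approx(1.0) for p in dunn_posthoc(values).values())

    def test_extreme_group_has_smallest_pair_ps(self):
        values = ([("A", v) for v in (1, 2, 3, 4)] + [("B", v) for v in (5, 6, 7, 8)]
                  + [("C", v) for v in (50, 60, 70, 80)])
        ps = dunn_posthoc(values)
        assert max(ps[("A", "C")], ps[("B", "C")]) <= ps[("A", "B")]

    def test_holm_dominates_raw_p_and_preserves_order(self):
        rng = np.random.default_rng(11)
        values = [(g, float(v)) for g, mu in zip("ABC", (0, 1, 3))
                  for v in rng.normal(mu, 1, 6)]
        adjusted = dunn_posthoc(values)
        # recompute raw Dunn p-values by rank arithmetic
        groups = {}
        for g, v in values:
            groups.setdefault(g, []).append(v)
        pooled = np.concatenate([groups[g] for g in sorted(groups)])
        ranks = stats.rankdata(pooled)
        mean_rank, start = {}, 0
        for g in sorted(groups):
            mean_rank[g] = ranks[start:start + len(groups[g])].mean()
            start += len(groups[g])
        n = len(pooled)
        raw = {}
        for (a, b) in adjusted:
            se = np.sqrt(n * (n + 1) / 12 * (1 / len(groups[a]) + 1 / len(groups[b])))
            z = (mean_rank[a] - mean_rank[b]) / se
            raw[(a, b)] = 2 * stats.norm.sf(abs(z))
        for pair in adjusted:
            assert adjusted[pair] >= raw[pair] - 1e-12
        raw_order = sorted(raw, key=raw.get)
        adj_sorted = [adjusted[p] for p in raw_order]
        assert adj_sorted == sorted(adj_sorted)


def test_holm_adjust_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    from uvep import holm_adjust

    rng = np.random.default_rng(7)
    for m in (1, 2, 3, 6, 10):
        p = rng.uniform(0, 1, m)
        np.testing.assert_allclose(holm_adjust(p), multipletests(p, method="holm")[1])


class TestChi2Yates:
    def test_perfectly_balanced_table(self):
        chi2, p = chi2_yates([[1, 1], [1, 1]])
        assert chi2 == 0.0 and p == 1.0

    def test_small_deviation_truncates_to_zero(self):
        chi2, p = chi2_yates([[10, 2], [7, 2]])
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_continuity_correction(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            t = rng.integers(1, 20, (2, 2))
            chi2, p = chi2_yates(t)
            ref = stats.chi2_contingency(t, correction=True)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_invariant_under_transpose_and_double_swap(self):
        t = np.array([[5, 7], [2, 9]])
        base = chi2_yates(t)
        assert chi2_yates(t.T) == pytest.approx(base)
        assert chi2_yates(t[::-1, ::-1]) == pytest.approx(base)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValidationError, match="margin"):
            chi2_yates([[0, 0], [3, 4]])

    def test_wrong_shape_is_error(self):
        with pytest.raises(ValidationError, match="2x2"):
            chi2_yates([[1, 2, 3], [4, 5, 6]])


class TestCompareGroupsFot:
    def test_planted_shift_has_smallest_p_in_majority_of_seeds(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = {}
            groups = {}
            for g, shift in zip("ABC", (1.5, 0.0, 0.0)):
                for i in range(7):
                    sid = f"{g.lower()}{i}"
                    base = rng.normal(0, 1, 7)
                    base[0] += shift if g == "A" else 0.0  # shift z_rrs6 only
                    z[sid] = base
                    groups[sid] = g
            report = compare_groups_fot(make_records(z), groups)
            table = report["table"].set_index("variable")
            if table["p"].idxmin() == "z_rrs6":
                wins += 1
        assert wins >= 6

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(101)
        n_sig, n_tests = 0, 0
        for _ in range(60):
            z = {f"s{i}": rng.normal(0, 1, 7) for i in range(21)}
            groups = {f"s{i}": "ABC"[i % 3] for i in range(21)}
            report = compare_groups_fot(make_records(z), groups)
            n_sig += int(report["table"]["significant"].sum())
            n_tests += len(report["table"])
        assert 0.01 <= n_sig / n_tests <= 0.12  # coarse check; tight bound in acceptance

    def test_single_group_is_error(self):
        z = {f"s{i}": np.zeros(7) for i in range(4)}
        with pytest.raises(ValidationError, match="2 groups"):
            compare_groups_fot(make_records(z), {f"s{i}": "A" for i in range(4)})

    def test_missing_subject_listed(self):
        z = {"s1": np.zeros(7)}
        with pytest.raises(ValidationError, match="s2"):
            compare_groups_fot(make_records(z), {"s1": "A", "s2": "B"})

    def test_accepts_group_assignment_object(self):
        rng = np.random.default_rng(1)
        z = {f"s{i}": rng.normal(0, 1, 7) for i in range(6)}
        ga = GroupAssignment(labels={f"s{i}": "AB"[i % 2] for i in range(6)}, k=2)
        report = compare_groups_fot(make_records(z), ga)
        assert set(report["table"]["variable"]) == set(FOT_VARIABLES)


class TestCohortTable:
    @staticmethod
    def _cohort():
        """21 subjects, 12 late-preterm vs 9 term, sex and smoke as printed."""
        rng = np.random.default_rng(2)
        z, cov, birth = {}, {}, {}
        for i in range(21):
            sid = f"s{i:02d}"
            z[sid] = rng.normal(0, 1, 7)
            lp = i < 12
            birth[sid] = "LP" if lp else "T"
            cov[sid] = {
                "female": 1 if (i < 5 if lp else i < 14) else 0,   # 5/12 vs 2/9
                "smoke": 1 if lp and i < 4 else 0,                  # 4/12 vs 0/9
                "constant": 1,
                "age": 3.5 + rng.uniform(0, 2),
            }
        return make_records(z, cov, birth)

    def test_sex_row_matches_yates_p(self):
        table = cohort_table(self._cohort(), split="birth_group").set_index("variable")
        assert table.loc["female", "p"] == pytest.approx(0.640, abs=5e-4)
        assert table.loc["female", "LP"] == "5 (41.67)"
        assert table.loc["female", "T"] == "2 (22.22)"

    def test_smoke_row_matches_yates_p(self):
        table = cohort_table(self._cohort(), split="birth_group").set_index("variable")
        assert table.loc["smoke", "p"] == pytest.approx(0.173, abs=5e-4)

    def test_constant_covariate_p_one(self):
        table = cohort_table(self._cohort(), split="birth_group").set_index("variable")
        assert table.loc["constant", "p"] == 1.0

    def test_quantitative_rows_use_kruskal(self):
        table = cohort_table(self._cohort(), split="birth_group").set_index("variable")
        assert table.loc["age", "kind"] == "quantitative"
        assert 0 <= table.loc["age", "p"] <= 1

    def test_non_binary_split_is_error(self):
        records = self._cohort()
        for r in records:
            r.covariates["tri"] = r.subject_id[-1]
        with pytest.raises(ValidationError, match="binary"):
            cohort_table(records, split="tri")

    def test_missing_values_use_row_denominators(self):
        records = self._cohort()
        # drop one term subject's bronchiolitis answer -> denominator 8
        for r in records:
            r.covariates["bronchiolitis"] = 1 if int(r.subject_id[1:]) % 3 == 0 else 0
        del records[-1].covariates["bronchiolitis"]
        table = cohort_table(records, split="birth_group").set_index("variable")
        assert table.loc["bronchiolitis", "n_T"] == 8
        assert table.loc["bronchiolitis", "n_LP"] == 12


def test_fot_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    z = {f"s{i}": rng.normal(0, 1, 7) for i in range(4)}
    records = make_records(z, birth={f"s{i}": "LP" if i < 2 else "T" for i in range(4)})
    path = tmp_path / "fot.tsv"
    fot_frame(records).to_csv(path, sep="\t", index=False)
    back = read_fot_table(path)
    assert [r.subject_id for r in back] == [r.subject_id for r in records]
    for a, b in zip(back, records):
        assert a.z_scores == pytest.approx(b.z_scores)
        assert a.birth_group == b.birth_group


def test_non_finite_z_score_rejected():
    z = dict(zip(FOT_VARIABLES, [0.0] * 6 + [float("nan")]))
    with pytest.raises(ValidationError, match="non-finite"):
        FotRecord(subject_id="s1", z_scores=z)
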