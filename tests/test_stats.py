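"""Statistics: Wilcoxon (vs brute force and scipy), Friedman, agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pupilpress import (
    DeviationModel,
    agreement_report,
    build_cohort,
    friedman_repeated_measures,
    laterality_check,
    simulate_measurements,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(d: np.ndarray) -> tuple[float, float]:
    """Exhaustive signed-rank two-sided p by enumerating all sign vectors."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = np.array(
        [np.sum(ranks[list(signs)]) for signs in _subsets(n)], dtype=float
    )
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(lower, upper))


def _subsets(n):
    for mask in range(2**n):
        yield [i for i in range(n) if mask >> i & 1]


class TestWilcoxon:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.statistic == 15.0
        assert res.pvalue == pytest.approx(0.0625, abs=1e-12)

    def test_identical_samples_flagged(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.all_zero and res.pvalue == 1.0 and res.statistic == 0.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            d = np.round(rng.normal(0, 2, size=n), 1)
            if np.all(d == 0):
                continue
            w_bf, p_bf = brute_force_wilcoxon_p(d)
            res = wilcoxon_signed_rank(d, mode="exact")
            assert res.statistic == pytest.approx(w_bf)
            assert res.pvalue == pytest.approx(p_bf, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            mine = wilcoxon_signed_rank(x, y, mode="exact").pvalue
            ref = sps.wilcoxon(x, y, method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_approx_matches_scipy_corrected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = rng.normal(0.3, 1, size=40)
        mine = wilcoxon_signed_rank(x, y, mode="approx").pvalue
        ref = sps.wilcoxon(x, y, method="approx", correction=True).pvalue
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_pratt_zero_handling(self):
        d = np.array([0.0, 1.0, -2.0, 3.0, 0.0, 4.0])
        res = wilcoxon_signed_rank(d, zero_method="pratt")
        # zeros occupy ranks 1-2; nonzero ranks are 3,4,5,6
        assert res.statistic == 3.0 + 5.0 + 6.0

    def test_auto_switches_to_approx_for_large_n(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=31)
        assert wilcoxon_signed_rank(d).mode == "approx"
        assert wilcoxon_signed_rank(d[:20]).mode == "exact"

    def test_type_one_error_calibrated_at_n31(self):
        # null deviations from the study's mixture model, alpha = 0.05
        model = DeviationModel()
        rng = np.random.default_rng(123)
        n_reject = 0
        n_sim = 2000
        from pupilpress import sample_deviations

        for _ in range(n_sim):
            d = sample_deviations(model, 31, rng)
            if wilcoxon_signed_rank(d).pvalue <= 0.05:
                n_reject += 1
        assert n_reject / n_sim == pytest.approx(0.05, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([])


class TestFriedman:
    def test_no_variation_gives_p_one(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]})
        res = friedman_repeated_measures(data)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_scipy_on_crafted_table(self):
        data = np.array(
            [[1.0, 2.5, 3.1], [2.0, 1.1, 3.0], [1.5, 2.9, 2.2], [1.0, 3.0, 2.0]]
        )
        res = friedman_repeated_measures(pd.DataFrame(data))
        ref = sps.friedmanchisquare(*data.T)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_matches_scipy_with_ties(self):
        data = np.array([[1.0, 1.0, 2.0], [3.0, 2.0, 2.0], [1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        res = friedman_repeated_measures(pd.DataFrame(data))
        ref = sps.friedmanchisquare(*data.T)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_incomplete_rows_excluded_and_counted(self):
        data = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan], "b": [2.0, 1.0, 2.0], "c": [3.0, 3.0, 1.0]}
        )
        res = friedman_repeated_measures(data)
        assert res.n_complete == 2 and res.n_excluded == 1

    def test_too_few_complete_cases_rejected(self):
        data = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 1.0], "c": [3.0, 2.0]})
        with pytest.raises(ValueError):
            friedman_repeated_measures(data)


def _hand_table(devs_by_session=None):
    """4-pair compared table with prescribed deviations, one subject/eye each."""
    devs = devs_by_session or {"supine": [0.0, 1.0], "raised_legs": [-2.0], "sitting2": [4.0]}
    rows = []
    i = 0
    for session, dlist in devs.items():
        for d in dlist:
            sid = f"S{i:02d}"
            ref_inst = "iCare" if session in ("supine", "raised_legs") else "GAT"
            rows.append((sid, "OD", session, "prototype", 18.0 + d, False))
            rows.append((sid, "OD", session, ref_inst, 18.0, False))
            i += 1
    return pd.DataFrame(
        rows,
        columns=["subject_id", "eye", "session", "instrument", "iop_mmHg", "is_calibration"],
    )


class TestAgreementReport:
    def test_hand_built_deviations(self):
        report = agreement_report(_hand_table())
        assert report.n_compared == 4
        assert report.frac_within_1 == 0.5
        assert report.frac_within_3 == 0.75
        for b, frac in {0: 0.25, 1: 0.25, 2: 0.25, 4: 0.25, 3: 0.0}.items():
            assert report.deviation_hist[b] == frac

    def test_perfect_agreement(self):
        table = _hand_table({"supine": [0.0, 0.0], "sitting2": [0.0, 0.0]})
        report = agreement_report(table)
        assert report.frac_within_1 == 1.0
        assert report.overall.wilcoxon_p == 1.0

    def test_row_order_invariance(self):
        table = _hand_table()
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        r1, r2 = agreement_report(table), agreement_report(shuffled)
        assert r1.frac_within_1 == r2.frac_within_1
        assert r1.deviation_hist == r2.deviation_hist
        assert r1.overall.prototype_mean == pytest.approx(r2.overall.prototype_mean)

    def test_fractions_monotone_and_hist_mass_bounded(self):
        table = simulate_measurements(build_cohort(), seed=2)
        report = agreement_report(table)
        assert report.frac_within_1 <= report.frac_within_3
        assert sum(report.deviation_hist.values()) <= 1.0 + 1e-12

    def test_calibration_rows_excluded(self):
        table = simulate_measurements(build_cohort(), seed=2)
        report = agreement_report(table)
        assert report.n_compared == 85

    def test_empty_comparison_rejected(self):
        table = _hand_table()
        table["is_calibration"] = True
        with pytest.raises(ValueError):
            agreement_report(table)


class TestLaterality:
    def test_identical_eyes_give_p_one(self):
        rows = []
        for sid in ("S1", "S2", "S3"):
            for eye in ("OD", "OS"):
                for session, inst in (("supine", "iCare"), ("sitting2", "GAT")):
                    v = 18.0 + hash(sid) % 3  # same value for both eyes
                    rows.append((sid, eye, session, "prototype", v, False))
                    rows.append((sid, eye, session, inst, v, False))
        table = pd.DataFrame(
            rows,
            columns=["subject_id", "eye", "session", "instrument", "iop_mmHg", "is_calibration"],
        )
        result = laterality_check(table)
        assert (result["pvalue"] == 1.0).all()

    def test_no_builtin_laterality_in_simulator(self):
        # under the null, most cells should be non-significant in most seeds
        good = 0
        n_seeds = 20
        for seed in range(n_seeds):
            table = simulate_measurements(build_cohort(), seed=seed)
            res = laterality_check(table)
            if (res["pvalue"] > 0.05).sum() >= 5:
                good += 1
        assert good >= 0.9 * n_seeds

    def test_single_eyed_cohort_rejected(self):
        table = _hand_table()  # all OD only
        with pytest.raises(ValueError):
            laterality_check(table)
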