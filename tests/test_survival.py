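"""Cox fit correctness (closed form + independent library), sweeps, selection."""

from __future__ import annotations

import numpy as np
import pytest

from ftvsweep.ftv import PredictorRecord, default_grid
from ftvsweep.survival import (
    CoxFitError,
    CoxResult,
    SelectionError,
    SubsetError,
    SurvivalRecord,
    SweepResult,
    fit_cox,
    select_optimized,
    sweep,
)


def _records(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return [
        SurvivalRecord(patient_id=i, rfs_months=float(t), event=bool(e))
        for i, t, e in zip(ids, times, events)
    ]


CLOSED_FORM_BETA = np.log(np.sqrt(2.0))  # argmax of L(b) = [1/(2+e^b)] [e^b/(1+e^b)]


class TestFitCox:
    def test_closed_form_three_subject_example(self):
        """Two events and one censored subject give a partial likelihood
        whose maximizer is available in closed form: beta = ln sqrt(2)."""
        recs = _records([1.0, 2.0, 3.0], [1, 1, 0])
        res = fit_cox([0.0, 1.0, 0.0], recs)
        assert res.converged
        assert res.beta == pytest.approx(CLOSED_FORM_BETA, abs=1e-10)
        assert res.hazard_ratio == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_sign_equivariance(self, rng):
        x = rng.normal(size=20)
        recs = _records(rng.exponential(10, size=20), rng.random(20) < 0.6)
        a = fit_cox(x, recs)
        b = fit_cox(-x, recs)
        assert a.beta == pytest.approx(-b.beta, abs=1e-8)
        assert a.lr_pvalue == pytest.approx(b.lr_pvalue, rel=1e-8)

    def test_scale_divides_covariate(self, rng):
        x = rng.normal(size=25) * 50
        recs = _records(rng.exponential(10, size=25), rng.random(25) < 0.5)
        per_unit = fit_cox(x, recs, scale=1.0)
        per_ten = fit_cox(x, recs, scale=10.0)
        assert per_ten.beta == pytest.approx(10.0 * per_unit.beta, rel=1e-6)

    def test_missing_covariates_dropped(self, rng):
        x = np.array([1.0, np.nan, 2.0, 0.5, np.nan, 3.0])
        recs = _records([5, 8, 3, 9, 2, 7], [1, 1, 0, 1, 1, 0])
        res = fit_cox(x, recs)
        assert res.n_used == 4
        keep = np.isfinite(x)
        direct = fit_cox(x[keep], [r for r, k in zip(recs, keep) if k])
        assert res.beta == pytest.approx(direct.beta, abs=1e-12)

    def test_all_censored_is_fit_error(self):
        with pytest.raises(CoxFitError, match="no events"):
            fit_cox([0.0, 1.0, 2.0], _records([1, 2, 3], [0, 0, 0]))

    def test_constant_covariate_is_fit_error(self):
        with pytest.raises(CoxFitError, match="non-identifiable"):
            fit_cox([1.0, 1.0, 1.0], _records([1, 2, 3], [1, 1, 0]))

    def test_too_few_subjects_is_fit_error(self):
        with pytest.raises(CoxFitError, match=">= 2"):
            fit_cox([1.0], _records([1.0], [1]))

    def test_separation_flagged_degenerate_not_raised(self):
        """Perfectly separated data has monotone likelihood; the fit must
        flag the cell rather than raise or return an absurd CI silently."""
        x = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]
        recs = _records([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 1])
        res = fit_cox(x, recs)
        assert res.degenerate or abs(res.beta) > 5

    def test_lr_statistic_nonnegative_and_p_in_unit_interval(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 25))
            x = rng.normal(size=n)
            recs = _records(rng.exponential(10, size=n), rng.random(n) < 0.7)
            try:
                res = fit_cox(x, recs)
            except CoxFitError:
                continue
            assert 0.0 < res.lr_pvalue <= 1.0
            assert res.wald_ci_lo <= res.hazard_ratio <= res.wald_ci_hi


class TestAgainstLifelines:
    """Cross-check on random small datasets with tied event times."""

    @staticmethod
    def _lifelines_fit(x, times, events):
        import warnings

        import pandas as pd
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"x": x, "t": times, "e": events})
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny-n convergence chatter
            cph.fit(df, duration_col="t", event_col="e", show_progress=False,
                    fit_options={"precision": 1e-12, "max_steps": 500})
        return (
            float(cph.params_["x"]),
            float(cph.standard_errors_["x"]),
            float(cph.log_likelihood_ratio_test().p_value),
        )

    def test_beta_se_p_agree_to_1e5(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        while n_checked < 50:
            n = int(rng.integers(8, 31))
            x = np.round(rng.normal(size=n), 2)
            times = rng.integers(1, 8, size=n).astype(float)  # many ties
            events = rng.random(n) < 0.7
            if events.sum() == 0 or np.ptp(x) == 0:
                continue
            res = fit_cox(x, _records(times, events))
            if not res.converged or res.degenerate:
                continue
            beta, se, p = self._lifelines_fit(x, times, events)
            assert res.beta == pytest.approx(beta, abs=1e-5)
            assert res.se == pytest.approx(se, abs=1e-5)
            assert res.lr_pvalue == pytest.approx(p, abs=1e-5)
            n_checked += 1


def _predictor_records(grid, values_by_patient, subtypes=None):
    records = []
    for k, (pid, vals) in enumerate(values_by_patient.items()):
        arr = np.full(grid.shape, float(vals)) if np.isscalar(vals) else np.asarray(vals, float)
        subtype = subtypes[k] if subtypes else "unknown"
        records.append(
            PredictorRecord(
                patient_id=pid, subtype=subtype, grid=grid,
                delta_ftv2=arr.copy(), delta_ftvf=arr.copy(), ftv_f=arr.copy(),
            )
        )
    return records


class TestSweep:
    def _cohort(self, rng, n=30):
        grid = default_grid()
        base = rng.normal(size=(n, *grid.shape))
        values = {f"p{i}": base[i] for i in range(n)}
        subtypes = ["HRpos_HER2neg", "HER2pos", "TN", "unknown"] * (n // 4) + ["TN"] * (n % 4)
        preds = _predictor_records(grid, values, subtypes)
        surv = [
            SurvivalRecord(f"p{i}", float(rng.exponential(20) + 0.1),
                           bool(rng.random() < 0.6), subtypes[i])
            for i in range(n)
        ]
        return grid, preds, surv

    def test_attempts_all_198_cells(self, rng):
        grid, preds, surv = self._cohort(rng)
        result = sweep(preds, surv, grid, "ftv_f")
        assert result.hr_matrix.shape == (18, 11)
        total = sum(len(row) for row in result.results)
        assert total == 198
        assert result.n_fit == 198  # random predictors: every cell fittable

    def test_empty_subset_raises(self, rng):
        grid, preds, surv = self._cohort(rng)
        preds = [p for p in preds if p.subtype != "TN"]
        with pytest.raises(SubsetError, match="TN"):
            sweep(preds, surv, grid, "ftv_f", subset="TN")

    def test_subtype_filter_restricts_n(self, rng):
        grid, preds, surv = self._cohort(rng, n=32)
        full = sweep(preds, surv, grid, "ftv_f", subset="full")
        her2 = sweep(preds, surv, grid, "ftv_f", subset="HER2pos")
        assert full.results[0][0].n_used == 32
        assert her2.results[0][0].n_used == 8

    def test_per_cell_missing_drops_from_that_cell_only(self, rng):
        grid, preds, surv = self._cohort(rng)
        preds[0].ftv_f[3, 4] = np.nan
        result = sweep(preds, surv, grid, "ftv_f")
        assert result.results[3][4].n_used == len(preds) - 1
        assert result.results[0][0].n_used == len(preds)


class TestSelectOptimized:
    def _sweep_with_p(self, p_matrix, hr_matrix=None):
        grid = default_grid()
        p_matrix = np.asarray(p_matrix, dtype=float)
        hr_matrix = np.ones_like(p_matrix) if hr_matrix is None else np.asarray(hr_matrix)
        results = []
        for i in range(grid.shape[0]):
            row = []
            for j in range(grid.shape[1]):
                row.append(
                    CoxResult(
                        beta=np.log(hr_matrix[i, j]), se=0.1,
                        hazard_ratio=hr_matrix[i, j], wald_ci_lo=0.5, wald_ci_hi=2.0,
                        lr_pvalue=p_matrix[i, j], n_used=30, n_events=15,
                        converged=True, degenerate=False,
                    )
                )
            results.append(row)
        return SweepResult(
            predictor="ftv_f", subset="full", grid=grid,
            hr_matrix=hr_matrix, p_matrix=p_matrix,
            ci_lo_matrix=np.full(grid.shape, 0.5), ci_hi_matrix=np.full(grid.shape, 2.0),
            degenerate_matrix=np.zeros(grid.shape, dtype=bool), results=results,
        )

    def test_unique_minimum_selected(self):
        grid = default_grid()
        p = np.full(grid.shape, 0.5)
        i, j = grid.index_of(120.0, 1.4)
        p[i, j] = 0.001
        assert select_optimized(self._sweep_with_p(p)) == (120.0, 1.4)

    def test_all_degenerate_is_selection_error(self):
        result = self._sweep_with_p(np.full((18, 11), 0.5))
        for row in result.results:
            for r in row:
                r.degenerate = True
        result.degenerate_matrix[:] = True
        with pytest.raises(SelectionError, match="no eligible"):
            select_optimized(result)

    def test_exact_tie_broken_by_lower_pe_threshold(self):
        grid = default_grid()
        p = np.full(grid.shape, 0.5)
        for pe_t in (90.0, 150.0):
            i, j = grid.index_of(pe_t, 0.4)
            p[i, j] = 0.01
        assert select_optimized(self._sweep_with_p(p)) == (90.0, 0.4)

    def test_exact_tie_broken_by_higher_hazard_ratio_first(self):
        grid = default_grid()
        p = np.full(grid.shape, 0.5)
        hr = np.ones(grid.shape)
        i1 = grid.index_of(90.0, 0.4)
        i2 = grid.index_of(150.0, 0.4)
        p[i1], p[i2] = 0.01, 0.01
        hr[i2] = 1.5  # higher HR wins despite higher PE_t
        assert select_optimized(self._sweep_with_p(p, hr)) == (150.0, 0.4)
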