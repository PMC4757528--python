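"""Univariate Cox proportional-hazards fits and threshold-grid sweeps.

Each grid cell's predictor is tested against recurrence-free survival (RFS)
with a univariate Cox model: hazard h(t | x) = h0(t) * exp(beta * x / scale).
The partial likelihood uses the Efron correction for tied event times and is
maximized by Newton's method with step-halving.  Reported per cell: the
hazard ratio exp(beta) per ``scale`` units of the predictor, its Wald 95%
confidence interval, and the likelihood-ratio test p-value against beta = 0.

Small subsets produce monotone-likelihood degeneracies (the partial
likelihood increases without bound in |beta|, hazard ratios explode);
affected cells are flagged and excluded from optimum selection but kept in
the matrices so heat maps can display them.

The optimized cell is the one attaining the lowest likelihood-ratio p-value
among converged, non-degenerate cells; exact ties are broken by higher
hazard ratio, then lower PE threshold, then lower SER threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .ftv import PREDICTOR_KINDS, SUBTYPES, PredictorRecord, ThresholdGrid

__all__ = [
    "SurvivalRecord",
    "CoxResult",
    "SweepResult",
    "CoxFitError",
    "SubsetError",
    "SelectionError",
    "DEFAULT_SCALES",
    "fit_cox",
    "sweep",
    "select_optimized",
]

#: Per-unit scaling of the predictors: 10 percentage points per unit for the
#: percent-change predictors, 1 cc per unit for absolute final FTV.
DEFAULT_SCALES = {"delta_ftv2": 10.0, "delta_ftvf": 10.0, "ftv_f": 1.0}

#: Monotone-likelihood guard on the scaled coefficient and its standard error.
BETA_BOUND = 15.0
SE_BOUND = 10.0


class CoxFitError(ValueError):
    """Unfittable input: no events, or a non-identifiable (constant) covariate."""


class SubsetError(ValueError):
    """A cohort subset filter selected no patients."""


class SelectionError(RuntimeError):
    """No converged, non-degenerate cell to select an optimum from."""


@dataclass(frozen=True)
class SurvivalRecord:
    """RFS time in months, event indicator, and subtype for one patient.

    ``event`` is true for a local or distant recurrence; censored patients
    carry the time to their most recent follow-up.
    """

    patient_id: str
    rfs_months: float
    event: bool
    subtype: str = "unknown"

    def __post_init__(self) -> None:
        if self.rfs_months <= 0:
            raise ValueError(f"rfs_months must be positive, got {self.rfs_months}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


@dataclass
class CoxResult:
    beta: float
    se: float
    hazard_ratio: float
    wald_ci_lo: float
    wald_ci_hi: float
    lr_pvalue: float
    n_used: int
    n_events: int
    converged: bool
    degenerate: bool
    scale: float = 1.0
    n_iter: int = 0

    @classmethod
    def placeholder(cls, n_used: int = 0, n_events: int = 0, scale: float = 1.0) -> "CoxResult":
        """Flagged stand-in for a cell whose fit preconditions failed."""
        nan = float("nan")
        return cls(
            beta=nan, se=nan, hazard_ratio=nan, wald_ci_lo=nan, wald_ci_hi=nan,
            lr_pvalue=nan, n_used=n_used, n_events=n_events,
            converged=False, degenerate=True, scale=scale,
        )


class _EfronLikelihood:
    """Efron partial log-likelihood for one covariate, fully vectorized.

    Built once per fit from time-sorted data; each evaluation is O(n) numpy.
    For each distinct event time with ``d`` tied events, the Efron terms
    ``l = 0..d-1`` subtract the fraction ``l/d`` of the tied-set sums from
    the risk-set sums.  Term bookkeeping (which group each term belongs to,
    its fraction, the risk-set start index) is precomputed.
    """

    def __init__(self, z: np.ndarray, time: np.ndarray, event: np.ndarray):
        self.z = z
        new_group = np.r_[True, time[1:] != time[:-1]]
        starts = np.flatnonzero(new_group)
        group_of = np.cumsum(new_group) - 1
        self.death_idx = np.flatnonzero(event)
        self.zd_sum = float(z[self.death_idx].sum())
        dg = group_of[self.death_idx]
        n_groups = len(starts)
        d_count = np.bincount(dg, minlength=n_groups)
        with_deaths = np.flatnonzero(d_count)
        counts = d_count[with_deaths]
        self._dg = dg
        self._n_groups = n_groups
        term_group = np.repeat(with_deaths, counts)
        offsets = np.repeat(np.cumsum(counts) - counts, counts)
        l = np.arange(counts.sum()) - offsets
        self.term_frac = l / np.repeat(counts, counts)
        self.term_start = starts[term_group]
        self.term_group = term_group

    def __call__(self, beta: float):
        """Returns (loglik, gradient, hessian) at ``beta``."""
        z = self.z
        w = np.exp(beta * z)
        wz = w * z
        wzz = wz * z
        # suffix sums: risk set at time t = all subjects with time >= t
        c0 = np.cumsum(w[::-1])[::-1]
        c1 = np.cumsum(wz[::-1])[::-1]
        c2 = np.cumsum(wzz[::-1])[::-1]
        di = self.death_idx
        sd0 = np.bincount(self._dg, weights=w[di], minlength=self._n_groups)
        sd1 = np.bincount(self._dg, weights=wz[di], minlength=self._n_groups)
        sd2 = np.bincount(self._dg, weights=wzz[di], minlength=self._n_groups)
        tg, tf, ts = self.term_group, self.term_frac, self.term_start
        denom = c0[ts] - tf * sd0[tg]
        num1 = c1[ts] - tf * sd1[tg]
        num2 = c2[ts] - tf * sd2[tg]
        with np.errstate(divide="ignore", invalid="ignore"):
            mean1 = num1 / denom
            ll = beta * self.zd_sum - np.log(denom).sum()
            grad = self.zd_sum - mean1.sum()
            hess = -(num2 / denom - mean1**2).sum()
        return ll, grad, hess


def fit_cox(
    x: Sequence[float] | np.ndarray,
    surv: Sequence[SurvivalRecord],
    scale: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> CoxResult:
    """Fit a univariate Cox model of RFS on ``x / scale``.

    Subjects with missing (NaN) covariates are dropped.  Raises
    :class:`CoxFitError` when fewer than two usable subjects remain, no
    events remain, or the covariate is constant.  Non-convergence is
    reported on the result (``converged=False``), never as an exception.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) != len(surv):
        raise ValueError(f"covariate length {len(x)} != number of records {len(surv)}")
    keep = np.isfinite(x)
    x = x[keep]
    records = [r for r, k in zip(surv, keep) if k]
    n = len(records)
    if n < 2:
        raise CoxFitError(f"need >= 2 subjects with non-missing covariate, have {n}")
    time = np.array([r.rfs_months for r in records])
    event = np.array([r.event for r in records], dtype=bool)
    n_events = int(event.sum())
    if n_events == 0:
        raise CoxFitError("no events")
    if np.ptp(x) == 0:
        raise CoxFitError("non-identifiable: constant covariate")

    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    # center the scaled covariate for numerical stability; beta is unchanged
    z_raw = x[order] / scale
    shift = z_raw.mean()
    z = z_raw - shift

    loglik = _EfronLikelihood(z, time, event)
    ll0, _, _ = loglik(0.0)
    beta = 0.0
    ll = ll0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, hess = loglik(beta)
        if hess >= 0 or not np.isfinite(hess):
            break  # flat/irregular likelihood: monotone-likelihood territory
        step = -grad / hess
        # step-halving keeps the likelihood non-decreasing
        new_beta = beta + step
        new_ll, _, _ = loglik(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-14) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, _, _ = loglik(new_beta)
            halvings += 1
        beta = new_beta
        if abs(step) < tol and abs(grad) < 1e-6:
            converged = True
            break
        if abs(beta) > 2 * BETA_BOUND:
            break  # runaway estimate: stop and flag

    ll, _, hess = loglik(beta)
    info = -hess
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    lr_stat = max(2.0 * (ll - ll0), 0.0)
    lr_p = float(stats.chi2.sf(lr_stat, df=1))
    lr_p = min(max(lr_p, np.nextafter(0, 1)), 1.0)  # p in (0, 1]
    degenerate = bool(abs(beta) > BETA_BOUND or se > SE_BOUND or not np.isfinite(se))
    def _safe_exp(v: float) -> float:
        if v > 700:
            return float("inf")
        if v < -700:
            return 0.0
        return math.exp(v)

    hr = _safe_exp(beta)
    ci_lo = _safe_exp(beta - 1.96 * se) if np.isfinite(se) else 0.0
    ci_hi = _safe_exp(beta + 1.96 * se) if np.isfinite(se) else float("inf")
    return CoxResult(
        beta=float(beta), se=float(se), hazard_ratio=float(hr),
        wald_ci_lo=float(ci_lo), wald_ci_hi=float(ci_hi), lr_pvalue=lr_p,
        n_used=n, n_events=n_events, converged=converged,
        degenerate=degenerate, scale=scale, n_iter=n_iter,
    )


@dataclass
class SweepResult:
    """Per-cell Cox results over the threshold grid for one subset/predictor."""

    predictor: str
    subset: str
    grid: ThresholdGrid
    hr_matrix: np.ndarray = field(repr=False)
    p_matrix: np.ndarray = field(repr=False)
    ci_lo_matrix: np.ndarray = field(repr=False)
    ci_hi_matrix: np.ndarray = field(repr=False)
    degenerate_matrix: np.ndarray = field(repr=False)
    results: list[list[CoxResult]] = field(repr=False)
    scale: float = 1.0
    default_cell: tuple[float, float] = (70.0, 0.0)
    optimized_cell: tuple[float, float] | None = None
    n_fit: int = 0
    n_significant: int = 0
    n_degenerate: int = 0

    def result_at(self, pe_t: float, ser_t: float) -> CoxResult:
        i, j = self.grid.index_of(pe_t, ser_t)
        return self.results[i][j]


def _subset_filter(subset: str, subtype: str) -> bool:
    if subset == "full":
        return True
    return subtype == subset


def sweep(
    predictors: Sequence[PredictorRecord],
    survival: Sequence[SurvivalRecord],
    grid: ThresholdGrid,
    predictor: str,
    subset: str = "full",
    scale: float | None = None,
    default_cell: tuple[float, float] = (70.0, 0.0),
    alpha: float = 0.05,
) -> SweepResult:
    """Fit one Cox model per grid cell for a predictor and cohort subset.

    ``subset`` is ``"full"`` (everyone, including unknown subtype) or one of
    the subtype labels.  Patients missing the predictor at a cell are dropped
    from that cell's fit only; cells whose fit preconditions fail carry a
    flagged placeholder.  The significant-cell count uses p < ``alpha`` with
    no multiple-testing correction; the number of fits is always reported
    alongside.
    """
    if predictor not in PREDICTOR_KINDS:
        raise KeyError(f"unknown predictor kind {predictor!r}")
    if subset != "full" and subset not in SUBTYPES:
        raise ValueError(f"unknown subset {subset!r}")
    if scale is None:
        scale = DEFAULT_SCALES[predictor]

    surv_by_id = {r.patient_id: r for r in survival}
    pairs = [
        (p, surv_by_id[p.patient_id])
        for p in predictors
        if p.patient_id in surv_by_id and _subset_filter(subset, p.subtype)
    ]
    if not pairs:
        raise SubsetError(f"subset filter {subset!r} selected no patients")

    n_pe, n_ser = grid.shape
    value_stack = np.stack([p.values(predictor) for p, _ in pairs])  # (n, pe, ser)
    records = [s for _, s in pairs]

    hr = np.full((n_pe, n_ser), np.nan)
    pv = np.full((n_pe, n_ser), np.nan)
    lo = np.full((n_pe, n_ser), np.nan)
    hi = np.full((n_pe, n_ser), np.nan)
    degen = np.zeros((n_pe, n_ser), dtype=bool)
    results: list[list[CoxResult]] = []
    n_fit = n_sig = 0
    for i in range(n_pe):
        row: list[CoxResult] = []
        for j in range(n_ser):
            xs = value_stack[:, i, j]
            try:
                res = fit_cox(xs, records, scale=scale)
                n_fit += 1
            except CoxFitError:
                finite = np.isfinite(xs)
                res = CoxResult.placeholder(
                    n_used=int(finite.sum()),
                    n_events=int(sum(r.event for r, f in zip(records, finite) if f)),
                    scale=scale,
                )
            row.append(res)
            hr[i, j] = res.hazard_ratio
            pv[i, j] = res.lr_pvalue
            lo[i, j] = res.wald_ci_lo
            hi[i, j] = res.wald_ci_hi
            degen[i, j] = res.degenerate
            if res.converged and not res.degenerate and res.lr_pvalue < alpha:
                n_sig += 1
        results.append(row)

    out = SweepResult(
        predictor=predictor, subset=subset, grid=grid,
        hr_matrix=hr, p_matrix=pv, ci_lo_matrix=lo, ci_hi_matrix=hi,
        degenerate_matrix=degen, results=results, scale=scale,
        default_cell=default_cell, n_fit=n_fit, n_significant=n_sig,
        n_degenerate=int(degen.sum()),
    )
    try:
        out.optimized_cell = select_optimized(out)
    except SelectionError:
        out.optimized_cell = None
    return out


def select_optimized(sweep_result: SweepResult) -> tuple[float, float]:
    """Grid cell with the lowest likelihood-ratio p-value.

    Only converged, non-degenerate cells with a finite p-value are eligible.
    Exact ties are broken by higher hazard ratio, then lower PE threshold,
    then lower SER threshold.
    """
    grid = sweep_result.grid
    candidates = []
    n_total = 0
    for i, pe_t in enumerate(grid.pe_thresholds):
        for j, ser_t in enumerate(grid.ser_thresholds):
            n_total += 1
            res = sweep_result.results[i][j]
            if res.converged and not res.degenerate and np.isfinite(res.lr_pvalue):
                candidates.append((res.lr_pvalue, -res.hazard_ratio, pe_t, ser_t))
    if not candidates:
        raise SelectionError(
            f"no eligible cells among {n_total} "
            f"({sweep_result.n_degenerate} flagged degenerate, {sweep_result.n_fit} fit)"
        )
    _, _, pe_t, ser_t = min(candidates)
    return (float(pe_t), float(ser_t))
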