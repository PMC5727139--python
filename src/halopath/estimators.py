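"""Work-based free-energy estimators.

Given ensembles of nonequilibrium pull traces, this module estimates:

* endpoint free-energy differences — :func:`jarzynski_df` (exponential work
  average) and :func:`bar_df` (Bennett acceptance ratio, the minimum-variance
  self-consistent combination of forward and reverse work samples);
* path-ensemble averages via Crooks reweighting of the reverse process
  (:func:`crooks_reweighted_average`);
* the potential of mean force G0(lambda) of the unperturbed system from
  time-slice work statistics — unidirectional (:func:`hummer_szabo_pmf`) and
  bidirectional (:func:`minh_adib_pmf`), the latter weighting each slice
  contribution by Bennett factors built from total works so that forward and
  reverse pulls are combined optimally;
* bootstrap standard errors by resampling whole traces
  (:func:`bootstrap_sem`).

All exponential averages are computed in log space, so beta*W spans of
hundreds of kT are handled without overflow.  The time-slice estimators share
one self-consistency scheme for the biased-state free energies dF_t: starting
from dF_t = 0, the profile and dF_t are iterated to a fixed point
(max |change| < tol).  Profiles are reported anchored at their minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .errors import BarConvergenceError, EstimatorError
from .steered import PullEnsemble, SteeringSchedule, WorkTrace
from .thermo import ThermoContext

__all__ = [
    "BinGrid", "PMFProfile", "FreeEnergySeries", "BootstrapResult",
    "jarzynski_df", "bar_df", "crooks_reweighted_average",
    "hummer_szabo_pmf", "minh_adib_pmf", "bootstrap_sem",
]


@dataclass(frozen=True)
class BinGrid:
    """Strictly increasing bin edges over the reaction coordinate."""

    edges: np.ndarray

    def __init__(self, edges: Sequence[float]):
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("BinGrid needs at least two edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @classmethod
    def linear(cls, lo: float, hi: float, n_bins: int = 50) -> "BinGrid":
        if hi <= lo:
            lo, hi = hi, lo
        return cls(np.linspace(lo, hi, n_bins + 1))

    @classmethod
    def from_schedule(cls, schedule: SteeringSchedule, n_bins: int = 50) -> "BinGrid":
        return cls.linear(schedule.lambda_start, schedule.lambda_end, n_bins)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 for out-of-range."""
        idx = np.searchsorted(self.edges, values, side="right") - 1
        idx[np.asarray(values) == self.edges[-1]] = self.n_bins - 1
        idx[(idx < 0) | (idx >= self.n_bins)] = -1
        return idx


@dataclass
class PMFProfile:
    """Estimated G0(lambda) per bin, NaN where the bin was never visited."""

    grid: BinGrid
    g0: np.ndarray
    sem: Optional[np.ndarray] = None
    estimator_tag: str = ""
    anchored: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.g0)

    def anchored_copy(self) -> "PMFProfile":
        g = self.g0 - np.nanmin(self.g0)
        return PMFProfile(self.grid, g, self.sem, self.estimator_tag, True, dict(self.meta))


@dataclass
class FreeEnergySeries:
    """Biased-state free energies dF_t = F_t - F_0 per time slice (dF_0 = 0)."""

    times: np.ndarray
    delta_f: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        if self.times.shape != self.delta_f.shape:
            raise ValueError("times and delta_f must have equal length")
        if abs(self.delta_f[0]) > 1e-9:
            raise ValueError("delta_f must be zero at the first slice")


# ---------------------------------------------------------------------------
# endpoint estimators
# ---------------------------------------------------------------------------

def jarzynski_df(works: Sequence[float], thermo: ThermoContext) -> float:
    """Jarzynski estimate -1/beta ln<exp(-beta W)> with a log-sum-exp guard."""
    w = np.asarray(works, dtype=float)
    if w.size == 0:
        raise EstimatorError("jarzynski_df needs at least one work value")
    if not np.all(np.isfinite(w)):
        raise EstimatorError("non-finite work value passed to jarzynski_df")
    beta = thermo.beta
    return float(-(logsumexp(-beta * w) - np.log(w.size)) / beta)


def bar_df(
    forward_works: Sequence[float],
    reverse_works: Sequence[float],
    thermo: ThermoContext,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> float:
    """Bennett acceptance ratio free-energy difference.

    Solves the self-consistent Bennett equation

        sum_F f(M + beta(W_F - dF)) = sum_R f(-M + beta(W_R + dF)),

    with f the Fermi function and M = ln(n_F/n_R); ``forward_works`` and
    ``reverse_works`` are each measured in their own pulling direction, and
    the returned dF is that of the forward process.
    """
    wf = np.asarray(forward_works, dtype=float)
    wr = np.asarray(reverse_works, dtype=float)
    if wf.size == 0 or wr.size == 0:
        raise EstimatorError("bar_df needs non-empty forward and reverse work lists")
    beta = thermo.beta
    M = np.log(wf.size / wr.size)

    def h(df: float) -> float:
        # increasing in df: forward Fermi terms grow, reverse terms shrink
        a = expit(-(M + beta * (wf - df)))
        b = expit(-(-M + beta * (wr + df)))
        return float(a.sum() - b.sum())

    guess = 0.5 * (jarzynski_df(wf, thermo) - jarzynski_df(wr, thermo))
    span = max(1.0, np.ptp(wf) + np.ptp(wr))
    lo, hi = guess - span, guess + span
    for _ in range(60):
        if h(lo) < 0:
            break
        lo -= span
        span *= 2
    else:
        raise BarConvergenceError(lo, "could not bracket the Bennett root from below")
    span = max(1.0, np.ptp(wf) + np.ptp(wr))
    for _ in range(60):
        if h(hi) > 0:
            break
        hi += span
        span *= 2
    else:
        raise BarConvergenceError(hi, "could not bracket the Bennett root from above")
    try:
        return float(brentq(h, lo, hi, xtol=tol, maxiter=max_iter))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - brentq rarely fails
        raise BarConvergenceError(0.5 * (lo + hi), str(exc)) from exc


def crooks_reweighted_average(
    values: Sequence[float],
    works: Sequence[float],
    df: float,
    thermo: ThermoContext,
) -> float:
    """Work-reweighted path-ensemble average <v * exp(-beta (W - df))>.

    ``works`` and ``df`` must refer to the same process direction as the
    ensemble being averaged over: to recover a *forward* average from reverse
    pulls, pass the reverse works with the reverse free-energy difference
    (df_R = -df_F).  With values identically 1 and the exact df, the average
    is 1 by the Crooks normalization identity.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(works, dtype=float)
    if v.shape != w.shape:
        raise EstimatorError("values and works must have equal length")
    if v.size == 0:
        raise EstimatorError("empty ensemble passed to crooks_reweighted_average")
    loge = -thermo.beta * (w - df)
    shift = float(np.max(loge))
    return float(np.exp(shift) * np.mean(v * np.exp(loge - shift)))


# ---------------------------------------------------------------------------
# time-slice PMF estimators
# ---------------------------------------------------------------------------

def _trace_matrix(traces: List[WorkTrace]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack (n_traces, n_slices) rc and cumulative-work arrays."""
    z = np.stack([tr.rc_value for tr in traces])
    w = np.stack([tr.work for tr in traces])
    return z, w


def _slice_bin_matrix(log_weights: np.ndarray, bins: np.ndarray, n_slices: int,
                      slice_idx: np.ndarray, n_bins: int) -> np.ndarray:
    """(n_slices, n_bins) log-sum-exp accumulation of flat weighted points.

    ``log_weights``, ``bins`` and ``slice_idx`` are flat and aligned; bin -1
    marks out-of-range points.  Empty cells are -inf.
    """
    ok = bins >= 0
    out = np.full(n_slices * n_bins, -np.inf)
    if np.any(ok):
        lw = log_weights[ok]
        flat = slice_idx[ok] * n_bins + bins[ok]
        shift = float(np.max(lw))
        sums = np.bincount(flat, weights=np.exp(lw - shift), minlength=n_slices * n_bins)
        nz = sums > 0
        out[nz] = shift + np.log(sums[nz])
    return out.reshape(n_slices, n_bins)


def _iterate_profile(
    log_a: np.ndarray,
    beta_v: np.ndarray,
    beta: float,
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, np.ndarray, int, bool]:
    """WHAM-style fixed point coupling G0 and the biased-state free energies dF_t.

    ``log_a[t, b]`` is the per-slice, per-bin log numerator (work-weighted
    visitation); ``beta_v`` is beta * V(lambda_bin; t).  Each iteration forms

        exp(-beta G0(b)) ∝ sum_t A[t, b] e^{beta dF_t} / sum_t e^{-beta V[t, b] + beta dF_t}

    — every slice is an unbiased estimate of the same profile, combined with
    inverse-variance (biased-density) weights — then refreshes dF_t from the
    running profile's biased partition functions.  In exact statistics the
    profile is independent of dF_t; the iteration only optimizes the weights,
    which is why the fixed point is benign.  Returns (g0, dF_t, iterations,
    converged); g0 is NaN on unoccupied bins and not yet anchored.
    """
    n_slices, n_bins = beta_v.shape
    occupied = logsumexp(log_a, axis=0) > -np.inf
    if not np.any(occupied):
        raise EstimatorError("no occupied bins: schedule and grid do not overlap")
    beta_dft = np.zeros(n_slices)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_num = logsumexp(log_a + beta_dft[:, None], axis=0)
        log_den = logsumexp(-beta_v + beta_dft[:, None], axis=0)
        log_rho = log_num - log_den          # -beta * G0 up to a constant
        # biased-state partition functions from the running profile
        log_zt = logsumexp(log_rho[None, occupied] - beta_v[:, occupied], axis=1)
        new = -(log_zt - log_zt[0])          # beta * dF_t
        delta = float(np.max(np.abs(new - beta_dft)))
        beta_dft = new
        if delta < beta * tol:
            converged = True
            break
    log_num = logsumexp(log_a + beta_dft[:, None], axis=0)
    log_den = logsumexp(-beta_v + beta_dft[:, None], axis=0)
    g0 = np.where(occupied, -(log_num - log_den) / beta, np.nan)
    return g0, beta_dft / beta, it, converged


def _bias_matrix(centers: np.ndarray, grid: BinGrid, k: float, beta: float) -> np.ndarray:
    return beta * 0.5 * k * (centers[:, None] - grid.centers[None, :]) ** 2


def hummer_szabo_pmf(
    ensemble: PullEnsemble,
    grid: BinGrid,
    direction: str = "forward",
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> Tuple[PMFProfile, FreeEnergySeries]:
    """Unidirectional time-slice PMF reconstruction.

    Per bin, G0(lambda) = -1/beta ln[ sum_t <delta(lambda - lambda_t)
    exp(-beta W_t)> / sum_t exp(-beta (V(lambda; t) - dF_t)) ], with dF_t from
    the fixed-point iteration described in the module docstring.  The reverse
    direction is treated as a pull process in its own right (its own schedule
    frame); the resulting profile lives on the same grid and is anchored at
    its minimum, so the two directions are directly comparable.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    traces = ensemble.forward if direction == "forward" else ensemble.reverse
    if not traces:
        raise EstimatorError(f"ensemble has no {direction} traces")
    beta = ensemble.thermo.beta
    sched = ensemble.schedule if direction == "forward" else ensemble.schedule.reversed()
    centers = sched.centers()

    z, w = _trace_matrix(traces)
    n_traces, n_slices = z.shape
    bins = grid.assign(z.ravel())
    logw = (-beta * w - np.log(n_traces)).ravel()
    slice_idx = np.tile(np.arange(n_slices), (n_traces, 1)).ravel()
    log_a = _slice_bin_matrix(logw, bins, n_slices, slice_idx, grid.n_bins)

    beta_v = _bias_matrix(centers, grid, sched.k, beta)
    g0, dft, iters, conv = _iterate_profile(log_a, beta_v, beta, tol, max_iter)
    profile = PMFProfile(
        grid=grid, g0=g0, estimator_tag=f"hummer_szabo_{direction}",
        meta={"iterations": iters, "converged": conv, "beta": beta,
              "n_traces": n_traces},
    ).anchored_copy()
    series = FreeEnergySeries(times=sched.times(), delta_f=dft)
    return profile, series


def minh_adib_pmf(
    ensemble: PullEnsemble,
    grid: BinGrid,
    tol: float = 1e-6,
    max_iter: int = 1000,
    df: Optional[float] = None,
) -> Tuple[PMFProfile, FreeEnergySeries]:
    """Bidirectional time-slice PMF estimator.

    Forward slice contributions are weighted by
    ``n_F exp(-beta W_0^t) / (n_F + n_R exp(-beta (W - dF)))`` and reverse
    ones by ``n_R exp(beta (Wbar - Wbar_{tau-t})) / (n_F + n_R exp(beta (Wbar
    + dF)))``, where W (Wbar) are total forward (reverse) works, the reverse
    slice is aligned as lambda_{tau-t}, and dF is the endpoint free-energy
    difference (from :func:`bar_df` unless supplied).  The denominator and the
    dF_t series are shared with the unidirectional estimator.  As the reverse
    weights vanish this reduces to the forward Hummer-Szabo estimate; as
    n_F -> 0 it reduces to the reverse one.
    """
    if not ensemble.forward or not ensemble.reverse:
        raise EstimatorError(
            "minh_adib_pmf needs both pull directions; "
            "use hummer_szabo_pmf for a unidirectional ensemble"
        )
    beta = ensemble.thermo.beta
    sched = ensemble.schedule
    centers = sched.centers()

    zf, wf = _trace_matrix(ensemble.forward)
    zr, wr = _trace_matrix(ensemble.reverse)
    n_f, n_slices = zf.shape
    n_r = zr.shape[0]
    wf_tot = wf[:, -1]
    wr_tot = wr[:, -1]
    if df is None:
        df = bar_df(wf_tot, wr_tot, ensemble.thermo)

    # Bennett log-weights per trace (totals only)
    lw_f = np.log(n_f) - np.logaddexp(np.log(n_f), np.log(n_r) - beta * (wf_tot - df))
    lw_r = (np.log(n_r) + beta * wr_tot
            - np.logaddexp(np.log(n_f), np.log(n_r) + beta * (wr_tot + df)))

    # forward points: slice t contributes at z_f[i, t] with log weight lw_f[i] - beta W_f[i, t]
    logw_fwd = (lw_f[:, None] - beta * wf - np.log(n_f)).ravel()
    bins_fwd = grid.assign(zf.ravel())
    slices_fwd = np.tile(np.arange(n_slices), (n_f, 1)).ravel()
    # reverse points: forward slice t uses the reverse trace's own step
    # s = tau - t, with log weight lw_r[j] - beta Wbar[j, s]
    logw_rev = (lw_r[:, None] - beta * wr - np.log(n_r)).ravel()
    bins_rev = grid.assign(zr.ravel())
    slices_rev = np.tile(n_slices - 1 - np.arange(n_slices), (n_r, 1)).ravel()

    log_a = _slice_bin_matrix(
        np.concatenate([logw_fwd, logw_rev]),
        np.concatenate([bins_fwd, bins_rev]),
        n_slices,
        np.concatenate([slices_fwd, slices_rev]),
        grid.n_bins,
    )
    beta_v = _bias_matrix(centers, grid, sched.k, beta)
    g0, dft, iters, conv = _iterate_profile(log_a, beta_v, beta, tol, max_iter)
    profile = PMFProfile(
        grid=grid, g0=g0, estimator_tag="minh_adib",
        meta={"iterations": iters, "converged": conv, "beta": beta,
              "n_forward": n_f, "n_reverse": n_r, "df_endpoint": float(df)},
    ).anchored_copy()
    series = FreeEnergySeries(times=sched.times(), delta_f=dft)
    return profile, series


# ---------------------------------------------------------------------------
# bootstrap errors
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Bootstrap SEM with bookkeeping of dropped replicates."""

    sem: Union[np.ndarray, float]
    n_boot: int
    n_failed: int
    replicates: list = field(default_factory=list)


def bootstrap_sem(
    ensemble: PullEnsemble,
    estimator: Callable[[PullEnsemble], Union[PMFProfile, float, np.ndarray]],
    n_boot: int = 50,
    seed: int = 0,
    max_drop_fraction: float = 0.2,
) -> BootstrapResult:
    """Trace-level bootstrap of any ensemble estimator.

    Whole traces are resampled with replacement within each direction; the SEM
    is the (n-1)-normalized standard deviation of the replicate estimates.
    Replicates in which the estimator raises :class:`EstimatorError` are
    dropped and counted; more than ``max_drop_fraction`` drops is an error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    reps = []
    failed = 0
    for _ in range(n_boot):
        fwd = [ensemble.forward[i]
               for i in rng.integers(0, ensemble.n_forward, ensemble.n_forward)]
        rev = ([ensemble.reverse[j]
                for j in rng.integers(0, ensemble.n_reverse, ensemble.n_reverse)]
               if ensemble.n_reverse else [])
        boot = PullEnsemble(forward=fwd, reverse=rev, thermo=ensemble.thermo,
                            schedule=ensemble.schedule)
        try:
            reps.append(estimator(boot))
        except EstimatorError:
            failed += 1
    if failed > max_drop_fraction * n_boot:
        raise EstimatorError(
            f"{failed}/{n_boot} bootstrap replicates failed (> {max_drop_fraction:.0%})"
        )
    if not reps:
        raise EstimatorError("all bootstrap replicates failed")

    first = reps[0]
    if isinstance(first, PMFProfile):
        mat = np.stack([r.g0 for r in reps])
        counts = np.sum(np.isfinite(mat), axis=0)
        with np.errstate(invalid="ignore"):
            sem = np.where(counts >= 2, np.nanstd(mat, axis=0, ddof=1), np.nan)
    else:
        mat = np.stack([np.atleast_1d(np.asarray(r, dtype=float)) for r in reps])
        sem = np.std(mat, axis=0, ddof=1)
        if sem.size == 1:
            sem = float(sem[0])
    return BootstrapResult(sem=sem, n_boot=n_boot, n_failed=failed, replicates=reps)
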