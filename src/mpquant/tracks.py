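"""Single-cell migration analysis on micropatterned colonies.

Cells confined to circular adhesive islands are tracked over time; each
track is summarised by its mean-square displacement (MSD), fitted with the
persistent random walk (PRW) model, and classified as showing "biased"
(directional) or "random" migration.  Tracks are partitioned into a centre
and a perimeter population by the radial position of their first sample.

The PRW model describes a cell whose velocity direction decorrelates over a
persistence time ``P`` while its root-mean-square speed is ``S``; its
mean-square displacement in two dimensions is

    MSD(t) = 2 S^2 P [ t - P (1 - exp(-t/P)) ]

which is ballistic (``S^2 t^2``) for ``t << P`` and diffusive
(``4 mu t`` with motility coefficient ``mu = S^2 P / 2``) for ``t >> P``.

The fitting interface follows the Model/Results idiom: build a
:class:`PRWModel` from an MSD curve (or a track, or a pooled set of
curves), call :meth:`PRWModel.fit`, and inspect the returned
:class:`PRWResults` (``summary()``, ``conf_int()``, ``predict()``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientDataError, SamplingError

CENTRE = "centre"
PERIMETER = "perimeter"
BIASED = "biased"
RANDOM = "random"

#: number of spatial dimensions of migration on a flat substrate
N_DIM = 2


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class CellTrack:
    """One cell's sampled positions over time.

    Parameters
    ----------
    cell_id : str or int
        Identifier of the tracked cell.
    times : array-like, shape (n,)
        Sample timestamps in minutes, uniformly spaced.
    positions : array-like, shape (n, 2)
        Positions (x, y) in micrometres, in the pattern's coordinate frame.
    region : str, optional
        ``"centre"`` or ``"perimeter"`` once assigned (see
        :func:`assign_region`).
    """

    cell_id: object
    times: np.ndarray
    positions: np.ndarray
    region: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise InsufficientDataError(
                f"track {self.cell_id!r}: need at least 2 samples"
            )
        if self.positions.shape != (len(self.times), 2):
            raise ValueError(
                f"track {self.cell_id!r}: positions must have shape (n, 2) "
                f"matching {len(self.times)} timestamps"
            )
        if not (np.isfinite(self.times).all() and np.isfinite(self.positions).all()):
            raise ValueError(f"track {self.cell_id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Sampling interval in minutes; raises if sampling is non-uniform."""
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise SamplingError(
                f"track {self.cell_id!r}: non-uniform sampling interval"
            )
        return float(steps[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def step_displacements(self) -> np.ndarray:
        """Frame-to-frame displacement magnitudes (μm)."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    @property
    def mean_speed(self) -> float:
        """Migratory velocity: mean frame-to-frame displacement / Δt (μm/min)."""
        return float(self.step_displacements.mean() / self.dt)


@dataclass
class MSDCurve:
    """Mean-square displacement versus lag time.

    ``n_pairs[k]`` counts the overlapping (start, start+lag) pairs that were
    averaged at each lag; for a single track of N+1 positions, lag k averages
    the N−k+1 pairs (i, i+k) with 0 ≤ i ≤ N−k.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs)):
            raise ValueError("lags, msd and n_pairs must have equal length")
        if (self.msd < -1e-12).any():
            raise ValueError("msd values must be non-negative")


@dataclass(frozen=True)
class RegionRule:
    """Centre/perimeter partition of a circular pattern.

    A cell belongs to the perimeter when the radial distance of its *initial*
    position from the pattern centre exceeds ``radial_threshold`` strictly;
    exactly at the threshold it is a centre cell.  The default threshold of
    100 μm is half the radius of a 400-μm pattern.
    """

    centre: tuple[float, float] = (0.0, 0.0)
    radial_threshold: float = 100.0

    def __post_init__(self):
        if self.radial_threshold <= 0:
            raise ValueError("radial_threshold must be positive")

    def classify_point(self, point) -> str:
        r = math.hypot(point[0] - self.centre[0], point[1] - self.centre[1])
        return PERIMETER if r > self.radial_threshold else CENTRE


# ---------------------------------------------------------------------------
# MSD estimation
# ---------------------------------------------------------------------------

def compute_msd(track: CellTrack, max_lag_fraction: float = 1 / 3) -> MSDCurve:
    """Mean-square displacement by the overlapping time-interval method.

    For lag ``k``, all N−k overlapping start indices contribute
    ``|r(i+k) − r(i)|²`` and their mean is MSD(kΔt).  Lags are restricted to
    ``kΔt ≤ max_lag_fraction · NΔt`` (default one third of the track
    duration, which bounds the estimator variance at long lags).

    Raises
    ------
    InsufficientDataError
        If the track has fewer than 3 positions.
    SamplingError
        If timestamps are not uniformly spaced.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = len(track)
    if n < 3:
        raise InsufficientDataError(
            f"track {track.cell_id!r}: need at least 3 positions for an MSD"
        )
    dt = track.dt  # validates uniform sampling
    n_steps = n - 1
    kmax = int(math.floor(max_lag_fraction * n_steps + 1e-9))
    kmax = max(1, min(kmax, n_steps))
    ks = np.arange(1, kmax + 1)
    msd = np.empty(kmax)
    for k in ks:
        d = track.positions[k:] - track.positions[:-k]
        msd[k - 1] = np.einsum("ij,ij->i", d, d).mean()
    # lag k on N+1 positions has N-k+1 overlapping (i, i+k) pairs
    return MSDCurve(lags=ks * dt, msd=msd, n_pairs=n - ks)


def pooled_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Pool per-track MSD curves into an ensemble curve.

    At each lag present in any curve, the pooled MSD is the n_pairs-weighted
    mean of the per-track values; pooled n_pairs is the total pair count.
    """
    if not curves:
        raise InsufficientDataError("no MSD curves to pool")
    acc: dict[float, list[float]] = {}
    for c in curves:
        for lag, m, n in zip(c.lags, c.msd, c.n_pairs):
            key = round(float(lag), 9)
            acc.setdefault(key, [0.0, 0.0])
            acc[key][0] += n * m
            acc[key][1] += n
    lags = np.array(sorted(acc))
    msd = np.array([acc[l][0] / acc[l][1] for l in lags])
    n_pairs = np.array([acc[l][1] for l in lags])
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# PRW model
# ---------------------------------------------------------------------------

def prw_msd(t, persistence_time, speed):
    """Closed-form PRW mean-square displacement (2D).

    Uses ``t + P·expm1(−t/P)`` to avoid cancellation for ``t << P``.
    """
    t = np.asarray(t, dtype=float)
    P = persistence_time
    return 2.0 * speed**2 * P * (t + P * np.expm1(-t / P))


class PRWModel:
    """Persistent-random-walk model of an MSD curve.

    Nonlinear weighted least squares of the 2D PRW form over the supplied
    lags.  Each lag is weighted by ``sqrt(n_pairs)``: the overlapping MSD
    estimator averages fewer pairs at long lags, so their variance is
    larger.  The optimisation runs over (log P, log S), which enforces
    positivity without explicit bounds.

    Parameters
    ----------
    lags, msd : array-like
        The MSD curve (minutes, μm²).
    n_pairs : array-like, optional
        Pair counts per lag; equal weights when omitted.
    n_d : int
        Spatial dimension; the motility coefficient is ``μ = S²P / n_d``.
    """

    def __init__(self, lags, msd, n_pairs=None, n_d: int = N_DIM):
        self.lags = np.asarray(lags, dtype=float)
        self.msd = np.asarray(msd, dtype=float)
        if self.lags.ndim != 1 or len(self.lags) != len(self.msd):
            raise ValueError("lags and msd must be 1-D of equal length")
        if len(self.lags) < 3:
            raise InsufficientDataError("need at least 3 lags to fit the PRW model")
        if n_pairs is None:
            n_pairs = np.ones_like(self.lags)
        self.n_pairs = np.asarray(n_pairs, dtype=float)
        self.n_d = n_d
        self.weights = np.sqrt(self.n_pairs / self.n_pairs.mean())
        self._whitener: np.ndarray | None = None

    @classmethod
    def from_msd(cls, curve: MSDCurve, n_d: int = N_DIM) -> "PRWModel":
        return cls(curve.lags, curve.msd, curve.n_pairs, n_d=n_d)

    @classmethod
    def from_track(cls, track: CellTrack, max_lag_fraction: float = 1 / 3,
                   n_d: int = N_DIM) -> "PRWModel":
        return cls.from_msd(compute_msd(track, max_lag_fraction), n_d=n_d)

    @classmethod
    def from_tracks(cls, tracks: list[CellTrack], max_lag_fraction: float = 1 / 3,
                    n_d: int = N_DIM) -> "PRWModel":
        """Ensemble model on the pooled MSD of several tracks."""
        curves = [compute_msd(t, max_lag_fraction) for t in tracks]
        return cls.from_ensemble(curves, n_d=n_d)

    @classmethod
    def from_ensemble(cls, curves: list[MSDCurve], n_d: int = N_DIM,
                      shrinkage: float = 0.1) -> "PRWModel":
        """Generalised-least-squares ensemble model over replicate curves.

        When every curve shares the same lag grid, the model fits the
        ensemble-mean MSD whitened by the empirical covariance of that mean
        (shrunk toward its diagonal by ``shrinkage`` for conditioning).
        MSD values at different lags are strongly correlated and their
        variance grows with the MSD itself, so GLS recovers P and μ with
        substantially less spread than per-lag weighting.  Falls back to
        the pair-count-weighted pooled curve when the grids differ or the
        covariance is degenerate.
        """
        pooled = pooled_msd(curves)
        same_grid = all(
            len(c.lags) == len(curves[0].lags)
            and np.allclose(c.lags, curves[0].lags) for c in curves
        )
        if len(curves) < 8 or not same_grid:
            return cls.from_msd(pooled, n_d=n_d)
        M = np.array([c.msd for c in curves])
        cov = np.cov(M, rowvar=False) / len(M)
        cov = (1 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
        model = cls(curves[0].lags, M.mean(axis=0),
                    n_pairs=pooled.n_pairs, n_d=n_d)
        try:
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
            model._whitener = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return cls.from_msd(pooled, n_d=n_d)
        return model

    # -- fitting -----------------------------------------------------------

    def _residuals(self, theta):
        P, S = np.exp(theta)
        raw = prw_msd(self.lags, P, S) - self.msd
        if self._whitener is not None:
            return np.linalg.solve(self._whitener, raw)
        return self.weights * raw

    def _starts(self):
        t, y = self.lags, self.msd
        mu0 = max(y[-1] / (2 * self.n_d * t[-1]), 1e-12)
        s_ball = math.sqrt(max(y[0], 1e-24)) / t[0]
        starts = []
        for P0 in (t[0], float(t.mean()), 2 * t[-1]):
            S0 = math.sqrt(self.n_d * mu0 / P0)
            starts.append((math.log(P0), math.log(max(S0, 1e-12))))
        starts.append((math.log(2 * t[-1]), math.log(max(s_ball, 1e-12))))
        return starts

    def fit(self) -> "PRWResults":
        """Fit P and S; never raises on non-convergence (flagged instead)."""
        if np.max(self.msd) <= 0.0:
            # stationary cell: S = 0 reproduces the data at any P.  P is
            # reported as the first lag purely so that mu = S^2 P / n_d
            # stays an exact identity (it is 0 regardless).
            return PRWResults(
                model=self, persistence_time=float(self.lags[0]), speed=0.0,
                residual_norm=0.0, converged=True, degenerate=True,
                cov_log=np.full((2, 2), np.nan),
            )
        best = None
        for x0 in self._starts():
            try:
                res = optimize.least_squares(
                    self._residuals, x0, method="trf", xtol=1e-14, ftol=1e-14,
                    gtol=1e-14, max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.isfinite(best.cost):
            return PRWResults(
                model=self, persistence_time=np.nan, speed=np.nan,
                residual_norm=np.nan, converged=False, degenerate=False,
                cov_log=np.full((2, 2), np.nan),
            )
        P, S = np.exp(best.x)
        resid = prw_msd(self.lags, P, S) - self.msd
        # in the diffusive limit (t >> P) only the product S^2 P is
        # identified; the optimizer can exhaust its step budget wandering
        # the flat ridge with an essentially perfect fit, so an
        # excellent residual also counts as convergence
        norm_msd = float(np.linalg.norm(self.msd))
        excellent = np.linalg.norm(resid) <= 1e-6 * max(norm_msd, 1e-300)
        dof = max(len(self.lags) - 2, 1)
        try:
            jtj = best.jac.T @ best.jac
            cov_log = np.linalg.inv(jtj) * (2 * best.cost / dof)
        except np.linalg.LinAlgError:
            cov_log = np.full((2, 2), np.nan)
        return PRWResults(
            model=self, persistence_time=float(P), speed=float(S),
            residual_norm=float(np.linalg.norm(resid)),
            converged=bool(best.success or excellent), degenerate=False,
            cov_log=cov_log,
        )


@dataclass
class PRWResults:
    """Fitted PRW parameters and diagnostics.

    Attributes
    ----------
    persistence_time : float
        P, minutes — average time between drastic direction changes.
    speed : float
        S, μm/min — root-mean-square migration speed.
    motility_coefficient : float
        μ = S²P / n_d (μm²/min), computed exactly from the fitted P and S.
    residual_norm : float
        Unweighted ‖model − msd‖₂ (μm²).
    relative_residual : float
        residual_norm / ‖msd‖₂; the goodness-of-fit statistic used by
        :func:`classify_migration`.
    classification : str or None
        "biased" / "random" once :func:`classify_migration` has been applied.
    """

    model: PRWModel
    persistence_time: float
    speed: float
    residual_norm: float
    converged: bool
    degenerate: bool
    cov_log: np.ndarray = field(repr=False)
    classification: str | None = None

    @property
    def motility_coefficient(self) -> float:
        return self.speed**2 * self.persistence_time / self.model.n_d

    @property
    def relative_residual(self) -> float:
        denom = float(np.linalg.norm(self.model.msd))
        if denom == 0.0:
            return 0.0
        return self.residual_norm / denom

    @property
    def nobs(self) -> int:
        return len(self.model.lags)

    def predict(self, t) -> np.ndarray:
        return prw_msd(t, self.persistence_time, self.speed)

    def bse(self) -> np.ndarray:
        """Delta-method standard errors of (P, S) from the log-space fit."""
        se_log = np.sqrt(np.diag(self.cov_log))
        return se_log * np.array([self.persistence_time, self.speed])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(P, S) confidence intervals (lognormal, from the log-space fit)."""
        se_log = np.sqrt(np.diag(self.cov_log))
        z = stats.t.ppf(1 - alpha / 2, max(self.nobs - 2, 1))
        centre = np.log([self.persistence_time, self.speed])
        lo = np.exp(centre - z * se_log)
        hi = np.exp(centre + z * se_log)
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        lines = [
            "Persistent Random Walk fit",
            "=" * 44,
            f"n lags:               {self.nobs}",
            f"converged:            {self.converged}",
            f"degenerate:           {self.degenerate}",
            f"P (persistence, min): {self.persistence_time:.4g}",
            f"S (speed, um/min):    {self.speed:.4g}",
            f"mu (um^2/min):        {self.motility_coefficient:.4g}",
            f"residual norm (um^2): {self.residual_norm:.4g}",
            f"relative residual:    {self.relative_residual:.4g}",
            f"classification:       {self.classification or 'unset'}",
        ]
        return "\n".join(lines)


def fit_prw(msd: MSDCurve, n_d: int = N_DIM) -> PRWResults:
    """Convenience wrapper: fit the PRW model to an MSD curve."""
    return PRWModel.from_msd(msd, n_d=n_d).fit()


def classify_migration(fit: PRWResults, mu_threshold: float = 5.0,
                       gof_threshold: float = 0.3) -> PRWResults:
    """Label a fitted track as "biased" or "random".

    A cell is "biased" when the PRW fit converged, the relative residual is
    at most ``gof_threshold`` (the track is well described by the model) and
    the motility coefficient strictly exceeds ``mu_threshold`` (default 5
    μm²/min).  The inequality is strict: μ exactly at the threshold is
    "random".
    """
    biased = (
        fit.converged
        and fit.relative_residual <= gof_threshold
        and fit.motility_coefficient > mu_threshold
    )
    fit.classification = BIASED if biased else RANDOM
    return fit


def assign_region(track: CellTrack, rule: RegionRule) -> CellTrack:
    """Return a copy of the track with its centre/perimeter label set.

    Only the first position matters: the cell's initial radial distance from
    the pattern centre decides the region.
    """
    return dataclasses.replace(
        track, region=rule.classify_point(track.positions[0])
    )


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-region migration statistics with between-region t-tests."""

    per_cell: pd.DataFrame
    by_region: pd.DataFrame
    pvalues: dict
    missing_regions: list

    def to_dict(self) -> dict:
        return {
            "by_region": self.by_region.reset_index().to_dict(orient="records"),
            "pvalues": self.pvalues,
            "missing_regions": list(self.missing_regions),
        }


def summarize_cohort(tracks: list[CellTrack], fits: list[PRWResults]) -> CohortSummary:
    """Summarise a tracked cohort by centre/perimeter region.

    Reports mean ± s.d. of migratory velocity (mean step displacement / Δt),
    motility coefficient, persistence time, and the percentage of "biased"
    cells per region, with two-sided Student's t-test p-values between
    regions for each continuous metric.  Tracks must carry region labels
    (see :func:`assign_region`) and be aligned with ``fits``.
    """
    if len(tracks) != len(fits):
        raise ValueError("tracks and fits must be aligned")
    rows = []
    for tr, ft in zip(tracks, fits):
        if tr.region is None:
            raise ValueError(f"track {tr.cell_id!r} has no region label")
        rows.append({
            "cell_id": tr.cell_id,
            "region": tr.region,
            "velocity": tr.mean_speed,
            "motility_coefficient": ft.motility_coefficient,
            "persistence_time": ft.persistence_time,
            "biased": ft.classification == BIASED,
        })
    per_cell = pd.DataFrame(rows)
    metrics = ["velocity", "motility_coefficient", "persistence_time"]
    summaries = {}
    for region in (CENTRE, PERIMETER):
        sub = per_cell[per_cell.region == region]
        if len(sub):
            entry = {"n": len(sub), "pct_biased": 100.0 * sub.biased.mean()}
            for m in metrics:
                entry[f"{m}_mean"] = float(sub[m].mean())
                entry[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
            summaries[region] = entry
    missing = [r for r in (CENTRE, PERIMETER) if r not in summaries]
    pvalues = {}
    if not missing:
        a = per_cell[per_cell.region == CENTRE]
        b = per_cell[per_cell.region == PERIMETER]
        for m in metrics:
            pvalues[m] = float(stats.ttest_ind(a[m], b[m]).pvalue)
    by_region = pd.DataFrame(summaries).T
    by_region.index.name = "region"
    return CohortSummary(per_cell=per_cell, by_region=by_region,
                         pvalues=pvalues, missing_regions=missing)
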