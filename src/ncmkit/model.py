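"""Sloan neutral community model: prediction, fitting, and taxon classification.

Under Sloan et al.'s continuous approximation of Hubbell's neutral dynamics, the
relative abundance x of a taxon in a local community of size N with immigration
probability m is, at stationarity, Beta-distributed::

    x ~ Beta(N m p, N m (1 - p))

where p is the taxon's relative abundance in the regional species pool. A taxon
is observed in a sequenced sample when its abundance exceeds a detection limit
d, so its predicted occurrence frequency across local communities is the Beta
tail probability ``1 - I_d(N m p, N m (1 - p))`` (``I`` the regularised
incomplete beta function). The single free parameter m is estimated by
nonlinear least squares against observed occurrence frequencies; per-taxon
classification compares the observed frequency with a Wilson score band around
the prediction.

``detection="reads"`` replaces the hard threshold with the exact probability of
seeing at least ``min_reads`` reads when ``depth`` reads are drawn
multinomially from the Beta-distributed composition (a beta-binomial tail).
This matters when N·m is not small relative to the read depth, where the hard
threshold underestimates the sampling dispersion; the fit is still ordinary
least squares on occurrence frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import betainc, betaln, gammaln
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "Z95",
    "predicted_frequency",
    "read_detection_frequency",
    "wilson_interval",
    "prediction_band",
    "classify_taxon",
    "rmse",
    "NCMParams",
    "TaxonFit",
    "NCMFitResult",
    "NeutralCommunityModel",
    "fit_ncm",
]

#: two-sided 95% normal quantile used for Wilson score bands
Z95 = 1.959964

CLASS_ABOVE = "above"
CLASS_WITHIN = "within"
CLASS_BELOW = "below"


def _check_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def predicted_frequency(p, N: float, m: float, d: float):
    """Predicted occurrence frequency of taxa with pool abundance ``p``.

    ``1 - I_d(N m p, N m (1 - p))``: the probability that a Beta-distributed
    local relative abundance exceeds the detection limit ``d``.

    Accepts a scalar or array ``p`` with ``0 < p < 1``.
    """
    _check_positive("N", N)
    _check_positive("m", m)
    if m > 1:
        raise ValueError(f"m must be in (0, 1], got {m!r}")
    if not (0 < d < 1):
        raise ValueError(f"detection limit d must be in (0, 1), got {d!r}")
    p_arr = np.asarray(p, dtype=float)
    if not np.isfinite(p_arr).all():
        raise ValueError("p must be finite")
    if ((p_arr <= 0) | (p_arr >= 1)).any():
        raise ValueError("p must be strictly inside (0, 1); boundary values have undefined beta parameters")
    nm = N * m
    out = 1.0 - betainc(nm * p_arr, nm * (1.0 - p_arr), d)
    return float(out) if np.isscalar(p) else out


def read_detection_frequency(p, N: float, m: float, depth: int, min_reads: int = 1):
    """Exact detection probability under multinomial read sampling.

    Probability of observing at least ``min_reads`` reads of a taxon when
    ``depth`` reads are drawn from a composition whose marginal is
    ``Beta(N m p, N m (1 - p))`` — i.e. one minus a beta-binomial CDF. Used as
    a read-sampling-aware alternative to the hard detection threshold.
    """
    _check_positive("N", N)
    _check_positive("m", m)
    if m > 1:
        raise ValueError(f"m must be in (0, 1], got {m!r}")
    depth = int(depth)
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr <= 0) | (p_arr >= 1)).any() or not np.isfinite(p_arr).all():
        raise ValueError("p must be strictly inside (0, 1)")
    a = N * m * p_arr
    b = N * m * (1.0 - p_arr)
    # P(count = j) = C(depth, j) * B(a + j, b + depth - j) / B(a, b)
    log_cdf_terms = []
    for j in range(min_reads):
        log_choose = gammaln(depth + 1) - gammaln(j + 1) - gammaln(depth - j + 1)
        log_cdf_terms.append(log_choose + betaln(a + j, b + depth - j) - betaln(a, b))
    stacked = np.stack([np.broadcast_to(t, p_arr.shape) for t in log_cdf_terms])
    cdf = np.exp(stacked).sum(axis=0)
    out = np.clip(1.0 - cdf, 0.0, 1.0)
    return float(out) if np.isscalar(p) else out


def wilson_interval(phat, n: int, z: float = Z95):
    """Wilson score confidence interval for a binomial proportion.

    Returns ``(lower, upper)``; vectorised over ``phat``.
    """
    if n <= 0:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    ph = np.asarray(phat, dtype=float)
    if ((ph < 0) | (ph > 1)).any() or not np.isfinite(ph).all():
        raise ValueError("phat must lie in [0, 1]")
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = (ph + z2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(ph * (1 - ph) / n + z2 / (4 * n * n))
    lower = np.clip(centre - half, 0.0, 1.0)
    upper = np.clip(centre + half, 0.0, 1.0)
    # exact at the boundaries and guaranteed to contain phat (the closed form
    # cancels catastrophically for extreme phat, leaving epsilon residues)
    lower = np.where(ph == 0.0, 0.0, np.minimum(lower, ph))
    upper = np.where(ph == 1.0, 1.0, np.maximum(upper, ph))
    if np.isscalar(phat):
        return float(lower), float(upper)
    return lower, upper


def prediction_band(predicted, n: int, z: float = Z95):
    """Acceptance band around a predicted frequency for classifying taxa.

    The score-test acceptance region ``predicted ± z * sqrt(predicted (1 -
    predicted) / n)`` clipped to [0, 1]. By the Wilson duality this contains an
    observed frequency exactly when the prediction falls inside the Wilson
    score interval of that observed frequency, so the band is calibrated: a
    truly neutral taxon lands outside it with probability about ``2(1 -
    Phi(z))``. (A Wilson interval *centred on the prediction* is not a
    calibrated band — near saturation its upper limit sits below 1 while the
    observed frequency has an atom at exactly 1.)
    """
    if n <= 0:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    pred = np.asarray(predicted, dtype=float)
    if ((pred < 0) | (pred > 1)).any() or not np.isfinite(pred).all():
        raise ValueError("predicted must lie in [0, 1]")
    half = z * np.sqrt(pred * (1 - pred) / n)
    lower = np.clip(pred - half, 0.0, 1.0)
    upper = np.clip(pred + half, 0.0, 1.0)
    if np.isscalar(predicted):
        return float(lower), float(upper)
    return lower, upper


def classify_taxon(observed: float, lower: float, upper: float) -> str:
    """Classify an observed frequency against a prediction band.

    Boundary ties resolve to ``"within"`` (conservative toward neutrality).
    """
    if lower > upper:
        raise ValueError(f"lower ({lower}) must not exceed upper ({upper})")
    if observed > upper:
        return CLASS_ABOVE
    if observed < lower:
        return CLASS_BELOW
    return CLASS_WITHIN


def _classify_array(observed: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    out = np.full(observed.shape, CLASS_WITHIN, dtype=object)
    out[observed > upper] = CLASS_ABOVE
    out[observed < lower] = CLASS_BELOW
    return out


def rmse(observed, predicted) -> float:
    """Root mean squared difference between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("rmse requires at least one value")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass(frozen=True)
class NCMParams:
    """Fitted/fixed model parameters.

    N: local community size (by convention the mean read depth of the fitted
    samples unless overridden); m: per-capita immigration probability;
    d: detection limit on relative abundance.
    """

    N: float
    m: float
    d: float

    def __post_init__(self) -> None:
        _check_positive("N", self.N)
        if not (0 < self.m <= 1):
            raise ValueError(f"m must be in (0, 1], got {self.m!r}")
        if not (0 < self.d < 1):
            raise ValueError(f"d must be in (0, 1), got {self.d!r}")

    @property
    def nm(self) -> float:
        return self.N * self.m


@dataclass(frozen=True)
class TaxonFit:
    taxon_id: str
    p: float
    observed_freq: float
    predicted_freq: float
    ci_lower: float
    ci_upper: float
    classification: str


@dataclass(frozen=True)
class NCMFitResult:
    """Result of a single neutral-model fit."""

    params: NCMParams
    taxa: tuple[TaxonFit, ...]
    rmse: float
    n_samples: int
    n_taxa_fit: int
    converged: bool
    detection: str = "threshold"
    depth: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "taxon_id": t.taxon_id,
                    "p": t.p,
                    "observed_freq": t.observed_freq,
                    "predicted_freq": t.predicted_freq,
                    "ci_lower": t.ci_lower,
                    "ci_upper": t.ci_upper,
                    "classification": t.classification,
                }
                for t in self.taxa
            ]
        )

    def classification_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {CLASS_ABOVE: set(), CLASS_WITHIN: set(), CLASS_BELOW: set()}
        for t in self.taxa:
            out[t.classification].add(t.taxon_id)
        return out


class NeutralCommunityModel(RegressorMixin, BaseEstimator):
    """Single-parameter Sloan neutral community model.

    scikit-learn-style estimator: ``X`` is a column of regional-pool relative
    abundances (shape ``(n_taxa, 1)`` or ``(n_taxa,)``), ``y`` the observed
    occurrence frequencies. ``fit`` estimates the immigration probability ``m``
    by bounded nonlinear least squares, initialised from the best point of a
    log-spaced grid of ``N·m`` values (the objective can be nearly flat, so the
    grid avoids stalls far from the optimum).

    Parameters
    ----------
    N : float
        Local community size; fixed during the fit (conventionally the mean
        read depth of the fitted samples).
    d : float, optional
        Detection limit on relative abundance; defaults to ``1/N``.
    detection : {"threshold", "reads"}
        "threshold": hard detection limit ``d`` on the Beta abundance
        distribution (the classical form). "reads": exact beta-binomial
        detection given ``depth`` reads and ``min_reads_detect``.
    depth : int, optional
        Read depth, required for ``detection="reads"``.
    min_reads_detect : int
        Reads needed to call a taxon present (used by ``detection="reads"``).
    n_obs : int, optional
        Number of samples behind each observed frequency; enables Wilson score
        bands on the predictions (`ci_lower_`, `ci_upper_`, `classification_`).
    confidence_z : float
        Normal quantile for the Wilson band (default two-sided 95%).
    grid : tuple (lo, hi, n)
        Log-spaced initialisation grid of N·m values.
    m_bounds : tuple
        Box constraints on m for the refinement step.

    Attributes
    ----------
    m_ : float
        Fitted immigration probability.
    nm_ : float
        ``N * m_``.
    rmse_ : float
        Root mean squared residual at the optimum.
    converged_ : bool
        Whether the bounded least-squares refinement reported success; when
        False, ``m_`` is the best grid point.
    """

    def __init__(
        self,
        N: float | None = None,
        d: float | None = None,
        detection: str = "threshold",
        depth: int | None = None,
        min_reads_detect: int = 1,
        n_obs: int | None = None,
        confidence_z: float = Z95,
        grid: tuple[float, float, int] = (1e-1, 1e6, 25),
        m_bounds: tuple[float, float] = (1e-9, 1.0),
    ) -> None:
        self.N = N
        self.d = d
        self.detection = detection
        self.depth = depth
        self.min_reads_detect = min_reads_detect
        self.n_obs = n_obs
        self.confidence_z = confidence_z
        self.grid = grid
        self.m_bounds = m_bounds

    # -- internal ----------------------------------------------------------
    def _resolved(self) -> tuple[float, float]:
        if self.N is None:
            raise ValueError("N must be set before fitting (e.g. mean read depth)")
        _check_positive("N", self.N)
        d = self.d if self.d is not None else 1.0 / self.N
        if not (0 < d < 1):
            raise ValueError(f"detection limit d must be in (0, 1), got {d!r}")
        if self.detection not in ("threshold", "reads"):
            raise ValueError(f"unknown detection model {self.detection!r}")
        if self.detection == "reads" and self.depth is None:
            raise ValueError('detection="reads" requires depth')
        return float(self.N), float(d)

    def _curve(self, p: np.ndarray, m: float, d: float) -> np.ndarray:
        if self.detection == "reads":
            return read_detection_frequency(p, self.N, m, self.depth, self.min_reads_detect)
        return predicted_frequency(p, self.N, m, d)

    @staticmethod
    def _as_p(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("X must be a single column of pool abundances")
            arr = arr[:, 0]
        elif arr.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        return arr

    # -- API ---------------------------------------------------------------
    def fit(self, X, y):
        N, d = self._resolved()
        p = self._as_p(X)
        y = np.asarray(y, dtype=float)
        if y.shape != p.shape:
            raise ValueError("X and y have mismatched lengths")
        if not np.isfinite(p).all() or not np.isfinite(y).all():
            raise ValueError("X and y must be finite")
        if ((y < 0) | (y > 1)).any():
            raise ValueError("observed frequencies must lie in [0, 1]")
        eligible = (p > 0) & (p < 1)
        n_fit = int(eligible.sum())
        if n_fit < 5:
            raise ValueError(
                f"need at least 5 taxa with pool abundance in (0, 1) to fit, got {n_fit}"
            )
        p_fit, y_fit = p[eligible], y[eligible]

        lo, hi, n_grid = self.grid
        m_lo, m_hi = self.m_bounds
        m_grid = np.unique(np.clip(np.geomspace(lo, hi, int(n_grid)) / N, m_lo, m_hi))
        sse = np.array(
            [np.sum((y_fit - self._curve(p_fit, mm, d)) ** 2) for mm in m_grid]
        )
        m0 = float(m_grid[int(np.argmin(sse))])

        def resid(theta: np.ndarray) -> np.ndarray:
            return y_fit - self._curve(p_fit, float(theta[0]), d)

        result = least_squares(resid, [m0], bounds=(m_lo, m_hi), method="trf")
        if result.success:
            self.m_ = float(result.x[0])
            self.converged_ = True
        else:
            self.m_ = m0
            self.converged_ = False
        self.nm_ = N * self.m_
        self.d_ = d
        self.eligible_ = eligible
        self.n_taxa_fit_ = n_fit
        self.predicted_ = self._curve(p_fit, self.m_, d)
        self.rmse_ = rmse(y_fit, self.predicted_)
        if self.n_obs is not None:
            self.ci_lower_, self.ci_upper_ = prediction_band(
                self.predicted_, self.n_obs, self.confidence_z
            )
            self.classification_ = _classify_array(y_fit, self.ci_lower_, self.ci_upper_)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "m_"):
            raise ValueError("estimator is not fitted; call fit first")
        p = self._as_p(X)
        return self._curve(p, self.m_, self.d_)


def fit_ncm(
    pool,
    observed_freq,
    N: float,
    d: float | None = None,
    confidence_z: float = Z95,
    n_obs: int | None = None,
    detection: str = "threshold",
    depth: int | None = None,
    min_reads_detect: int = 1,
    grid: tuple[float, float, int] = (1e-1, 1e6, 25),
) -> NCMFitResult:
    """Fit the neutral model to a source pool and observed occurrence frequencies.

    Taxa with pool abundance 0 (or 1) are excluded from the fit; at least five
    eligible taxa are required. ``n_obs`` (the number of samples behind the
    observed frequencies) defaults to ``pool.n_samples_pooled`` and sets the
    Wilson band width for per-taxon classification.
    """
    if n_obs is None:
        n_obs = pool.n_samples_pooled
    est = NeutralCommunityModel(
        N=N,
        d=d,
        detection=detection,
        depth=depth,
        min_reads_detect=min_reads_detect,
        n_obs=n_obs,
        confidence_z=confidence_z,
        grid=grid,
    ).fit(np.asarray(pool.p), np.asarray(observed_freq, dtype=float))

    taxa = []
    idx = np.flatnonzero(est.eligible_)
    obs = np.asarray(observed_freq, dtype=float)
    for k, i in enumerate(idx):
        taxa.append(
            TaxonFit(
                taxon_id=pool.taxon_ids[i],
                p=float(pool.p[i]),
                observed_freq=float(obs[i]),
                predicted_freq=float(est.predicted_[k]),
                ci_lower=float(est.ci_lower_[k]),
                ci_upper=float(est.ci_upper_[k]),
                classification=str(est.classification_[k]),
            )
        )
    return NCMFitResult(
        params=NCMParams(N=float(N), m=est.m_, d=est.d_),
        taxa=tuple(taxa),
        rmse=est.rmse_,
        n_samples=int(n_obs),
        n_taxa_fit=est.n_taxa_fit_,
        converged=est.converged_,
        detection=detection,
        depth=depth,
    )
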