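"""The three K-extraction strategies and mixed-population deconvolution.

* **direct**: invert the calibrated response surface per event; sensitive to
  contour noise (the surface is a steep power law in D) but resolves
  heterogeneity.
* **collective**: regress deformation on relative area across the whole
  population and convert the slope via the slope law; noise in individual
  contours averages out in the regression, so the estimate is robust.
* **combined**: per-event direct moduli -> Gaussian mixture on ln K ->
  discard the lowest-modulus component (doublets and missegmented contours
  deform more, hence masquerade as anomalously soft vesicles) -> collective
  refit on the survivors.

Because the direct surface is a convex power law in D, averaging per-event
moduli and converting the averaged slope give systematically different
numbers (Jensen's inequality); the collective route is the statistically
less biased one and is what the combined method reports.

Measurement noise is multiplicative on the non-negative deformation, hence
approximately lognormal, which is why mixtures are modelled on ln K with
Gaussian components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .calibration import DEFAULT_CALIBRATION, Calibration, linear_fit
from .errors import EstimationError
from .scaling import ChannelSetup, dim_K, nondim_area
from . import scaling

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureModel",
    "PopulationEstimate",
    "CombinedResult",
    "direct_K",
    "forward_D",
    "collective_K",
    "fit_lnK_mixture",
    "classify",
    "direct_aggregate",
    "combined_K",
]


def _as_arrays(area_um, deform):
    a = np.atleast_1d(np.asarray(area_um, dtype=float))
    d = np.atleast_1d(np.asarray(deform, dtype=float))
    if a.shape != d.shape:
        raise ValueError("area and deformation arrays must have the same shape")
    return a, d


def direct_K(
    deform,
    area_um,
    setup: ChannelSetup,
    calib: Calibration = DEFAULT_CALIBRATION,
    warn_validity: bool = True,
):
    """Per-event area expansion modulus in N/m from (D, A).

    Scalar inputs with D <= 0 raise (the power law is undefined there);
    in arrays such events yield NaN with a logged count.  Events outside the
    calibration validity range are flagged with a warning, not rejected.
    """
    scalar = np.isscalar(deform) and np.isscalar(area_um)
    a, d = _as_arrays(area_um, deform)
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    bad = d <= 0
    if scalar and bad.any():
        raise EstimationError("deformation must be > 0 for direct fitting")
    if bad.any():
        logger.info("direct fit: %d events with D <= 0 set to NaN", int(bad.sum()))
    ahat = nondim_area(a, setup)
    if warn_validity:
        valid = calib.in_validity(d[~bad], ahat[~bad])
        if not valid.all():
            logger.warning(
                "direct fit: %d of %d events outside calibration validity",
                int((~valid).sum()),
                valid.size,
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        khat = calib.khat_direct(np.where(bad, np.nan, d), ahat)
    k = dim_K(khat, setup)
    return float(k[0]) if scalar else k


def forward_D(
    K,
    area_um,
    setup: ChannelSetup,
    calib: Calibration = DEFAULT_CALIBRATION,
):
    """Stationary deformation predicted for a vesicle of modulus K (N/m).

    Exact algebraic inverse of :func:`direct_K`: monotone decreasing in K
    (stiff vesicles stay round) and increasing in area over the calibrated
    domain (larger, softer vesicles are more stretched).
    """
    k = np.atleast_1d(np.asarray(K, dtype=float))
    a = np.atleast_1d(np.asarray(area_um, dtype=float))
    if np.any(k <= 0) or np.any(a <= 0):
        raise ValueError("K and area must be positive")
    khat = scaling.nondim_K(k, setup)
    ahat = nondim_area(a, setup)
    d = calib.deform_direct(khat, ahat)
    scalar = np.isscalar(K) and np.isscalar(area_um)
    return float(d[0]) if scalar else d


@dataclass(frozen=True)
class MixtureModel:
    """Gaussian mixture on ln K, components sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray  # on ln K (K in N/m)
    sigmas: np.ndarray
    log_likelihood: float
    seed: int
    converged: bool = True
    variance_floored: bool = False
    ll_trace: tuple[float, ...] = ()

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def component_K(self) -> np.ndarray:
        """exp(mean) per component — geometric-mean modulus in N/m."""
        return np.exp(self.means)

    def log_responsibilities(self, ln_k) -> np.ndarray:
        """(n_components, n) matrix of log posterior responsibilities."""
        x = np.atleast_1d(np.asarray(ln_k, dtype=float))
        logp = (
            np.log(self.weights)[:, None]
            - 0.5 * math.log(2 * math.pi)
            - np.log(self.sigmas)[:, None]
            - 0.5 * ((x[None, :] - self.means[:, None]) / self.sigmas[:, None]) ** 2
        )
        return logp - logsumexp(logp, axis=0, keepdims=True)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means_lnK": self.means.tolist(),
            "sigmas": self.sigmas.tolist(),
            "component_K_N_per_m": self.component_K.tolist(),
            "log_likelihood": self.log_likelihood,
            "seed": self.seed,
            "converged": self.converged,
            "variance_floored": self.variance_floored,
        }


def _em_run(x, mu, sigma, w, tol, max_iter, var_floor):
    """One EM run on 1-D data; returns params, ll trace, flags."""
    n = x.size
    trace = []
    ll_prev = -np.inf
    floored = False
    converged = False
    for _ in range(max_iter):
        logp = (
            np.log(w)[:, None]
            - 0.5 * math.log(2 * math.pi)
            - np.log(sigma)[:, None]
            - 0.5 * ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2
        )
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(logp - norm[None, :])
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp @ x) / nk
        var = np.array(
            [np.dot(resp[k], (x - mu[k]) ** 2) / nk[k] for k in range(len(mu))]
        )
        if np.any(var < var_floor):
            floored = True
            var = np.maximum(var, var_floor)
        sigma = np.sqrt(var)
        if ll - ll_prev < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
    return w, mu, sigma, trace, converged, floored


def fit_lnK_mixture(
    k_values,
    n_components: int = 2,
    *,
    seed: int,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = 1e-6,
) -> MixtureModel:
    """Maximum-likelihood Gaussian mixture on ln K via EM.

    Initialization is quantile-based (component means at evenly spaced
    sample quantiles) with seeded jitter across restarts; the best
    log-likelihood wins.  The per-iteration log-likelihood is non-decreasing
    (EM guarantee; exposed via ``ll_trace`` of the winning run).  Vanishing
    component variances are floored at ``var_floor`` and flagged.
    """
    k = np.asarray(k_values, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if k.size < 10 * n_components:
        raise EstimationError(
            f"mixture fit needs >= {10 * n_components} finite positive K values"
        )
    x = np.log(k)
    rng = np.random.default_rng(seed)
    std = float(np.std(x)) or 1.0
    q = np.quantile(x, (np.arange(n_components) + 0.5) / n_components)
    best = None
    for restart in range(n_restarts):
        mu = q.copy()
        if restart > 0:
            mu = mu + rng.normal(0.0, std / (2 * n_components), size=n_components)
        sigma = np.full(n_components, max(std / n_components, math.sqrt(var_floor)))
        w = np.full(n_components, 1.0 / n_components)
        out = _em_run(x, mu, sigma, w, tol, max_iter, var_floor)
        if best is None or out[3][-1] > best[3][-1]:
            best = out
    w, mu, sigma, trace, converged, floored = best
    order = np.argsort(mu)
    model = MixtureModel(
        weights=w[order],
        means=mu[order],
        sigmas=sigma[order],
        log_likelihood=trace[-1],
        seed=seed,
        converged=converged,
        variance_floored=floored,
        ll_trace=tuple(trace),
    )
    if floored:
        logger.warning("mixture fit: a component variance was floored at %g", var_floor)
    return model


def classify(k_values, model: MixtureModel) -> np.ndarray:
    """Hard component assignment per event (argmax posterior responsibility).

    Posterior ties break deterministically to the lower-index (lower-mean)
    component.  Component 0 — the lowest mean — is the outlier class:
    spuriously high deformations (doublets, bad contours) map to spuriously
    low moduli.
    """
    k = np.asarray(k_values, dtype=float)
    logr = model.log_responsibilities(np.log(k))
    return np.argmax(logr, axis=0)


def direct_aggregate(k_values, model: MixtureModel | None = None, *, seed=None,
                     n_components: int = 2) -> float:
    """Population modulus from the dominant mixture component.

    Returns exp(mu) of the highest-weight non-outlier component — the
    geometric-mean convention for a lognormal population.  Fits a mixture
    first when none is supplied (``seed`` then required).
    """
    if model is None:
        if seed is None:
            raise ValueError("seed required when fitting the mixture here")
        model = fit_lnK_mixture(k_values, n_components, seed=seed)
    if model.n_components == 1:
        return float(np.exp(model.means[0]))
    idx = 1 + int(np.argmax(model.weights[1:]))
    return float(np.exp(model.means[idx]))


@dataclass(frozen=True)
class PopulationEstimate:
    """A population-level modulus estimate with method tag and diagnostics."""

    K: float  # N/m
    method: str  # direct-aggregate | collective | combined
    n_used: int
    n_rejected: int = 0
    slope_nd: float | None = None  # dD/dA_hat of the area-deformation fit
    intercept: float | None = None
    component: int | None = None  # mixture class for combined estimates
    mixture: MixtureModel | None = None

    def to_dict(self) -> dict:
        d = {
            "K_N_per_m": self.K,
            "method": self.method,
            "n_used": self.n_used,
            "n_rejected": self.n_rejected,
        }
        if self.slope_nd is not None:
            d["slope_nd"] = self.slope_nd
            d["intercept"] = self.intercept
        if self.component is not None:
            d["component"] = self.component
        if self.mixture is not None:
            d["mixture"] = self.mixture.to_dict()
        return d


def collective_K(
    area_um,
    deform,
    setup: ChannelSetup,
    calib: Calibration = DEFAULT_CALIBRATION,
    *,
    n_rejected: int = 0,
    method: str = "collective",
    component: int | None = None,
    mixture: MixtureModel | None = None,
) -> PopulationEstimate:
    """Population modulus from the slope of the area-deformation regression.

    OLS with free intercept of D on A_hat; the slope converts to K_hat via
    the slope law.  A non-positive slope cannot be converted (the power law
    is undefined) and raises :class:`EstimationError`.
    """
    a, d = _as_arrays(area_um, deform)
    if a.size < 2:
        raise EstimationError("collective fit needs >= 2 events")
    ahat = nondim_area(a, setup)
    fit = linear_fit(ahat, d)
    if fit.slope <= 0:
        raise EstimationError(
            f"collective fit: non-positive area-deformation slope ({fit.slope:g})"
        )
    k = dim_K(calib.khat_from_slope(fit.slope), setup)
    return PopulationEstimate(
        K=float(k),
        method=method,
        n_used=int(a.size),
        n_rejected=n_rejected,
        slope_nd=fit.slope,
        intercept=fit.intercept,
        component=component,
        mixture=mixture,
    )


@dataclass(frozen=True)
class CombinedResult:
    """Outcome of the combined (GMM-filtered collective) pipeline."""

    estimates: tuple[PopulationEstimate, ...]
    mixture: MixtureModel
    assignments: np.ndarray  # component per finite-D event
    n_outliers: int
    n_undefined: int  # events with D <= 0, excluded before mixture fitting

    @property
    def K(self) -> float:
        """Modulus of the largest retained class (convenience accessor)."""
        return max(self.estimates, key=lambda e: e.n_used).K


def combined_K(
    area_um,
    deform,
    setup: ChannelSetup,
    calib: Calibration = DEFAULT_CALIBRATION,
    n_components: int = 2,
    *,
    seed: int,
    **mixture_kwargs,
) -> CombinedResult:
    """Direct fit -> mixture on ln K -> drop outlier class -> collective refit.

    With ``n_components = 2`` a single estimate is returned; with 3 (mixed
    populations of two vesicle types plus outliers) one estimate per
    retained class.  Any stage failure propagates with a stage label.
    """
    a, d = _as_arrays(area_um, deform)
    defined = d > 0
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.info("combined fit: %d events with D <= 0 excluded", n_undefined)
    a, d = a[defined], d[defined]
    try:
        k_event = direct_K(d, a, setup, calib, warn_validity=False)
    except Exception as exc:  # pragma: no cover - direct_K validates inputs
        raise EstimationError(f"combined fit failed at stage 'direct': {exc}") from exc
    try:
        model = fit_lnK_mixture(k_event, n_components, seed=seed, **mixture_kwargs)
    except EstimationError as exc:
        raise EstimationError(f"combined fit failed at stage 'mixture': {exc}") from exc
    labels = classify(k_event, model)
    n_outliers = int((labels == 0).sum()) if n_components > 1 else 0
    estimates = []
    classes = range(1, n_components) if n_components > 1 else [0]
    for c in classes:
        mask = labels == c
        if mask.sum() < 2:
            logger.warning("combined fit: class %d has <2 events; skipped", c)
            continue
        try:
            est = collective_K(
                a[mask],
                d[mask],
                setup,
                calib,
                n_rejected=n_outliers + n_undefined,
                method="combined",
                component=c,
                mixture=model,
            )
        except EstimationError as exc:
            raise EstimationError(
                f"combined fit failed at stage 'collective' (class {c}): {exc}"
            ) from exc
        estimates.append(est)
    if not estimates:
        raise EstimationError("combined fit: no retained class had enough events")
    return CombinedResult(
        estimates=tuple(estimates),
        mixture=model,
        assignments=labels,
        n_outliers=n_outliers,
        n_undefined=n_undefined,
    )
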