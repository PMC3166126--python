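"""Gaussian models of particle-spacing distributions.

Connection-distance samples are summarized as one- or two-component
Gaussian models reported as center +- HWHM (half width at half maximum,
HWHM = sigma * sqrt(2 ln 2)), the convention used for spacing tables in
quantitative immunogold work.

Two fitting routes are provided:

``histogram_least_squares``
    Nonlinear least squares of a sum of Gaussians against the 1-nm-binned
    histogram — the classic curve-fitting workflow (fityk-style).
``mixture_likelihood``
    Maximum likelihood for a (truncated) Gaussian mixture on the unbinned
    distances.  Truncation matters because connection distances are
    bounded by the pair-type cutoff; ignoring it biases centers downward
    near the cutoff.  An optional random-pair background component
    (distance density proportional to r^2, the null for uniformly
    scattered particles) absorbs coincidental cross-assembly pairs; its
    weight can be fitted or fixed from the expected complete-spatial-
    randomness pair count.
``windowed_peak``
    Iteratively window-refined histogram Gaussian fit: find the dominant
    histogram peak, fit a single Gaussian within ~1.5 FWHM of it, and
    re-center the window.  Robust to contamination far from the peak
    (neighboring spacing multiples leaking through the cutoff) at the
    cost of only ever modeling one component.

All methods are deterministic given the seed (multi-start initialization
from distance quantiles plus seeded jitter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator

_HWHM_PER_SIGMA = math.sqrt(2.0 * math.log(2.0))

MIN_DISTANCES = 10


def hwhm_to_sigma(hwhm: float) -> float:
    """Convert half width at half maximum to the Gaussian sigma."""
    return hwhm / _HWHM_PER_SIGMA


def sigma_to_hwhm(sigma: float) -> float:
    """Convert a Gaussian sigma to half width at half maximum."""
    return sigma * _HWHM_PER_SIGMA


class FitError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


@dataclass
class GaussianComponent:
    center: float
    hwhm: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError("hwhm must be > 0")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must be in (0, 1]")

    @property
    def sigma(self) -> float:
        return hwhm_to_sigma(self.hwhm)


@dataclass
class SpacingModel:
    """Fitted spacing distribution for one pair type.

    ``background_weight`` is the fraction of distances attributed to the
    random-pair background (pair-distance density proportional to r^2 up
    to the cutoff); the Gaussian component weights are normalized over
    the structured part only.
    """

    components: list
    n_distances: int
    fit_loss: float
    method: str
    pair_type: str | None = None
    truncation: tuple | None = None
    background_weight: float = 0.0

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c.center)
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            for c in self.components:
                c.weight /= total

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.components])

    @property
    def hwhms(self) -> np.ndarray:
        return np.array([c.hwhm for c in self.components])

    def to_dict(self) -> dict:
        return {
            "pair_type": self.pair_type,
            "method": self.method,
            "n_distances": self.n_distances,
            "fit_loss": self.fit_loss,
            "truncation": list(self.truncation) if self.truncation else None,
            "background_weight": self.background_weight,
            "components": [{"center": c.center, "hwhm": c.hwhm, "weight": c.weight}
                           for c in self.components],
        }


def _trunc_log_pdf(x: np.ndarray, mu: float, sigma: float,
                   bounds: tuple | None) -> np.ndarray:
    lp = norm.logpdf(x, mu, sigma)
    if bounds is not None:
        a, b = bounds
        z = norm.cdf(b, mu, sigma) - norm.cdf(a, mu, sigma)
        lp = lp - math.log(max(z, 1e-300))
    return lp


def _nll(x: np.ndarray, weights, mus, sigmas, bounds,
         bg_weight: float = 0.0) -> float:
    """Negative log likelihood of a (truncated) Gaussian mixture with an
    optional random-pair background whose density is 3 r^2 / c^3 on
    (0, c) — the null for uniformly scattered particles."""
    scale = 1.0 - bg_weight
    comps = [math.log(max(w * scale, 1e-300)) + _trunc_log_pdf(x, m, s, bounds)
             for w, m, s in zip(weights, mus, sigmas)]
    if bg_weight > 0.0:
        c = bounds[1]
        comps.append(math.log(bg_weight)
                     + np.log(3.0 * np.maximum(x, 1e-12) ** 2 / c ** 3))
    return float(-np.sum(logsumexp(np.stack(comps), axis=0)))


class SpacingGaussianFit(BaseEstimator):
    """Fit a 1- or 2-component Gaussian spacing model to distances.

    Parameters
    ----------
    n_components : 1 or 2.
    method : 'histogram_least_squares' (default) or 'mixture_likelihood'.
    bin_width : histogram bin width in nm (histogram method only).
    truncation : (lo, hi) support bounds for the likelihood method, e.g.
        (0, cutoff); None fits an untruncated mixture.
    seed : seed for the multi-start jitter of the likelihood method.

    After :meth:`fit`: ``components_`` (sorted by center, weights sum
    to 1), ``loss_`` (residual sum of squares, or negative log
    likelihood), ``n_distances_``.
    """

    def __init__(self, n_components: int = 1, method: str = "histogram_least_squares",
                 bin_width: float = 1.0, truncation: tuple | None = None,
                 background: bool = False,
                 background_weight_fixed: float | None = None, seed: int = 1,
                 min_sigma: float = 0.05, max_restarts: int = 6,
                 peak_width_factor: float = 1.5, peak_iterations: int = 4):
        self.n_components = n_components
        self.method = method
        self.bin_width = bin_width
        self.truncation = truncation
        self.background = background
        self.background_weight_fixed = background_weight_fixed
        self.seed = seed
        self.min_sigma = min_sigma
        self.max_restarts = max_restarts
        self.peak_width_factor = peak_width_factor
        self.peak_iterations = peak_iterations

    # -- fitting ----------------------------------------------------------
    def fit(self, distances, y=None) -> "SpacingGaussianFit":
        x = np.sort(np.asarray(distances, dtype=float).ravel())
        if len(x) < MIN_DISTANCES:
            raise ValueError(f"need at least {MIN_DISTANCES} distances, got {len(x)}")
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if self.method not in ("histogram_least_squares", "mixture_likelihood",
                               "windowed_peak"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "windowed_peak" and self.n_components != 1:
            raise ValueError("windowed_peak fits a single component")

        self.n_distances_ = len(x)
        self.background_weight_ = 0.0
        if np.std(x) < 1e-9:
            # degenerate sample: all distances identical
            self.components_ = [GaussianComponent(float(x[0]),
                                                  sigma_to_hwhm(self.min_sigma), 1.0)]
            self.loss_ = 0.0
            return self

        if self.method == "histogram_least_squares":
            self._fit_histogram(x)
        elif self.method == "windowed_peak":
            self._fit_windowed_peak(x)
        else:
            self._fit_mixture(x)
        self.components_ = sorted(self.components_, key=lambda c: c.center)
        return self

    def _fit_histogram(self, x: np.ndarray) -> None:
        bw = self.bin_width
        edges = np.arange(0.0, x.max() + 2 * bw, bw)
        counts, edges = np.histogram(x, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2.0

        spread = max(float(np.std(x)), self.min_sigma)
        model, params = None, None
        if self.n_components == 1:
            inits = [(float(np.median(x)),)]
        else:
            inits = [(float(np.percentile(x, 25)), float(np.percentile(x, 75)))]
        mus = inits[0]
        for i, mu in enumerate(mus, start=1):
            g = GaussianModel(prefix=f"g{i}_")
            model = g if model is None else model + g
        params = model.make_params()
        for i, mu in enumerate(mus, start=1):
            params[f"g{i}_center"].set(value=mu, min=0.0, max=float(x.max()) + 3 * spread)
            params[f"g{i}_sigma"].set(value=spread / self.n_components,
                                      min=self.min_sigma, max=float(x.max()))
            params[f"g{i}_amplitude"].set(value=len(x) * bw / self.n_components,
                                          min=1e-9)
        result = model.fit(counts.astype(float), params, x=centers)
        if not result.success:
            raise FitError(f"histogram least-squares fit failed: {result.message}")
        areas = np.array([result.params[f"g{i}_amplitude"].value
                          for i in range(1, self.n_components + 1)])
        weights = areas / areas.sum()
        self.components_ = [
            GaussianComponent(center=float(result.params[f"g{i}_center"].value),
                              hwhm=sigma_to_hwhm(max(result.params[f"g{i}_sigma"].value,
                                                     self.min_sigma)),
                              weight=float(w))
            for i, w in zip(range(1, self.n_components + 1), weights)]
        self.loss_ = float(np.sum(result.residual ** 2))

    def _fit_windowed_peak(self, x: np.ndarray) -> None:
        """Iteratively window-refined single-Gaussian histogram fit."""
        bw = self.bin_width
        edges = np.arange(0.0, x.max() + 2 * bw, bw)
        counts, edges = np.histogram(x, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2.0
        smoothed = np.convolve(counts, [0.25, 0.5, 0.25], mode="same")
        c = float(centers[np.argmax(smoothed)])
        sigma, result = 2.0 * bw, None
        for _ in range(max(1, self.peak_iterations)):
            half = self.peak_width_factor * _HWHM_PER_SIGMA * sigma
            sel = (centers >= c - half) & (centers <= c + half)
            if sel.sum() < 4:
                half = 2.0 * bw
                sel = (centers >= c - half) & (centers <= c + half)
            g = GaussianModel()
            pars = g.make_params(center=c, sigma=max(sigma, 0.6 * bw),
                                 amplitude=max(float(counts[sel].sum()) * bw, 1.0))
            pars["center"].set(min=c - half, max=c + half)
            pars["sigma"].set(min=0.4 * bw, max=2.0 * half)
            result = g.fit(counts[sel].astype(float), pars, x=centers[sel])
            c = float(result.params["center"].value)
            sigma = float(result.params["sigma"].value)
        self.components_ = [GaussianComponent(c, sigma_to_hwhm(sigma), 1.0)]
        self.loss_ = float(np.sum(result.residual ** 2))

    def _mixture_starts(self, x: np.ndarray) -> list:
        rng = np.random.default_rng(self.seed)
        spread = max(float(np.std(x)), self.min_sigma)
        if self.n_components == 1:
            starts = [(float(np.mean(x)), spread),
                      (float(np.median(x)), spread / 2)]
            starts += [(float(np.mean(x)) + rng.normal(0, spread / 2),
                        spread * rng.uniform(0.5, 1.5))
                       for _ in range(self.max_restarts - len(starts))]
            return [(None, s) for s in starts]
        quantile_pairs = [(25, 75), (10, 90), (35, 65)]
        starts = [(0.5, (float(np.percentile(x, q1)), float(np.percentile(x, q2)),
                         spread / 2, spread / 2))
                  for q1, q2 in quantile_pairs]
        while len(starts) < self.max_restarts:
            q1, q2 = sorted(rng.uniform(5, 95, size=2))
            starts.append((rng.uniform(0.3, 0.7),
                           (float(np.percentile(x, q1)), float(np.percentile(x, q2)),
                            spread * rng.uniform(0.3, 1.0),
                            spread * rng.uniform(0.3, 1.0))))
        return starts

    def _fit_mixture(self, x: np.ndarray) -> None:
        bounds = self.truncation
        fixed_bg = self.background_weight_fixed
        if (self.background or fixed_bg) and (bounds is None or bounds[1] <= 0):
            raise ValueError("the background component requires a (0, cutoff) "
                             "truncation window")
        with_bg = self.background and fixed_bg is None

        def sigmoid(t):
            if t >= 0:
                return 1.0 / (1.0 + math.exp(-t))
            e = math.exp(t)
            return e / (1.0 + e)

        def unpack(theta):
            if self.n_components == 1:
                mu, ls = theta[0], theta[1]
                weights, mus = [1.0], [mu]
                sigmas = [max(math.exp(ls), self.min_sigma)]
                rest = theta[2:]
            else:
                lw, m1, m2, ls1, ls2 = theta[:5]
                w = min(max(sigmoid(lw), 1e-6), 1 - 1e-6)
                weights, mus = [w, 1 - w], [m1, m2]
                sigmas = [max(math.exp(ls1), self.min_sigma),
                          max(math.exp(ls2), self.min_sigma)]
                rest = theta[5:]
            if with_bg:
                bg = min(sigmoid(rest[0]), 0.95)
            elif fixed_bg is not None:
                bg = min(max(float(fixed_bg), 0.0), 0.95)
            else:
                bg = 0.0
            return weights, mus, sigmas, bg

        def nll(theta):
            weights, mus, sigmas, bg = unpack(theta)
            return _nll(x, weights, mus, sigmas, bounds, bg)

        bg0 = [math.log(0.15 / 0.85)] if with_bg else []
        best = None
        for w0, start in self._mixture_starts(x):
            if self.n_components == 1:
                mu0, s0 = start
                theta0 = [mu0, math.log(max(s0, self.min_sigma))] + bg0
            else:
                m1, m2, s1, s2 = start
                theta0 = [math.log(w0 / (1 - w0)), m1, m2,
                          math.log(max(s1, self.min_sigma)),
                          math.log(max(s2, self.min_sigma))] + bg0
            res = minimize(nll, theta0, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 6000})
            if res.fun == res.fun and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitError("mixture fit did not converge from any start")
        weights, mus, sigmas, bg = unpack(best.x)
        self.components_ = [
            GaussianComponent(float(m), sigma_to_hwhm(s), float(w))
            for w, m, s in zip(weights, mus, sigmas)]
        self.background_weight_ = float(bg)
        self.loss_ = float(best.fun)

    # -- reporting --------------------------------------------------------
    def bic(self) -> float:
        """Bayesian information criterion (likelihood-based fits only)."""
        if self.method != "mixture_likelihood":
            raise ValueError("BIC requires the mixture_likelihood method")
        k = 3 * len(self.components_) - 1 + (1 if self.background else 0)
        return 2.0 * self.loss_ + k * math.log(self.n_distances_)

    def model(self, pair_type: str | None = None) -> SpacingModel:
        return SpacingModel(components=[GaussianComponent(c.center, c.hwhm, c.weight)
                                        for c in self.components_],
                            n_distances=self.n_distances_, fit_loss=self.loss_,
                            method=self.method, pair_type=pair_type,
                            truncation=self.truncation,
                            background_weight=self.background_weight_)


def fit_spacing_model(distances, n_components: int = 1,
                      method: str = "histogram_least_squares",
                      seed: int = 1, truncation: tuple | None = None,
                      background: bool = False,
                      background_weight_fixed: float | None = None,
                      bin_width: float = 1.0,
                      pair_type: str | None = None) -> SpacingModel:
    """Fit a spacing model and return it (see :class:`SpacingGaussianFit`)."""
    est = SpacingGaussianFit(n_components=n_components, method=method,
                             bin_width=bin_width, truncation=truncation,
                             background=background,
                             background_weight_fixed=background_weight_fixed,
                             seed=seed)
    return est.fit(distances).model(pair_type=pair_type)


def select_n_components(distances, max_components: int = 2, seed: int = 1,
                        truncation: tuple | None = None,
                        background: bool = False,
                        forced: int | None = None) -> int:
    """Choose 1 or 2 components by BIC (or honor a forced count)."""
    if forced is not None:
        if forced not in (1, 2):
            raise ValueError("forced component count must be 1 or 2")
        return forced
    best_k, best_bic = 1, math.inf
    for k in range(1, max_components + 1):
        est = SpacingGaussianFit(n_components=k, method="mixture_likelihood",
                                 truncation=truncation, background=background,
                                 seed=seed)
        bic = est.fit(distances).bic()
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def spacing_multiple_report(models: dict) -> list:
    """Express every fitted center as a multiple of the basic repeat.

    ``models`` maps pair_type -> :class:`SpacingModel`; the reference
    repeat is the first (smallest) blue-blue center.  Each row reports
    the ratio center/reference and its deviation from the nearest
    multiple in {1, 2, 3} — dimers that skip one or two decoration sites
    double or triple the basic spacing.
    """
    if "blue_blue" not in models:
        raise ValueError("a fitted blue_blue model is required as the reference")
    ref = models["blue_blue"].components[0].center
    rows = []
    for pair_type, model in models.items():
        for idx, comp in enumerate(model.components):
            ratio = comp.center / ref
            nearest = min((1, 2, 3), key=lambda m: abs(ratio - m))
            rows.append({"pair_type": pair_type, "component": idx,
                         "center_nm": comp.center, "ratio": ratio,
                         "nearest_multiple": nearest,
                         "deviation": ratio - nearest})
    return rows
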