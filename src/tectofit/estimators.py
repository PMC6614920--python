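"""scikit-learn-style regressors for tectoRNA binding isotherms.

Three estimators share one fitting backend (bounded trust-region least
squares over log10 Kd, multi-started from log-spaced initial values):

* :class:`HomodimerIsothermRegressor` - gel-shift titrations, free or fixed
  active fraction beta;
* :class:`TwoStateCleavageRegressor` - lead-probing monomer-fraction curves,
  beta fixed at 1 with free monomer/dimer endpoint levels to absorb
  incomplete saturation of the concentration ladder;
* :class:`HeterodimerIsothermRegressor` - equimolar two-partner titrations.

All follow the estimator contract: parameters in ``__init__``, fitted
attributes with trailing underscores, ``fit(X, y)`` / ``predict(X)``, and
composability with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .thermo import heterodimer_fraction, homodimer_fraction

__all__ = [
    "HomodimerIsothermRegressor",
    "TwoStateCleavageRegressor",
    "HeterodimerIsothermRegressor",
]


def _as_conc_vector(X) -> np.ndarray:
    """Accept a 1-d concentration vector or an (n, 1) column."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError(f"expected 1 concentration feature, got shape {X.shape}")
    if not np.all(np.isfinite(X)) or not np.all(X > 0):
        raise ValueError("concentrations must be finite and > 0")
    return X


class _IsothermRegressorBase(RegressorMixin, BaseEstimator):
    """Shared multi-start bounded least-squares machinery."""

    def _check_xy(self, X, y, min_points: int, min_span: float = 1.0):
        M0 = _as_conc_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != M0.shape:
            raise ValueError("X and y must have matching lengths")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        if M0.size < min_points:
            raise ValueError(f"need at least {min_points} titration points")
        if M0.max() / M0.min() < min_span:
            raise ValueError(
                f"concentrations must span at least {min_span:g}-fold, "
                f"got {M0.max() / M0.min():.3g}-fold"
            )
        self.n_features_in_ = 1
        return M0, y

    def _multistart(self, residual, make_x0, kd_starts, bounds, tol, max_iter):
        """Run least_squares from each start; best RSS wins, ties -> lower Kd."""
        best = None
        for kd0 in kd_starts:
            res = least_squares(
                residual,
                x0=make_x0(np.log10(kd0)),
                bounds=bounds,
                xtol=tol,
                ftol=tol,
                gtol=None,
                max_nfev=max_iter,
            )
            key = (2.0 * res.cost, res.x[0])
            if best is None or key < best[0]:
                best = (key, res)
        return best[1]


class HomodimerIsothermRegressor(_IsothermRegressorBase):
    """Fit the homodimer isotherm fD(M0; Kd, beta) to gel-shift titrations.

    Parameters
    ----------
    fix_beta : float or None
        Fix the active fraction at this value instead of fitting it.
    detection_limit_nM : float
        Kd estimates below this are flagged ``below_detection_`` (the assay
        cannot resolve stronger binders; default 1 nM).
    no_assembly_max_fd : float
        When every observed fD stays under this level the series is flagged
        ``no_assembly_`` and Kd is reported as a lower bound at the highest
        tested concentration.
    kd_bounds_nM : (float, float)
        Box bounds on Kd during optimization.
    n_starts : int
        Number of log-spaced Kd starting values across the observed
        concentration range.
    tol, max_iter : float, int
        Optimizer termination tolerance and function-evaluation budget.

    Attributes
    ----------
    kd_nM_, beta_, rss_ : fitted parameters and residual sum of squares.
    converged_, below_detection_, no_assembly_, kd_is_bound_ : status flags.
    """

    def __init__(
        self,
        fix_beta=None,
        detection_limit_nM: float = 1.0,
        no_assembly_max_fd: float = 0.05,
        kd_bounds_nM=(1e-2, 1e8),
        n_starts: int = 5,
        tol: float = 1e-10,
        max_iter: int = 500,
    ):
        self.fix_beta = fix_beta
        self.detection_limit_nM = detection_limit_nM
        self.no_assembly_max_fd = no_assembly_max_fd
        self.kd_bounds_nM = kd_bounds_nM
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        M0, fD = self._check_xy(X, y, min_points=4, min_span=10.0)
        if self.fix_beta is not None and not 0 < self.fix_beta <= 1:
            raise ValueError(f"fix_beta must be in (0, 1], got {self.fix_beta}")

        self.no_assembly_ = bool(fD.max() < self.no_assembly_max_fd)
        self.kd_is_bound_ = False
        if self.no_assembly_:
            # No measurable dimer over the tested range: Kd exceeds the
            # highest concentration probed; report that as a lower bound.
            self.kd_nM_ = float(M0.max())
            self.kd_is_bound_ = True
            self.beta_ = float(self.fix_beta) if self.fix_beta else float("nan")
            self.rss_ = float(np.sum(fD**2))
            self.converged_ = True
            self.below_detection_ = False
            return self

        lo, hi = self.kd_bounds_nM
        beta0 = float(np.clip(fD.max(), 0.051, 1.0))
        if self.fix_beta is None:

            def residual(theta):
                kd, beta = 10.0 ** theta[0], theta[1]
                return homodimer_fraction(M0, kd, beta) - fD

            bounds = ([np.log10(lo), 1e-6], [np.log10(hi), 1.0])
            make_x0 = lambda logkd: [logkd, beta0]
        else:
            beta_fixed = float(self.fix_beta)

            def residual(theta):
                return homodimer_fraction(M0, 10.0 ** theta[0], beta_fixed) - fD

            bounds = ([np.log10(lo)], [np.log10(hi)])
            make_x0 = lambda logkd: [logkd]

        starts = np.geomspace(max(M0.min(), lo), min(M0.max(), hi), self.n_starts)
        res = self._multistart(residual, make_x0, starts, bounds, self.tol, self.max_iter)

        self.kd_nM_ = float(10.0 ** res.x[0])
        self.beta_ = float(res.x[1]) if self.fix_beta is None else float(self.fix_beta)
        self.rss_ = float(2.0 * res.cost)
        self.converged_ = bool(res.status > 0)
        self.below_detection_ = bool(self.kd_nM_ < self.detection_limit_nM)
        return self

    def predict(self, X):
        M0 = _as_conc_vector(X)
        return homodimer_fraction(M0, self.kd_nM_, self.beta_)


class TwoStateCleavageRegressor(_IsothermRegressorBase):
    """Fit a two-state assembly curve to lead-cleavage monomer fractions.

    The theoretical curve is fM = 1 - fD(M0; Kd, beta=1). Because the
    normalized monomer fraction anchors the *observed* extremes of the
    concentration ladder to 0 and 1 (a ladder that rarely saturates both
    states), the curve is fitted with free endpoint levels by default:

        fM_model = f_dimer + (f_mono - f_dimer) * (1 - fD(M0; Kd))

    which recovers the generating Kd exactly on noiseless data under any
    affine normalization. Set ``fit_endpoints=False`` for the bare
    one-parameter curve.

    Attributes
    ----------
    kd_nM_ : fitted dissociation constant.
    f_mono_, f_dimer_ : fitted full-monomer / full-dimer fM levels.
    rss_, converged_, noisy_, no_assembly_ : fit quality and status flags.
    """

    def __init__(
        self,
        fit_endpoints: bool = True,
        kd_bounds_nM=(1e-2, 1e8),
        n_starts: int = 5,
        noisy_rmse: float = 0.10,
        no_assembly_min_range: float = 0.05,
        tol: float = 1e-12,
        max_iter: int = 500,
    ):
        self.fit_endpoints = fit_endpoints
        self.kd_bounds_nM = kd_bounds_nM
        self.n_starts = n_starts
        self.noisy_rmse = noisy_rmse
        self.no_assembly_min_range = no_assembly_min_range
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        M0, fM = self._check_xy(X, y, min_points=4, min_span=1.0)

        self.no_assembly_ = bool(fM.max() - fM.min() < self.no_assembly_min_range)
        self.kd_is_bound_ = False
        if self.no_assembly_:
            # Flat monomer-only series: assembly, if any, occurs above the
            # tested range.
            self.kd_nM_ = float(M0.max())
            self.kd_is_bound_ = True
            self.f_mono_, self.f_dimer_ = float(fM.mean()), float("nan")
            self.rss_ = float(np.sum((fM - fM.mean()) ** 2))
            self.converged_ = True
            self.noisy_ = False
            return self

        lo, hi = self.kd_bounds_nM
        if self.fit_endpoints:

            def residual(theta):
                kd = 10.0 ** theta[0]
                fmono, fdim = theta[1], theta[2]
                return fdim + (fmono - fdim) * (1.0 - homodimer_fraction(M0, kd)) - fM

            bounds = (
                [np.log10(lo), 0.5, -0.5],
                [np.log10(hi), 1.5, 0.5],
            )
            make_x0 = lambda logkd: [logkd, 1.0, 0.0]
        else:

            def residual(theta):
                return 1.0 - homodimer_fraction(M0, 10.0 ** theta[0]) - fM

            bounds = ([np.log10(lo)], [np.log10(hi)])
            make_x0 = lambda logkd: [logkd]

        starts = np.geomspace(max(M0.min(), lo), min(M0.max(), hi), self.n_starts)
        res = self._multistart(residual, make_x0, starts, bounds, self.tol, self.max_iter)

        self.kd_nM_ = float(10.0 ** res.x[0])
        if self.fit_endpoints:
            self.f_mono_, self.f_dimer_ = float(res.x[1]), float(res.x[2])
        else:
            self.f_mono_, self.f_dimer_ = 1.0, 0.0
        self.rss_ = float(2.0 * res.cost)
        self.converged_ = bool(res.status > 0)
        self.noisy_ = bool(np.sqrt(self.rss_ / M0.size) > self.noisy_rmse)
        return self

    def predict(self, X):
        M0 = _as_conc_vector(X)
        curve = 1.0 - homodimer_fraction(M0, self.kd_nM_)
        return self.f_dimer_ + (self.f_mono_ - self.f_dimer_) * curve


class HeterodimerIsothermRegressor(_IsothermRegressorBase):
    """Fit A + B <=> AB with equimolar partners to dimerized fractions.

    ``X`` is the per-partner total concentration C (nM); ``y`` the fraction
    of each partner in the dimer.
    """

    def __init__(
        self,
        kd_bounds_nM=(1e-2, 1e8),
        n_starts: int = 5,
        tol: float = 1e-12,
        max_iter: int = 500,
    ):
        self.kd_bounds_nM = kd_bounds_nM
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        C, frac = self._check_xy(X, y, min_points=4, min_span=1.0)
        lo, hi = self.kd_bounds_nM

        def residual(theta):
            return heterodimer_fraction(C, 10.0 ** theta[0]) - frac

        bounds = ([np.log10(lo)], [np.log10(hi)])
        starts = np.geomspace(max(C.min(), lo), min(C.max(), hi), self.n_starts)
        res = self._multistart(
            residual, lambda logkd: [logkd], starts, bounds, self.tol, self.max_iter
        )
        self.kd_nM_ = float(10.0 ** res.x[0])
        self.rss_ = float(2.0 * res.cost)
        self.converged_ = bool(res.status > 0)
        return self

    def predict(self, X):
        C = _as_conc_vector(X)
        return heterodimer_fraction(C, self.kd_nM_)
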