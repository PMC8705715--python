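"""Smallest-worthwhile-change prescriber: the core fit/predict estimator.

The training-modulation rule is a two-window classifier calibrated per
individual. A baseline period of daily scores gives a mean m and sample SD s;
two symmetric smallest-worthwhile-change (SWC) windows are drawn around the
mean,

    SWC1 = [m - 0.5 s, m + 0.5 s]      no modification (FULL)
    SWC2 = [m - 1.0 s, m + 1.0 s]      between SWC1 and SWC2: REDUCED
                                        outside SWC2: RECOVERY

and each subsequent day the 7-day rolling average of the score is classified
into one of the three tiers. ``SWCPrescriber`` follows the scikit-learn
estimator protocol: ``fit`` on the baseline scores, ``predict`` on rolling
averages; it composes with ``sklearn.base.clone`` and ``get_params`` /
``set_params``.

Boundary ties go to the milder tier (|deviation| == 0.5 s -> FULL,
|deviation| == 1.0 s -> REDUCED). A degenerate baseline (SD exactly 0)
collapses both windows onto the mean; every day is then classified FULL and
the fitted estimator is flagged degenerate.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "FULL",
    "REDUCED",
    "RECOVERY",
    "SEVERITY",
    "classify_deviation",
    "SWCPrescriber",
]

FULL = "FULL"
REDUCED = "REDUCED"
RECOVERY = "RECOVERY"

#: ordering of prescriptions from mildest to most protective
SEVERITY = {FULL: 0, REDUCED: 1, RECOVERY: 2}


def classify_deviation(deviation, sd: float, swc1: float = 0.5, swc2: float = 1.0,
                       degenerate: bool = False):
    """Tier for a (signed) deviation of the rolling average from baseline mean.

    Vectorized; returns a str for scalar input, an object array otherwise.
    Both directions of deviation are treated symmetrically.
    """
    dev = np.abs(np.asarray(deviation, dtype=float))
    scalar = dev.ndim == 0
    dev = np.atleast_1d(dev)
    if degenerate or sd == 0:
        tiers = np.full(dev.shape, FULL, dtype=object)
    else:
        # boundary ties go to the milder tier; allow a few ulp of slack so a
        # score constructed exactly on a window edge is not tipped over by
        # floating-point rounding of the subtraction
        def _le(x, threshold):
            return (x <= threshold) | np.isclose(x, threshold, rtol=1e-9, atol=1e-12)

        tiers = np.where(_le(dev, swc1 * sd), FULL,
                         np.where(_le(dev, swc2 * sd), REDUCED, RECOVERY)).astype(object)
    return tiers[0] if scalar else tiers


class SWCPrescriber(BaseEstimator):
    """Three-tier training prescription from individualized SWC windows.

    Parameters
    ----------
    swc1, swc2 : float
        Window half-widths in baseline-SD units (defaults 0.5 and 1.0).
    min_days : int
        Minimum number of baseline scores required by :meth:`fit`.
    ddof : int
        Delta degrees of freedom for the baseline SD (1 = sample SD).

    Attributes
    ----------
    mean_, sd_ : float
        Baseline mean and SD of the daily score.
    swc1_bounds_, swc2_bounds_ : tuple of float
        (lo, hi) bounds of the two windows.
    n_days_ : int
        Number of baseline scores used.
    degenerate_ : bool
        True when the baseline SD is exactly zero.
    """

    def __init__(self, swc1: float = 0.5, swc2: float = 1.0,
                 min_days: int = 10, ddof: int = 1):
        self.swc1 = swc1
        self.swc2 = swc2
        self.min_days = min_days
        self.ddof = ddof

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValueError("expected a 1-d sequence of daily scores")
        if not np.all(np.isfinite(X)):
            raise ValueError("daily scores must be finite")
        return X

    def fit(self, X, y=None) -> "SWCPrescriber":
        """Calibrate the baseline from daily scores (one per baseline day)."""
        if not 0 < self.swc1 <= self.swc2:
            raise ValueError("require 0 < swc1 <= swc2")
        X = self._validate(X)
        if X.size < self.min_days:
            raise ValueError(
                f"insufficient baseline: {X.size} readings, need >= {self.min_days}"
            )
        self.mean_ = float(np.mean(X))
        self.sd_ = float(np.std(X, ddof=self.ddof))
        self.n_days_ = int(X.size)
        self.degenerate_ = self.sd_ == 0.0
        self.swc1_bounds_ = (self.mean_ - self.swc1 * self.sd_,
                             self.mean_ + self.swc1 * self.sd_)
        self.swc2_bounds_ = (self.mean_ - self.swc2 * self.sd_,
                             self.mean_ + self.swc2 * self.sd_)
        return self

    def decision_function(self, X):
        """Signed deviation of each rolling average from the baseline mean."""
        if not hasattr(self, "mean_"):
            raise AttributeError("SWCPrescriber is not fitted; call fit first")
        return self._validate(X) - self.mean_

    def predict(self, X):
        """Tier (FULL | REDUCED | RECOVERY) for each rolling-average score."""
        return classify_deviation(self.decision_function(X), self.sd_,
                                  self.swc1, self.swc2, self.degenerate_)
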