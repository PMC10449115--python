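"""Therapy-response modelling from cancer-subtype proportions.

A binomial GLM with logit link predicts binary therapy response (e.g.
RECIST complete/partial response vs all else) from the three
cancer-epithelial proportions (Basal, HER2, Luminal).  The intended
use is cross-cohort transfer: fit on one PDX cohort, score another
treated with the same drug class, and evaluate with ROC AUC.

AUC uses the rank (Mann-Whitney) formulation with midranks for ties:
the probability a random positive outscores a random negative, plus
half the tie probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["ResponseModel", "fit_response_glm", "predict_response", "roc_auc", "binarize_recist"]

PREDICTORS = ("Basal", "HER2", "Luminal")


@dataclass
class ResponseModel:
    """Logistic model of response on three subtype proportions."""

    intercept: float
    coefficients: np.ndarray  # one per predictor, order PREDICTORS
    n: int
    converged: bool
    separable: bool = False

    def __post_init__(self) -> None:
        if len(self.coefficients) != 3:
            raise ValueError("exactly three predictor coefficients required")

    def predict_proba(self, P3: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(P3, dtype=float) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def binarize_recist(labels: Sequence[str], scheme: str = "crpr") -> np.ndarray:
    """Binary response from RECIST categories.

    ``crpr``: CR or PR count as response; ``cr``: only CR does.
    """
    positive = {"crpr": {"CR", "PR"}, "cr": {"CR"}}.get(scheme)
    if positive is None:
        raise ValueError("scheme must be 'crpr' or 'cr'")
    known = {"CR", "PR", "SD", "PD"}
    out = []
    for lab in labels:
        lab = str(lab).upper()
        if lab not in known:
            raise ValueError(f"unknown RECIST category {lab!r}")
        out.append(int(lab in positive))
    return np.asarray(out)


def fit_response_glm(P3: np.ndarray, response: Sequence[int]) -> ResponseModel:
    """Fit response ~ Basal + HER2 + Luminal by binomial IRLS.

    ``P3`` is samples x 3 (proportions of the three cancer subtypes).
    Perfect or quasi-perfect separation is detected and flagged; the
    returned coefficients then come from a lightly ridge-penalized
    refit so predictions remain usable.
    """
    P3 = np.asarray(P3, dtype=float)
    y = np.asarray(response, dtype=float)
    if P3.ndim != 2 or P3.shape[1] != 3:
        raise ValueError("P3 must be samples x 3")
    if P3.shape[0] != y.shape[0]:
        raise ValueError("response length must match the number of samples")
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both classes")
    if np.any(np.ptp(P3, axis=0) == 0):
        raise ValueError("constant predictor column")
    X = sm.add_constant(P3, has_constant="add")
    separable = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(fit.params)
        converged = bool(fit.converged)
        # quasi-separation shows up as exploding coefficients with fitted
        # probabilities saturating at 0/1
        mu = fit.fittedvalues
        if np.abs(params).max() > 50 or np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
            separable = True
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError):
        separable = True
        converged = False
    if separable:
        logger.warning("perfect separation detected; refitting with a small ridge penalty")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-3, L1_wt=0.0
        )
        params = np.asarray(fit.params)
        converged = True
    return ResponseModel(
        intercept=float(params[0]),
        coefficients=params[1:4],
        n=int(y.shape[0]),
        converged=converged,
        separable=separable,
    )


def predict_response(model: ResponseModel, P3: np.ndarray) -> np.ndarray:
    """Response probabilities for a (possibly different) cohort."""
    return model.predict_proba(np.asarray(P3, dtype=float))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based ROC AUC with midrank tie handling.

    Equals P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg)
    over random positive/negative pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
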