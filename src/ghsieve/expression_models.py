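"""Expression summaries and signal-peptide response models.

The binary response (does a transcript carry a predicted signal peptide?)
is modeled against expression with three candidate curves, compared by AIC:

* LOGISTIC — ``P(y=1|x) = 1 / (1 + exp(-(b0 + b1 x)))`` (2 parameters);
* SIGMOID  — ``P(y=1|x) = L / (1 + exp(-k (x - x0)))`` with a free maximum
  asymptote ``0 < L <= 1`` (3 parameters);
* RELU     — ``P(y=1|x) = clip(a (x - b), 0, 1)`` (2 parameters).

All three are fit by maximum likelihood on a Bernoulli likelihood with
probabilities clipped to ``[1e-9, 1 - 1e-9]``, using a fixed multi-start
grid so fits are deterministic.  The default predictor is log2(TPM);
zero-TPM transcripts cannot enter the regression and are counted instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

PROB_CLIP = 1e-9

EUKARYOTIC_LABELS = {"G", "E", "U"}
PROKARYOTIC_LABELS = {"PC", "EC"}


class ResponseModel(str, Enum):
    LOGISTIC = "LOGISTIC"
    SIGMOID = "SIGMOID"
    RELU = "RELU"


N_PARAMS = {ResponseModel.LOGISTIC: 2, ResponseModel.SIGMOID: 3,
            ResponseModel.RELU: 2}


class DegenerateResponseError(ValueError):
    """The binary response has a single class; nothing to fit."""


def log2_transform(tpm: float, pseudocount: float = 0.0) -> float | None:
    """log2(TPM + pseudocount); None ("not detected") when the argument is
    zero under the default zero pseudocount."""
    if tpm < 0:
        raise ValueError(f"TPM must be >= 0, got {tpm}")
    shifted = tpm + pseudocount
    return math.log2(shifted) if shifted > 0 else None


@dataclass(frozen=True)
class BinaryResponseFit:
    model: ResponseModel
    params: tuple[float, ...]
    loglik: float
    aic: float
    n: int
    wald_p: float | None = None  # LOGISTIC only

    def __post_init__(self) -> None:
        expected = 2 * len(self.params) - 2 * self.loglik
        if not math.isclose(self.aic, expected, rel_tol=0, abs_tol=1e-9):
            raise ValueError("AIC does not satisfy 2k - 2*loglik")

    def predict(self, x: Sequence[float] | np.ndarray) -> np.ndarray:
        return predict_probability(self.model, self.params, np.asarray(x, float))


def predict_probability(
    model: ResponseModel, params: Sequence[float], x: np.ndarray
) -> np.ndarray:
    x = np.asarray(x, float)
    if model is ResponseModel.LOGISTIC:
        b0, b1 = params
        return 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
    if model is ResponseModel.SIGMOID:
        L, k, x0 = params
        return L / (1.0 + np.exp(-k * (x - x0)))
    if model is ResponseModel.RELU:
        a, b = params
        return np.clip(a * (x - b), 0.0, 1.0)
    raise ValueError(f"unknown model {model}")


def bernoulli_loglik(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 10:
        raise ValueError(f"need at least 10 observations, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary")
    if len(np.unique(y)) < 2:
        raise DegenerateResponseError("degenerate response: y has a single class")
    return x, y


def _logistic_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    pbar = float(np.mean(y))
    b0 = math.log(pbar / (1.0 - pbar))
    return [np.array([b0, b1]) for b1 in (0.0, -1.0, 1.0)]


def _sigmoid_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    qs = np.quantile(x, [0.25, 0.5, 0.75])
    return [
        np.array([L, k, x0])
        for L in (0.7, 1.0)
        for k in (-2.0, -0.5, 0.5, 2.0)
        for x0 in qs
    ]


def _relu_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    pbar = float(np.mean(y))
    lo, mid, hi = np.min(x), np.median(x), np.max(x)
    span = max(hi - lo, 1.0)
    starts = [
        np.array([a, b])
        for a in (0.5 / span, 2.0 / span, -0.5 / span, -2.0 / span)
        for b in (lo, mid, hi)
    ]
    # near-constant curves: a -> 0 with a*(x - b) ~ pbar
    for a in (0.01, -0.01):
        starts.append(np.array([a, mid - pbar / a]))
    return starts


def fit_binary_response(
    x: Sequence[float],
    y: Sequence[bool] | Sequence[int],
    model: ResponseModel | str,
) -> BinaryResponseFit:
    """Maximum-likelihood fit of one response curve.

    Deterministic: the optimizer runs from a fixed multi-start grid and the
    best converged solution is reported.  Under perfect separation the
    clipped likelihood plateaus and the reported coefficients are the point
    where the optimizer stalls on that plateau (loglik near 0).
    """
    model = ResponseModel(model)
    x, y = _validate_xy(x, y)

    def nll(params: np.ndarray) -> float:
        return -bernoulli_loglik(predict_probability(model, params, x), y)

    if model is ResponseModel.LOGISTIC:
        starts, bounds, method = _logistic_starts(x, y), None, "BFGS"
    elif model is ResponseModel.SIGMOID:
        starts = _sigmoid_starts(x, y)
        sd = max(float(np.std(x)), 1.0)
        bounds = [
            (1e-6, 1.0),
            (-60.0, 60.0),
            (float(np.min(x)) - 10 * sd, float(np.max(x)) + 10 * sd),
        ]
        method = "L-BFGS-B"
    else:
        starts, bounds, method = _relu_starts(x, y), None, "Nelder-Mead"

    best: optimize.OptimizeResult | None = None
    for start in starts:
        try:
            res = optimize.minimize(
                nll, start, method=method, bounds=bounds,
                options={"maxiter": 2000},
            )
        except (ValueError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"{model.value} fit failed to converge from any start "
            f"(n={len(x)}, class balance={float(np.mean(y)):.3f})"
        )
    # polish non-smooth / bounded fits with a second local pass
    res = optimize.minimize(nll, best.x, method=method, bounds=bounds,
                            options={"maxiter": 2000, "xatol": 1e-10,
                                     "fatol": 1e-12}
                            if method == "Nelder-Mead" else {"maxiter": 2000})
    if np.isfinite(res.fun) and res.fun <= best.fun:
        best = res

    params = tuple(float(v) for v in best.x)
    loglik = -float(best.fun)
    k = N_PARAMS[model]
    wald_p = _logistic_wald_p(params, x) if model is ResponseModel.LOGISTIC else None
    return BinaryResponseFit(
        model=model, params=params, loglik=loglik,
        aic=2 * k - 2 * loglik, n=len(x), wald_p=wald_p,
    )


def _logistic_wald_p(params: tuple[float, ...], x: np.ndarray) -> float | None:
    """Two-sided Wald p-value for the slope, from the observed information
    X'WX at the MLE.  None when the information matrix is singular (e.g.
    complete separation)."""
    b0, b1 = params
    p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
    w = p * (1.0 - p)
    X = np.column_stack([np.ones_like(x), x])
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    se = math.sqrt(max(cov[1, 1], 0.0))
    if not math.isfinite(se) or se == 0.0:
        return None
    z = b1 / se
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class ModelComparison:
    ranking: tuple[BinaryResponseFit, ...]  # ascending AIC
    delta_aic: tuple[float, ...]

    @property
    def winner(self) -> BinaryResponseFit:
        return self.ranking[0]


def compare_models(fits: Sequence[BinaryResponseFit]) -> ModelComparison:
    """Rank fits of the same data by AIC (ascending), with ΔAIC to the best."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    if len({f.n for f in fits}) > 1:
        raise ValueError("fits were made on different sample sizes")
    ranked = tuple(sorted(fits, key=lambda f: (f.aic, f.model.value)))
    best = ranked[0].aic
    return ModelComparison(ranked, tuple(f.aic - best for f in ranked))


def association_report(
    records: Iterable,
    predictor: str = "log2tpm",
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-enzyme-type logistic fits of signal-peptide presence vs
    expression, separately for host/eukaryotic-side transcripts (labels
    G, E, U) and prokaryotic-side ones (PC, EC).

    Zero-TPM transcripts cannot take the log and are excluded (counted in
    ``n_zero_tpm``); groups failing the fit preconditions appear as
    ``not testable`` rows rather than errors.
    """
    if predictor not in {"log2tpm", "tpm"}:
        raise ValueError(f"unknown predictor {predictor!r}")
    groups: dict[tuple[str, str], list] = {}
    for rec in records:
        side = "eukaryotic" if rec.origin_label in EUKARYOTIC_LABELS else "prokaryotic"
        groups.setdefault((rec.enzyme_type, side), []).append(rec)

    rows = []
    for (etype, side), recs in sorted(groups.items()):
        detected = [r for r in recs if r.tpm > 0]
        n_zero = len(recs) - len(detected)
        x = [
            math.log2(r.tpm) if predictor == "log2tpm" else r.tpm
            for r in detected
        ]
        y = [int(r.signal_peptide) for r in detected]
        row = {
            "enzyme_type": etype, "origin_side": side,
            "n": len(detected), "n_zero_tpm": n_zero,
            "beta0": np.nan, "beta1": np.nan, "wald_p": np.nan,
        }
        if len(detected) < min_n:
            row["status"] = "not testable (too few detected transcripts)"
        elif len(set(y)) < 2:
            row["status"] = "not testable (degenerate response)"
        else:
            fit = fit_binary_response(x, y, ResponseModel.LOGISTIC)
            row.update(
                beta0=fit.params[0], beta1=fit.params[1],
                wald_p=np.nan if fit.wald_p is None else fit.wald_p,
                status="ok",
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["enzyme_type", "origin_side", "n", "n_zero_tpm",
                 "beta0", "beta1", "wald_p", "status"],
    )
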