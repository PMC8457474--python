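"""Cox proportional-hazards comparator.

Per-SNP Cox regression of (time, event) on a coded genotype plus the binary
covariate (and optionally their interaction), reported as P = -log10 of the
genotype coefficient's Wald p-value. Single-cohort fits go through lifelines
(the field-standard implementation); the mass replicate studies use a
vectorized Newton solver of the Cox partial likelihood that fits thousands of
replicates simultaneously and is cross-checked against lifelines in the test
suite.

A constant coded predictor (e.g. recessive coding with no minor-allele
homozygotes) leaves the coefficient undefined; such fits are flagged
``degenerate`` rather than raising, mirroring the NaN returned by standard
survival software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import Cohort

__all__ = [
    "MODES",
    "CPHResult",
    "code_genotype",
    "cph_p",
    "max_over_modes",
    "cox_scan_batch",
    "neglog10_wald_p",
]

MODES = ("additive", "recessive", "dominant")
_LOG10 = float(np.log(10.0))


@dataclass
class CPHResult:
    coefficient: float = np.nan
    p_value: float = np.nan
    P: float = np.nan  # -log10(p)
    coding: str = "additive"
    interaction_P: float = np.nan
    degenerate: bool = False
    reason: str = ""


def code_genotype(g, mode: str) -> np.ndarray:
    """Predictor coding of minor-allele counts for a mode of inheritance."""
    g = np.asarray(g)
    if mode == "additive":
        return g.astype(float)
    if mode == "recessive":
        return (g == 2).astype(float)
    if mode == "dominant":
        return (g >= 1).astype(float)
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def neglog10_wald_p(z) -> np.ndarray:
    """-log10 of the two-sided Wald p for z-statistics, stable far in the tail."""
    z = np.abs(np.asarray(z, dtype=float))
    return -(np.log(2.0) + stats.norm.logsf(z)) / _LOG10


def cph_p(cohort: Cohort, mode: str = "additive", include_interaction: bool = False) -> CPHResult:
    """Cox PH Wald test of the genotype term for one cohort (lifelines fit)."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    x = code_genotype(cohort.genotype, mode)
    if np.ptp(x) == 0:
        return CPHResult(coding=mode, degenerate=True, reason="constant genotype predictor")
    if int(cohort.event.sum()) < 2:
        return CPHResult(coding=mode, degenerate=True, reason="fewer than 2 events")
    df = pd.DataFrame(
        {
            "time": cohort.time,
            "event": cohort.event,
            "geno": x,
            "cov": (cohort.covariate == 2).astype(float),
        }
    )
    if np.ptp(df["cov"].to_numpy()) == 0:  # single-stratum subset: drop the covariate
        df = df.drop(columns=["cov"])
    if include_interaction:
        df["inter"] = df["geno"] * df["cov"]
        if np.ptp(df["inter"].to_numpy()) == 0:
            return CPHResult(coding=mode, degenerate=True, reason="constant interaction predictor")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        return CPHResult(coding=mode, degenerate=True, reason=f"non-convergence: {exc}")
    summ = fitter.summary
    coef = float(summ.loc["geno", "coef"])
    z = float(summ.loc["geno", "z"])
    P = float(neglog10_wald_p(z))
    out = CPHResult(
        coefficient=coef,
        p_value=float(summ.loc["geno", "p"]),
        P=P,
        coding=mode,
    )
    if include_interaction:
        out.interaction_P = float(neglog10_wald_p(float(summ.loc["inter", "z"])))
    return out


def max_over_modes(cohort: Cohort, include_interaction: bool = False) -> CPHResult:
    """Largest P over additive/recessive/dominant codings, skipping degenerate fits."""
    best: CPHResult | None = None
    for mode in MODES:
        res = cph_p(cohort, mode, include_interaction=include_interaction)
        if res.degenerate:
            continue
        if best is None or res.P > best.P:
            best = res
    if best is None:
        return CPHResult(degenerate=True, reason="all modes degenerate")
    return best


def _cox_newton(time, event, X, max_iter=20, tol=1e-9):
    """Damped Newton on the Cox partial likelihood for a batch of replicates.

    ``time``/``event`` have shape (R, n); ``X`` has shape (R, n, p). Event
    times are assumed continuous (no event-event ties); censored individuals
    tied with an event time are kept in that event's risk set. Returns
    (beta, cov, converged) with shapes (R, p), (R, p, p), (R,).
    """
    R, n, p = X.shape
    # sort descending in time; among ties, censored first so cumulative risk
    # sums at an event's position include tied censored individuals
    order = np.lexsort((event, -time), axis=-1)
    t_s = np.take_along_axis(time, order, axis=1)
    e_s = np.take_along_axis(event, order, axis=1).astype(float)
    X_s = np.take_along_axis(X, order[:, :, None], axis=1)
    X_s = X_s - X_s.mean(axis=1, keepdims=True)  # centering for conditioning
    beta = np.zeros((R, p))
    ll_prev = np.full(R, -np.inf)
    active = np.arange(R)  # replicates still iterating
    for _ in range(max_iter):
        if active.size == 0:
            break
        Xa, ea = X_s[active], e_s[active]
        eta = np.clip(np.einsum("rnp,rp->rn", Xa, beta[active]), -500.0, 500.0)
        w = np.exp(eta)
        S0 = np.cumsum(w, axis=1)
        S1 = np.cumsum(Xa * w[:, :, None], axis=1)
        S2 = np.cumsum(Xa[:, :, :, None] * Xa[:, :, None, :] * w[:, :, None, None], axis=1)
        Ebar = S1 / S0[:, :, None]
        ll = np.sum(ea * (eta - np.log(S0)), axis=1)
        grad = np.einsum("rn,rnp->rp", ea, Xa - Ebar)
        V = S2 / S0[:, :, None, None] - Ebar[:, :, :, None] * Ebar[:, :, None, :]
        H = np.einsum("rn,rnpq->rpq", ea, V)
        Hreg = H + 1e-10 * np.eye(p)[None, :, :]
        try:
            delta = np.linalg.solve(Hreg, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(Hreg + 1e-6 * np.eye(p)[None, :, :], grad[:, :, None])[:, :, 0]
        # halve steps for replicates whose previous step reduced the likelihood
        worse = ll < ll_prev[active] - 1e-12
        step = np.clip(delta * np.where(worse, 0.5, 1.0)[:, None], -5.0, 5.0)
        beta[active] += step
        ll_prev[active] = ll
        converged = np.max(np.abs(grad), axis=1) < tol
        active = active[~converged]
    # covariance from the information matrix at the final iterate
    eta = np.clip(np.einsum("rnp,rp->rn", X_s, beta), -500.0, 500.0)
    w = np.exp(eta)
    S0 = np.cumsum(w, axis=1)
    S1 = np.cumsum(X_s * w[:, :, None], axis=1)
    S2 = np.cumsum(X_s[:, :, :, None] * X_s[:, :, None, :] * w[:, :, None, None], axis=1)
    Ebar = S1 / S0[:, :, None]
    V = S2 / S0[:, :, None, None] - Ebar[:, :, :, None] * Ebar[:, :, None, :]
    H = np.einsum("rn,rnpq->rpq", e_s, V)
    grad = np.einsum("rn,rnp->rp", e_s, X_s - Ebar)
    converged = np.max(np.abs(grad), axis=1) < 1e-4
    with np.errstate(all="ignore"):
        cov = np.linalg.inv(H + 1e-12 * np.eye(p)[None, :, :])
    return beta, cov, converged


def cox_scan_batch(
    time: np.ndarray,
    event: np.ndarray,
    genotype: np.ndarray,
    covariate: np.ndarray,
    mode: str = "additive",
    include_interaction: bool = False,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Cox Wald P for many replicates at once.

    All arrays have shape (R, n). Returns a frame with columns ``coef``,
    ``P`` (-log10 Wald p for the genotype term), ``interaction_P`` (when
    requested) and ``degenerate``; degenerate replicates (constant coded
    predictor) carry NaNs, mirroring the NaN of standard survival software.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    R, n = time.shape
    x = code_genotype(genotype.reshape(-1), mode).reshape(R, n)
    cov2 = (np.asarray(covariate) == 2).astype(float)
    cols = [x, cov2]
    if include_interaction:
        cols.append(x * cov2)
    X = np.stack(cols, axis=2)
    degen = np.ptp(x, axis=1) == 0
    if include_interaction:
        degen |= np.ptp(X[:, :, 2], axis=1) == 0
    degen |= event.sum(axis=1) < 2
    coef = np.full(R, np.nan)
    P = np.full(R, np.nan)
    inter_P = np.full(R, np.nan)
    ok_idx = np.flatnonzero(~degen)
    for start in range(0, ok_idx.size, chunk):
        idx = ok_idx[start : start + chunk]
        beta, covm, _ = _cox_newton(time[idx], event[idx], X[idx])
        se = np.sqrt(np.maximum(covm[:, 0, 0], 0.0))
        with np.errstate(all="ignore"):
            z = beta[:, 0] / se
        coef[idx] = beta[:, 0]
        P[idx] = neglog10_wald_p(z)
        if include_interaction:
            se_i = np.sqrt(np.maximum(covm[:, 2, 2], 0.0))
            with np.errstate(all="ignore"):
                z_i = beta[:, 2] / se_i
            inter_P[idx] = neglog10_wald_p(z_i)
    out = pd.DataFrame({"coef": coef, "P": P, "degenerate": degen})
    if include_interaction:
        out["interaction_P"] = inter_P
    return out
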