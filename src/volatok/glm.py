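"""Time-resolved single-trial EEG regressions and model comparison.

For each sample position and each time point in a 1 s post-sample epoch,
the outcome (motor beta lateralisation, or an electrode-group-averaged
ERP) is regressed across trials on model-derived quantities.  Signed
regressors (psi, LLR, delta-psi) are used for lateralisation, unsigned
magnitudes for the ERP.  When ``standardise`` is on, predictors and the
outcome are z-scored within each (sample position, time point) across
trials, so coefficients are standardised betas; the session covariate is
kept raw (nuisance role) and the first sample is excluded whenever a
prior term is in the design (the prior is identically zero there).
Coefficients are averaged over sample positions (default 2..10).

The single-regressor model comparison contrasts adjusted R-squared time
courses of models containing only a decision-variable, effective-evidence
or objective-evidence regressor (plus intercept and session), and the
residual machinery extracts per-(trial, sample) scalar residuals that
feed the choice-coupling and motor-update analyses:

    dMBL_s = b0 + b1 * dpsi_s + b2 * dpsi_s * residualCPP_s
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observer import BeliefTraceSet
from .task import TrialSet

__all__ = [
    "TimeResolvedCoefficients",
    "AdjustedR2Comparison",
    "sample_regressors",
    "timeresolved_regression",
    "single_regressor_comparison",
    "extract_residuals",
    "motor_update_coupling",
    "adjusted_r2",
]


def sample_regressors(trialset: TrialSet, traces: BeliefTraceSet,
                      full_only: bool = True) -> dict[str, np.ndarray]:
    """Per-(trial, sample) regressor arrays on full trials.

    Keys: signed ``psi``, ``llr``, ``llr_x_surprise``, ``delta_psi``,
    ``psi_next`` and their unsigned counterparts (``abs_*``), plus
    ``session`` (per trial).  ``psi_next`` is the updated prior
    psi + delta_psi (the decision-variable candidate).
    """
    sel = np.flatnonzero(trialset.is_full) if full_only else np.arange(len(trialset))
    llr = trialset.llr[sel]
    psi = traces.psi[sel]
    dpsi = traces.delta_psi[sel]
    slog = traces.surprise_logit[sel] if traces.surprise_logit is not None else None
    out = {
        "psi": psi,
        "llr": llr,
        "delta_psi": dpsi,
        "psi_next": psi + dpsi,
        "abs_psi": np.abs(psi),
        "abs_llr": np.abs(llr),
        "abs_delta_psi": np.abs(dpsi),
        "abs_psi_next": np.abs(psi + dpsi),
        "session": trialset.session[sel].astype(float),
        "trial_index": sel,
    }
    if slog is not None:
        out["llr_x_surprise"] = llr * slog
        out["abs_llr_x_surprise"] = np.abs(llr) * slog
    return out


@dataclass
class TimeResolvedCoefficients:
    """Betas over the sample epoch, averaged across sample positions."""

    regressors: list[str]
    beta: np.ndarray  # (n_regressors, n_times)
    per_sample: np.ndarray  # (n_regressors, n_positions, n_times)
    positions: np.ndarray  # 1-based sample positions used
    times: np.ndarray  # epoch clock relative to sample onset
    standardised: bool
    dropped: list[str] = field(default_factory=list)


def _zcols(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.where(ok, (X - X.mean(axis=0)) / np.where(ok, sd, 1.0), 0.0)
    return Z, ok


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of Y (n, T) on X (n, p); returns (beta (p, T), residuals (n, T))."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return beta, Y - X @ beta


def timeresolved_regression(epochs: np.ndarray, regressors: dict[str, np.ndarray],
                            names: list[str], session: np.ndarray,
                            times: np.ndarray,
                            sample_range: tuple[int, int] = (2, 10),
                            standardise: bool = True) -> TimeResolvedCoefficients:
    """Per-sample, per-timepoint OLS, averaged over sample positions.

    ``epochs``: (n_trials, n_samples, n_times) sample-locked outcome on
    full trials; ``regressors``: name -> (n_trials, n_samples) arrays
    (as from :func:`sample_regressors`); ``names`` selects and orders the
    design.  Returns standardised betas averaged over ``sample_range``.
    """
    n, m, T = epochs.shape
    lo, hi = sample_range
    positions = np.arange(lo, hi + 1)
    if positions.min() < 1 or positions.max() > m:
        raise ValueError(f"sample_range {sample_range} outside 1..{m}")
    if n < len(names) + 10:
        raise ValueError(f"too few trials ({n}) for {len(names)} regressors")

    p = len(names)
    per_sample = np.full((p, len(positions), T), np.nan)
    dropped: set[str] = set()
    for k, pos in enumerate(positions):
        s = pos - 1
        cols = np.column_stack([regressors[nm][:, s] for nm in names])
        if standardise:
            cols, ok = _zcols(cols)
        else:
            ok = cols.std(axis=0) > 0
        if not ok.all():
            dropped.update(np.asarray(names)[~ok])
        X = np.column_stack([np.ones(n), cols, session.astype(float)])
        Y = epochs[:, s, :]
        if standardise:
            Y, _ = _zcols(Y)
        beta, _ = _ols(X, Y)
        per_sample[:, k, :] = beta[1:1 + p]
        per_sample[~ok, k, :] = np.nan
    return TimeResolvedCoefficients(
        regressors=list(names),
        beta=np.nanmean(per_sample, axis=1),
        per_sample=per_sample,
        positions=positions,
        times=times,
        standardised=standardise,
        dropped=sorted(dropped),
    )


def adjusted_r2(r2: np.ndarray, n: int, p: int) -> np.ndarray:
    """Adjusted R^2 = 1 - (1 - R^2) (n - 1) / (n - p - 1)."""
    return 1.0 - (1.0 - np.asarray(r2)) * (n - 1) / (n - p - 1)


@dataclass
class AdjustedR2Comparison:
    """Adjusted-R^2 time courses per candidate and differences vs reference."""

    candidates: list[str]
    adj_r2: dict[str, np.ndarray]  # name -> (n_times,)
    diff_vs_reference: dict[str, np.ndarray]
    reference: str
    times: np.ndarray


def single_regressor_comparison(epochs: np.ndarray,
                                regressors: dict[str, np.ndarray],
                                candidates: dict[str, str],
                                session: np.ndarray, times: np.ndarray,
                                sample_range: tuple[int, int] = (2, 10),
                                reference: str = "OE",
                                include_session: bool = True) -> AdjustedR2Comparison:
    """Adjusted-R^2 comparison of single-regressor encoding models.

    ``candidates`` maps model label (e.g. "DV", "EE", "OE") to a regressor
    name; each model contains intercept + that regressor (+ session unless
    disabled).  Adjusted R^2 is computed per (sample, time point) and
    averaged over samples.
    """
    n, m, T = epochs.shape
    lo, hi = sample_range
    positions = np.arange(lo, hi + 1)
    out = {lab: np.zeros(T) for lab in candidates}
    p_pred = 2 if include_session else 1
    for pos in positions:
        s = pos - 1
        Y = epochs[:, s, :]
        sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        sst[sst == 0] = np.nan
        for lab, nm in candidates.items():
            colz, _ = _zcols(regressors[nm][:, s][:, None])
            parts = [np.ones(n), colz[:, 0]]
            if include_session:
                parts.append(session.astype(float))
            X = np.column_stack(parts)
            _, resid = _ols(X, Y)
            r2 = 1.0 - (resid**2).sum(axis=0) / sst
            out[lab] += adjusted_r2(r2, n, p_pred) / len(positions)
    diffs = {lab: out[lab] - out[reference] for lab in candidates if lab != reference}
    return AdjustedR2Comparison(
        candidates=list(candidates),
        adj_r2=out,
        diff_vs_reference=diffs,
        reference=reference,
        times=times,
    )


def extract_residuals(epochs: np.ndarray, regressors: dict[str, np.ndarray],
                      names: list[str], session: np.ndarray, times: np.ndarray,
                      sample_range: tuple[int, int] = (1, 10),
                      window: tuple[float, float] = (0.25, 0.50)) -> np.ndarray:
    """Scalar per-(trial, sample) residuals of an unstandardised fit.

    The regression is fit per sample position and time point in original
    units; residuals are averaged over ``window`` on the sample-epoch
    clock.  Positions outside ``sample_range`` are NaN.  By OLS these
    scalars have (numerically) zero mean and are orthogonal to the design
    at every averaged time point.
    """
    n, m, T = epochs.shape
    lo, hi = sample_range
    tsel = (times >= window[0]) & (times < window[1])
    if not tsel.any():
        raise ValueError("residual window outside the sample epoch")
    out = np.full((n, m), np.nan)
    for pos in range(lo, hi + 1):
        s = pos - 1
        cols = np.column_stack([regressors[nm][:, s] for nm in names])
        X = np.column_stack([np.ones(n), cols, session.astype(float)])
        _, resid = _ols(X, epochs[:, s, :])
        out[:, s] = resid[:, tsel].mean(axis=1)
    return out


@dataclass
class MotorUpdateCoupling:
    """Per-sample-position betas of the motor-update regression."""

    positions: np.ndarray  # 1-based s for dMBL_s = MBL_{s+1} - MBL_s
    beta_dpsi: np.ndarray  # (n_positions,)
    beta_interaction: np.ndarray  # (n_positions,)
    standardised: bool


def motor_update_coupling(mbl_scalars: np.ndarray, delta_psi: np.ndarray,
                          cpp_residuals: np.ndarray,
                          standardise: bool = True) -> MotorUpdateCoupling:
    """Regress motor updates on belief updates and their CPP-residual
    interaction, per sample position.

    ``mbl_scalars``: (n_trials, m) first-100-ms lateralisation per sample;
    ``delta_psi`` and ``cpp_residuals``: (n_trials, m).  dMBL_s uses
    consecutive samples, so positions run 1..m-1; rows with NaN residuals
    are dropped per position.
    """
    n, m = mbl_scalars.shape
    if delta_psi.shape != (n, m) or cpp_residuals.shape != (n, m):
        raise ValueError("inputs must share the (n_trials, n_samples) shape")
    dmbl = mbl_scalars[:, 1:] - mbl_scalars[:, :-1]  # dMBL_s, s = 1..m-1
    b1 = np.full(m - 1, np.nan)
    b2 = np.full(m - 1, np.nan)
    for s in range(m - 1):
        y = dmbl[:, s]
        x1 = delta_psi[:, s]
        x2 = delta_psi[:, s] * cpp_residuals[:, s]
        ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
        if ok.sum() < 12:
            continue
        cols = np.column_stack([x1[ok], x2[ok]])
        yv = y[ok]
        if standardise:
            cols, _ = _zcols(cols)
            sd = yv.std()
            yv = (yv - yv.mean()) / sd if sd > 0 else yv - yv.mean()
        X = np.column_stack([np.ones(ok.sum()), cols])
        beta, _ = _ols(X, yv[:, None])
        b1[s], b2[s] = beta[1, 0], beta[2, 0]
    return MotorUpdateCoupling(
        positions=np.arange(1, m),
        beta_dpsi=b1,
        beta_interaction=b2,
        standardised=standardise,
    )
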