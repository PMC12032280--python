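"""Psychophysical-kernel logistic regressions (weight on choice).

The kernel regression estimates, per sample position i = 1..10, the weight
of that sample's LLR on the final choice, together with interaction terms
capturing how surprise (logit change-point probability) and uncertainty
(-|psi|) modulate the weight at positions 2..10:

    logit P(choice = right) = b0 + sum_i b1_i LLR_i
                              + sum_j b2_j LLR_j * surprise_j
                              + sum_j b3_j LLR_j * uncertainty_j

Residual-augmented variants add single-trial EEG residuals either as an
LLR interaction (centroparietal residuals) or as main effects (motor
lateralisation residuals).  Modulator variables are z-scored per
participant before the interactions are built, so modulation coefficients
are comparable across participants; LLR stays in its natural units.

All regressions use full trials (maximum-length sequences) only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .observer import BeliefTraceSet
from .task import TrialSet

__all__ = [
    "KernelResult",
    "kernel_regression",
    "recency_test",
    "residual_weight_regression",
    "residual_choice_bias_regression",
    "model_predicted_kernel",
]


@dataclass
class KernelResult:
    """Coefficients of one participant's kernel regression.

    ``betas`` maps regressor family -> coefficient vector over positions
    (``llr``: 10 entries for positions 1..10; modulators: 9 entries for
    positions 2..10; optional families follow their own ranges).
    """

    participant: int
    betas: dict[str, np.ndarray]
    ses: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]
    n_trials: int
    converged: bool
    ridge_fallback: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, b in self.betas.items():
            rows.append(
                pd.DataFrame(
                    {
                        "participant": self.participant,
                        "regressor": name,
                        "position": self.positions[name],
                        "beta": b,
                        "se": self.ses[name],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = np.std(a)
    return (a - np.mean(a)) / sd if sd > 0 else a - np.mean(a)


def _fit_logistic(X: np.ndarray, y01: np.ndarray):
    """ML logistic fit with an L2-regularised fallback on separation."""
    model = sm.Logit(y01, X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(method="lbfgs", maxiter=500, disp=False)
        bad = (not np.all(np.isfinite(res.params))) or np.any(np.abs(res.params) > 1e3)
    except Exception:
        bad = True
    if bad:
        # separation: ridge-stabilised refit (L2, lambda = 1e-3)
        glm = sm.GLM(y01, X, family=sm.families.Binomial())
        rres = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = np.asarray(rres.params)
        return params, np.full_like(params, np.nan), False, True
    return (
        np.asarray(res.params),
        np.asarray(res.bse),
        bool(res.mle_retvals.get("converged", True)),
        False,
    )


def _kernel_design(trialset: TrialSet, traces: BeliefTraceSet,
                   extra_cols: list[tuple[str, np.ndarray, np.ndarray]] | None = None):
    """Design matrix on full trials.

    ``extra_cols`` is a list of (name, values (n_full, m), positions) blocks
    appended after the standard Eq-7 design.  Returns X, column bookkeeping
    and the full-trial index.
    """
    full = np.flatnonzero(trialset.is_full)
    if len(full) < 50:
        raise ValueError(f"need >= 50 full trials, got {len(full)}")
    m = trialset.config.max_samples
    llr = trialset.llr[full]
    slog = traces.surprise_logit[full]
    unc = traces.uncertainty[full]
    # z-score modulators per participant, pooled over positions 2..m
    slog_z = np.empty_like(slog)
    unc_z = np.empty_like(unc)
    slog_z[:, 1:] = _zscore(slog[:, 1:])
    unc_z[:, 1:] = _zscore(unc[:, 1:])

    blocks = [("llr", llr, np.arange(1, m + 1))]
    blocks.append(("llr_x_surprise", llr[:, 1:] * slog_z[:, 1:], np.arange(2, m + 1)))
    blocks.append(("llr_x_uncertainty", llr[:, 1:] * unc_z[:, 1:], np.arange(2, m + 1)))
    if extra_cols:
        blocks.extend(extra_cols)

    X = np.column_stack([np.ones(len(full))] + [b[1] for b in blocks])
    layout = []
    start = 1
    for name, vals, pos in blocks:
        layout.append((name, start, start + vals.shape[1], np.asarray(pos)))
        start += vals.shape[1]
    return X, layout, full


def _run_kernel(trialset, traces, choices, extra_cols, participant) -> KernelResult:
    X, layout, full = _kernel_design(trialset, traces, extra_cols)
    y01 = (np.asarray(choices)[full] > 0).astype(float)
    params, ses, converged, ridge = _fit_logistic(X, y01)
    betas, se_out, pos_out = {}, {}, {}
    for name, a, b, pos in layout:
        betas[name] = params[a:b]
        se_out[name] = ses[a:b]
        pos_out[name] = pos
    return KernelResult(
        participant=participant,
        betas=betas,
        ses=se_out,
        positions=pos_out,
        n_trials=len(full),
        converged=converged,
        ridge_fallback=ridge,
    )


def kernel_regression(trialset: TrialSet, traces: BeliefTraceSet,
                      choices: np.ndarray, participant: int = 0) -> KernelResult:
    """Weight-on-choice logistic regression on full trials."""
    return _run_kernel(trialset, traces, choices, None, participant)


def residual_weight_regression(trialset: TrialSet, traces: BeliefTraceSet,
                               choices: np.ndarray, cpp_residuals: np.ndarray,
                               participant: int = 0) -> KernelResult:
    """Kernel regression augmented with LLR x residual-CPP interactions.

    ``cpp_residuals`` holds per-(trial, sample) scalar residuals from the
    centroparietal effective-evidence regression, aligned with the trial
    set (rows = all trials; full-trial rows are consumed).  Residuals are
    z-scored per participant before forming the interaction.
    """
    full = np.flatnonzero(trialset.is_full)
    m = trialset.config.max_samples
    res = np.asarray(cpp_residuals)[full]
    if res.shape != (len(full), m):
        raise ValueError("cpp_residuals must be (n_trials, max_samples)")
    res_z = _zscore(res)
    llr = trialset.llr[full]
    extra = [("llr_x_residual_cpp", llr * res_z, np.arange(1, m + 1))]
    return _run_kernel(trialset, traces, choices, extra, participant)


def residual_choice_bias_regression(trialset: TrialSet, traces: BeliefTraceSet,
                                    choices: np.ndarray, mbl_residuals: np.ndarray,
                                    participant: int = 0) -> KernelResult:
    """Kernel regression augmented with residual-lateralisation main effects
    at positions 2..10."""
    full = np.flatnonzero(trialset.is_full)
    m = trialset.config.max_samples
    res = np.asarray(mbl_residuals)[full]
    if res.shape != (len(full), m):
        raise ValueError("mbl_residuals must be (n_trials, max_samples)")
    res_z = _zscore(res[:, 1:])  # position 1 has no defined residual (prior is 0)
    extra = [("residual_mbl", res_z, np.arange(2, m + 1))]
    return _run_kernel(trialset, traces, choices, extra, participant)


def model_predicted_kernel(trialset: TrialSet, traces: BeliefTraceSet,
                           fitted_noise: float, rng: np.random.Generator,
                           participant: int = 0) -> KernelResult:
    """Kernel recomputed on model-simulated choices (predicted kernel)."""
    from .observer import simulate_choices

    sim = simulate_choices(traces.L_final, fitted_noise, rng)
    return kernel_regression(trialset, traces, sim, participant)


def recency_test(kernels: list[KernelResult], n_perm: int = 10_000,
                 seed: int = 0) -> dict:
    """Two-tailed sign-flip permutation test of late-vs-early weighting.

    Statistic: group mean of (mean of last-5 LLR weights minus mean of
    first-5) per participant.
    """
    if len(kernels) < 2:
        raise ValueError("need >= 2 participants")
    diffs = np.array(
        [k.betas["llr"][5:].mean() - k.betas["llr"][:5].mean() for k in kernels]
    )
    from .stats import paired_permutation_test

    p = paired_permutation_test(diffs, np.zeros_like(diffs), n_perm=n_perm, seed=seed)
    return {"mean_diff": float(diffs.mean()), "p": p, "per_participant": diffs}


def kernels_to_frame(kernels: list[KernelResult]) -> pd.DataFrame:
    return pd.concat([k.to_frame() for k in kernels], ignore_index=True)
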