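"""Observer models: normative belief updating and rival accumulators.

The normative observer tracks the log-posterior odds of the two generative
states.  After each sample the posterior ``L_s`` is carried through a
hazard-dependent non-linear transform to form the prior for the next sample:

    psi = L + log((1-H)/H + exp(-L)) - log((1-H)/H + exp(L))

which saturates at +/- log((1-H)/H) and so bounds the attainable belief.
The posterior then accumulates the (gain-scaled) sample LLR:

    L_s = psi_s + gain * LLR_s

Alternative accumulators share the choice rule but replace the recursion:
perfect (linear unbounded), bounded (clip at a non-absorbing bound), leaky
(multiplicative retention).  Choice probabilities for all models are
p(right) = 0.5 + 0.5*erf(L_final / noise).

Surprise is the analytic change-point probability: the posterior probability,
given the pre-sample belief and the hazard rate, that the sample directly
followed a state change.  At a flat prior it equals H exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import erf, ndtr

from .task import Trial, TrialSet

__all__ = [
    "ObserverParams",
    "BeliefTrace",
    "prior_transform",
    "change_point_probability",
    "logit_surprise",
    "choice_probability",
    "run_observer",
    "run_observer_set",
    "simulate_choices",
]

ModelKind = Literal["normative", "perfect", "bounded", "leaky"]

_EPS = 1e-12


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of an observer model.

    ``h_subj`` is the subjective hazard rate (normative model only);
    ``gain`` scales the LLR multiplicatively before accumulation (and, by
    default, inside the surprise computation — subjective evidence);
    ``noise`` is the terminal decision noise in log-odds units; ``bound``
    and ``leak`` parameterise the bounded and leaky accumulators.
    """

    model_kind: ModelKind = "normative"
    h_subj: float = 0.1
    gain: float = 1.0
    noise: float = 1.0
    bound: float = 3.0
    leak: float = 0.2
    gain_in_surprise: bool = True

    def __post_init__(self) -> None:
        if self.model_kind not in ("normative", "perfect", "bounded", "leaky"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "normative" and not 0.0 < self.h_subj < 1.0:
            raise ValueError(f"h_subj must lie in (0, 1), got {self.h_subj}")
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if self.noise <= 0:
            raise ValueError(f"noise must be positive, got {self.noise}")
        if self.model_kind == "bounded" and self.bound <= 0:
            raise ValueError(f"bound must be positive, got {self.bound}")
        if self.model_kind == "leaky" and not 0.0 <= self.leak <= 1.0:
            raise ValueError(f"leak must lie in [0, 1], got {self.leak}")

    @property
    def k_free(self) -> int:
        """Number of free parameters when the model is fit to choices."""
        return {"normative": 3, "perfect": 2, "bounded": 3, "leaky": 3}[self.model_kind]


def prior_transform(L_prev, H: float):
    """Hazard-dependent prior: posterior log-odds -> next-sample prior.

    Numerically stable for |L_prev| of several hundred via log-add-exp
    evaluation of both logarithms; saturates at +/- log((1-H)/H).
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must lie in (0, 1), got {H}")
    L = np.asarray(L_prev, dtype=float)
    log_r = np.log((1.0 - H) / H)
    return L + np.logaddexp(log_r, -L) - np.logaddexp(log_r, L)


def change_point_probability(llr_s, L_prev, H: float):
    """Analytic change-point probability ("surprise") of a sample.

    With prior state probabilities p(L), p(R) derived from the pre-sample
    belief ``L_prev`` and sample likelihoods under each state, the change
    hypothesis pairs each likelihood with the *other* state's prior:

        H * [p(x|L) p(R) + p(x|R) p(L)]
        -------------------------------------------------------------
        H * [p(x|L) p(R) + p(x|R) p(L)] + (1-H) * [p(x|L) p(L) + p(x|R) p(R)]

    Only likelihood ratios matter, so the function consumes the sample LLR.
    Computed in log space for stability; equals H at a flat prior.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must lie in (0, 1), got {H}")
    llr = np.asarray(llr_s, dtype=float)
    L = np.asarray(L_prev, dtype=float)
    log_pR = -np.logaddexp(0.0, -L)  # log p(Right | prior belief)
    log_pL = -np.logaddexp(0.0, L)
    # divide through by p(x|Left): p(x|R)/p(x|L) = exp(llr)
    log_change = np.log(H) + np.logaddexp(log_pR, llr + log_pL)
    log_stay = np.log1p(-H) + np.logaddexp(log_pL, llr + log_pR)
    return np.exp(log_change - np.logaddexp(log_change, log_stay))


def logit_surprise(surprise):
    """Logit transform, clamped at a machine-epsilon margin from {0, 1}."""
    s = np.clip(np.asarray(surprise, dtype=float), _EPS, 1.0 - _EPS)
    return np.log(s) - np.log1p(-s)


def choice_probability(L_final, noise: float, rule: str = "erf"):
    """Probability of a rightward choice given the terminal log-odds.

    The default rule is p = 0.5 + 0.5*erf(L/noise).  ``rule="probit"``
    exposes the Gaussian-CDF alternative p = Phi(L/noise) for sensitivity
    checks.
    """
    if noise <= 0:
        raise ValueError(f"noise must be positive, got {noise}")
    L = np.asarray(L_final, dtype=float)
    if rule == "erf":
        return 0.5 + 0.5 * erf(L / noise)
    if rule == "probit":
        return ndtr(L / noise)
    raise ValueError(f"unknown choice rule {rule!r}")


@dataclass
class BeliefTrace:
    """Per-sample observer quantities for one trial.

    ``psi[s]`` is the prior before sample s (psi[0] = 0), ``L[s]`` the
    posterior after it.  ``delta_psi[s] = psi[s+1] - psi[s]``; at the final
    sample the post-sequence prior (one extra transform of ``L_final``) is
    used, flagged by ``last_delta_extrapolated``.  Surprise is only defined
    for the normative model.
    """

    psi: np.ndarray
    L: np.ndarray
    delta_psi: np.ndarray
    surprise: np.ndarray | None
    surprise_logit: np.ndarray | None
    uncertainty: np.ndarray
    last_delta_extrapolated: bool = True

    @property
    def L_final(self) -> float:
        return float(self.L[-1])


def _accumulate(llr: np.ndarray, mask: np.ndarray, params: ObserverParams,
                surprise_H: float | None = None):
    """Vectorised observer recursion over padded (n, m) LLR arrays.

    Returns (psi, L, surprise, psi_post) where psi/L/surprise are (n, m)
    arrays (NaN beyond each trial's length) and psi_post is the prior after
    the final sample (used for the last belief update).  ``surprise_H``
    overrides the hazard used in the surprise computation (e.g. the
    generative H while the accumulation runs at a fitted subjective H).
    """
    n, m = llr.shape
    g = params.gain
    kind = params.model_kind
    psi = np.full((n, m), np.nan)
    L_out = np.full((n, m), np.nan)
    surprise = np.full((n, m), np.nan) if kind == "normative" else None
    sH = surprise_H if surprise_H is not None else params.h_subj

    L = np.zeros(n)
    for s in range(m):
        active = mask[:, s]
        if kind == "normative":
            p = prior_transform(L, params.h_subj)
        elif kind == "perfect":
            p = L
        elif kind == "bounded":
            p = L  # clipping applies to the posterior
        else:  # leaky
            p = (1.0 - params.leak) * L
        if surprise is not None:
            ev = g * llr[:, s] if params.gain_in_surprise else llr[:, s]
            surprise[active, s] = change_point_probability(ev, L, sH)[active]
        newL = p + g * llr[:, s]
        if kind == "bounded":
            newL = np.clip(newL, -params.bound, params.bound)
        psi[active, s] = p[active]
        L_out[active, s] = newL[active]
        L = np.where(active, newL, L)

    if kind == "normative":
        psi_post = prior_transform(L, params.h_subj)
    elif kind == "leaky":
        psi_post = (1.0 - params.leak) * L
    else:
        psi_post = L.copy()
    return psi, L_out, surprise, psi_post


def run_observer(trial: Trial, params: ObserverParams,
                 surprise_H: float | None = None) -> BeliefTrace:
    """Run an observer model over one trial's LLR sequence."""
    if trial.n_samples < 1:
        raise ValueError("trial must contain at least one sample")
    llr = trial.llr[None, :]
    mask = np.ones_like(llr, dtype=bool)
    psi, L, surprise, psi_post = _accumulate(llr, mask, params, surprise_H)
    psi, L = psi[0], L[0]
    delta_psi = np.empty_like(psi)
    delta_psi[:-1] = np.diff(psi)
    delta_psi[-1] = psi_post[0] - psi[-1]
    if surprise is not None:
        surprise = surprise[0]
        slogit = logit_surprise(surprise)
    else:
        slogit = None
    return BeliefTrace(
        psi=psi,
        L=L,
        delta_psi=delta_psi,
        surprise=surprise,
        surprise_logit=slogit,
        uncertainty=-np.abs(psi),
    )


@dataclass
class BeliefTraceSet:
    """Padded per-trial observer quantities for a whole TrialSet.

    Arrays are (n_trials, max_samples) with NaN beyond each trial's length.
    ``delta_psi[:, s] = psi[:, s+1] - psi[:, s]`` with the final sample's
    update taken to the post-sequence prior, and ``psi_next`` the prior
    *after* each sample (psi_next[:, s] = psi[:, s] + delta_psi[:, s]).
    """

    params: ObserverParams
    psi: np.ndarray
    L: np.ndarray
    delta_psi: np.ndarray
    surprise: np.ndarray | None
    surprise_logit: np.ndarray | None
    uncertainty: np.ndarray
    L_final: np.ndarray

    @property
    def psi_next(self) -> np.ndarray:
        return self.psi + self.delta_psi

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        n, m = self.psi.shape
        tid, sidx = np.nonzero(~np.isnan(self.psi))
        out = {
            "trial_id": tid,
            "sample_index": sidx + 1,
            "psi": self.psi[tid, sidx],
            "L": self.L[tid, sidx],
            "delta_psi": self.delta_psi[tid, sidx],
            "uncertainty": self.uncertainty[tid, sidx],
        }
        if self.surprise is not None:
            out["surprise"] = self.surprise[tid, sidx]
            out["surprise_logit"] = self.surprise_logit[tid, sidx]
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_observer_set(trialset: TrialSet, params: ObserverParams,
                     surprise_H: float | None = None) -> BeliefTraceSet:
    """Vectorised observer run over every trial in a TrialSet."""
    mask = trialset.mask
    psi, L, surprise, psi_post = _accumulate(trialset.llr, mask, params, surprise_H)
    n, m = psi.shape
    last = trialset.n_samples - 1
    delta_psi = np.full((n, m), np.nan)
    delta_psi[:, :-1] = psi[:, 1:] - psi[:, :-1]
    delta_psi[np.arange(n), last] = psi_post - psi[np.arange(n), last]
    slogit = logit_surprise(surprise) if surprise is not None else None
    if slogit is not None:
        slogit[np.isnan(surprise)] = np.nan
    return BeliefTraceSet(
        params=params,
        psi=psi,
        L=L,
        delta_psi=delta_psi,
        surprise=surprise,
        surprise_logit=slogit,
        uncertainty=-np.abs(psi),
        L_final=L[np.arange(n), last],
    )


def simulate_choices(L_final, noise: float, rng: np.random.Generator,
                     rule: str = "erf") -> np.ndarray:
    """Draw +/-1 choices from the noisy choice rule."""
    p = choice_probability(L_final, noise, rule=rule)
    return np.where(rng.random(np.shape(L_final)) < p, 1, -1)
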