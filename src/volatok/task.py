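"""Generative process of the volatile token task.

A trial presents a sequence of stimulus "samples" whose polar angles are drawn
from one of two Gaussian generative states (Right: +mu, Left: -mu, common
s.d. sigma).  Between consecutive samples the active state switches with a
fixed hazard rate.  Trials run to ``max_samples`` unless they terminate early,
in which case the length is uniform over ``early_range``.  The observer's
task is to report the state active at the final sample.

Because the two state-conditional likelihoods are equal-variance Gaussians,
the log-likelihood ratio of a sample at angle ``x`` is linear in ``x``:

    LLR(x) = log N(x; +mu, sigma) - log N(x; -mu, sigma) = 2 * mu * x / sigma**2
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "Trial",
    "TrialSet",
    "compute_llr",
    "snr",
    "generate_trials",
]


@dataclass(frozen=True)
class TaskConfig:
    """Generative parameters of the task.

    Defaults mirror the study design: hazard 0.1 per between-sample
    transition, generative means at +/-26 deg with s.d. 29 deg, at most 10
    samples per trial, 0.3 probability of early termination (length then
    uniform on 1..9), 0.4 s stimulus onset asynchrony.
    """

    hazard: float = 0.1
    mu: float = 26.0
    sigma: float = 29.0
    max_samples: int = 10
    p_early: float = 0.3
    early_range: tuple[int, int] = (1, 9)
    soa: float = 0.4
    sample_duration: float = 0.3
    n_trials: int = 1440
    n_sessions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 0.5:
            raise ValueError(f"hazard must lie in [0, 0.5], got {self.hazard}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 <= self.p_early <= 1.0:
            raise ValueError(f"p_early must lie in [0, 1], got {self.p_early}")
        lo, hi = self.early_range
        if not (1 <= lo <= hi <= self.max_samples - 1):
            raise ValueError(
                f"early_range {self.early_range} must satisfy "
                f"1 <= lo <= hi <= max_samples-1 = {self.max_samples - 1}"
            )
        if self.max_samples < 1 or self.n_trials < 1 or self.n_sessions < 1:
            raise ValueError("max_samples, n_trials and n_sessions must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["early_range"] = tuple(raw["early_range"])
        return cls(**raw)


def compute_llr(x, mu: float, sigma: float):
    """Log-likelihood ratio (Right vs Left) of sample angle(s) ``x``.

    Evaluates log N(x; +mu, sigma) - log N(x; -mu, sigma), which for
    equal-variance Gaussians reduces to the closed form 2*mu*x/sigma**2.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return 2.0 * mu * np.asarray(x, dtype=float) / sigma**2


def snr(config: TaskConfig) -> float:
    """Generative signal-to-noise ratio: difference in means over s.d."""
    return 2.0 * config.mu / config.sigma


@dataclass
class Trial:
    """One simulated trial (per-sample arrays are 0-indexed internally)."""

    trial_id: int
    session: int
    n_samples: int
    states: np.ndarray  # +/-1 per sample
    x: np.ndarray  # polar angle in degrees per sample
    llr: np.ndarray  # log-likelihood ratio per sample

    @property
    def final_state(self) -> int:
        return int(self.states[self.n_samples - 1])

    def is_full(self, max_samples: int) -> bool:
        return self.n_samples == max_samples


@dataclass
class TrialSet:
    """A set of trials plus the config that generated them.

    Padded (n_trials, max_samples) arrays are exposed for vectorised
    downstream computation; entries beyond a trial's length are zero (and
    excluded by ``mask``).
    """

    config: TaskConfig
    states: np.ndarray  # (n, max_samples) int, zero-padded
    x: np.ndarray  # (n, max_samples) float, zero-padded
    llr: np.ndarray  # (n, max_samples) float, zero-padded
    n_samples: np.ndarray  # (n,) int
    session: np.ndarray  # (n,) int

    def __len__(self) -> int:
        return len(self.n_samples)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (n, max_samples): True where a sample was presented."""
        return np.arange(self.config.max_samples)[None, :] < self.n_samples[:, None]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[np.arange(len(self)), self.n_samples - 1]

    @property
    def is_full(self) -> np.ndarray:
        return self.n_samples == self.config.max_samples

    def trial(self, i: int) -> Trial:
        k = int(self.n_samples[i])
        return Trial(
            trial_id=i,
            session=int(self.session[i]),
            n_samples=k,
            states=self.states[i, :k].copy(),
            x=self.x[i, :k].copy(),
            llr=self.llr[i, :k].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per presented sample."""
        rows = []
        full = self.is_full
        fs = self.final_state
        for i in range(len(self)):
            k = int(self.n_samples[i])
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": i,
                        "session": int(self.session[i]),
                        "n_samples": k,
                        "sample_index": np.arange(1, k + 1),
                        "state": self.states[i, :k].astype(int),
                        "x_deg": self.x[i, :k],
                        "llr": self.llr[i, :k],
                        "final_state": int(fs[i]),
                        "is_full": bool(full[i]),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: TaskConfig) -> "TrialSet":
        n = frame["trial_id"].nunique()
        m = config.max_samples
        states = np.zeros((n, m))
        x = np.zeros((n, m))
        llr = np.zeros((n, m))
        n_samples = np.zeros(n, dtype=int)
        session = np.zeros(n, dtype=int)
        for tid, grp in frame.groupby("trial_id"):
            k = len(grp)
            idx = grp["sample_index"].to_numpy() - 1
            states[tid, idx] = grp["state"].to_numpy()
            x[tid, idx] = grp["x_deg"].to_numpy()
            llr[tid, idx] = grp["llr"].to_numpy()
            n_samples[tid] = k
            session[tid] = grp["session"].iloc[0]
        return cls(config, states, x, llr, n_samples, session)

    @classmethod
    def from_csv(cls, path, config: TaskConfig) -> "TrialSet":
        return cls.from_frame(pd.read_csv(path), config)


def generate_trials(config: TaskConfig, rng: np.random.Generator | None = None) -> TrialSet:
    """Simulate a set of trials from the task's generative process.

    The initial state is equiprobable; each subsequent sample's state flips
    with probability ``hazard``.  Trial length is drawn at trial start:
    ``max_samples`` with probability 1 - p_early, else uniform over
    ``early_range``.  Sample angles come from the untruncated Gaussian for
    the active state.  Trials are split into ``n_sessions`` contiguous blocks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_trials, config.max_samples

    early = rng.random(n) < config.p_early
    lo, hi = config.early_range
    n_samples = np.where(early, rng.integers(lo, hi + 1, size=n), m)

    states = np.empty((n, m))
    states[:, 0] = rng.choice([-1.0, 1.0], size=n)
    flips = rng.random((n, m - 1)) < config.hazard
    for s in range(1, m):
        states[:, s] = states[:, s - 1] * np.where(flips[:, s - 1], -1.0, 1.0)

    x = rng.normal(states * config.mu, config.sigma)
    llr = compute_llr(x, config.mu, config.sigma)

    mask = np.arange(m)[None, :] < n_samples[:, None]
    states = np.where(mask, states, 0.0)
    x = np.where(mask, x, 0.0)
    llr = np.where(mask, llr, 0.0)

    # contiguous session blocks, labelled 0 .. n_sessions-1
    session = np.minimum(
        (np.arange(n) * config.n_sessions) // n, config.n_sessions - 1
    ).astype(int)
    return TrialSet(config, states, x, llr, n_samples.astype(int), session)
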