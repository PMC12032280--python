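"""Synthetic multi-channel EEG with known ground-truth encodings.

The generator emits "post-preprocessing" epochs (clean of artifacts, 200 Hz,
[-0.4, 5.4] s around trial onset) whose statistical structure matches what
the downstream analyses assume:

* an internal decision variable d(t) that is piecewise-constant at the
  normative prior and ramps to the updated belief after each sample, with
  each update corrupted by a shared multiplicative gain noise eta;
* motor channels carrying a beta-band (default 20 Hz) oscillation whose
  left/right envelopes are exponentially modulated by d(t) such that the
  decibel-transformed left-minus-right power difference equals
  kappa_mbl * d(t) in expectation (the dB-linear coding makes the
  lateralisation regressions analytic);
* centroparietal channels with a transient sample-locked raised-cosine
  deflection scaling with |delta_psi * (1 + eta)|;
* anterior channels with the same kernel scaling with |LLR|;
* pink slow drift, white sensor noise and an additive session offset;
* agent choices read out from the eta-corrupted final decision variable,
  so the same noise source couples neural residuals to behaviour.

Default amplitudes and noise levels are in the realistic range for
single-trial scalp EEG (evoked components of a few microvolts against
10-15 uV single-trial noise); the kernel peaks 0.35 s post sample.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .observer import BeliefTraceSet, ObserverParams, run_observer_set
from .task import TaskConfig, TrialSet, generate_trials

__all__ = [
    "SynthConfig",
    "EEGDataset",
    "GroundTruth",
    "ParticipantData",
    "simulate_participant",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-EEG generator settings (times in seconds, rates in Hz)."""

    fs: float = 200.0
    t_start: float = -0.4
    t_end: float = 5.4
    soa: float = 0.4
    n_left_motor: int = 6
    n_right_motor: int = 6
    n_centroparietal: int = 4
    n_anterior: int = 4
    n_uninformative: int = 4
    beta_freq: float = 20.0
    kappa_mbl: float = 1.0  # dB of lateralisation per unit decision variable
    kappa_cpp: float = 1.0  # uV per unit |belief update|
    kappa_ant: float = 0.4  # uV per unit |LLR|
    kernel_peak: float = 0.35  # s post sample onset
    kernel_halfwidth: float = 0.2  # half-width at half maximum, s
    ramp_window: tuple[float, float] = (0.1, 0.4)  # DV ramp, s post onset
    sigma_eta: float = 0.3  # shared multiplicative gain-noise s.d.
    carrier_amp: float = 2.0  # baseline beta carrier amplitude, uV
    motor_noise_sd: float = 0.5  # broadband noise on motor channels, uV
    erp_noise_sd: float = 14.0  # white noise on broadband channels, uV
    drift_amp: float = 2.0  # RMS of pink slow drift, uV
    session_offset: float = 0.5  # additive offset for session 1 vs 0, uV
    choice_noise: float = 1.0  # terminal decision noise, log-odds units
    seed: int = 0

    def __post_init__(self) -> None:
        n_t = (self.t_end - self.t_start) * self.fs
        if abs(n_t - round(n_t)) > 1e-9:
            raise ValueError("fs * epoch length must be an integer sample count")
        for name in ("kappa_mbl", "kappa_cpp", "kappa_ant", "sigma_eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_times(self) -> int:
        return round((self.t_end - self.t_start) * self.fs)

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_times) / self.fs

    def onset_times(self, max_samples: int) -> np.ndarray:
        return self.soa * np.arange(1, max_samples + 1)

    def channel_table(self) -> pd.DataFrame:
        rows = []
        for role, hemi, n in (
            ("left_motor", "L", self.n_left_motor),
            ("right_motor", "R", self.n_right_motor),
            ("centroparietal", "M", self.n_centroparietal),
            ("anterior", "M", self.n_anterior),
            ("uninformative", "M", self.n_uninformative),
        ):
            for i in range(n):
                rows.append({"label": f"{role}_{i}", "role": role, "hemisphere": hemi})
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Per-(trial, sample) generative quantities behind one dataset."""

    psi: np.ndarray
    delta_psi: np.ndarray
    llr: np.ndarray
    surprise_logit: np.ndarray
    eta: np.ndarray  # shared gain noise, NaN beyond trial length
    dv_final: np.ndarray  # eta-corrupted final decision variable per trial
    choice: np.ndarray  # +/-1 per trial


@dataclass
class EEGDataset:
    """Trials x channels x time array plus metadata."""

    data: np.ndarray  # float32 (n_trials, n_channels, n_times)
    time: np.ndarray
    channels: pd.DataFrame  # label, role, hemisphere
    trials: pd.DataFrame  # session, choice, n_samples
    onsets: np.ndarray  # onset indices into the time axis, (max_samples,)
    config: SynthConfig
    participant: int = 0

    def channel_indices(self, role: str) -> np.ndarray:
        idx = np.flatnonzero(self.channels["role"].to_numpy() == role)
        if len(idx) == 0:
            raise KeyError(f"no channels with role {role!r}")
        return idx

    def save_h5(self, path, ground_truth: GroundTruth | None = None) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data.astype(np.float32))
            fh.create_dataset("time", data=self.time)
            ch = fh.create_group("channels")
            for col in ("label", "role", "hemisphere"):
                ch.create_dataset(
                    col, data=np.array(self.channels[col], dtype="S32")
                )
            tr = fh.create_group("trials")
            for col in ("session", "choice", "n_samples"):
                tr.create_dataset(col, data=self.trials[col].to_numpy())
            fh.create_dataset("onsets", data=self.onsets)
            if ground_truth is not None:
                gt = fh.create_group("ground_truth")
                for fld in dataclasses.fields(GroundTruth):
                    gt.create_dataset(fld.name, data=getattr(ground_truth, fld.name))
            fh.attrs["config"] = json.dumps(dataclasses.asdict(self.config))
            fh.attrs["participant"] = self.participant

    @classmethod
    def load_h5(cls, path) -> tuple["EEGDataset", GroundTruth | None]:
        with h5py.File(path, "r") as fh:
            raw = json.loads(fh.attrs["config"])
            raw["ramp_window"] = tuple(raw["ramp_window"])
            cfg = SynthConfig(**raw)
            channels = pd.DataFrame(
                {
                    col: [s.decode() for s in fh["channels"][col][()]]
                    for col in ("label", "role", "hemisphere")
                }
            )
            trials = pd.DataFrame(
                {col: fh["trials"][col][()] for col in ("session", "choice", "n_samples")}
            )
            ds = cls(
                data=fh["data"][()],
                time=fh["time"][()],
                channels=channels,
                trials=trials,
                onsets=fh["onsets"][()],
                config=cfg,
                participant=int(fh.attrs["participant"]),
            )
            gt = None
            if "ground_truth" in fh:
                gt = GroundTruth(
                    **{k: fh["ground_truth"][k][()] for k in fh["ground_truth"]}
                )
        return ds, gt


def _raised_cosine(cfg: SynthConfig) -> tuple[np.ndarray, int]:
    """Evoked kernel K(t) and the index offset of its first tap.

    Raised cosine centred at ``kernel_peak`` with half maximum at
    +/- ``kernel_halfwidth``, i.e. support peak +/- 2*halfwidth.
    """
    w = 2.0 * cfg.kernel_halfwidth
    t = np.arange(round((cfg.kernel_peak - w) * cfg.fs), round((cfg.kernel_peak + w) * cfg.fs) + 1) / cfg.fs
    k = 0.5 * (1.0 + np.cos(np.pi * (t - cfg.kernel_peak) / w))
    return k, round((cfg.kernel_peak - w) * cfg.fs)


def _pink_noise(shape: tuple, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise along the last axis (zero mean)."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = (rng.standard_normal(shape[:-1] + (len(freqs),))
                + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * scale
    out = np.fft.irfft(spectrum, n=n, axis=-1)
    rms = out.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return out / rms


def _dv_trace(cfg: SynthConfig, trialset: TrialSet, dpsi_corrupt: np.ndarray) -> np.ndarray:
    """(n_trials, n_times) internal decision variable d(t).

    Holds the running corrupted belief, ramping linearly within
    ``ramp_window`` after each sample onset to incorporate that sample's
    corrupted update.
    """
    n, m = dpsi_corrupt.shape
    D = np.cumsum(np.nan_to_num(dpsi_corrupt), axis=1)  # level after sample s
    onsets = cfg.onset_times(m)
    r0, r1 = cfg.ramp_window
    # interpolation knots shared across trials
    knot_t = np.concatenate([[cfg.t_start], np.column_stack([onsets + r0, onsets + r1]).ravel()])
    times = cfg.times
    out = np.empty((n, cfg.n_times))
    levels = np.concatenate([np.zeros((n, 1)), D], axis=1)  # level before each ramp
    for i in range(n):
        vals = np.empty(1 + 2 * m)
        vals[0] = 0.0
        vals[1::2] = levels[i, :-1]
        vals[2::2] = levels[i, 1:]
        out[i] = np.interp(times, knot_t, vals)
    return out


def simulate_participant(trialset: TrialSet, traces: BeliefTraceSet,
                         cfg: SynthConfig,
                         rng: np.random.Generator | None = None,
                         participant: int = 0) -> tuple[EEGDataset, GroundTruth]:
    """Generate one participant's synthetic EEG and ground truth."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(trialset)
    m = trialset.config.max_samples
    if traces.psi.shape != (n, m):
        raise ValueError("traces and trialset do not match")
    times = cfg.times
    n_t = cfg.n_times
    mask = trialset.mask

    eta = np.where(mask, rng.normal(0.0, cfg.sigma_eta, size=(n, m)), np.nan)
    dpsi_corrupt = traces.delta_psi * (1.0 + eta)
    dv = _dv_trace(cfg, trialset, dpsi_corrupt)
    dv_final = np.nansum(dpsi_corrupt, axis=1)
    choice = np.where(
        dv_final + cfg.choice_noise * rng.standard_normal(n) >= 0.0, 1, -1
    )

    channels = cfg.channel_table()
    n_ch = len(channels)
    data = np.zeros((n, n_ch, n_t), dtype=np.float32)
    roles = channels["role"].to_numpy()

    # --- motor channels: amplitude-modulated beta carrier ---------------
    for side, sgn in (("left_motor", +1.0), ("right_motor", -1.0)):
        idx = np.flatnonzero(roles == side)
        env = cfg.carrier_amp * 10.0 ** (sgn * cfg.kappa_mbl * dv / 40.0)
        for c in idx:
            phase = rng.uniform(0.0, 2.0 * np.pi, size=(n, 1))
            carrier = np.cos(2.0 * np.pi * cfg.beta_freq * times[None, :] + phase)
            data[:, c, :] += (env * carrier
                              + rng.normal(0.0, cfg.motor_noise_sd, size=(n, n_t)))

    # --- sample-locked evoked responses ---------------------------------
    kern, k_off = _raised_cosine(cfg)
    onset_idx = np.round((cfg.onset_times(m) - cfg.t_start) * cfg.fs).astype(int)
    amp_cpp = cfg.kappa_cpp * np.abs(np.nan_to_num(dpsi_corrupt))
    amp_ant = cfg.kappa_ant * np.abs(trialset.llr)
    evoked_cpp = np.zeros((n, n_t))
    evoked_ant = np.zeros((n, n_t))
    for s in range(m):
        a = onset_idx[s] + k_off
        b = a + len(kern)
        lo, hi = max(a, 0), min(b, n_t)
        seg = kern[lo - a:hi - a]
        evoked_cpp[:, lo:hi] += amp_cpp[:, s, None] * seg[None, :]
        evoked_ant[:, lo:hi] += amp_ant[:, s, None] * seg[None, :]

    session_off = cfg.session_offset * trialset.session[:, None]
    for role, evoked in (("centroparietal", evoked_cpp),
                         ("anterior", evoked_ant),
                         ("uninformative", np.zeros((n, n_t)))):
        for c in np.flatnonzero(roles == role):
            noise = rng.normal(0.0, cfg.erp_noise_sd, size=(n, n_t))
            drift = cfg.drift_amp * _pink_noise((n, n_t), cfg.fs, rng)
            data[:, c, :] += evoked + noise + drift + session_off

    trials_tab = pd.DataFrame(
        {
            "session": trialset.session,
            "choice": choice,
            "n_samples": trialset.n_samples,
        }
    )
    ds = EEGDataset(
        data=data,
        time=times,
        channels=channels,
        trials=trials_tab,
        onsets=onset_idx,
        config=cfg,
        participant=participant,
    )
    gt = GroundTruth(
        psi=traces.psi,
        delta_psi=traces.delta_psi,
        llr=np.where(mask, trialset.llr, np.nan),
        surprise_logit=traces.surprise_logit,
        eta=eta,
        dv_final=dv_final,
        choice=choice,
    )
    return ds, gt


@dataclass
class ParticipantData:
    participant: int
    trialset: TrialSet
    traces: BeliefTraceSet
    eeg: EEGDataset
    ground_truth: GroundTruth


def simulate_cohort(n_participants: int = 20,
                    task_config: TaskConfig | None = None,
                    observer_params: ObserverParams | None = None,
                    synth_config: SynthConfig | None = None,
                    seed: int = 0) -> Iterator[ParticipantData]:
    """Yield independent participants (own trials, traces, EEG, choices).

    Defaults mirror the study: 20 participants, 1440 trials each over two
    sessions.  Lazily yields one participant at a time so a cohort's raw
    EEG never has to be held in memory at once.
    """
    tcfg = task_config or TaskConfig()
    oparams = observer_params or ObserverParams()
    scfg = synth_config or SynthConfig()
    ss = np.random.SeedSequence(seed)
    for pid, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        trials = generate_trials(
            dataclasses.replace(tcfg, seed=int(child.generate_state(1)[0] % 2**31)),
            rng,
        )
        traces = run_observer_set(trials, oparams)
        eeg, gt = simulate_participant(trials, traces, scfg, rng, participant=pid)
        yield ParticipantData(pid, trials, traces, eeg, gt)
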