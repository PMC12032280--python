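"""End-to-end orchestration of the synthetic study.

Ties the stages together: task simulation -> observer traces -> strategy
benchmarks -> model fitting -> choice kernels -> synthetic EEG ->
feature extraction -> time-resolved regressions -> group statistics.
Every stage draws its randomness from seeds derived deterministically
from one global seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour, features, glm, stats
from .fitting import FitConfig, fit_model
from .observer import ObserverParams, run_observer_set, simulate_choices
from .synth import ParticipantData, SynthConfig, simulate_cohort
from .task import TaskConfig, TrialSet, generate_trials

__all__ = [
    "PipelineConfig",
    "strategy_accuracies",
    "compute_mbl",
    "conditioned_erp",
    "analyse_participant",
    "analyse_cohort",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of the full synthetic study."""

    task: TaskConfig = field(default_factory=TaskConfig)
    observer: ObserverParams = field(default_factory=ObserverParams)
    fit: FitConfig = field(default_factory=FitConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_participants: int = 20
    n_benchmark_trials: int = 100_000
    n_perm: int = 1000
    seed: int = 0
    skip_eeg: bool = False
    skip_fits: bool = False

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage 31-bit seed derived from the global seed."""
        import zlib

        h = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(h.generate_state(1)[0] % 2**31)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["task"]["early_range"] = tuple(raw["task"]["early_range"])
        raw["synth"]["ramp_window"] = tuple(raw["synth"]["ramp_window"])
        return cls(
            task=TaskConfig(**raw.pop("task")),
            observer=ObserverParams(**raw.pop("observer")),
            fit=FitConfig(**raw.pop("fit")),
            synth=SynthConfig(**raw.pop("synth")),
            **raw,
        )


def strategy_accuracies(trialset: TrialSet, rng: np.random.Generator | None = None) -> dict:
    """Benchmark accuracies of three strategies against the final state.

    ideal: noiseless normative observer with the generative hazard rate;
    last_sample: sign of the final sample's LLR; perfect: sign of the sum
    of all LLRs.  Exact-zero decision variables are split by a seeded coin.
    """
    if len(trialset) == 0:
        raise ValueError("empty trial set")
    if rng is None:
        rng = np.random.default_rng(trialset.config.seed)
    cfg = trialset.config
    params = ObserverParams(model_kind="normative", h_subj=cfg.hazard, gain=1.0)
    traces = run_observer_set(trialset, params)
    target = trialset.final_state

    def acc(dv: np.ndarray) -> float:
        sign = np.sign(dv)
        ties = sign == 0
        if ties.any():
            sign[ties] = rng.choice([-1.0, 1.0], size=int(ties.sum()))
        return float(np.mean(sign == target))

    n = np.arange(len(trialset))
    last_llr = trialset.llr[n, trialset.n_samples - 1]
    return {
        "ideal": acc(traces.L_final.copy()),
        "last_sample": acc(last_llr.copy()),
        "perfect": acc(trialset.llr.sum(axis=1)),
    }


def compute_mbl(eeg, band: tuple[float, float] = (13.0, 30.0),
                baseline_window: tuple[float, float] = (-0.1, 0.0)) -> np.ndarray:
    """Motor beta lateralisation trace per trial: (n_trials, n_times).

    STFT power on each motor channel, dB against the trial-averaged
    pre-trial baseline, averaged over the band and over each hemispheric
    electrode group; returns left minus right.  Channels are processed one
    at a time to bound memory.
    """
    cfg = eeg.config
    freqs = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1)
    sums = {}
    for role in ("left_motor", "right_motor"):
        idx = eeg.channel_indices(role)
        acc = None
        for c in idx:
            tfr = features.stft_power(
                eeg.data[:, c, :], cfg.fs, freqs=freqs, times=eeg.time
            )
            tfr_db = features.db_baseline(tfr, baseline_window)
            band_db = tfr_db.power.mean(axis=-2)  # average the band
            acc = band_db if acc is None else acc + band_db
        sums[role] = acc / len(idx)
    return sums["left_motor"] - sums["right_motor"]


def conditioned_erp(eeg, role: str, highpass: float = 0.1,
                    lowpass: float = 6.0, baseline: bool = True) -> np.ndarray:
    """Electrode-group-averaged ERP after the analysis filter chain.

    High-pass (3rd-order two-pass Butterworth) at ``highpass``, low-pass
    at ``lowpass``; with ``baseline`` the 100 ms preceding trial onset is
    subtracted per trial (the 0.1 Hz variant).  The 1 Hz variant used for
    residual analyses conventionally skips the baseline step.
    """
    sig = eeg.data[:, eeg.channel_indices(role), :].mean(axis=1).astype(float)
    cfg = eeg.config
    sig = features.butterworth(sig, cfg.fs, "high", highpass, order=3)
    sig = features.butterworth(sig, cfg.fs, "low", lowpass, order=3)
    if baseline:
        sel = (eeg.time >= -0.1) & (eeg.time < 0.0)
        sig = sig - sig[:, sel].mean(axis=1, keepdims=True)
    return sig


# canonical regression designs (signed for MBL, unsigned for the ERP)
MBL_FULL = ["psi", "llr", "llr_x_surprise"]
MBL_SIMPLE = ["psi", "delta_psi"]
ERP_FULL = ["abs_psi", "abs_llr", "abs_llr_x_surprise"]
ERP_SIMPLE = ["abs_delta_psi"]
MBL_CANDIDATES = {"DV": "psi_next", "EE": "delta_psi", "OE": "llr"}
ERP_CANDIDATES = {"DV": "abs_psi_next", "EE": "abs_delta_psi", "OE": "abs_llr"}


def analyse_participant(pdata: ParticipantData,
                        sample_window: tuple[float, float] = (0.0, 1.0),
                        residual_window: tuple[float, float] = (0.25, 0.50),
                        sample_range: tuple[int, int] = (2, 10)) -> dict:
    """Run the full single-participant EEG analysis battery.

    Returns a dict of compact summaries: time-resolved betas for the
    lateralisation and ERP designs, adjusted-R^2 differences for the
    DV/EE/OE single-regressor models on MBL, centroparietal and anterior
    signals, residual stores, the motor-update coupling betas and the
    choice-kernel results (plain and residual-augmented).
    """
    trialset, traces, eeg = pdata.trialset, pdata.traces, pdata.eeg
    choices = pdata.ground_truth.choice
    cfg = eeg.config
    m = trialset.config.max_samples
    onsets_s = cfg.onset_times(m)
    full = np.flatnonzero(trialset.is_full)
    regs = glm.sample_regressors(trialset, traces, full_only=True)
    session_full = regs["session"]
    epoch_times = np.arange(round(sample_window[0] * cfg.fs),
                            round(sample_window[1] * cfg.fs)) / cfg.fs

    def sample_epochs(sig: np.ndarray) -> np.ndarray:
        return features.epoch_samples(sig[full], eeg.time, onsets_s, cfg.fs,
                                      window=sample_window)

    # --- motor beta lateralisation --------------------------------------
    mbl = compute_mbl(eeg)
    mbl_ep = sample_epochs(mbl)
    eq9 = glm.timeresolved_regression(mbl_ep, regs, MBL_FULL, session_full,
                                      epoch_times, sample_range)
    eq10 = glm.timeresolved_regression(mbl_ep, regs, MBL_SIMPLE, session_full,
                                       epoch_times, sample_range)
    cmp_mbl = glm.single_regressor_comparison(mbl_ep, regs, MBL_CANDIDATES,
                                              session_full, epoch_times,
                                              sample_range)
    mbl_resid = glm.extract_residuals(mbl_ep, regs, MBL_FULL, session_full,
                                      epoch_times, sample_range=(2, m),
                                      window=residual_window)
    mbl_scalars = features.sample_scalars(mbl[full], eeg.time, onsets_s, cfg.fs)

    # --- centroparietal / anterior ERPs ---------------------------------
    cp_slow = conditioned_erp(eeg, "centroparietal", highpass=0.1)
    cp_ep = sample_epochs(cp_slow)
    eq11 = glm.timeresolved_regression(cp_ep, regs, ERP_FULL, session_full,
                                       epoch_times, sample_range)
    eq12 = glm.timeresolved_regression(cp_ep, regs, ERP_SIMPLE, session_full,
                                       epoch_times, sample_range)

    cp_fast = conditioned_erp(eeg, "centroparietal", highpass=1.0, baseline=False)
    cp_fast_ep = sample_epochs(cp_fast)
    ant_fast = conditioned_erp(eeg, "anterior", highpass=1.0, baseline=False)
    ant_fast_ep = sample_epochs(ant_fast)
    cmp_cpp = glm.single_regressor_comparison(cp_fast_ep, regs, ERP_CANDIDATES,
                                              session_full, epoch_times,
                                              sample_range)
    cmp_ant = glm.single_regressor_comparison(ant_fast_ep, regs, ERP_CANDIDATES,
                                              session_full, epoch_times,
                                              sample_range)
    cpp_resid = glm.extract_residuals(cp_fast_ep, regs, ERP_SIMPLE, session_full,
                                      epoch_times, sample_range=(1, m),
                                      window=residual_window)

    coupling = glm.motor_update_coupling(mbl_scalars, regs["delta_psi"], cpp_resid)

    # scatter full-trial residual stores back onto the whole trial set
    n_total = len(trialset)
    cpp_resid_all = np.full((n_total, m), np.nan)
    cpp_resid_all[full] = cpp_resid
    mbl_resid_all = np.full((n_total, m), np.nan)
    mbl_resid_all[full] = mbl_resid

    kernel = behaviour.kernel_regression(trialset, traces, choices,
                                         participant=pdata.participant)
    kernel_cpp = behaviour.residual_weight_regression(
        trialset, traces, choices, cpp_resid_all, participant=pdata.participant
    )
    kernel_mbl = behaviour.residual_choice_bias_regression(
        trialset, traces, choices, mbl_resid_all, participant=pdata.participant
    )

    return {
        "participant": pdata.participant,
        "times": epoch_times,
        "eq9": eq9,
        "eq10": eq10,
        "eq11": eq11,
        "eq12": eq12,
        "cmp_mbl": cmp_mbl,
        "cmp_cpp": cmp_cpp,
        "cmp_ant": cmp_ant,
        "coupling": coupling,
        "kernel": kernel,
        "kernel_cpp_residual": kernel_cpp,
        "kernel_mbl_residual": kernel_mbl,
        "cpp_residuals": cpp_resid_all,
        "mbl_residuals": mbl_resid_all,
        "mbl_scalars": mbl_scalars,
    }


def analyse_cohort(n_participants: int = 20,
                   task_config: TaskConfig | None = None,
                   observer_params: ObserverParams | None = None,
                   synth_config: SynthConfig | None = None,
                   seed: int = 0) -> list[dict]:
    """Simulate and analyse a cohort; one summary dict per participant."""
    out = []
    for pdata in simulate_cohort(n_participants, task_config, observer_params,
                                 synth_config, seed):
        out.append(analyse_participant(pdata))
    return out


def stack_betas(results: list[dict], key: str, regressor: str) -> np.ndarray:
    """Participants x time matrix of one regressor's betas."""
    out = []
    for r in results:
        coef = r[key]
        out.append(coef.beta[coef.regressors.index(regressor)])
    return np.asarray(out)


def stack_r2_diff(results: list[dict], key: str, candidate: str) -> np.ndarray:
    return np.asarray([r[key].diff_vs_reference[candidate] for r in results])


def run_full_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute every stage of the synthetic study and collect a report."""
    report: dict = {"config_seed": config.seed}

    # 1. benchmark strategy accuracies on a fresh large simulation
    bench_cfg = dataclasses.replace(
        config.task, n_trials=config.n_benchmark_trials,
        seed=config.stage_seed("benchmark"),
    )
    rng = np.random.default_rng(config.stage_seed("benchmark-ties"))
    bench = generate_trials(bench_cfg)
    report["strategy_accuracies"] = strategy_accuracies(bench, rng)
    report["snr"] = 2.0 * config.task.mu / config.task.sigma

    # 2. observer fit on one simulated agent (normative model)
    if not config.skip_fits:
        rng_fit = np.random.default_rng(config.stage_seed("fit-agent"))
        agent_cfg = dataclasses.replace(config.task, seed=config.stage_seed("fit-trials"))
        agent_trials = generate_trials(agent_cfg)
        traces = run_observer_set(agent_trials, config.observer)
        choices = simulate_choices(traces.L_final, config.observer.noise, rng_fit)
        fit = fit_model(
            agent_trials, choices, "normative",
            dataclasses.replace(config.fit, seed=config.stage_seed("pso")),
        )
        report["fit"] = json.loads(fit.to_json())

    # 3. EEG cohort and group statistics
    if not config.skip_eeg:
        results = analyse_cohort(
            config.n_participants, config.task, config.observer,
            config.synth, seed=config.stage_seed("cohort"),
        )
        psi_b = stack_betas(results, "eq10", "psi")
        dpsi_b = stack_betas(results, "eq10", "delta_psi")
        abs_dpsi_b = stack_betas(results, "eq12", "abs_delta_psi")
        dv_oe = stack_r2_diff(results, "cmp_mbl", "DV")
        ee_oe = stack_r2_diff(results, "cmp_cpp", "EE")
        sseed = config.stage_seed("cluster")
        report["eeg_group"] = {
            "psi_cluster_p": stats.cluster_permutation_test(
                psi_b, n_perm=config.n_perm, seed=sseed).min_p,
            "delta_psi_cluster_p": stats.cluster_permutation_test(
                dpsi_b, n_perm=config.n_perm, seed=sseed).min_p,
            "abs_delta_psi_cluster_p": stats.cluster_permutation_test(
                abs_dpsi_b, n_perm=config.n_perm, seed=sseed).min_p,
            "dv_minus_oe_cluster_p": stats.cluster_permutation_test(
                dv_oe, n_perm=config.n_perm, seed=sseed).min_p,
            "ee_minus_oe_cluster_p": stats.cluster_permutation_test(
                ee_oe, n_perm=config.n_perm, seed=sseed).min_p,
        }
        recency = behaviour.recency_test(
            [r["kernel"] for r in results], n_perm=config.n_perm,
            seed=config.stage_seed("recency"),
        )
        report["recency"] = {"mean_diff": recency["mean_diff"], "p": recency["p"]}
        b2 = np.asarray([np.nanmean(r["coupling"].beta_interaction) for r in results])
        report["coupling_beta2_mean"] = float(b2.mean())
        report["coupling_beta2_p"] = stats.paired_permutation_test(
            b2, np.zeros_like(b2), n_perm=config.n_perm,
            seed=config.stage_seed("coupling"),
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        config.to_yaml(out / "config.yaml")
    return report
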