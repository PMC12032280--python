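"""Synthetic EEG: recover the injected neural encodings by regression.

One synthetic participant is generated (beta-band motor lateralisation
tracking the decision variable; sample-locked centroparietal deflections
tracking |belief update|), then analysed exactly as real data would be:
STFT -> dB -> lateralisation index, filtering, sample-locked epochs, and
time-resolved standardised regressions.
"""

import numpy as np

import volatok as v

participant = next(iter(v.simulate_cohort(
    1, v.TaskConfig(n_trials=320), seed=7,
)))
print(f"EEG: {participant.eeg.data.shape[0]} trials x "
      f"{participant.eeg.data.shape[1]} channels x "
      f"{participant.eeg.data.shape[2]} samples at "
      f"{participant.eeg.config.fs:.0f} Hz")

res = v.analyse_participant(participant)
times = res["times"]


def peak(beta):
    i = np.nanargmax(beta)
    return f"peak {beta[i]:+.3f} at {times[i]*1000:.0f} ms post sample"


eq10 = res["eq10"]
print("\nmotor beta lateralisation ~ prior + belief update (+ session):")
for name in eq10.regressors:
    b = eq10.beta[eq10.regressors.index(name)]
    print(f"  {name:>10}: mean standardised beta {np.nanmean(b):+.3f}, {peak(b)}")

eq12 = res["eq12"]
b = eq12.beta[0]
print(f"\ncentroparietal ERP ~ |belief update|: mean {np.nanmean(b):+.3f}, {peak(b)}")

print("\nsingle-regressor adjusted-R2 minus the objective-evidence (LLR) model:")
print(f"  lateralisation, decision-variable model: "
      f"{res['cmp_mbl'].diff_vs_reference['DV'].mean():+.4f}")
print(f"  centroparietal, effective-evidence model: "
      f"{res['cmp_cpp'].diff_vs_reference['EE'].mean():+.4f}")
print("positive differences: the lateralisation is best described by the "
      "evolving belief, the centroparietal response by the belief update — "
      "matching what was injected.")
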