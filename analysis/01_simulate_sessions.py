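"""Generate one synthetic session of every kind and summarize what each
contains.

Writes results/session_summary.csv.  Raw recordings are kept in memory
only; downstream drivers regenerate their own sessions from seeds so every
analysis is reproducible without intermediate files.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from neurostack import synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []

    rec, truth = synth.gen_microwire(n_channels=4, fs=10_000, duration_s=30,
                                     seed=0)
    rows.append({
        "session": "microwire",
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "duration_s": rec.duration_s,
        "detail": f"{sum(t.size for t in truth.unit_spike_times.values())} "
                  f"ground-truth spikes across {len(truth.unit_spike_times)} units",
    })

    rec, events, _ = synth.gen_walk_session(seed=0)
    rows.append({
        "session": "walk",
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "duration_s": rec.duration_s,
        "detail": f"{len(events.of_kind('crossing_start'))} crossings",
    })

    rec, events, truth = synth.gen_memory_session(seed=0)
    labels = np.array(truth.condition_labels)
    rows.append({
        "session": "memory",
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "duration_s": rec.duration_s,
        "detail": f"{labels.size} word onsets, {labels.sum()} remembered",
    })

    rec, protocol, _ = synth.gen_stim_session(interburst_s=0.5, seed=0)
    rows.append({
        "session": "stimulation",
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "duration_s": round(rec.duration_s, 1),
        "detail": f"{protocol.n_bursts} bursts x {protocol.pulses_per_burst} pulses",
    })

    rec, truth = synth.gen_theta_lfp(seed=0)
    rows.append({
        "session": "theta_lfp",
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "duration_s": rec.duration_s,
        "detail": f"theta burst duty cycle "
                  f"{np.mean(truth.theta_envelope > 0.5):.2f}",
    })

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "session_summary.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
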