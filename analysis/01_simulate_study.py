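"""Generate the default digit-span study and summarise what it contains.

Simulates 24 subjects x 12 trials per difficulty level at 50 Hz (2 s
fixation; 3/5/8 digits at one per second; 4 s retention) and writes the
raw trace CSV plus a small per-level summary.

Outputs: results/analysis/traces.csv, results/analysis/trace_summary.csv
"""

import json
from pathlib import Path

import pandas as pd

from pupilload import GeneratorConfig, simulate_dataset, write_trials

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(seed=SEED)
    dataset = simulate_dataset(config)
    write_trials(dataset, OUT / "traces.csv")

    rows = []
    for level in ("low", "medium", "high"):
        trials = [t for t in dataset.trials if t.difficulty == level]
        rows.append(
            {
                "difficulty": level,
                "n_trials": len(trials),
                "digits": config.digits_per_level[level],
                "stimulus_s": config.digits_per_level[level] + config.post_digit_s,
                "samples_per_trial": len(trials[0]),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "trace_summary.csv", index=False)
    (OUT / "generator_config.json").write_text(
        json.dumps({k: str(v) for k, v in vars(config).items()}, indent=2)
    )

    print(f"{dataset.n_trials} trials from {len(dataset.subjects)} subjects "
          f"({dataset.n_samples} samples) -> {OUT/'traces.csv'}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
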