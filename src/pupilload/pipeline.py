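"""End-to-end orchestration: simulate -> preprocess -> extract -> stats -> classify.

Each stage writes its CSV contract into the output directory so stages can
also be run (and inspected) independently:

    traces.csv      raw long-format pupil recordings
    rejections.csv  trials excluded by preprocessing, with reasons
    features.csv    per-trial feature matrix
    lrt.csv         per-feature likelihood-ratio tests
    contrasts.csv   per-feature pairwise contrasts (initial + final stage)
    report.csv      ranked classifier x feature-subset table
    manifest.json   resolved config, seed, and per-stage row counts

Runs are deterministic: the same config and seed produce byte-identical
feature and report CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from .classify import reports_to_frame, wrapper_search
from .config import PipelineConfig
from .features import feature_table
from .preprocess import preprocess_dataset
from .stats import run_feature_analysis
from .synthetic_data import simulate_dataset
from .trace_io import Dataset, read_trials, write_trials

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return len(df)


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None, traces: str | None = None) -> Path:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Input priority: an in-memory ``dataset``, else a ``traces`` CSV path,
    else the synthetic generator seeded with ``config.seed``.
    Returns the artifact directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if dataset is None:
            if traces is not None:
                dataset = read_trials(traces)
            else:
                dataset = simulate_dataset(config.generator, seed=config.seed)
        write_trials(dataset, out / "traces.csv")
        counts["traces"] = dataset.n_samples
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        clean, rejected = preprocess_dataset(dataset, config.preprocess)
        rej = pd.DataFrame(
            [vars(r) for r in rejected], columns=["subject_id", "trial_id", "reason"]
        )
        counts["rejections"] = _write(rej, out / "rejections.csv")
        counts["clean_trials"] = len(clean)
        timings[stage] = time.perf_counter() - t0

        stage = "extract"
        t0 = time.perf_counter()
        feats = feature_table(clean, config.features)
        counts["features"] = _write(feats, out / "features.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "stats"
        t0 = time.perf_counter()
        analysis = run_feature_analysis(feats, config.stats)
        counts["lrt"] = _write(analysis.lrt_frame(), out / "lrt.csv")
        counts["contrasts"] = _write(analysis.contrast_frame(), out / "contrasts.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        reports = wrapper_search(
            feats,
            families=config.classify.families,
            k=config.classify.k,
            seed=config.seed,
            groups_col="subject_id" if config.classify.group_by_subject else None,
        )
        counts["report"] = _write(reports_to_frame(reports), out / "report.csv")
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "row_counts": counts,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    with open(out / "run.log", "w") as fh:
        for k, v in timings.items():
            fh.write(f"{k}: {v:.3f} s, rows={counts}\n")
    return out
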