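"""End-to-end analysis chain and result bundle.

The four processing stages: (1) preprocess (baseline removal, broadband
filter), (2) per-band PLI connectivity from instantaneous phase, (3)
proportional-threshold binary graphs over the sparsity grid, (4)
range-averaged small-world metrics and two-group statistics.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .connectivity import PLIMatrix, average_matrices, pli_matrix
from .montage import MontageSpec
from .network import SmallWorldMetrics, sparsity_sweep
from .recording import EEGRecording
from .signal import bandpass, instantaneous_phase, preprocess
from .simulate import generate_cohort
from .stats import GLOBAL_METRICS, compare_table, roi_aggregate
from .io import write_pli_matrix

__all__ = ["SubjectResult", "PipelineResult", "analyze_recording", "run_pipeline"]


@dataclass
class SubjectResult:
    """Per-band connectivity and range-averaged metrics for one subject."""

    subject_id: str
    condition: str
    pli: dict[str, PLIMatrix]
    per_sparsity: dict[str, list[SmallWorldMetrics]]
    averaged: dict[str, SmallWorldMetrics]


@dataclass
class PipelineResult:
    """Everything one run produces, plus tidy tables."""

    subjects: list[SubjectResult]
    metrics_table: pd.DataFrame
    comparison_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    mean_pli: dict[tuple[str, str], PLIMatrix] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def analyze_recording(
    recording: EEGRecording, config: PipelineConfig, seed: int = 0
) -> SubjectResult:
    """Run stages 1-4 for a single recording (no group statistics)."""
    clean = preprocess(recording)
    pli: dict[str, PLIMatrix] = {}
    per_sparsity: dict[str, list[SmallWorldMetrics]] = {}
    averaged: dict[str, SmallWorldMetrics] = {}
    rng = np.random.default_rng(seed)
    for band in config.bands:
        banded = bandpass(clean, band)
        phases = instantaneous_phase(banded, band)
        conn = pli_matrix(phases, epoch_length=config.epoch_length)
        conn.condition = recording.condition
        pli[band.name] = conn
        per_s, avg = sparsity_sweep(
            conn,
            grid=config.sparsity_grid,
            n_realizations=config.n_random_realizations,
            seed=int(rng.integers(1, 2**31 - 1)),
            path_method=config.path_method,
        )
        per_sparsity[band.name] = per_s
        averaged[band.name] = avg
    return SubjectResult(
        subject_id=recording.subject_id or "unknown",
        condition=recording.condition or "unknown",
        pli=pli,
        per_sparsity=per_sparsity,
        averaged=averaged,
    )


def _metrics_row(subject: SubjectResult, band: str, montage: MontageSpec) -> dict:
    m = subject.averaged[band]
    row = {
        "subject": subject.subject_id,
        "condition": subject.condition,
        "band": band,
        **m.as_dict(),
    }
    for roi, value in roi_aggregate(m.NE_loc, montage, "lobe").items():
        row[f"NE_loc_{roi}"] = value
    for hemi, value in roi_aggregate(m.NE_loc, montage, "hemisphere").items():
        row[f"NE_loc_{hemi}"] = value
    return row


def run_pipeline(
    config: PipelineConfig,
    recordings: list[EEGRecording] | None = None,
    output_dir: str | Path | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute the full chain and (optionally) write the artifact bundle.

    With no ``recordings``, a two-group cohort is simulated from the
    config's state profiles. Outputs: per-condition mean PLI matrices
    (CSV), a tidy per-subject metrics table, per-band comparison tables,
    and a manifest sufficient to re-run the analysis exactly.
    """
    if recordings is None:
        recordings = generate_cohort(
            config.profile_a,
            config.profile_b,
            n_per_group=config.n_per_group,
            duration=config.duration,
            fs=config.fs,
            seed=config.seed,
        )
    if not recordings:
        raise ValueError("no recordings to analyze")
    montage = recordings[0].montage
    rng = np.random.default_rng(config.seed + 1)
    subjects = []
    for rec in recordings:
        try:
            subjects.append(
                analyze_recording(rec, config, seed=int(rng.integers(1, 2**31 - 1)))
            )
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for subject {rec.subject_id!r} "
                f"(condition {rec.condition!r}): {exc}"
            ) from exc

    rows = [
        _metrics_row(s, band.name, montage)
        for s in subjects
        for band in config.bands
    ]
    metrics_table = pd.DataFrame(rows)

    conditions = list(dict.fromkeys(s.condition for s in subjects))
    comparison_tables: dict[str, pd.DataFrame] = {}
    if len(conditions) == 2:
        roi_metrics = tuple(
            c for c in metrics_table.columns if c.startswith("NE_loc_")
        )
        for band in config.bands:
            sub = metrics_table[metrics_table["band"] == band.name]
            comparison_tables[band.name] = compare_table(
                sub, metrics=GLOBAL_METRICS + roi_metrics,
                conditions=(conditions[0], conditions[1]),
            )

    mean_pli: dict[tuple[str, str], PLIMatrix] = {}
    for condition in conditions:
        for band in config.bands:
            group = [
                s.pli[band.name] for s in subjects if s.condition == condition
            ]
            for m in group:
                m.condition = condition
            mean_pli[(condition, band.name)] = average_matrices(group)

    manifest = {
        "package": "neurostates",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "n_recordings": len(recordings),
        "conditions": conditions,
    }
    result = PipelineResult(
        subjects=subjects,
        metrics_table=metrics_table,
        comparison_tables=comparison_tables,
        mean_pli=mean_pli,
        manifest=manifest,
    )
    if write_outputs:
        out = Path(output_dir or config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_table.to_csv(out / "metrics.csv", index=False)
        for band_name, table in comparison_tables.items():
            table.to_csv(out / f"comparisons_{band_name}.csv", index=False)
        for (condition, band_name), matrix in mean_pli.items():
            write_pli_matrix(matrix, out / f"pli_{condition}_{band_name}.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
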