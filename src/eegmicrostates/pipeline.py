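"""End-to-end pipeline: preprocess -> cluster -> backfit -> parameters ->
group statistics, with a JSON run manifest for reproducibility.

Clustering is group-level: GFP-peak maps are pooled across every subject and
condition and clustered once; the single model is canonically labelled and
backfit to each subject's condition epochs.  Peak maps may be randomly
subsampled (``config.max_peak_maps``) before clustering to bound the fit
cost; the subsample is drawn from the config seed, so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import microstates as ms
from . import preprocess as pp
from .io import ConditionEpoch, EEGRecording, PipelineConfig, extract_condition_epochs, read_recording
from .parameters import parameter_table
from .simulate import default_templates
from .stats import ComparisonFamily, results_frame, run_study_comparisons


@dataclass
class PipelineResult:
    model: ms.MicrostateModel
    cv_table: list[dict]
    parameters: pd.DataFrame
    families: list[ComparisonFamily]
    sign_summary: pd.DataFrame
    manifest: dict


def _collect_epochs(
    recordings: list[EEGRecording], config: PipelineConfig,
) -> dict[tuple[str, str, str], ConditionEpoch]:
    epochs = {}
    for rec in recordings:
        clean, _report = pp.preprocess(
            rec, band=config.band, resample_hz=config.resample_hz,
            artifact_mode=config.artifact_mode, seed=config.seed,
        )
        for ep in extract_condition_epochs(clean, rec.group_tag):
            epochs[(rec.subject_id, rec.group_tag, ep.condition_tag)] = ep
    return epochs


def run_pipeline(
    config: PipelineConfig,
    inputs: list[str | Path] | None = None,
    recordings: list[EEGRecording] | None = None,
    subjects: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    fixed_k: int | None = None,
) -> PipelineResult:
    """Execute the full chain on a cohort of marked recordings.

    Either file ``inputs`` or in-memory ``recordings`` must be given.
    ``subjects`` (columns subject, group, age, sex) enables the group
    statistics; with fewer than 2 subjects per group the statistical block
    is skipped.  ``fixed_k`` bypasses cluster-number selection.
    """
    if recordings is None:
        if not inputs:
            raise ValueError("no input recordings given")
        try:
            recordings = [read_recording(p) for p in inputs]
        except Exception as exc:
            raise RuntimeError(f"[read] {exc}") from exc

    rng = np.random.default_rng(config.seed)
    try:
        epochs = _collect_epochs(recordings, config)
    except Exception as exc:
        raise RuntimeError(f"[preprocess/extract] {exc}") from exc

    keys = sorted(epochs)
    try:
        peak_maps = np.vstack([ms.extract_peak_maps(epochs[k]) for k in keys])
        n_total_peaks = len(peak_maps)
        if config.max_peak_maps and n_total_peaks > config.max_peak_maps:
            sel = rng.choice(n_total_peaks, config.max_peak_maps, replace=False)
            peak_maps = peak_maps[np.sort(sel)]
        if fixed_k is not None:
            model = ms.modified_kmeans(
                peak_maps, fixed_k, config.n_restarts, config.max_iter,
                config.tol, rng)
            model.cv_value = ms.cross_validation_criterion(peak_maps, model)
            cv_table = [{"K": fixed_k, "cv": model.cv_value, "gev": model.gev}]
        else:
            _best_k, table = ms.select_cluster_number(
                peak_maps, config.cluster_range, config.n_restarts,
                config.max_iter, config.tol, rng)
            model = min(table, key=lambda r: r["cv"])["model"]
            cv_table = [{k: r[k] for k in ("K", "cv", "gev")} for r in table]
        model = ms.assign_canonical_labels(
            model, default_templates(recordings[0].ch_pos))
    except Exception as exc:
        raise RuntimeError(f"[cluster] {exc}") from exc

    try:
        segmentations = {
            k: ms.backfit(epochs[k], model, config.smoothing_min_samples)
            for k in keys
        }
        params = parameter_table(segmentations)
    except Exception as exc:
        raise RuntimeError(f"[parameters] {exc}") from exc

    families: list[ComparisonFamily] = []
    summary = pd.DataFrame()
    counts = params.groupby("group")["subject"].nunique()
    if subjects is not None and counts.min() >= 2 and len(counts) == 2:
        try:
            families, summary = run_study_comparisons(params, subjects)
        except Exception as exc:
            raise RuntimeError(f"[stats] {exc}") from exc

    manifest = {
        "config": {**dataclasses.asdict(config)},
        "n_recordings": len(recordings),
        "n_epochs": len(epochs),
        "n_peak_maps_total": int(n_total_peaks),
        "n_peak_maps_used": int(len(peak_maps)),
        "selected_k": int(model.K),
        "gev": float(model.gev),
        "cv_table": [{k: (int(r[k]) if k == "K" else float(r[k]))
                      for k in ("K", "cv", "gev")} for r in cv_table],
    }
    result = PipelineResult(model, cv_table, params, families, summary, manifest)
    if out_dir is not None:
        _write_outputs(Path(out_dir), result)
    return result


def _write_outputs(out_dir: Path, result: PipelineResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    result.parameters.to_csv(out_dir / "parameters.csv", index=False)
    maps = pd.DataFrame(result.model.maps.T, columns=result.model.labels)
    maps.to_csv(out_dir / "model_maps.csv", index=False)
    if result.families:
        results_frame(result.families).to_csv(out_dir / "stat_results.csv", index=False)
        result.sign_summary.to_csv(out_dir / "sign_summary.csv")
        (out_dir / "sign_summary.md").write_text(
            result.sign_summary.to_markdown())
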