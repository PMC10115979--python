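"""Temporal microstate parameters from a segmentation.

Per class: coverage (fraction of samples), occurrence (runs per second, edge
runs included), mean duration (ms over interior runs — the first and last run
of an epoch are censored, their true extent being unknown, so they are
excluded from duration but kept in coverage and occurrence), and the
first-order Markov transition matrix (conditional on leaving: row i gives the
probability that a run of class i is immediately followed by each other
class; diagonal zero by construction).  Classes never observed get coverage
and occurrence 0 and a missing duration; transition rows without a successor
are flagged undefined rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microstates import Segmentation


@dataclass
class MicrostateParameters:
    class_names: list[str]
    coverage: np.ndarray          # fraction of samples
    occurrence: np.ndarray        # runs / second
    duration_ms: np.ndarray       # NaN when no interior run
    transition: np.ndarray        # K x K, zero diagonal
    transition_defined: np.ndarray  # per-row bool
    n_segments: np.ndarray
    meta: dict = field(default_factory=dict)


def coverage(seg: Segmentation) -> np.ndarray:
    """Fraction of samples spent in each class."""
    if seg.n_samples == 0:
        raise ValueError("empty segmentation")
    return np.bincount(seg.labels_per_sample, minlength=seg.K) / seg.n_samples


def occurrence(seg: Segmentation) -> np.ndarray:
    """Runs of each class per second (censored edge runs count)."""
    counts = np.zeros(seg.K)
    for lab, _s, _e in seg.segments:
        counts[lab] += 1
    return counts / (seg.n_samples / seg.srate)


def mean_duration(seg: Segmentation) -> np.ndarray:
    """Mean run length per class in ms, excluding the first and last run."""
    runs = seg.segments
    interior = runs[1:-1] if len(runs) > 2 else []
    out = np.full(seg.K, np.nan)
    for k in range(seg.K):
        lens = [e - s for lab, s, e in interior if lab == k]
        if lens:
            out[k] = np.mean(lens) * 1000.0 / seg.srate
    return out


def transition_matrix(seg: Segmentation) -> tuple[np.ndarray, np.ndarray]:
    """(K x K conditional transition matrix, per-row defined flags)."""
    runs = seg.segments
    if len(runs) < 2:
        raise ValueError("need >= 2 runs for transitions")
    counts = np.zeros((seg.K, seg.K))
    for (a, _s, _e), (b, _s2, _e2) in zip(runs[:-1], runs[1:]):
        counts[a, b] += 1
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    trans = np.zeros_like(counts)
    trans[defined] = counts[defined] / row_sums[defined, None]
    return trans, defined


def microstate_parameters(seg: Segmentation, **meta) -> MicrostateParameters:
    trans, defined = transition_matrix(seg)
    n_seg = np.zeros(seg.K, dtype=int)
    for lab, _s, _e in seg.segments:
        n_seg[lab] += 1
    return MicrostateParameters(
        class_names=list(seg.class_names),
        coverage=coverage(seg),
        occurrence=occurrence(seg),
        duration_ms=mean_duration(seg),
        transition=trans,
        transition_defined=defined,
        n_segments=n_seg,
        meta=meta,
    )


def parameter_table(
    segmentations: dict[tuple[str, str, str], Segmentation]
) -> pd.DataFrame:
    """Long-format table: one row per subject x condition x class.

    Keys are (subject_id, group_tag, condition_tag).  Each row carries the
    class's coverage, occurrence, duration, and its outgoing transition
    probabilities as ``to_<class>`` columns (own class NaN; undefined rows
    NaN with ``transition_defined`` False).
    """
    if not segmentations:
        raise ValueError("no segmentations given")
    names = None
    rows = []
    for (subject, group, condition), seg in segmentations.items():
        if names is None:
            names = list(seg.class_names)
        elif list(seg.class_names) != names:
            raise ValueError("segmentations disagree on class labels")
        p = microstate_parameters(seg)
        for k, cls in enumerate(names):
            row = {
                "subject": subject, "group": group, "condition": condition,
                "class": cls,
                "coverage": p.coverage[k],
                "occurrence": p.occurrence[k],
                "duration_ms": p.duration_ms[k],
                "n_segments": int(p.n_segments[k]),
                "transition_defined": bool(p.transition_defined[k]),
            }
            for j, other in enumerate(names):
                row[f"to_{other}"] = (
                    np.nan if (j == k or not p.transition_defined[k])
                    else p.transition[k, j]
                )
            rows.append(row)
    return pd.DataFrame(rows)
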