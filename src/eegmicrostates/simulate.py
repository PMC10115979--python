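"""Synthetic multichannel EEG with planted microstate dynamics.

The generative model is a semi-Markov chain over K template topographies:
segment labels follow a zero-diagonal transition matrix, segment lengths a
gamma duration law (tens of ms), and each segment renders as

    x(t) = sign * envelope(t) * template[label] + noise(t)

with a per-segment random polarity ``sign`` (topographic clustering must
ignore polarity), a rectified-sine GFP envelope (default 10 Hz, the alpha
regime, giving GFP peaks roughly every 50 ms), and spatially smoothed,
band-limited 1/f Gaussian noise scaled to an exact target SNR.  Condition
effects (duration scaling, extra incoming transition mass toward a class)
plant the directional contrasts the group statistics should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AI_CONDITIONS, RA_CONDITIONS, EEGRecording, default_montage

CLASS_NAMES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# Canonical template maps
# ---------------------------------------------------------------------------

def default_templates(ch_pos: np.ndarray, K: int = 4) -> np.ndarray:
    """Four canonical microstate topographies built analytically on a montage.

    A: diagonal gradient from left-posterior to right-anterior; B: its
    left-right mirror; C: anterior-posterior gradient; D: radial
    fronto-central maximum.  Each map is average-referenced and unit-norm.
    """
    ch_pos = np.asarray(ch_pos, dtype=float)
    if K != 4:
        raise ValueError("only the canonical K=4 template set is built in")
    if ch_pos.shape[0] < 8:
        raise ValueError("montage must have at least 8 positions")
    x, y = ch_pos[:, 0], ch_pos[:, 1]
    c = np.cos(np.pi / 4)
    maps = np.stack([
        x * c + y * c,              # A
        -x * c + y * c,             # B
        y,                          # C
        np.exp(-((x - 0.0) ** 2 + (y - 0.2) ** 2) / (2 * 0.35 ** 2)),  # D
    ])
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps


# ---------------------------------------------------------------------------
# Truth and plan
# ---------------------------------------------------------------------------

@dataclass
class ConditionEffect:
    """Per-condition shifts applied to the base dynamics.

    ``duration_scale`` multiplies the mean segment duration of a class;
    ``incoming_boost`` adds transition mass toward a class in every other
    class's row (rows renormalised, diagonal stays zero).
    """

    duration_scale: dict[str, float] = field(default_factory=dict)
    incoming_boost: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated cohort."""

    templates: np.ndarray
    transition: np.ndarray
    duration_mean_ms: np.ndarray   # per class
    duration_shape: float = 4.0    # gamma shape: positive, right-skewed
    gfp_mod_hz: float = 10.0
    snr_db: float = 10.0
    condition_effects: dict[str, ConditionEffect] = field(default_factory=dict)
    subject_sd: float = 0.05       # lognormal sd of per-subject duration factor
    seed: int = 0

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.duration_mean_ms = np.broadcast_to(
            np.asarray(self.duration_mean_ms, dtype=float), (self.K,)
        ).copy()
        if self.transition.shape != (self.K, self.K):
            raise ValueError("transition must be K x K")
        if np.any(np.abs(np.diag(self.transition)) > 0):
            raise ValueError("transition diagonal must be exactly zero")
        if np.any(np.abs(self.transition.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition rows must sum to 1")
        corr = np.abs(self.templates @ self.templates.T)
        off = corr[~np.eye(self.K, dtype=bool)]
        if np.any(off >= 0.95):
            raise ValueError("templates must be mutually distinct (|r| < 0.95)")

    @property
    def K(self) -> int:
        return self.templates.shape[0]

    def for_condition(self, tag: str) -> "SimulationTruth":
        """Truth with this condition's effects folded in."""
        eff = self.condition_effects.get(tag)
        if eff is None:
            return self
        means = self.duration_mean_ms.copy()
        for cls, f in eff.duration_scale.items():
            means[CLASS_NAMES.index(cls)] *= f
        trans = self.transition.copy()
        for cls, boost in eff.incoming_boost.items():
            j = CLASS_NAMES.index(cls)
            for i in range(self.K):
                if i != j:
                    trans[i, j] += boost
        trans[np.eye(self.K, dtype=bool)] = 0.0
        trans /= trans.sum(axis=1, keepdims=True)
        return replace(self, duration_mean_ms=means, transition=trans,
                       condition_effects={})


def uniform_transition(K: int) -> np.ndarray:
    """Uniform off-diagonal row-stochastic matrix with zero diagonal."""
    t = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(t, 0.0)
    return t


def default_truth(snr_db: float = 10.0, seed: int = 0,
                  condition_effects: dict[str, ConditionEffect] | None = None,
                  ) -> SimulationTruth:
    """Default 31-channel, 4-class truth: gamma durations (mean 80 ms),
    uniform transitions, 10 Hz GFP modulation."""
    _, pos = default_montage()
    return SimulationTruth(
        templates=default_templates(pos),
        transition=uniform_transition(4),
        duration_mean_ms=np.full(4, 80.0),
        snr_db=snr_db,
        condition_effects=condition_effects or {},
        seed=seed,
    )


def table2_preset() -> dict[str, ConditionEffect]:
    """Condition effects planting the headline directional pattern: class A
    coverage/duration rise under both imagery and real needling relative to
    rest, with the imagery effect slightly stronger than the needling one."""
    imagery = ConditionEffect(duration_scale={"A": 1.45},
                              incoming_boost={"A": 0.12})
    needling = ConditionEffect(duration_scale={"A": 1.25},
                               incoming_boost={"A": 0.08})
    return {
        "imagery_left": imagery,
        "imagery_right": imagery,
        "real_needle": needling,
    }


@dataclass
class CohortPlan:
    """Shape of a two-arm cohort: an imagery arm (three conditions, repeated
    blocks) and a needling arm (rest + needling)."""

    n_ai_subjects: int = 30
    n_ra_subjects: int = 20
    ai_block_s: float = 60.0    # 4 repeats per condition -> 4 min/condition
    ai_repeats: int = 4
    ra_block_s: float = 120.0   # one block per condition -> 2 min/condition
    srate: float = 200.0
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"AI": 21.7, "RA": 21.5})
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"AI": 1.12, "RA": 2.40})
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"AI": 11 / 30, "RA": 8 / 20})

    def __post_init__(self) -> None:
        if self.n_ai_subjects < 1 or self.n_ra_subjects < 1:
            raise ValueError("subject counts must be >= 1")
        if min(self.ai_block_s, self.ra_block_s, self.srate) <= 0:
            raise ValueError("block lengths and srate must be positive")


# ---------------------------------------------------------------------------
# Label sequences
# ---------------------------------------------------------------------------

def simulate_label_sequence(
    truth: SimulationTruth, duration_s: float, srate: float,
    rng: np.random.Generator | None = None, start: int | None = None,
) -> np.ndarray:
    """Per-sample class labels from the planted semi-Markov chain.

    Segment lengths are gamma draws (shape ``duration_shape``, class mean
    ``duration_mean_ms``) rounded to at least one sample; the next label is
    drawn from the current label's transition row.
    """
    if srate <= 0:
        raise ValueError("srate must be positive")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    n = int(round(duration_s * srate))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if np.any(truth.transition.sum(axis=1) == 0):
        raise ValueError("degenerate transition row (all zero)")
    K = truth.K
    shape = truth.duration_shape
    scale_samp = truth.duration_mean_ms / 1000.0 * srate / shape
    cum = np.cumsum(truth.transition, axis=1)
    labels = np.empty(n, dtype=np.int64)
    cur = int(rng.integers(K)) if start is None else int(start)
    pos = 0
    while pos < n:
        seg = max(1, int(round(rng.gamma(shape, scale_samp[cur]))))
        labels[pos : pos + seg] = cur
        pos += seg
        cur = int(np.searchsorted(cum[cur], rng.random()))
    return labels


def segment_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of ``labels`` as (label, start, end) half-open tuples."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    return [
        (int(labels[s]), int(s), int(e))
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _spatial_smoothing_kernel(ch_pos: np.ndarray, scale: float = 0.3) -> np.ndarray:
    d2 = ((ch_pos[:, None, :] - ch_pos[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2 * scale**2))
    return k / np.linalg.norm(k, axis=1, keepdims=True)


def _pink_noise(shape: tuple[int, int], srate: float,
                rng: np.random.Generator,
                band: tuple[float, float] = (1.0, 45.0)) -> np.ndarray:
    """Band-limited 1/f Gaussian noise, mimicking the spectrum of
    band-passed resting EEG (white noise would put most power above 20 Hz
    at a 200 Hz rate, which real EEG does not)."""
    n = shape[1]
    f = np.fft.rfftfreq(n, 1.0 / srate)
    gain = np.zeros_like(f)
    sel = (f >= band[0]) & (f <= band[1])
    gain[sel] = 1.0 / np.sqrt(f[sel])
    spec = np.fft.rfft(rng.standard_normal(shape), axis=1) * gain
    return np.fft.irfft(spec, n=n, axis=1)


def render_eeg(
    labels: np.ndarray, truth: SimulationTruth, srate: float,
    ch_pos: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    amplitude_uv: float = 10.0,
) -> EEGRecording:
    """Render a label sequence into an average-referenced recording.

    Noise is spatially smoothed, band-limited 1/f Gaussian,
    average-referenced, and scaled so the realised signal-to-noise power
    ratio equals ``truth.snr_db`` exactly.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    names, pos = default_montage()
    if ch_pos is not None:
        pos = np.asarray(ch_pos, dtype=float)
        names = [f"ch{i}" for i in range(len(pos))]
    if truth.templates.shape[1] != len(pos):
        raise ValueError("template channel count does not match montage")
    n = len(labels)
    t = np.arange(n) / srate
    phase = rng.uniform(0, np.pi)
    env = np.abs(np.sin(2 * np.pi * truth.gfp_mod_hz * t + phase))
    signs = np.empty(n)
    for lab, s, e in segment_runs(labels):
        signs[s:e] = rng.choice([-1.0, 1.0])
    sig = truth.templates[labels].T * (amplitude_uv * env * signs)

    noise = _spatial_smoothing_kernel(pos) @ _pink_noise(sig.shape, srate, rng)
    noise -= noise.mean(axis=0, keepdims=True)
    p_sig = np.mean(sig**2)
    p_noise = np.mean(noise**2)
    if p_noise > 0 and p_sig > 0:
        noise *= np.sqrt(p_sig / (10 ** (truth.snr_db / 10) * p_noise))
    data = sig + noise
    data -= data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, srate=srate, ch_names=names, ch_pos=pos)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSubject:
    recording: EEGRecording
    truth: SimulationTruth
    labels_by_condition: dict[str, np.ndarray]
    age: float
    sex: int  # 1 = male, 0 = female


def _subject_truth(truth: SimulationTruth, rng: np.random.Generator) -> SimulationTruth:
    factor = np.exp(rng.normal(0.0, truth.subject_sd, truth.K))
    return replace(truth, duration_mean_ms=truth.duration_mean_ms * factor)


def _simulate_subject(
    base: SimulationTruth, plan: CohortPlan, group: str, subject_id: str,
    rng: np.random.Generator,
) -> SimulatedSubject:
    truth = _subject_truth(base, rng)
    srate = plan.srate
    if group == "AI":
        schedule: list[str] = []
        for _ in range(plan.ai_repeats):
            schedule.extend(rng.permutation(AI_CONDITIONS))
        block_s = plan.ai_block_s
    else:
        schedule = list(RA_CONDITIONS)
        block_s = plan.ra_block_s
    blen = int(round(block_s * srate))
    chunks, events, labels_by_cond = [], [], {c: [] for c in set(schedule)}
    pos_sample = 0
    for tag in schedule:
        cond_truth = truth.for_condition(tag)
        labels = simulate_label_sequence(cond_truth, block_s, srate, rng)
        rec = render_eeg(labels, cond_truth, srate, rng=rng)
        chunks.append(rec.data)
        events.append((pos_sample, tag))
        labels_by_cond[tag].append(labels)
        pos_sample += blen
    names, posxy = default_montage()
    recording = EEGRecording(
        data=np.concatenate(chunks, axis=1), srate=srate, ch_names=names,
        ch_pos=posxy, events=events, subject_id=subject_id, group_tag=group,
    )
    age = rng.normal(plan.age_mean[group], plan.age_sd[group])
    sex = int(rng.random() < plan.male_fraction[group])
    return SimulatedSubject(
        recording=recording, truth=truth,
        labels_by_condition={c: np.concatenate(v) for c, v in labels_by_cond.items()},
        age=age, sex=sex,
    )


def simulate_cohort(
    plan: CohortPlan, truth: SimulationTruth
) -> list[SimulatedSubject]:
    """Simulate a full two-arm cohort; all randomness derives from
    ``truth.seed`` so the same seed reproduces the cohort exactly."""
    ss = np.random.SeedSequence(truth.seed)
    n_total = plan.n_ai_subjects + plan.n_ra_subjects
    children = ss.spawn(n_total)
    subjects = []
    for i in range(plan.n_ai_subjects):
        rng = np.random.default_rng(children[i])
        subjects.append(_simulate_subject(truth, plan, "AI", f"ai{i + 1:02d}", rng))
    for j in range(plan.n_ra_subjects):
        rng = np.random.default_rng(children[plan.n_ai_subjects + j])
        subjects.append(_simulate_subject(truth, plan, "RA", f"ra{j + 1:02d}", rng))
    return subjects
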