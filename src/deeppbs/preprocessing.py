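"""Raw 1-Hz recordings -> fixed-length labeled model samples.

The pipeline per infant: valid-range filtering (out-of-range values become
missing), truncation to the last 80 h (shorter recordings are zero-padded at
the front and masked), imputation of missing values, a causal 5-min rolling
mean emitted per second (the first 5 min initialize it), partition of the
rolled series into consecutive non-overlapping 5-min segments of
5 signals x 300 values = 1500 features, and one appended all-zero terminal
segment.  For an 80-h recording this yields (80*60/5) - 1 = 959 data
segments and a final padded length of S = 960.

Per-step labels: for dying infants every segment whose end time falls in
the final 6 h before death is "alert"; survivors are all "not alert".  The
turning point is the first alert segment, or the terminal padded step when
no alert step exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import SIGNALS, ClinicalRecord, RawRecording

__all__ = [
    "ValidRange",
    "VALID_RANGES",
    "apply_valid_ranges",
    "truncate_or_pad",
    "segment_recording",
    "make_labels",
    "build_global_features",
    "SegmentedSample",
    "preprocess_recording",
    "preprocess_cohort",
    "ALERT_WINDOW_HOURS",
    "SEGMENT_SECONDS",
]

SEGMENT_SECONDS = 300          # 5-min rolling window and segment length
ALERT_WINDOW_HOURS = 6.0       # final hours before death labeled "alert"
MIN_RECORDING_HOURS = 6.0
N_GLOBAL = 9
RACE_ORDER = ("Asian", "Black", "Hispanic", "White", "Other")


@dataclass(frozen=True)
class ValidRange:
    """Physiologic validity interval with explicit endpoint openness."""

    low: float
    high: float
    low_open: bool
    high_open: bool

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"invalid range: [{self.low}, {self.high}]")

    def contains(self, x: np.ndarray) -> np.ndarray:
        lo = x > self.low if self.low_open else x >= self.low
        hi = x < self.high if self.high_open else x <= self.high
        return lo & hi


VALID_RANGES: dict[str, ValidRange] = {
    "HR": ValidRange(0.0, 250.0, low_open=True, high_open=False),
    "RR": ValidRange(0.0, 120.0, low_open=True, high_open=False),
    "SPO2": ValidRange(0.0, 100.0, low_open=True, high_open=False),
    "ART-M": ValidRange(10.0, 90.0, low_open=False, high_open=False),
    "NIBP-M": ValidRange(10.0, 90.0, low_open=True, high_open=False),
}


def apply_valid_ranges(values: np.ndarray, signal: str,
                       ranges: dict[str, ValidRange] = VALID_RANGES) -> np.ndarray:
    """Replace out-of-range values with NaN; in-range values pass unchanged."""
    if signal not in ranges:
        raise KeyError(f"unknown signal name: {signal!r}")
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    bad = finite & ~ranges[signal].contains(x)
    x[bad] = np.nan
    return x


def truncate_or_pad(recording: RawRecording, target_hours: float = 80.0
                    ) -> tuple[dict[str, np.ndarray], int, float]:
    """Keep the last `target_hours` of a recording.

    Returns (window series, leading pad seconds, window-start elapsed time).
    Shorter recordings keep all their data; the leading deficit is recorded
    so segmentation can emit masked zero segments (the pad never enters the
    rolling means).  Recordings under 6 h are excluded outright.
    """
    n = recording.n_samples
    if n < MIN_RECORDING_HOURS * 3600:
        raise ValueError(
            f"recording {recording.infant_id} shorter than "
            f"{MIN_RECORDING_HOURS} h; excluded")
    target = int(round(target_hours * 3600))
    keep = min(n, target)
    start = n - keep
    window = {name: recording.series[name][start:] for name in SIGNALS}
    pad_seconds = target - keep
    return window, pad_seconds, float(recording.start_time) + start


def _rolling_mean(x: np.ndarray, w: int = SEGMENT_SECONDS) -> np.ndarray:
    """Trailing mean over the previous `w` samples: out[j] = mean(x[j:j+w]),
    emitted per second; length len(x) - w."""
    c = np.concatenate([[0.0], np.cumsum(x, dtype=np.float64)])
    return (c[w:-1] - c[:-w - 1]) / w if len(x) > w else np.empty(0)


@dataclass
class SegmentedSample:
    """One model-ready sample: S x n_v features, mask, labels, turning point."""

    infant_id: str
    X: np.ndarray                 # (S, n_v)
    pad_mask: np.ndarray          # (S,) True on zero-padded steps (incl. terminal)
    labels: np.ndarray            # (S,) 1 = alert, 0 = not alert
    turning_point: int            # first alert step, else S-1
    segment_end_times: np.ndarray  # (S,) elapsed seconds; NaN on padded steps
    global_features: np.ndarray | None = None   # (9,)


def segment_recording(window: dict[str, np.ndarray], pad_seconds: int = 0,
                      window_start: float = 0.0, target_hours: float = 80.0
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rolled, segmented features for one windowed recording.

    Returns (X, pad_mask, segment_end_times) with X of shape (S, 1500) where
    S = target_hours*12; the last row is the all-zero terminal segment.
    Requires imputation to have been applied (no NaN in the real data).
    """
    n_slots = int(round(target_hours * 3600 / SEGMENT_SECONDS)) - 1  # data slots
    S = n_slots + 1
    lengths = {len(window[name]) for name in SIGNALS}
    if len(lengths) != 1:
        raise ValueError(f"signals have differing lengths: {sorted(lengths)}")
    L = lengths.pop()
    if set(window) != set(SIGNALS):
        raise ValueError(f"expected signals {SIGNALS}, got {sorted(window)}")
    n_real = (L - SEGMENT_SECONDS) // SEGMENT_SECONDS
    if n_real < 1:
        raise ValueError("window too short to produce any segment")
    if n_real > n_slots:
        raise ValueError(f"window yields {n_real} segments > {n_slots} slots")
    used = n_real * SEGMENT_SECONDS + SEGMENT_SECONDS
    front_drop = L - used  # sub-5-min remainder dropped from the front

    rolled = {}
    for name in SIGNALS:
        x = window[name][front_drop:]
        if np.isnan(x).any():
            raise ValueError(
                f"missing values remain in signal {name}; impute first")
        r = _rolling_mean(x)
        assert len(r) == n_real * SEGMENT_SECONDS
        rolled[name] = r

    n_v = len(SIGNALS) * SEGMENT_SECONDS
    X = np.zeros((S, n_v), dtype=np.float64)
    pad_mask = np.ones(S, dtype=bool)
    end_times = np.full(S, np.nan)
    n_pad_segments = n_slots - n_real
    a = window_start + front_drop
    for r in range(n_real):
        k = n_pad_segments + r
        X[k] = np.concatenate([
            rolled[name][r * SEGMENT_SECONDS:(r + 1) * SEGMENT_SECONDS]
            for name in SIGNALS])
        pad_mask[k] = False
        end_times[k] = a + SEGMENT_SECONDS * (r + 2)
    return X, pad_mask, end_times


def make_labels(clinical: ClinicalRecord, segment_end_times: np.ndarray,
                pad_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-segment alert labels and the turning-point index.

    A segment is "alert" iff the infant died and its end time lies in
    (death_time - 6 h, death_time].  Padded steps are never alert.
    """
    S = len(segment_end_times)
    labels = np.zeros(S, dtype=np.int8)
    if clinical.died:
        death = float(clinical.death_time)
        real = ~np.asarray(pad_mask, dtype=bool)
        window_start = np.nanmin(np.where(real, segment_end_times, np.nan)) \
            - 2 * SEGMENT_SECONDS
        if death < window_start:
            raise ValueError(
                f"death_time {death} precedes the evaluation window "
                f"start {window_start}")
        lo = death - ALERT_WINDOW_HOURS * 3600.0
        with np.errstate(invalid="ignore"):
            alert = real & (segment_end_times > lo) & (segment_end_times <= death)
        labels[alert] = 1
    turning_point = int(np.argmax(labels)) if labels.any() else S - 1
    return labels, turning_point


def build_global_features(clinical: ClinicalRecord) -> np.ndarray:
    """Length-9 fixed-variable vector: sex, GA, birth weight, prior NICU
    stay, and five mutually exclusive race dummies."""
    if clinical.race not in RACE_ORDER:
        raise ValueError(f"unrecognized race category: {clinical.race!r}")
    if clinical.sex not in ("male", "female"):
        raise ValueError(f"unrecognized sex: {clinical.sex!r}")
    g = np.zeros(N_GLOBAL)
    g[0] = 1.0 if clinical.sex == "male" else 0.0
    g[1] = clinical.ga_weeks
    g[2] = clinical.birth_weight_g
    g[3] = clinical.prior_stay_hours
    g[4 + RACE_ORDER.index(clinical.race)] = 1.0
    return g


def preprocess_recording(recording: RawRecording, clinical: ClinicalRecord,
                         imputer=None, target_hours: float = 80.0
                         ) -> SegmentedSample:
    """Full per-infant pipeline: ranges -> window -> impute -> segment -> label.

    ``imputer`` is a callable mapping a (L, n_signals) matrix with NaN to a
    completed matrix (see :mod:`deeppbs.imputation`); the absent
    blood-pressure channel is filled with zeros rather than imputed, since
    it carries no information for that infant.
    """
    cleaned = {name: apply_valid_ranges(recording.series[name], name)
               for name in SIGNALS}
    window, pad_seconds, window_start = truncate_or_pad(
        RawRecording(recording.infant_id, recording.start_time, cleaned,
                     recording.bp_channel), target_hours)
    absent_bp = "NIBP-M" if recording.bp_channel == "ART-M" else "ART-M"
    window[absent_bp] = np.zeros_like(window[absent_bp])
    present = [s for s in SIGNALS if s != absent_bp]
    if imputer is not None:
        mat = np.column_stack([window[s] for s in present])
        mat = imputer(mat, feature_names=present)
        for j, s in enumerate(present):
            window[s] = mat[:, j]
    X, pad_mask, end_times = segment_recording(
        window, pad_seconds, window_start, target_hours)
    labels, turning_point = make_labels(clinical, end_times, pad_mask)
    return SegmentedSample(
        infant_id=recording.infant_id, X=X, pad_mask=pad_mask, labels=labels,
        turning_point=turning_point, segment_end_times=end_times,
        global_features=build_global_features(clinical))


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on a training fold.

    Signal features are standardized over unmasked steps only (padded rows
    stay exactly zero); the nine global variables are standardized
    feature-wise.  Applying the training fold's statistics to validation
    samples avoids information leakage across folds.
    """

    x_mean: np.ndarray
    x_std: np.ndarray
    g_mean: np.ndarray
    g_std: np.ndarray

    @classmethod
    def fit(cls, samples: list["SegmentedSample"]) -> "Standardizer":
        rows = np.vstack([s.X[~s.pad_mask] for s in samples])
        G = np.vstack([s.global_features for s in samples])
        return cls(x_mean=rows.mean(axis=0),
                   x_std=np.maximum(rows.std(axis=0), 1e-6),
                   g_mean=G.mean(axis=0),
                   g_std=np.maximum(G.std(axis=0), 1e-6))

    def transform(self, sample: "SegmentedSample") -> "SegmentedSample":
        X = sample.X.copy()
        keep = ~sample.pad_mask
        X[keep] = (X[keep] - self.x_mean) / self.x_std
        return SegmentedSample(
            infant_id=sample.infant_id, X=X, pad_mask=sample.pad_mask,
            labels=sample.labels, turning_point=sample.turning_point,
            segment_end_times=sample.segment_end_times,
            global_features=(sample.global_features - self.g_mean) / self.g_std)


def preprocess_cohort(recordings: list[RawRecording],
                      clinical: list[ClinicalRecord], imputer=None,
                      target_hours: float = 80.0) -> list[SegmentedSample]:
    by_id = {c.infant_id: c for c in clinical}
    return [preprocess_recording(r, by_id[r.infant_id], imputer, target_hours)
            for r in recordings]
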