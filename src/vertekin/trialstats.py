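"""Kinematic trial post-processing and ASTM agreement statistics.

Kinematic trials are filtered with a zero-phase low-pass Butterworth filter
(4th order, 3 Hz cutoff at 60 Hz by default), exported as axis-labelled
Euler components — Y-X'-Z'' for flexion trials, X-Z'-Y'' for lateral
bending — and two methods' exports are compared frame by frame.  The
per-frame differences are summarised following the ASTM bias / precision /
RMSE convention with every trial weighted by its frame count:

    bias      = sum_t w_t * mean(d_t)
    precision = sqrt( sum_t w_t * var(d_t) )      (population variance)
    rmse      = sqrt( sum_t w_t * mean(d_t^2) )   with w_t = n_t / sum n

Population (n-denominator) variance makes the single-trial identity
``rmse^2 = bias^2 + precision^2`` exact; for multiple trials Jensen's
inequality gives ``rmse^2 >= bias^2 + precision^2``.  An ``ddof=1`` switch
is provided for the sample-variance convention.

The interrater SEM of static bead-centroid digitization is computed as the
RMS over beads and axes of the between-rater standard deviation of
session-averaged coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .geomkin import EulerSequence, RigidTransform, euler_from_rotation

__all__ = [
    "COMPONENTS",
    "sequence_for_motion",
    "KinematicTrial",
    "TrialDifferences",
    "SummaryStats",
    "ReliabilityTable",
    "butterworth_lowpass",
    "export_poses",
    "export_trial",
    "compare_methods",
    "astm_summary",
    "sem_interrater",
]

#: fixed component order: three rotations (degrees), three translations (mm)
COMPONENTS = ("LB(X)", "FE(Y)", "AR(Z)", "AP(X)", "ML(Y)", "SI(Z)")

#: Euler sequence per motion type; the angle order of each sequence maps
#: onto the axis-labelled rotation columns.
_MOTION_SEQUENCE = {
    "flexion": EulerSequence.YXZ,
    "lateral_bending": EulerSequence.XZY,
}

# position of each sequence-ordered angle among the (X, Y, Z) rotation columns
_ANGLE_COLUMNS = {
    EulerSequence.YXZ: (1, 0, 2),  # angles about (Y, X, Z)
    EulerSequence.XZY: (0, 2, 1),  # angles about (X, Z, Y)
}


def sequence_for_motion(motion: str) -> EulerSequence:
    try:
        return _MOTION_SEQUENCE[motion]
    except KeyError:
        raise ValueError(f"unknown motion {motion!r}") from None


def butterworth_lowpass(
    series: np.ndarray,
    fs: float,
    cutoff: float = 3.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter with unit DC gain.

    Zero-phase by default (forward-backward ``filtfilt``, so the effective
    magnitude response is the squared one-pass response) with reflective
    end padding of length ``3*order``.  ``zero_phase=False`` selects a
    single causal pass.
    """
    x = np.asarray(series, float)
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the cutoff {cutoff} Hz")
    n = x.shape[-1] if x.ndim else 0
    min_len = 3 * order + 1
    if n <= 3 * order:
        raise ValueError(
            f"series of length {n} too short to filter; need more than {3 * order} samples"
        )
    b, a = butter(order, cutoff / (fs / 2.0), btype="low")
    if zero_phase:
        return filtfilt(b, a, x, axis=-1, padtype="even", padlen=3 * order)
    from scipy.signal import lfilter

    return lfilter(b, a, x, axis=-1)


@dataclass(frozen=True)
class KinematicTrial:
    """One motion trial: per-frame rigid poses for one or more series.

    ``series`` maps a label (e.g. ``"C4/C5"``) to the per-frame pose of the
    moving segment expressed in its parent/anatomic frame, so rotations and
    translations read directly as intersegmental kinematics.
    """

    trial_id: str
    motion: str
    series: Mapping[str, Sequence[RigidTransform]]
    fps: float = 60.0

    def __post_init__(self) -> None:
        sequence_for_motion(self.motion)
        lengths = {len(v) for v in self.series.values()}
        if not self.series or lengths == {0}:
            raise ValueError("trial has no frames")
        if len(lengths) != 1:
            raise ValueError("all series must have the same frame count")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.series.values())))


@dataclass(frozen=True)
class TrialDifferences:
    """Per-frame 6-component differences between two methods for one trial."""

    trial_id: str
    values: np.ndarray  # (n_frames, 6) in COMPONENTS order

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("values must be (n_frames, n_components) with >= 1 frame")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite differences")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SummaryStats:
    """ASTM bias / precision / RMSE per component."""

    bias: np.ndarray
    precision: np.ndarray
    rmse: np.ndarray
    labels: tuple[str, ...] = COMPONENTS
    #: population-variance aggregation guarantees rmse^2 >= bias^2 + precision^2;
    #: the sample-variance (ddof=1) convention does not, so the check is skipped
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("bias", "precision", "rmse"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if np.any(self.precision < 0) or np.any(self.rmse < 0):
            raise ValueError("precision and rmse must be non-negative")
        if self.strict and np.any(self.rmse**2 < self.bias**2 + self.precision**2 - 1e-9):
            raise ValueError("rmse^2 < bias^2 + precision^2 violates the aggregation identity")

    def to_frame(self):
        import pandas as pd

        labels = self.labels[: len(self.bias)]
        return pd.DataFrame(
            [self.bias, self.precision, self.rmse],
            index=["Bias", "Precision", "RMSE"],
            columns=labels,
        )

    def summary(self) -> str:
        return self.to_frame().round(2).to_string()


def export_poses(
    poses: Sequence[RigidTransform],
    sequence: EulerSequence | str,
) -> np.ndarray:
    """Decompose a pose series into the six axis-labelled components.

    Rotations are the intrinsic Euler angles of ``sequence`` placed in the
    (X, Y, Z) rotation columns; translations are the parent-frame X, Y, Z
    components.  Returns (n_frames, 6) in :data:`COMPONENTS` order.
    """
    seq = EulerSequence(sequence)
    cols = _ANGLE_COLUMNS[seq]
    out = np.empty((len(poses), 6))
    for k, T in enumerate(poses):
        e = euler_from_rotation(T.rotation, seq)
        for pos, ang in zip(cols, e.angles):
            out[k, pos] = ang
        out[k, 3:] = T.translation
    return out


def export_trial(
    trial: KinematicTrial,
    filter: bool = True,
    cutoff: float = 3.0,
    order: int = 4,
) -> dict[str, np.ndarray]:
    """Export a trial's series as filtered, axis-labelled 6-vectors.

    The Euler sequence follows the motion label (flexion -> Y-X'-Z'',
    lateral bending -> X-Z'-Y'').  With ``filter=True`` each of the six
    component series is low-pass filtered independently (zero-phase
    Butterworth); validation-block style raw exports use ``filter=False``.
    """
    seq = sequence_for_motion(trial.motion)
    out = {}
    for label, poses in trial.series.items():
        comp = export_poses(poses, seq)
        if filter:
            comp = butterworth_lowpass(comp.T, trial.fps, cutoff, order).T
        out[label] = comp
    return out


def compare_methods(
    a: np.ndarray,
    b: np.ndarray,
    trial_id: str = "trial",
) -> TrialDifferences:
    """Per-frame component-wise differences ``a - b`` of two exports."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"export shapes differ: {a.shape} vs {b.shape}")
    return TrialDifferences(trial_id, a - b)


def astm_summary(
    diffs: Sequence[TrialDifferences],
    ddof: int = 0,
) -> SummaryStats:
    """Frame-count-weighted ASTM bias / precision / RMSE over trials.

    ``ddof=0`` (population variance, default) makes ``rmse^2 = bias^2 +
    precision^2`` exact for a single trial; ``ddof=1`` selects the sample
    variance convention.
    """
    if len(diffs) == 0:
        raise ValueError("no trials supplied")
    n = np.array([d.n_frames for d in diffs], float)
    w = n / n.sum()
    means = np.stack([d.values.mean(axis=0) for d in diffs])
    variances = np.stack([d.values.var(axis=0, ddof=ddof) for d in diffs])
    meansq = np.stack([(d.values**2).mean(axis=0) for d in diffs])
    bias = w @ means
    precision = np.sqrt(w @ variances)
    rmse = np.sqrt(w @ meansq)
    ncomp = means.shape[1]
    labels = COMPONENTS if ncomp == 6 else tuple(f"c{i}" for i in range(ncomp))
    return SummaryStats(bias, precision, rmse, labels, strict=(ddof == 0))


@dataclass(frozen=True)
class ReliabilityTable:
    """Rater x session x bead x axis centroid coordinates (mm).

    The default layout mirrors a reliability study with 5 raters, 3
    sessions and 12 beads, but any complete table is accepted.
    """

    coords: np.ndarray  # (raters, sessions, beads, 3)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, float)
        if c.ndim != 4 or c.shape[-1] != 3:
            raise ValueError("coords must be (raters, sessions, beads, 3)")
        if c.shape[0] < 2:
            raise ValueError("need >= 2 raters")
        if not np.all(np.isfinite(c)):
            raise ValueError("reliability table has missing cells")
        object.__setattr__(self, "coords", c)


def sem_interrater(table: ReliabilityTable | np.ndarray) -> float:
    """Interrater SEM of bead-centroid digitization (mm).

    Sessions are averaged within rater; the standard deviation (ddof=1)
    across rater means is taken per bead and axis; the SEM is the RMS of
    those standard deviations over all beads and axes.
    """
    if not isinstance(table, ReliabilityTable):
        table = ReliabilityTable(table)
    rater_means = table.coords.mean(axis=1)  # (raters, beads, 3)
    sds = rater_means.std(axis=0, ddof=1)  # (beads, 3)
    return float(np.sqrt(np.mean(sds**2)))
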