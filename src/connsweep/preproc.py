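"""ROI-level BOLD signal cleaning.

Operates on region-averaged time series (T timepoints x N regions), never on
volumetric images.  The cleaning chain is: discard initial volumes, remove
linear trends, regress out nuisance signals (Friston-24 motion expansion plus
any supplied tissue signals), band-pass filter to the low-frequency BOLD band,
and flag high-motion volumes for scrubbing.  Motion quality control applies
the conventional maximum-excursion rule (1.0 mm translation / 1.0 degree
rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps


class PreprocError(ValueError):
    pass


@dataclass
class TimeSeriesMatrix:
    """T x N region-averaged signal with sampling interval ``tr`` (seconds).

    ``volume_mask`` marks volumes retained after scrubbing (False = flagged);
    the values themselves are never altered by scrubbing -- consumers index
    with the mask.
    """

    values: np.ndarray
    tr: float
    region_labels: list[str]
    volume_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocError("time series must be a 2-D matrix")
        if self.values.shape[1] < 2:
            raise PreprocError("need at least 2 regions")
        if self.tr <= 0:
            raise PreprocError("tr must be positive")
        if np.isnan(self.values).any():
            raise PreprocError("time series contains missing values")
        if len(self.region_labels) != self.values.shape[1]:
            raise PreprocError("region_labels length mismatch")
        if self.volume_mask is None:
            self.volume_mask = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.volume_mask = np.asarray(self.volume_mask, dtype=bool)
            if self.volume_mask.shape != (self.values.shape[0],):
                raise PreprocError("volume_mask length mismatch")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def masked_values(self) -> np.ndarray:
        """Rows surviving scrubbing."""
        return self.values[self.volume_mask]


@dataclass
class MotionTrace:
    """T x 6 rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise PreprocError("motion trace must have exactly 6 columns")


@dataclass
class NuisanceSet:
    """T x K nuisance regressor matrix with column labels."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2:
            raise PreprocError("regressors must be 2-D")
        if self.regressors.shape[1] != len(self.names):
            raise PreprocError("names length must match regressor columns")


def friston24_expand(motion: MotionTrace) -> NuisanceSet:
    """Expand 6 rigid-body parameters into the 24-regressor motion model.

    Column order: the 6 parameters, their one-volume lags (first row
    zero-padded), then the squares of both sets.
    """
    m = motion.values
    lag = np.zeros_like(m)
    lag[1:] = m[:-1]
    reg = np.hstack([m, lag, m**2, lag**2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (
        [f"mot_{b}" for b in base]
        + [f"mot_{b}_lag" for b in base]
        + [f"mot_{b}_sq" for b in base]
        + [f"mot_{b}_lag_sq" for b in base]
    )
    return NuisanceSet(reg, names)


def framewise_displacement(motion: MotionTrace, head_radius: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement, mm per volume.

    Rotations (stored in degrees) are converted to radians and mapped to arc
    length on a sphere of ``head_radius`` mm.  FD of the first volume is 0.
    """
    m = motion.values
    if m.shape[0] < 2:
        raise PreprocError("need at least 2 volumes for FD")
    d = np.abs(np.diff(m, axis=0))
    trans = d[:, :3].sum(axis=1)
    rot = np.deg2rad(d[:, 3:]).sum(axis=1) * head_radius
    fd = np.zeros(m.shape[0])
    fd[1:] = trans + rot
    return fd


def scrub_mask(fd: np.ndarray, threshold: float) -> np.ndarray:
    """True where a volume is retained; flagged iff FD strictly exceeds threshold."""
    if threshold <= 0:
        raise PreprocError("scrub threshold must be positive")
    return ~(np.asarray(fd, dtype=float) > threshold)


@dataclass
class MotionQC:
    passed: bool
    offending_parameter: str | None
    max_translation: float
    max_rotation: float


def qc_motion(motion: MotionTrace, max_trans: float = 1.0, max_rot: float = 1.0) -> MotionQC:
    """Exclusion rule: any |translation| > max_trans mm or |rotation| > max_rot degrees.

    Strict inequality: an excursion exactly at the limit passes.
    """
    m = np.abs(motion.values)
    names = ["tx", "ty", "tz", "rx", "ry", "rz"]
    limits = np.array([max_trans] * 3 + [max_rot] * 3)
    worst = m.max(axis=0)
    bad = worst > limits
    offender = names[int(np.argmax(bad))] if bad.any() else None
    return MotionQC(
        passed=not bad.any(),
        offending_parameter=offender,
        max_translation=float(worst[:3].max()),
        max_rotation=float(worst[3:].max()),
    )


def detrend_linear(values: np.ndarray) -> np.ndarray:
    """Remove per-column linear trend (least squares on intercept + time)."""
    return sps.detrend(np.asarray(values, dtype=float), axis=0, type="linear")


def bandpass_filter(values: np.ndarray, tr: float, band: tuple[float, float] = (0.01, 0.08),
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    lo, hi = band
    fs = 1.0 / tr
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise PreprocError(f"band {band} invalid for sampling rate {fs} Hz")
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(values, dtype=float), axis=0)


def regress_nuisance(values: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS residuals of each region on intercept + nuisance regressors.

    Constant (zero-variance) regressor columns carry no information beyond the
    intercept and are dropped; genuinely collinear non-constant columns raise,
    naming the offenders.
    """
    y = np.asarray(values, dtype=float)
    reg = nuisance.regressors
    if reg.shape[0] != y.shape[0]:
        raise PreprocError("regressor rows must match time series rows")
    keep = reg.std(axis=0) > 1e-14
    reg = reg[:, keep]
    names = [n for n, k in zip(nuisance.names, keep) if k]
    design = np.column_stack([np.ones(y.shape[0]), reg])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns via pivoted QR on the non-constant block
        _, r, piv = sla.qr(design, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        bad = [piv[i] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
        badnames = [("intercept" if j == 0 else names[j - 1]) for j in bad]
        raise PreprocError(f"nuisance design is rank deficient; collinear columns: {badnames}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def clean_timeseries(
    ts: TimeSeriesMatrix,
    motion: MotionTrace,
    nuisance: NuisanceSet | None = None,
    discard: int = 10,
    band: tuple[float, float] = (0.01, 0.08),
    fd_threshold: float = 0.5,
    filter_order: int = 4,
    head_radius: float = 50.0,
) -> TimeSeriesMatrix:
    """Full subject-level cleaning chain.

    Steps, in fixed order: discard initial volumes -> linear detrend ->
    nuisance regression -> band-pass -> residual detrend -> scrub flagging.
    If ``nuisance`` is None the Friston-24 expansion of ``motion`` is used.
    The returned matrix has T - discard rows; ``volume_mask`` is False at
    volumes whose framewise displacement exceeds ``fd_threshold``.

    The closing detrend guarantees exactly trend-free outputs regardless of
    filter edge effects; the band-pass leaves it a numerical no-op in the
    interior of the band.
    """
    T = ts.n_volumes
    if motion.values.shape[0] != T:
        raise PreprocError("motion trace must match the raw series length")
    if T <= discard + 20:
        raise PreprocError("too few volumes after discard to filter reliably")

    vals = ts.values[discard:]
    mot = MotionTrace(motion.values[discard:], motion.tr)
    if nuisance is None:
        nuis = friston24_expand(mot)
    else:
        nuis = NuisanceSet(nuisance.regressors[discard:], nuisance.names)

    vals = detrend_linear(vals)
    vals = regress_nuisance(vals, nuis)
    vals = bandpass_filter(vals, ts.tr, band=band, order=filter_order)
    vals = detrend_linear(vals)

    fd = framewise_displacement(mot, head_radius=head_radius)
    mask = scrub_mask(fd, fd_threshold)
    return TimeSeriesMatrix(vals, ts.tr, list(ts.region_labels), mask)
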