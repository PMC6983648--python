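"""DTOF processing: pathlength, absorption changes, and ICG concentration.

This module turns raw photon time-of-flight histograms (DTOFs) plus an
instrument response function (IRF) into the quantities the perfusion analysis
consumes:

* mean photon time of flight of a histogram,
* optical pathlength  p = (c/n) (<t>_DTOF - <t>_IRF),
* the modified Beer-Lambert absorption-change time course
  Dmu_a(t) = ln(I0 / I(t)) / p,
* tissue ICG concentration  Q(t) = Dmu_a(t) / (ln10 * eps_ICG),
* the expected absorption change of an India-ink titration step
  Dmu_a,expected = ln10 * 0.885 * eps_e,ink * Dc.

Sign convention: increased absorption gives positive Dmu_a (the log ratio is
taken baseline-over-measurement), so an ICG bolus produces a nonnegative
concentration curve.  All Beer-Lambert conversions here use decadic extinction
coefficients; ln10 factors bridge to the Napierian absorption coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    C_VACUUM_CM_PER_NS,
    DEFAULT_EPS_ICG,
    DEFAULT_N_TISSUE,
    INK_ABSORPTION_EXTINCTION_RATIO,
    LN10,
)


class InputError(ValueError):
    """Invalid user-supplied data or parameters."""


class ProcessingError(RuntimeError):
    """A derived quantity is unusable (e.g. nonpositive pathlength)."""


@dataclass
class DTOF:
    """A single photon time-of-flight histogram.

    ``counts`` may be floats for noise-free expected histograms; measured
    frames are nonnegative integers.  Bin k is centered at
    ``t_start_ns + k * bin_width_ns`` (uniform grid).
    """

    counts: np.ndarray
    bin_width_ns: float
    t_start_ns: float = 0.0
    role: str = "measurement"  # "measurement" | "IRF"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise InputError("DTOF counts must be a nonempty 1-D array")
        if np.any(self.counts < 0):
            raise InputError("DTOF counts must be nonnegative")
        if self.bin_width_ns <= 0:
            raise InputError("bin width must be positive")

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return self.t_start_ns + np.arange(self.counts.size) * self.bin_width_ns

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class DTOFStack:
    """A time series of DTOFs sharing one bin grid (frames x bins)."""

    counts: np.ndarray
    bin_width_ns: float
    frame_times_s: np.ndarray
    t_start_ns: float = 0.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.counts.ndim != 2:
            raise InputError("stack counts must be 2-D (frames x bins)")
        if self.counts.shape[0] != self.frame_times_s.size:
            raise InputError("frame_times length must match number of frames")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    def frame(self, i: int, role: str = "measurement") -> DTOF:
        return DTOF(self.counts[i], self.bin_width_ns, self.t_start_ns, role)


@dataclass
class PathlengthResult:
    p_cm: float
    t_mean_dtof_ns: float
    t_mean_irf_ns: float
    n_tissue: float
    c_vacuum_cm_per_ns: float = C_VACUUM_CM_PER_NS


@dataclass
class AbsorptionChangeCurve:
    """Dmu_a(t) relative to the pre-contrast baseline."""

    times_s: np.ndarray
    delta_mua: np.ndarray
    i0: float
    pathlength_cm: float
    baseline_window_s: tuple
    n_tissue: float = DEFAULT_N_TISSUE


@dataclass
class ConcentrationCurve:
    """ICG concentration time series (uM), arterial or tissue role."""

    times_s: np.ndarray
    values_um: np.ndarray
    role: str  # "arterial" | "tissue"
    extinction_um_cm: float | None = None  # tissue role: eps_ICG used

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values_um = np.asarray(self.values_um, dtype=float)
        if self.times_s.shape != self.values_um.shape:
            raise InputError("times and values must have the same shape")
        if self.role not in ("arterial", "tissue"):
            raise InputError("role must be 'arterial' or 'tissue'")
        if not np.all(np.isfinite(self.values_um)):
            raise InputError("concentration values must be finite")


@dataclass
class PhantomStep:
    """One India-ink titration step of the phantom validation."""

    step_index: int
    cumulative_ink_conc_um: float
    eps_e_ink_um_cm: float
    expected_delta_mua: float
    measured_delta_mua: float | None = None
    measured_sd: float | None = None


def mean_time_of_flight(d: DTOF) -> float:
    """Count-weighted mean arrival time (ns) of a histogram."""
    total = d.counts.sum()
    if total <= 0:
        raise InputError("cannot compute mean time of flight of an empty histogram")
    return float((d.counts * d.bin_centers_ns).sum() / total)


def pathlength(d: DTOF, irf: DTOF, n_tissue: float = DEFAULT_N_TISSUE) -> PathlengthResult:
    """Optical pathlength p = (c/n) (<t>_DTOF - <t>_IRF) in cm.

    A negative difference is physically impossible for real data and is
    flagged with a warning, but the (negative) value is preserved so that
    diagnostics can inspect it.
    """
    if not np.isclose(d.bin_width_ns, irf.bin_width_ns, rtol=1e-9):
        raise InputError("DTOF and IRF must share the same bin width")
    tm_d = mean_time_of_flight(d)
    tm_i = mean_time_of_flight(irf)
    p = C_VACUUM_CM_PER_NS / n_tissue * (tm_d - tm_i)
    if p < 0:
        warnings.warn(
            "mean time of flight of the measurement precedes the IRF; "
            "negative pathlength preserved for diagnostics",
            stacklevel=2,
        )
    return PathlengthResult(p, tm_d, tm_i, n_tissue)


def _masked_interpolated_intensity(stack: DTOFStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame total intensity with zero-count frames linearly interpolated.

    Returns (intensity, good_mask).  Zero-count frames (lost probe contact)
    carry no information; they are masked and bridged by linear interpolation
    in time, with a logged warning.
    """
    intensity = stack.counts.sum(axis=1)
    good = intensity > 0
    if not good.any():
        raise InputError("all frames in the stack are empty")
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} zero-count frame(s) masked and interpolated",
            stacklevel=3,
        )
        t = stack.frame_times_s
        intensity = intensity.copy()
        intensity[~good] = np.interp(t[~good], t[good], intensity[good])
    return intensity, good


def delta_mua_timecourse(
    stack: DTOFStack,
    irf: DTOF,
    baseline_window_s: tuple = (0.0, 10.0),
    n_tissue: float = DEFAULT_N_TISSUE,
    pathlength_cm: float | None = None,
    pathlength_scale: float = 1.0,
) -> AbsorptionChangeCurve:
    """Modified Beer-Lambert absorption-change time course.

    I(t) is the total photon count of each frame; I0 the mean over baseline
    frames (pre-contrast); p is computed once from the baseline-mean DTOF
    (static-pathlength convention) unless ``pathlength_cm`` overrides it.
    ``pathlength_scale`` perturbs whichever pathlength is used -- the handle
    for the pathlength sensitivity analysis.

    Dmu_a(t) = ln(I0 / I(t)) / p, so rising absorption is positive.
    """
    t = stack.frame_times_s
    lo, hi = baseline_window_s
    intensity, good = _masked_interpolated_intensity(stack)
    base = (t >= lo) & (t < hi) & good
    if base.sum() < 2:
        raise InputError("baseline window must contain at least 2 usable frames")
    i0 = float(intensity[base].mean())
    if pathlength_cm is None:
        base_mean = DTOF(stack.counts[base].mean(axis=0), stack.bin_width_ns, stack.t_start_ns)
        p = pathlength(base_mean, irf, n_tissue).p_cm
    else:
        p = float(pathlength_cm)
    p *= pathlength_scale
    if p <= 0:
        raise ProcessingError(f"nonpositive pathlength ({p:.3g} cm)")
    dmua = np.log(i0 / intensity) / p
    return AbsorptionChangeCurve(t, dmua, i0, p, (lo, hi), n_tissue)


def pathlength_per_frame(
    stack: DTOFStack, irf: DTOF, n_tissue: float = DEFAULT_N_TISSUE
) -> np.ndarray:
    """Diagnostic: pathlength recomputed from every individual frame (cm)."""
    tm_i = mean_time_of_flight(irf)
    intensity = stack.counts.sum(axis=1)
    out = np.full(stack.n_frames, np.nan)
    centers = stack.t_start_ns + np.arange(stack.counts.shape[1]) * stack.bin_width_ns
    nz = intensity > 0
    tm = (stack.counts[nz] * centers).sum(axis=1) / intensity[nz]
    out[nz] = C_VACUUM_CM_PER_NS / n_tissue * (tm - tm_i)
    return out


def expected_ink_delta_mua(
    eps_e_ink_um_cm: float,
    delta_conc_um,
    absorption_extinction_ratio: float = INK_ABSORPTION_EXTINCTION_RATIO,
):
    """Expected absorption change from added India ink (cm^-1).

    Dmu_a = ln10 * (0.885 * eps_e,ink) * Dc, where eps_e,ink is the decadic
    molar extinction measured in transmission and Dc the cumulative ink
    concentration in the final volume.
    """
    if eps_e_ink_um_cm <= 0:
        raise InputError("ink extinction coefficient must be positive")
    dc = np.asarray(delta_conc_um, dtype=float)
    if np.any(dc < 0):
        raise InputError("ink concentration must be nonnegative")
    out = LN10 * absorption_extinction_ratio * eps_e_ink_um_cm * dc
    return float(out) if np.isscalar(delta_conc_um) else out


def to_icg_concentration(
    curve: AbsorptionChangeCurve, eps_icg_um_cm: float = DEFAULT_EPS_ICG
) -> ConcentrationCurve:
    """Convert Dmu_a(t) to tissue ICG concentration Q(t) = Dmu_a / (ln10 * eps)."""
    if eps_icg_um_cm <= 0:
        raise InputError("eps_ICG must be positive")
    q = curve.delta_mua / (LN10 * eps_icg_um_cm)
    return ConcentrationCurve(curve.times_s, q, role="tissue", extinction_um_cm=eps_icg_um_cm)


def concentration_to_delta_mua(curve: ConcentrationCurve) -> np.ndarray:
    """Inverse of :func:`to_icg_concentration` (exact round trip)."""
    if curve.extinction_um_cm is None:
        raise InputError("curve does not record the extinction coefficient used")
    return curve.values_um * LN10 * curve.extinction_um_cm
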