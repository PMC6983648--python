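"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here with seeded
randomness: instrument response functions, DTOF stacks under a dynamic
absorption time course, arterial and tissue ICG concentration curves, the
India-ink titration series of the phantom validation, and multi-cohort
longitudinal study tables.

Study conditions emulated by the defaults
-----------------------------------------
* a 10-s pre-injection baseline followed by bolus kinetics over 120 s sampled
  as 400 DTOFs;
* a gamma-variate arterial curve with a delayed, scaled recirculation bump,
  and a tissue curve (flow-scaled convolution with the impulse residue
  function) roughly two orders of magnitude smaller;
* a cuvette titration adding 0.02-mL increments of an ink stock to 3.5 mL of
  scattering solution, 100 DTOF frames per step;
* a 12-animal longitudinal study: 4 controls in one cohort, 8 experimental
  animals in 4 cohorts of 2, measured on both ankles twice per day, with
  cohort-level disease heterogeneity, humane-endpoint dropout after day 15,
  and ankle-days that lose one of their two repeats at a configurable rate.

Absorption dialect
------------------
By default (``absorption_mode="pathlength"``) dynamic absorption attenuates
frame intensities through the baseline effective pathlength,
``I_k = I_0 exp(-p_b * Dmu_a(t_k))`` -- the exact adjoint of the modified
Beer-Lambert analysis, so noise-free generate -> process round trips are
identities.  ``absorption_mode="timedomain"`` instead reweights the slab TPSF
by exp(-v Dmu_a t) (the exact diffusion-theory behaviour); that mode exhibits
the real system's few-percent sublinearity of recovered vs true absorption
changes, because a static baseline pathlength linearizes a curved relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import gamma as _gamma_fn

from .constants import DEFAULT_EPS_ICG, LN10, C_VACUUM_CM_PER_NS, flow_scale
from .diffusion import slab_transmittance_tpsf
from .dtof import (
    DTOF,
    DTOFStack,
    ConcentrationCurve,
    InputError,
    PhantomStep,
    expected_ink_delta_mua,
    mean_time_of_flight,
)

# ---------------------------------------------------------------------------
# domain types


@dataclass
class OpticalScene:
    """Slab-geometry optical properties and the histogram grid."""

    mu_a_baseline: float = 0.15  # cm^-1
    mu_s_prime: float = 10.0  # cm^-1
    thickness: float = 1.0  # cm (transversal extent of a rat ankle / cuvette)
    n_tissue: float = 1.4
    bin_width_ns: float = 0.01
    n_bins: int = 1024

    def __post_init__(self):
        if self.mu_a_baseline <= 0 or self.mu_s_prime <= 0 or self.thickness <= 0:
            raise InputError("optical coefficients and thickness must be positive")
        if self.n_tissue < 1:
            raise InputError("refractive index must be >= 1")
        if self.bin_width_ns <= 0 or self.n_bins < 8:
            raise InputError("need a positive bin width and a usable number of bins")


#: 0.8% Intralipid cuvette: water-dominated absorption, moderate scattering
PHANTOM_SCENE = OpticalScene(mu_a_baseline=0.025, mu_s_prime=8.0, thickness=1.0)


@dataclass
class BolusModel:
    """Gamma-variate arterial bolus with first-pass recirculation."""

    injection_time_s: float = 10.0
    dose_amplitude_um: float = 5.0  # peak arterial ICG concentration
    alpha: float = 3.0  # gamma-variate shape
    beta_s: float = 1.5  # gamma-variate scale (peak at injection + alpha*beta)
    recirculation_fraction: float = 0.15
    recirculation_delay_s: float = 12.0
    recirculation_broadening: float = 2.5  # scale stretch of the recirc bump

    def __post_init__(self):
        if self.injection_time_s < 0:
            raise InputError("injection time must be >= 0")
        if self.dose_amplitude_um < 0:
            raise InputError("dose amplitude must be >= 0")
        if self.alpha <= 0 or self.beta_s <= 0:
            raise InputError("gamma-variate shape/scale must be positive")
        if not 0 <= self.recirculation_fraction < 1:
            raise InputError("recirculation fraction must be in [0, 1)")


@dataclass
class ResidueShape:
    """Parametric impulse residue function R(t): R(0)=1, non-increasing."""

    kind: str = "plateau_exp"  # "plateau_exp" | "exp"
    plateau_s: float = 3.0  # minimum vascular transit time
    tau_s: float = 15.0  # washout time constant

    def __call__(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        if self.kind == "exp":
            r = np.exp(-np.clip(t, 0, None) / self.tau_s)
        elif self.kind == "plateau_exp":
            r = np.where(t <= self.plateau_s, 1.0, np.exp(-(t - self.plateau_s) / self.tau_s))
        else:
            raise InputError(f"unknown residue family {self.kind!r}")
        return np.where(t < 0, 0.0, r)


@dataclass
class PerfusionGroundTruth:
    bf_true: float = 15.0  # mL/min/100 g
    residue_shape: ResidueShape = field(default_factory=ResidueShape)
    tissue_density: float = 1.05  # g/mL

    def __post_init__(self):
        if self.bf_true < 0:
            raise InputError("blood flow must be >= 0")
        if self.tissue_density <= 0:
            raise InputError("tissue density must be positive")


# ---------------------------------------------------------------------------
# concentration curves


def gamma_variate(t_s, t0_s: float, amplitude: float, alpha: float, beta_s: float):
    """Peak-normalized gamma variate: amplitude attained at t0 + alpha*beta.

    y(t) = A * ((t-t0)/(alpha*beta))^alpha * exp(alpha - (t-t0)/beta)
    """
    t = np.asarray(t_s, dtype=float)
    u = t - t0_s
    tp = alpha * beta_s
    y = np.zeros_like(t)
    pos = u > 0
    y[pos] = amplitude * (u[pos] / tp) ** alpha * np.exp(alpha - u[pos] / beta_s)
    return y


def gamma_variate_integral(amplitude: float, alpha: float, beta_s: float) -> float:
    """Closed-form time integral of the peak-normalized gamma variate."""
    tp = alpha * beta_s
    return amplitude * np.exp(alpha) * tp**-alpha * beta_s ** (alpha + 1) * _gamma_fn(alpha + 1)


def generate_airf(model: BolusModel, times_s: np.ndarray) -> ConcentrationCurve:
    """Arterial input function: gamma variate plus delayed recirculation copy."""
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise InputError("time grid must be 1-D and strictly increasing")
    ca = gamma_variate(t, model.injection_time_s, model.dose_amplitude_um, model.alpha, model.beta_s)
    if model.recirculation_fraction > 0:
        ca = ca + gamma_variate(
            t,
            model.injection_time_s + model.recirculation_delay_s,
            model.recirculation_fraction * model.dose_amplitude_um,
            model.alpha,
            model.beta_s * model.recirculation_broadening,
        )
    return ConcentrationCurve(t, ca, role="arterial")


def generate_tissue_curve(
    airf: ConcentrationCurve, truth: PerfusionGroundTruth
) -> ConcentrationCurve:
    """Forward indicator-dilution model Q(t) = f * (Ca (*) R)(t).

    Discretized as the lower-triangular (causal) convolution on the arterial
    grid with rectangle-rule weighting -- the exact adjoint of the
    deconvolution operator in :mod:`dcenirs.perfusion`.
    """
    t = airf.times_s
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise InputError("arterial curve must be sampled on a uniform grid")
    f = flow_scale(truth.bf_true, truth.tissue_density)
    h = f * truth.residue_shape(t - t[0])
    # direct convolution keeps exact zeros before bolus arrival
    q = dt[0] * np.convolve(airf.values_um, h)[: t.size]
    q = np.clip(q, 0.0, None)
    return ConcentrationCurve(t, q, role="tissue", extinction_um_cm=DEFAULT_EPS_ICG)


# ---------------------------------------------------------------------------
# DTOFs


def generate_irf(
    scene: OpticalScene,
    t0_ns: float = 1.0,
    sigma_ns: float = 0.05,
    tail_fraction: float = 0.15,
    tail_tau_ns: float = 0.25,
    total_counts: float = 1e7,
) -> DTOF:
    """Deterministic instrument response: Gaussian peak with exponential tail."""
    t = np.arange(scene.n_bins) * scene.bin_width_ns
    peak = np.exp(-0.5 * ((t - t0_ns) / sigma_ns) ** 2)
    tail = np.where(t > t0_ns, np.exp(-(t - t0_ns) / tail_tau_ns), 0.0)
    shape = peak + tail_fraction * tail
    return DTOF(shape / shape.sum() * total_counts, scene.bin_width_ns, role="IRF")


def _baseline_dtof(scene: OpticalScene, irf: DTOF) -> np.ndarray:
    """IRF-convolved slab TPSF at baseline absorption (unnormalized)."""
    t = np.arange(scene.n_bins) * scene.bin_width_ns
    tpsf = slab_transmittance_tpsf(
        t, scene.mu_a_baseline, scene.mu_s_prime, scene.thickness, scene.n_tissue
    )
    return np.clip(fftconvolve(tpsf, irf.counts)[: scene.n_bins], 0.0, None)


def generate_dtof_series(
    scene: OpticalScene,
    mua_timecourse: np.ndarray,
    irf: DTOF,
    counts_per_frame: float = 1e6,
    frame_times_s: np.ndarray | None = None,
    seed=None,
    absorption_mode: str = "pathlength",
    noise: bool = True,
) -> DTOFStack:
    """DTOF stack under a dynamic absorption coefficient.

    Each frame is an (optionally Poisson-sampled) histogram whose expectation
    is the IRF-convolved slab TPSF, attenuated according to the frame's mu_a.
    ``counts_per_frame`` sets the expected total count at baseline absorption;
    frames with mu_a above baseline collect fewer photons.
    """
    mua = np.asarray(mua_timecourse, dtype=float)
    if np.any(mua <= 0):
        raise InputError("mu_a must be positive in every frame")
    if counts_per_frame <= 0:
        raise InputError("counts_per_frame must be positive")
    if absorption_mode not in ("pathlength", "timedomain"):
        raise InputError("absorption_mode must be 'pathlength' or 'timedomain'")
    n_frames = mua.size
    if frame_times_s is None:
        frame_times_s = np.arange(n_frames, dtype=float)
    base = _baseline_dtof(scene, irf)
    base = base / base.sum() * counts_per_frame
    dmua = mua - scene.mu_a_baseline
    if absorption_mode == "pathlength":
        v = C_VACUUM_CM_PER_NS / scene.n_tissue
        p_b = v * (
            mean_time_of_flight(DTOF(base, scene.bin_width_ns)) - mean_time_of_flight(irf)
        )
        expected = base[None, :] * np.exp(-p_b * dmua)[:, None]
    else:
        tb = np.arange(scene.n_bins) * scene.bin_width_ns
        v = C_VACUUM_CM_PER_NS / scene.n_tissue
        tpsf = slab_transmittance_tpsf(
            tb, scene.mu_a_baseline, scene.mu_s_prime, scene.thickness, scene.n_tissue
        )
        scale = counts_per_frame / fftconvolve(tpsf, irf.counts)[: scene.n_bins].sum()
        weighted = tpsf[None, :] * np.exp(-v * np.outer(dmua, tb))
        expected = np.empty((n_frames, scene.n_bins))
        for i in range(n_frames):  # FFT per frame; stacks are a few hundred frames
            expected[i] = scale * np.clip(
                fftconvolve(weighted[i], irf.counts)[: scene.n_bins], 0.0, None
            )
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DTOFStack(counts, scene.bin_width_ns, frame_times_s, t_start_ns=0.0)


# ---------------------------------------------------------------------------
# end-to-end bolus measurement


@dataclass
class BolusMeasurement:
    """A complete synthetic in-vivo measurement with its ground truth."""

    stack: DTOFStack
    irf: DTOF
    arterial: ConcentrationCurve
    tissue_truth: ConcentrationCurve
    scene: OpticalScene
    bolus: BolusModel
    truth: PerfusionGroundTruth
    eps_icg_um_cm: float


def generate_bolus_measurement(
    scene: OpticalScene | None = None,
    bolus: BolusModel | None = None,
    truth: PerfusionGroundTruth | None = None,
    irf: DTOF | None = None,
    n_frames: int = 400,
    duration_s: float = 120.0,
    counts_per_frame: float = 1e6,
    eps_icg_um_cm: float = DEFAULT_EPS_ICG,
    seed=None,
    absorption_mode: str = "pathlength",
    noise: bool = True,
) -> BolusMeasurement:
    """Simulate the full in-vivo protocol: 10-s baseline, bolus, 400 DTOFs/120 s."""
    scene = scene or OpticalScene()
    bolus = bolus or BolusModel()
    truth = truth or PerfusionGroundTruth()
    irf = irf or generate_irf(scene)
    times = np.arange(n_frames) * (duration_s / n_frames)
    ca = generate_airf(bolus, times)
    q = generate_tissue_curve(ca, truth)
    dmua = q.values_um * LN10 * eps_icg_um_cm
    stack = generate_dtof_series(
        scene,
        scene.mu_a_baseline + dmua,
        irf,
        counts_per_frame=counts_per_frame,
        frame_times_s=times,
        seed=seed,
        absorption_mode=absorption_mode,
        noise=noise,
    )
    return BolusMeasurement(stack, irf, ca, q, scene, bolus, truth, eps_icg_um_cm)


# ---------------------------------------------------------------------------
# phantom titration


@dataclass
class PhantomSeries:
    """Baseline + titration-step DTOF sets with their expected absorption changes."""

    scene: OpticalScene
    irf: DTOF
    baseline_stack: DTOFStack
    steps: list  # list[PhantomStep]
    step_stacks: list  # list[DTOFStack], parallel to steps
    eps_e_ink_um_cm: float


def default_ink_stock_conc(
    eps_e_ink_um_cm: float,
    increment_volume_ml: float = 0.02,
    base_volume_ml: float = 3.5,
    first_step_delta_mua: float = 0.005,
) -> float:
    """Ink stock concentration (uM) whose first 0.02-mL addition produces the
    target expected absorption change in the diluted cuvette volume."""
    c1 = first_step_delta_mua / (LN10 * 0.885 * eps_e_ink_um_cm)
    return c1 * (base_volume_ml + increment_volume_ml) / increment_volume_ml


def generate_phantom_series(
    scene: OpticalScene | None = None,
    eps_e_ink_um_cm: float = 0.2,
    ink_stock_conc_um: float | None = None,
    increment_volume_ml: float = 0.02,
    base_volume_ml: float = 3.5,
    n_steps: int = 10,
    frames_per_step: int = 100,
    counts_per_frame: float = 1e6,
    irf: DTOF | None = None,
    seed=None,
    absorption_mode: str = "pathlength",
    noise: bool = True,
) -> PhantomSeries:
    """Simulate the ink titration: cumulative concentration accounts for dilution.

    After k additions of volume v to base volume V0, the cumulative ink
    concentration is ``k v c_stock / (V0 + k v)``; the per-step true absorption
    change is the expected value from the ink extinction relation.  Each step
    (and the ink-free baseline) yields ``frames_per_step`` DTOF frames.
    """
    if n_steps < 1:
        raise InputError("need at least one titration step")
    scene = scene or PHANTOM_SCENE
    irf = irf or generate_irf(scene)
    if ink_stock_conc_um is None:
        ink_stock_conc_um = default_ink_stock_conc(
            eps_e_ink_um_cm, increment_volume_ml, base_volume_ml
        )
    rng = np.random.default_rng(seed)
    k = np.arange(1, n_steps + 1)
    conc = k * increment_volume_ml * ink_stock_conc_um / (base_volume_ml + k * increment_volume_ml)
    expected = expected_ink_delta_mua(eps_e_ink_um_cm, conc)
    steps = [
        PhantomStep(int(i + 1), float(conc[i]), eps_e_ink_um_cm, float(expected[i]))
        for i in range(n_steps)
    ]

    def _stack(mua):
        return generate_dtof_series(
            scene,
            np.full(frames_per_step, mua),
            irf,
            counts_per_frame=counts_per_frame,
            frame_times_s=np.arange(frames_per_step, dtype=float),
            seed=rng.integers(2**31),
            absorption_mode=absorption_mode,
            noise=noise,
        )

    baseline_stack = _stack(scene.mu_a_baseline)
    step_stacks = [_stack(scene.mu_a_baseline + e) for e in expected]
    return PhantomSeries(scene, irf, baseline_stack, steps, step_stacks, eps_e_ink_um_cm)


def cumulative_ink_concentration(
    k: int, increment_volume_ml: float, stock_conc_um: float, base_volume_ml: float
) -> float:
    """Ink concentration in the cuvette after k additions (dilution included)."""
    if k == 0:
        return 0.0
    v = k * increment_volume_ml
    return v * stock_conc_um / (base_volume_ml + v)


# ---------------------------------------------------------------------------
# longitudinal cohort study

DEFAULT_TIMEPOINTS = ("B1", "B2", "B3", "5", "10", "15", "20", "25", "30", "35", "40")
DEFAULT_DAY_NUMBERS = {"B1": -7, "B2": -3, "B3": 0}


def _day_number(label: str) -> int:
    if label in DEFAULT_DAY_NUMBERS:
        return DEFAULT_DAY_NUMBERS[label]
    return int(label)


@dataclass
class StudyDesign:
    """Design and effect structure of the longitudinal animal study.

    ``time_effect`` shifts every animal's BF on a given day; ``group_effect``
    additionally shifts experimental animals (the disease signal).  Cohorts
    share a random intercept (disease-induction heterogeneity); animals have
    their own random intercept on top.  Heart rate couples into BF with a
    small linear slope so that per-day HR-BF correlations average near the
    weakly positive value seen in vivo.
    """

    n_control: int = 4
    n_experimental: int = 8
    cohort_size: int = 2  # experimental animals per cohort
    timepoints: tuple = DEFAULT_TIMEPOINTS
    baseline_bf: float = 10.0  # mL/min/100 g
    time_effect: dict = field(
        default_factory=lambda: {"5": 1.0, "10": 3.5, "15": 2.5, "20": 2.0,
                                 "25": 1.5, "30": 1.5, "35": 1.0, "40": 1.0}
    )
    group_effect: dict = field(
        default_factory=lambda: {"5": 6.0, "10": 1.5, "15": 1.5, "20": 1.0,
                                 "25": 0.5, "30": 0.5, "35": 0.5, "40": 0.5}
    )
    cohort_effect_sd: float = 2.0
    cohort_severity_sd: float = 0.6  # cohort-level multiplier on the disease profile
    #: optional deterministic per-cohort day profiles {cohort: {day: BF shift}},
    #: e.g. flares peaking on different days -- the planted structure used in
    #: clustering-recovery experiments
    cohort_day_profiles: dict | None = None
    animal_effect_sd: float = 1.0
    within_animal_sd: float = 2.5
    hr_mean_bpm: float = 350.0
    hr_sd_bpm: float = 25.0
    hr_bf_slope: float = 0.014  # mL/min/100 g per bpm
    missing_repeat_prob: float = 0.1  # ankle-day loses exactly one repeat
    hep_hazard: float = 0.15  # per-day hazard after hep_start_day (experimental)
    hep_start_day: int = 16
    symptom_mean_day: float = 12.0
    symptom_cohort_sd: float = 2.2

    def __post_init__(self):
        if self.n_control + self.n_experimental <= 0:
            raise InputError("study must contain at least one animal")
        if not 0 <= self.missing_repeat_prob <= 1 or not 0 <= self.hep_hazard <= 1:
            raise InputError("probabilities must lie in [0, 1]")
        if self.n_experimental % self.cohort_size:
            raise InputError("cohort size must divide the number of experimental animals")
        nums = [_day_number(tp) for tp in self.timepoints]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise InputError("timepoints must be strictly ordered in study day")


@dataclass
class StudyTruth:
    """Latent quantities behind a generated study table."""

    animal_effects: pd.DataFrame  # per animal: group, cohort, intercepts, hep, symptoms
    day_effects: pd.DataFrame  # per day: time_effect, group_effect
    design: StudyDesign


def generate_cohort_study(design: StudyDesign, seed=None) -> tuple[pd.DataFrame, StudyTruth]:
    """Generate the per-measurement study table and its ground truth.

    Rows: one per animal x day x side x repeat that was actually acquired.
    Experimental animals stop contributing once their cohort reaches the
    humane endpoint (geometric per-day hazard starting at ``hep_start_day``,
    shared within cohort up to a one-day jitter).  With probability
    ``missing_repeat_prob`` an ankle-day loses exactly one of its two repeats
    (both are never lost), matching the observed failure pattern.
    """
    rng = np.random.default_rng(seed)
    d = design
    n_cohorts_exp = d.n_experimental // d.cohort_size
    animals, groups, cohorts = [], [], []
    for i in range(d.n_experimental):
        animals.append(f"rat{i + 1:02d}")
        groups.append("experimental")
        cohorts.append(f"C{i // d.cohort_size + 1}")
    for i in range(d.n_control):
        animals.append(f"rat{d.n_experimental + i + 1:02d}")
        groups.append("control")
        cohorts.append(f"C{n_cohorts_exp + 1}")

    cohort_names = sorted(set(cohorts))
    cohort_eff = {c: rng.normal(0.0, d.cohort_effect_sd) for c in cohort_names}
    # disease-induction heterogeneity: each experimental cohort responds with
    # its own severity multiplier on the group (disease) profile
    cohort_sev = {c: max(0.0, rng.normal(1.0, d.cohort_severity_sd)) for c in cohort_names}
    animal_eff = {a: rng.normal(0.0, d.animal_effect_sd) for a in animals}

    day_nums = {tp: _day_number(tp) for tp in d.timepoints}
    last_day = max(day_nums.values())

    # cohort-level humane endpoint and first-symptom days (experimental only)
    hep_day, symptom_day = {}, {}
    for c in cohort_names:
        is_exp = any(g == "experimental" and co == c for g, co in zip(groups, cohorts))
        if not is_exp:
            continue
        base_hep = d.hep_start_day + (rng.geometric(d.hep_hazard) - 1 if d.hep_hazard > 0 else np.inf)
        base_sym = rng.normal(d.symptom_mean_day, d.symptom_cohort_sd)
        hep_day[c] = base_hep
        symptom_day[c] = base_sym

    rows = []
    truth_rows = []
    for a, g, c in zip(animals, groups, cohorts):
        if g == "experimental":
            a_hep = hep_day[c] + rng.integers(0, 2)
            a_sym = float(np.round(symptom_day[c]) + rng.integers(0, 2))
            a_hep = float(a_hep) if a_hep <= last_day else np.nan
        else:
            a_hep, a_sym = np.nan, np.nan
        truth_rows.append(
            dict(animal=a, group=g, cohort=c, cohort_effect=cohort_eff[c],
                 cohort_severity=cohort_sev[c], animal_effect=animal_eff[a],
                 hep_day=a_hep, first_symptom_day=a_sym)
        )
        for tp in d.timepoints:
            day = day_nums[tp]
            if np.isfinite(a_hep) and day >= a_hep:
                continue
            for side in ("L", "R"):
                drop = None
                if rng.random() < d.missing_repeat_prob:
                    drop = int(rng.integers(1, 3))
                for rep in (1, 2):
                    if rep == drop:
                        continue
                    hr = rng.normal(d.hr_mean_bpm, d.hr_sd_bpm)
                    bf = (
                        d.baseline_bf
                        + d.time_effect.get(tp, 0.0)
                        + (cohort_sev[c] * d.group_effect.get(tp, 0.0)
                           if g == "experimental" else 0.0)
                        + (d.cohort_day_profiles or {}).get(c, {}).get(tp, 0.0)
                        + cohort_eff[c]
                        + animal_eff[a]
                        + d.hr_bf_slope * (hr - d.hr_mean_bpm)
                        + rng.normal(0.0, d.within_animal_sd)
                    )
                    rows.append(
                        dict(animal=a, group=g, cohort=c, day=tp, day_num=day,
                             side=side, repeat=rep, bf=max(bf, 0.0), hr=hr,
                             hep_day=a_hep, first_symptom_day=a_sym)
                    )
    table = pd.DataFrame(rows)
    day_eff = pd.DataFrame(
        {
            "day": list(d.timepoints),
            "time_effect": [d.time_effect.get(tp, 0.0) for tp in d.timepoints],
            "group_effect": [d.group_effect.get(tp, 0.0) for tp in d.timepoints],
        }
    )
    return table, StudyTruth(pd.DataFrame(truth_rows), day_eff, design)
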