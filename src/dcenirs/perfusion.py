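"""Blood-flow quantification by regularized deconvolution.

The indicator-dilution model ties the tissue tracer curve Q(t) to the
arterial input Ca(t) through the flow-scaled impulse residue function
h(t) = f R(t):

    Q(t) = (Ca (*) h)(t),   R(0) = 1, R non-increasing,

so f = max h and blood flow BF = 6000 f / rho in mL/min/100 g.  On a uniform
grid the convolution is a lower-triangular Toeplitz system; h is recovered by
Tikhonov-regularized nonnegative least squares, with the regularization
weight chosen by generalized cross-validation (GCV) by default.  BF is read
from max(h) rather than h(0), which is robust to small arterial-to-tissue
delays; a bolus-arrival delay can additionally be scanned on a bounded grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import DEFAULT_RHO_TISSUE, ICG_MOLAR_MASS_G_PER_MOL, flow_from_scale
from .dtof import (
    DTOF,
    DTOFStack,
    ConcentrationCurve,
    InputError,
    delta_mua_timecourse,
    to_icg_concentration,
)


class DegenerateInputError(InputError):
    """The arterial input function carries no usable signal."""


@dataclass
class ResidueEstimate:
    """Deconvolution result: h(t) = f R(t) and the derived blood flow."""

    times_s: np.ndarray
    h_per_s: np.ndarray
    bf_ml_min_100g: float
    regularization: tuple  # (method, lambda)
    fit_residual_rms_um: float
    delay_s: float = 0.0
    rho_g_per_ml: float = DEFAULT_RHO_TISSUE


def mg_per_l_to_um(values_mg_per_l) -> np.ndarray:
    """Dye-densitometer arterial units (mg/L) to uM via the ICG molar mass."""
    return np.asarray(values_mg_per_l, dtype=float) / ICG_MOLAR_MASS_G_PER_MOL * 1000.0


def _resample_to(ca: ConcentrationCurve, q: ConcentrationCurve) -> np.ndarray:
    """Tissue values on the arterial grid (linear interpolation if needed)."""
    if q.times_s.size == ca.times_s.size and np.allclose(q.times_s, ca.times_s, rtol=1e-9):
        return q.values_um
    return np.interp(ca.times_s, q.times_s, q.values_um)


def _gcv_lambda(s: np.ndarray, beta: np.ndarray, n: int, grid: np.ndarray) -> float:
    """Minimize the GCV function over a lambda grid given the SVD of A.

    GCV(l) = ||(I - A A_l^+) q||^2 / tr(I - A A_l^+)^2 with Tikhonov filter
    factors s^2/(s^2+l^2); beta = U^T q.
    """
    best, best_g = grid[0], np.inf
    for lam in grid:
        fl = s**2 / (s**2 + lam**2)
        resid = float(np.sum(((1.0 - fl) * beta) ** 2))
        tr = n - float(fl.sum())
        g = resid / tr**2
        if g < best_g:
            best, best_g = lam, g
    return float(best)


def _solve(A: np.ndarray, q: np.ndarray, lam: float, mu: float, nonneg: bool) -> np.ndarray:
    n = A.shape[1]
    blocks = [A, lam * np.eye(n)]
    if mu > 0:  # first-difference roughness penalty
        blocks.append(mu * np.diff(np.eye(n), axis=0))
    A_aug = np.vstack(blocks)
    b_aug = np.concatenate([q, np.zeros(A_aug.shape[0] - n)])
    if nonneg:
        h, _ = optimize.nnls(A_aug, b_aug)
        return h
    return np.linalg.lstsq(A_aug, b_aug, rcond=None)[0]


def _monotone_after_peak(h: np.ndarray) -> np.ndarray:
    """Project h onto the cone {non-increasing after its maximum} (PAVA-style)."""
    k = int(np.argmax(h))
    out = h.copy()
    running = out[k]
    for i in range(k + 1, out.size):
        running = min(running, out[i])
        out[i] = running
    return out


def deconvolve_bf(
    ca: ConcentrationCurve,
    q: ConcentrationCurve,
    rho_g_per_ml: float = DEFAULT_RHO_TISSUE,
    reg: str = "gcv",
    lam: float | None = None,
    n_lambdas: int = 33,
    roughness: float = 1e-2,
    nonneg: bool = True,
    monotone: bool = False,
    delay_grid_s: np.ndarray | None = None,
) -> ResidueEstimate:
    """Recover h = f R and blood flow from an arterial/tissue curve pair.

    Parameters
    ----------
    reg : "gcv" (default) or "fixed" (requires ``lam``)
    roughness : weight of a first-difference smoothness penalty on h,
        relative to the largest singular value of the convolution operator.
        Suppresses the alternating-spike solutions nonnegative deconvolution
        produces when the data deviate smoothly from the convolution model;
        0 disables it.
    delay_grid_s : optional bolus-arrival delays to scan (the arterial curve
        is shifted by each candidate and the best-fitting delay kept)
    """
    if ca.role != "arterial" or q.role != "tissue":
        raise InputError("expected an arterial and a tissue concentration curve")
    t = ca.times_s
    dt = np.diff(t)
    if t.size < 3 or np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise InputError("arterial curve must be on a uniform, increasing time grid")
    dt = float(dt[0])
    qv = _resample_to(ca, q)
    if not np.any(ca.values_um > 0):
        raise DegenerateInputError("degenerate input function: arterial curve is all zero")
    if reg not in ("gcv", "fixed"):
        raise InputError("reg must be 'gcv' or 'fixed'")
    if reg == "fixed" and lam is None:
        raise InputError("fixed regularization requires lam")

    delays = np.atleast_1d(delay_grid_s if delay_grid_s is not None else [0.0]).astype(float)
    n = t.size
    best = None
    for delay in delays:
        cav = np.interp(t - delay, t, ca.values_um, left=0.0)
        col = cav * dt
        A = np.zeros((n, n))
        for i in range(n):  # lower-triangular Toeplitz
            A[i:, i] = col[: n - i]
        if reg == "gcv":
            U, s, _ = np.linalg.svd(A)
            smax = float(s.max())
            beta = U.T @ qv
            grid = smax * np.logspace(-8, 0, n_lambdas)
            lam_use = _gcv_lambda(s, beta, n, grid)
        else:
            smax = float(np.linalg.norm(A, 2))
            lam_use = float(lam)
        h = _solve(A, qv, lam_use, roughness * smax, nonneg)
        if monotone:
            h = _monotone_after_peak(h)
        resid = float(np.sqrt(np.mean((A @ h - qv) ** 2)))
        if best is None or resid < best[0]:
            best = (resid, delay, h, lam_use)
    resid, delay, h, lam_use = best
    bf = flow_from_scale(float(h.max()), rho_g_per_ml)
    return ResidueEstimate(t, h, bf, (reg, lam_use), resid, float(delay), rho_g_per_ml)


def refold(estimate: ResidueEstimate, ca: ConcentrationCurve) -> np.ndarray:
    """Forward-convolve the estimated h with the arterial curve (model check)."""
    t = ca.times_s
    dt = float(t[1] - t[0])
    cav = np.interp(t - estimate.delay_s, t, ca.values_um, left=0.0)
    return dt * np.convolve(cav, estimate.h_per_s)[: t.size]


def quantify_stack(
    stack: DTOFStack,
    irf: DTOF,
    ca: ConcentrationCurve,
    baseline_window_s: tuple = (0.0, 10.0),
    n_tissue: float = 1.4,
    eps_icg_um_cm: float | None = None,
    pathlength_scale: float = 1.0,
    **deconv_kwargs,
) -> ResidueEstimate:
    """Full chain: DTOF stack -> Dmu_a -> Q -> deconvolved blood flow."""
    from .constants import DEFAULT_EPS_ICG

    curve = delta_mua_timecourse(
        stack, irf, baseline_window_s, n_tissue, pathlength_scale=pathlength_scale
    )
    q = to_icg_concentration(curve, eps_icg_um_cm or DEFAULT_EPS_ICG)
    return deconvolve_bf(ca, q, **deconv_kwargs)


def pathlength_sensitivity(
    stack: DTOFStack,
    irf: DTOF,
    ca: ConcentrationCurve,
    perturbation: float = 0.005,
    **kwargs,
) -> float:
    """Maximum |percent change| in recovered BF under a pathlength perturbation.

    Reruns the full Dmu_a -> Q -> BF chain with the baseline pathlength scaled
    by (1 - perturbation) and (1 + perturbation) and returns
    ``max |BF_pert - BF_ref| / BF_ref * 100``.
    """
    if not abs(perturbation) < 0.1:
        raise InputError("perturbation magnitude must be below 0.1")
    bf_ref = quantify_stack(stack, irf, ca, **kwargs).bf_ml_min_100g
    if bf_ref == 0:
        raise InputError("reference blood flow is zero; sensitivity undefined")
    changes = []
    for scale in (1.0 - perturbation, 1.0 + perturbation):
        bf = quantify_stack(stack, irf, ca, pathlength_scale=scale, **kwargs).bf_ml_min_100g
        changes.append(abs(bf - bf_ref) / bf_ref * 100.0)
    return float(max(changes))


def aggregate_measurements(records) -> "pd.DataFrame":
    """Collapse repeat measurements to one BF value per animal x day x side.

    Two repeats -> their mean; one repeat -> that value; zero repeats -> the
    (animal, day, side) cell is absent from the output.  More than two repeats
    is an input error.  No imputation across sides or days.
    """
    import pandas as pd

    df = pd.DataFrame(records)
    required = {"animal", "day", "side", "bf"}
    if not required.issubset(df.columns):
        raise InputError(f"records must contain columns {sorted(required)}")
    df = df.dropna(subset=["bf"])
    counts = df.groupby(["animal", "day", "side"], sort=False)["bf"].size()
    if (counts > 2).any():
        raise InputError("more than two repeats for some animal x day x side")
    keep = [c for c in ("group", "cohort", "day_num") if c in df.columns]
    agg = (
        df.groupby(["animal", "day", "side"] + keep, sort=False, as_index=False)
        .agg(bf=("bf", "mean"), n_repeats=("bf", "size"))
    )
    return agg
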