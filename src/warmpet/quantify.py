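"""Washout-based quantification of dynamic [11C]PiB PET.

The central estimator is the washout allometric reference method: after the
brief arterial phase the tracer deposit in tissue is complete and regional
kinetics are governed by washout alone, so the non-displaceable binding
potential of a target region can be computed from the accumulated
log-signal of the target and of a reference region free of specific
binding (cerebellum grey matter):

    BP_ND = [ m(0) * Int_washout( ln m_ND(t) - ln m_ND(0) ) dt ]
            / [ m_ND(0) * Int_washout( ln m(t) - ln m(0) ) dt ]  -  1

where ``m(t)`` is the target curve, ``m_ND(t)`` the reference curve and
``m(0)``/``m_ND(0)`` are the respective peak-phase maxima (the tracer
initially deposited before washout). Each integral runs over that curve's
own washout phase, from its peak to the upper limit ``T`` (default 60 min),
evaluated by the trapezoidal rule on frame mid-times. The peak scaling
corrects for flow-dependent delivery; the log-integrals capture the
differential washout rates. For curves that washout mono-exponentially with
rates ``k`` (target) and ``k_ND`` (reference) and aligned peaks the
estimator reduces exactly to ``(m(0)*k_ND)/(m_ND(0)*k) - 1``.

Companion early-phase measures:

* ``R1`` (relative uptake, a relative perfusion index): the target
  peak-phase maximum divided by the reference one;
* ``sCBF`` (surrogate cerebral blood flow): the slope of the rise to the
  peak, ``peak value / time-to-peak``, optionally scaled by a site-specific
  calibration factor so the cohort mean matches a known mean CBF;
* ``SUVR``: ratio of late-window (40-60 min) activity integrals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateSignalError,
    CalibrationError,
    NonWashoutError,
    ScheduleError,
    WindowError,
)
from .io_pet import DynamicImage, RegionMask, TimeActivityCurve, extract_tac

__all__ = [
    "PhaseSplit",
    "WarmResult",
    "SuvrResult",
    "find_peak",
    "warm_bpnd",
    "warm_result",
    "relative_uptake_r1",
    "surrogate_cbf",
    "calibrate_scale_factor",
    "suvr",
    "parametric_maps",
    "regional_means_from_maps",
    "regional_summary",
]

PEAK_WINDOW = (2.0, 10.0)  # min; the peak-uptake phase
ARTERIAL_WINDOW = (0.0, 2.0)  # min; high-frequency arterial signal, ignored
DEFAULT_T = 60.0  # min; upper washout integration limit
SUVR_WINDOW = (40.0, 60.0)  # min; late steady-state window
CLAMP_FRACTION = 0.01  # nonpositive washout samples clamped to 1% of peak
MAX_CLAMPED_FRACTION = 0.25  # voxels with more clamped frames get NaN


@dataclass(frozen=True)
class PhaseSplit:
    """Decomposition of a TAC into arterial, peak-uptake and washout phases."""

    peak_frame_index: int
    peak_value: float
    time_to_peak: float
    arterial_window: tuple[float, float] = ARTERIAL_WINDOW
    peak_window: tuple[float, float] = PEAK_WINDOW
    washout_window: tuple[float, float] | None = None


@dataclass(frozen=True)
class WarmResult:
    """Per-region (or per-voxel) washout-method estimates."""

    bpnd: float
    r1: float
    scbf: float
    peak_value: float
    time_to_peak: float
    T: float
    n_clamped: int = 0


@dataclass(frozen=True)
class SuvrResult:
    suvr: float
    window: tuple[float, float] = SUVR_WINDOW


def find_peak(tac: TimeActivityCurve,
              window: tuple[float, float] = PEAK_WINDOW) -> PhaseSplit:
    """Locate the peak-uptake maximum of a TAC within the peak window.

    The peak value and its frame mid-time anchor both the washout integral
    (its time origin and normalisation) and the early-phase flow measures.
    Ties are broken toward the earliest frame.
    """
    mid = tac.mid_times
    in_window = (mid >= window[0]) & (mid <= window[1])
    if not np.any(in_window):
        raise WindowError(
            f"no frame mid-time falls in the peak window [{window[0]}, {window[1]}] min"
        )
    values = tac.activity[in_window]
    if np.all(values <= 0):
        raise DegenerateSignalError("TAC is nonpositive throughout the peak window")
    local = int(np.argmax(values))  # argmax returns the first maximum: earliest frame
    idx = int(np.flatnonzero(in_window)[local])
    last_mid = float(mid[-1])
    return PhaseSplit(
        peak_frame_index=idx,
        peak_value=float(tac.activity[idx]),
        time_to_peak=float(mid[idx]),
        peak_window=window,
        washout_window=(float(mid[idx]), last_mid),
    )


def _washout_log_integral(activity: np.ndarray, mid: np.ndarray,
                          peak_index: int, peak_value: float,
                          T: float) -> tuple[float, int, int]:
    """Trapezoidal integral of ``ln m(t) - ln m(0)`` from the peak mid-time
    to the last mid-time <= T.

    Nonpositive samples are clamped to ``CLAMP_FRACTION * peak_value``
    before the log (reconstruction noise makes small negatives common);
    positive samples are never altered. Returns
    (integral, n_frames_used, n_clamped).
    """
    sel = (np.arange(len(mid)) >= peak_index) & (mid <= T + 1e-9)
    t = mid[sel]
    if len(t) < 2:
        raise WindowError(
            f"washout phase from {mid[peak_index]:.2f} min to T={T} min spans "
            f"fewer than two frames"
        )
    values = activity[sel]
    floor = CLAMP_FRACTION * peak_value
    nonpositive = values <= 0
    n_clamped = int(np.count_nonzero(nonpositive))
    values = np.where(nonpositive, floor, values)
    integrand = np.log(values) - np.log(peak_value)
    return float(np.trapezoid(integrand, t)), len(t), n_clamped


def warm_bpnd(target: TimeActivityCurve, reference: TimeActivityCurve,
              T: float = DEFAULT_T) -> float:
    """Non-displaceable binding potential of the target region by the
    washout method (see module docstring for the operational equation)."""
    return warm_result(target, reference, T=T).bpnd


def warm_result(target: TimeActivityCurve, reference: TimeActivityCurve,
                T: float = DEFAULT_T, scale_factor: float = 1.0) -> WarmResult:
    """Full washout-method result: BP_ND plus the early-phase measures
    (R1, surrogate flow) derived from the same peak decomposition."""
    if target.schedule != reference.schedule:
        raise ScheduleError("target and reference TACs must share a frame schedule")
    split_t = find_peak(target)
    split_r = find_peak(reference)
    mid = target.mid_times
    int_ref, _, nc_r = _washout_log_integral(
        reference.activity, mid, split_r.peak_frame_index, split_r.peak_value, T
    )
    int_tgt, _, nc_t = _washout_log_integral(
        target.activity, mid, split_t.peak_frame_index, split_t.peak_value, T
    )
    denominator = split_r.peak_value * int_tgt
    if denominator >= 0:
        raise NonWashoutError(
            "target washout log-integral is non-negative: the curve does not "
            "decay after its peak, binding potential is undefined"
        )
    bpnd = (split_t.peak_value * int_ref) / denominator - 1.0
    return WarmResult(
        bpnd=float(bpnd),
        r1=relative_uptake_r1(split_t.peak_value, split_r.peak_value),
        scbf=surrogate_cbf(split_t.peak_value, split_t.time_to_peak, scale_factor),
        peak_value=split_t.peak_value,
        time_to_peak=split_t.time_to_peak,
        T=T,
        n_clamped=nc_t + nc_r,
    )


def relative_uptake_r1(target_peak: float, reference_peak: float) -> float:
    """Relative uptake coefficient: target peak over reference (cerebellum
    grey matter) peak. A relative, not absolute, perfusion measure."""
    if reference_peak <= 0:
        raise DegenerateSignalError("reference peak must be positive for R1")
    return float(target_peak / reference_peak)


def surrogate_cbf(peak_value: float, time_to_peak: float,
                  scale_factor: float = 1.0) -> float:
    """Surrogate cerebral blood flow: the slope of the rise to the peak
    (peak value / time-to-peak), times a site-specific calibration factor.

    With the default ``scale_factor=1`` the value is an uncalibrated flow
    index in kBq/mL/min; after :func:`calibrate_scale_factor` it is on the
    scale of the calibration target (typically mL/100g/min).
    """
    if time_to_peak <= 0:
        raise DegenerateSignalError("time-to-peak must be positive for sCBF")
    if scale_factor <= 0:
        raise CalibrationError("scale factor must be positive")
    return float(scale_factor * peak_value / time_to_peak)


def calibrate_scale_factor(cohort_scbf_raw, target_mean_cbf: float) -> float:
    """Site-specific flow calibration: the factor that maps the cohort mean
    of raw peak/time-to-peak slopes onto a known mean CBF value."""
    raw = np.asarray(cohort_scbf_raw, dtype=float)
    if raw.size == 0:
        raise CalibrationError("cohort of raw sCBF values is empty")
    mean = float(raw.mean())
    if mean <= 0:
        raise CalibrationError(f"cohort mean raw sCBF must be positive, got {mean}")
    if target_mean_cbf <= 0:
        raise CalibrationError("target mean CBF must be positive")
    return target_mean_cbf / mean


def suvr(target: TimeActivityCurve, reference: TimeActivityCurve,
         t_s: float = SUVR_WINDOW[0], t_e: float = SUVR_WINDOW[1]) -> SuvrResult:
    """Standard uptake value ratio over the late steady-state window: the
    trapezoidal integral of the target curve over [t_s, t_e] divided by the
    reference-region integral over the same window."""
    if target.schedule != reference.schedule:
        raise ScheduleError("target and reference TACs must share a frame schedule")
    mid = target.mid_times
    sel = (mid >= t_s - 1e-9) & (mid <= t_e + 1e-9)
    if np.count_nonzero(sel) < 2:
        raise WindowError(
            f"SUVR window [{t_s}, {t_e}] min covers fewer than two frame mid-times"
        )
    t = mid[sel]
    num = float(np.trapezoid(target.activity[sel], t))
    den = float(np.trapezoid(reference.activity[sel], t))
    if den <= 0:
        raise DegenerateSignalError("reference integral over the SUVR window is nonpositive")
    return SuvrResult(suvr=num / den, window=(t_s, t_e))


# ---------------------------------------------------------------------------
# voxelwise parametric maps
# ---------------------------------------------------------------------------

def parametric_maps(image: DynamicImage, mask: RegionMask,
                    reference_region: str = "CERB", T: float = DEFAULT_T,
                    scale_factor: float = 1.0,
                    t_s: float = SUVR_WINDOW[0], t_e: float = SUVR_WINDOW[1],
                    ) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Voxelwise parametric maps of BP_ND, R1, sCBF and SUVR.

    Every labelled voxel is quantified against the mean reference-region
    TAC. Voxels that fail a precondition (nonpositive peak, non-decaying
    washout, too many clamped frames) receive NaN and are counted in the QC
    report. Background voxels are NaN throughout.

    Returns ``(maps, qc)`` where ``maps`` holds one 3D float array per
    measure and ``qc`` counts the voxels excluded per failure mode.
    """
    reference = extract_tac(image, mask, reference_region)
    split_ref = find_peak(reference)  # raises if the reference itself is unusable
    mid = image.schedule.mid_times
    int_ref, _, _ = _washout_log_integral(
        reference.activity, mid, split_ref.peak_frame_index, split_ref.peak_value, T
    )

    in_brain = mask.labels > 0
    tacs = image.voxels[in_brain]  # (n_vox, n_frames)
    n_vox = tacs.shape[0]

    peak_sel = (mid >= PEAK_WINDOW[0]) & (mid <= PEAK_WINDOW[1])
    peak_idx_global = np.flatnonzero(peak_sel)
    window_vals = tacs[:, peak_sel]
    local_arg = np.argmax(window_vals, axis=1)  # first max: earliest-frame tie-break
    peak_index = peak_idx_global[local_arg]
    peak_value = tacs[np.arange(n_vox), peak_index]
    time_to_peak = mid[peak_index]

    bpnd = np.full(n_vox, np.nan)
    qc = {"nonpositive_peak": 0, "non_washout": 0, "excess_clamped": 0}
    ok_peak = peak_value > 0
    qc["nonpositive_peak"] = int(np.count_nonzero(~ok_peak))

    washout_ok = mid <= T + 1e-9
    for p in np.unique(peak_index[ok_peak]):
        group = ok_peak & (peak_index == p)
        sel = (np.arange(len(mid)) >= p) & washout_ok
        t = mid[sel]
        if len(t) < 2:
            continue
        vals = tacs[group][:, sel]
        floor = CLAMP_FRACTION * peak_value[group, None]
        nonpositive = vals <= 0
        n_clamped = nonpositive.sum(axis=1)
        vals = np.where(nonpositive, floor, vals)
        integrand = np.log(vals) - np.log(peak_value[group, None])
        int_tgt = np.trapezoid(integrand, t, axis=1)
        denom = split_ref.peak_value * int_tgt
        good = (denom < 0) & (n_clamped <= MAX_CLAMPED_FRACTION * len(t))
        qc["non_washout"] += int(np.count_nonzero(group) - np.count_nonzero(
            denom < 0))
        qc["excess_clamped"] += int(np.count_nonzero(
            (denom < 0) & (n_clamped > MAX_CLAMPED_FRACTION * len(t))))
        est = np.full(good.shape, np.nan)
        est[good] = (peak_value[group][good] * int_ref) / denom[good] - 1.0
        bpnd[group] = est

    r1 = np.where(ok_peak, peak_value / split_ref.peak_value, np.nan)
    scbf = np.where(ok_peak, scale_factor * peak_value / time_to_peak, np.nan)

    suvr_sel = (mid >= t_s - 1e-9) & (mid <= t_e + 1e-9)
    t_late = mid[suvr_sel]
    den = float(np.trapezoid(reference.activity[suvr_sel], t_late))
    suvr_vox = np.trapezoid(tacs[:, suvr_sel], t_late, axis=1) / den

    shape = image.voxels.shape[:3]
    maps: dict[str, np.ndarray] = {}
    for name, flat in (("bpnd", bpnd), ("r1", r1), ("scbf", scbf),
                       ("suvr", suvr_vox), ("peak", peak_value.astype(float)),
                       ("time_to_peak", time_to_peak.astype(float))):
        vol = np.full(shape, np.nan)
        vol[in_brain] = flat
        maps[name] = vol
    qc["n_voxels"] = n_vox
    qc["n_sentinel_bpnd"] = int(np.count_nonzero(np.isnan(bpnd)))
    return maps, qc


def regional_means_from_maps(maps: dict[str, np.ndarray], mask: RegionMask):
    """Region means of voxelwise parametric maps (NaN sentinels excluded).

    This is the regional route used for cohort statistics: because every
    voxel is quantified against the mean reference curve, reference-region
    voxels scatter around BP_ND = 0 / R1 = 1 / SUVR = 1 rather than being
    identically there, as in real parametric images.

    Returns a DataFrame with one row per region and one column per measure.
    """
    import pandas as pd

    rows = []
    for region in mask.region_names:
        idx = mask.indices(region)
        row = {"region": region, "n_voxels": int(np.count_nonzero(idx))}
        for name, vol in maps.items():
            values = vol[idx]
            row[name] = float(np.nanmean(values)) if np.any(
                np.isfinite(values)) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def regional_summary(image: DynamicImage, mask: RegionMask,
                     reference_region: str = "CERB", T: float = DEFAULT_T,
                     scale_factor: float = 1.0):
    """Region-level quantification from region-mean TACs.

    Returns a pandas DataFrame with one row per region and columns
    (region, bpnd, r1, scbf, suvr, peak, time_to_peak, n_voxels, n_clamped).
    """
    import pandas as pd

    reference = extract_tac(image, mask, reference_region)
    rows = []
    for region in mask.region_names:
        tac = extract_tac(image, mask, region)
        res = warm_result(tac, reference, T=T, scale_factor=scale_factor)
        rows.append({
            "region": region,
            "bpnd": res.bpnd,
            "r1": res.r1,
            "scbf": res.scbf,
            "suvr": suvr(tac, reference).suvr,
            "peak": res.peak_value,
            "time_to_peak": res.time_to_peak,
            "n_voxels": mask.n_voxels(region),
            "n_clamped": res.n_clamped,
        })
    return pd.DataFrame(rows)
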