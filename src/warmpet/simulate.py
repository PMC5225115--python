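"""Synthetic dynamic [11C]PiB data with known ground truth.

The simulator emulates the kinetic premises of amyloid PET with a
fast-clearing tracer: a sharp arterial input that has essentially vanished
by 10 min, flow-limited early uptake producing a tissue peak a few minutes
after injection, and mono/multi-exponential washout thereafter. Tissue
curves follow the one-tissue reference-tissue solution

    C(t) = R1 * C_ref(t) + R1 * (k2_ref - k2a) * [C_ref (x) exp(-k2a t)],
    k2a = R1 * k2_ref / (1 + BP_ND)

where ``C_ref`` is the reference (cerebellum grey matter) curve, ``R1`` the
relative delivery, ``k2_ref`` the reference washout rate and ``(x)``
convolution. Specific binding (BP_ND > 0) slows the apparent washout while
the delivery factor cancels between deposit and clearance; at
``BP_ND = 0, R1 = 1`` the target collapses onto the reference.

Curves are evaluated on a fine internal grid (0.01 min) and averaged over
each frame's duration, mimicking the time-integrating nature of PET frames.
Noise is multiplicative Gaussian per frame with count-based CV scaling:
late frames are noisier because the carbon-11 label has decayed.

Cohort presets (AD-like, DLB-like, FTLD-like, MCI-like, HC-like) encode the
qualitative regional patterns of the dementia groups: where amyloid binding
is raised and where flow is depressed. The magnitudes are simulator
presets, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import fftconvolve

from .errors import FormatError, WarmPetError
from .io_pet import (
    DynamicImage,
    FrameSchedule,
    RegionMask,
    STANDARD_REGIONS,
    TimeActivityCurve,
    default_schedule,
)

__all__ = [
    "KineticSpec",
    "CohortSpec",
    "simulate_input_function",
    "simulate_reference",
    "simulate_tac",
    "apply_frame_noise",
    "simulate_cohort_tacs",
    "build_phantom",
    "load_presets",
    "cohort_from_preset",
]

FINE_DT = 0.01  # min; internal integration grid
DEFAULT_K2_REF = 0.03  # 1/min; effective reference-tissue washout rate
DEFAULT_K1_REF = 100.0  # kBq/mL per unit input; sets the activity scale
DEFAULT_INPUT_SHARPNESS = (1.5, 3.0)  # gamma-variate (alpha, beta 1/min)


@dataclass(frozen=True)
class KineticSpec:
    """Ground-truth kinetics for one tissue region of one subject."""

    r1_true: float = 1.0
    bpnd_true: float = 0.0
    k2_ref: float = DEFAULT_K2_REF
    input_sharpness: tuple[float, float] = DEFAULT_INPUT_SHARPNESS
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.r1_true <= 0:
            raise FormatError("r1_true must be positive")
        if self.bpnd_true < 0:
            raise FormatError("bpnd_true must be nonnegative")
        if self.k2_ref <= 0:
            raise FormatError("k2_ref must be positive")
        if self.noise_cv < 0:
            raise FormatError("noise_cv must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """A simulated study: named groups with per-region kinetic distributions.

    ``groups`` maps group name -> region name -> dict with keys
    ``bpnd_mean, bpnd_sd, r1_mean, r1_sd``; ``n_per_group`` maps group name
    -> number of subjects. The region set must include the reference region.
    """

    groups: dict
    n_per_group: dict
    seed: int = 0
    noise_cv: float = 0.10
    k2_ref: float = DEFAULT_K2_REF
    reference_region: str = "CERB"

    def __post_init__(self) -> None:
        for name, n in self.n_per_group.items():
            if n < 1:
                raise FormatError(f"group {name!r} must have >= 1 subject")
            if name not in self.groups:
                raise FormatError(f"group {name!r} has no kinetic template")
        for name, regions in self.groups.items():
            if self.reference_region not in regions:
                raise FormatError(
                    f"group {name!r} template lacks the reference region "
                    f"{self.reference_region!r}"
                )


# ---------------------------------------------------------------------------
# fine-grid kinetics
# ---------------------------------------------------------------------------

def _fine_grid(schedule: FrameSchedule) -> np.ndarray:
    t_end = float(schedule.end_times[-1])
    return np.arange(0.0, t_end + FINE_DT, FINE_DT)


def _input_fine(t: np.ndarray, sharpness=DEFAULT_INPUT_SHARPNESS,
                amplitude: float = 1.0) -> np.ndarray:
    """Gamma-variate arterial input shape ``A * t^alpha * exp(-beta t)``,
    normalised to unit maximum before scaling by ``amplitude``."""
    alpha, beta = sharpness
    shape = np.power(t, alpha) * np.exp(-beta * t)
    peak = np.power(alpha / beta, alpha) * np.exp(-alpha)
    return amplitude * shape / peak


def _conv_exp(signal: np.ndarray, rate: float, t: np.ndarray) -> np.ndarray:
    """Convolution of a fine-grid signal with exp(-rate*t), via FFT."""
    kernel = np.exp(-rate * t)
    return fftconvolve(signal, kernel)[: len(t)] * FINE_DT

def _reference_fine(t: np.ndarray, k1_ref: float, k2_ref: float,
                    sharpness=DEFAULT_INPUT_SHARPNESS) -> np.ndarray:
    """One-compartment reference tissue: K1 * input (x) exp(-k2_ref t)."""
    return k1_ref * _conv_exp(_input_fine(t, sharpness), k2_ref, t)


def _target_fine(c_ref: np.ndarray, t: np.ndarray, spec: KineticSpec) -> np.ndarray:
    # one-tissue reference-tissue solution: the target's own efflux is
    # k2 = R1 * k2_ref (shared non-displaceable volume), apparent washout
    # k2a = k2 / (1 + BP_ND); specific binding slows washout while the
    # relative delivery R1 cancels between deposit and clearance
    k2 = spec.r1_true * spec.k2_ref
    k2a = k2 / (1.0 + spec.bpnd_true)
    coeff = spec.r1_true * (spec.k2_ref - k2a)
    out = spec.r1_true * c_ref
    if coeff != 0.0:
        out = out + coeff * _conv_exp(c_ref, k2a, t)
    return out


def _frame_average(fine: np.ndarray, t: np.ndarray,
                   schedule: FrameSchedule) -> np.ndarray:
    """Average the fine-grid curve over each frame's duration."""
    out = np.empty(len(schedule))
    for i, (s, e) in enumerate(zip(schedule.start_times, schedule.end_times)):
        sel = (t >= s - 1e-12) & (t < e - 1e-12)
        out[i] = fine[sel].mean()
    return out


# ---------------------------------------------------------------------------
# public simulation operations
# ---------------------------------------------------------------------------

def simulate_input_function(sharpness_params=DEFAULT_INPUT_SHARPNESS,
                            schedule: FrameSchedule | None = None,
                            amplitude: float = 1.0) -> TimeActivityCurve:
    """Arterial input function sampled on the frame schedule.

    The gamma-variate form peaks before 2 min and has cleared to under 5%
    of its maximum by 10 min, reproducing the rapid circulatory clearance
    that makes washout-only quantification possible.
    """
    schedule = schedule or default_schedule()
    t = _fine_grid(schedule)
    fine = _input_fine(t, sharpness_params, amplitude)
    return TimeActivityCurve(schedule, _frame_average(fine, t, schedule), source="input")


def simulate_reference(schedule: FrameSchedule | None = None,
                       k1_ref: float = DEFAULT_K1_REF,
                       k2_ref: float = DEFAULT_K2_REF,
                       sharpness=DEFAULT_INPUT_SHARPNESS) -> TimeActivityCurve:
    """Noiseless reference-region (cerebellum grey) TAC: one-compartment
    uptake of the arterial input, peaking a few minutes after injection."""
    schedule = schedule or default_schedule()
    t = _fine_grid(schedule)
    fine = _reference_fine(t, k1_ref, k2_ref, sharpness)
    return TimeActivityCurve(schedule, _frame_average(fine, t, schedule), source="CERB")


def simulate_tac(spec: KineticSpec, reference: TimeActivityCurve | None = None,
                 schedule: FrameSchedule | None = None,
                 seed: int | None = None) -> TimeActivityCurve:
    """Target-tissue TAC for the given kinetics.

    The deterministic part follows the simplified reference-tissue relation
    (module docstring); ``noise_cv > 0`` adds seeded multiplicative
    Gaussian noise per frame. The convolution runs on the fine internal
    grid of the reference curve, so ``reference`` defaults to the noiseless
    simulated reference with the spec's ``k2_ref``.
    """
    schedule = schedule or (reference.schedule if reference is not None
                            else default_schedule())
    t = _fine_grid(schedule)
    fine_ref = _reference_fine(t, DEFAULT_K1_REF, spec.k2_ref, spec.input_sharpness)
    if reference is not None:
        # rescale the template so its frame averages match the supplied
        # reference amplitude (allows per-subject flow scaling)
        template = _frame_average(fine_ref, t, schedule)
        scale = float(np.max(reference.activity) / np.max(template))
        fine_ref = fine_ref * scale
    fine_target = _target_fine(fine_ref, t, spec)
    activity = _frame_average(fine_target, t, schedule)
    tac = TimeActivityCurve(schedule, activity, source="target")
    if spec.noise_cv > 0:
        rng = np.random.default_rng(seed)
        tac = apply_frame_noise(tac, spec.noise_cv, rng)
    return tac


C11_DECAY = np.log(2.0) / 20.385  # 1/min; physical decay of carbon-11


def apply_frame_noise(tac: TimeActivityCurve, noise_cv: float,
                      rng: np.random.Generator,
                      count_scaled: bool = True) -> TimeActivityCurve:
    """Multiplicative Gaussian frame noise.

    With ``count_scaled=True`` (default) a frame's relative noise scales
    with the inverse square root of its expected true counts — activity
    times frame duration times the physical decay of the carbon-11 label
    (activities are decay-corrected, the recorded counts are not).
    ``noise_cv`` is then the CV of the best-counted frame, so late 6-10 min
    frames are noisier than the peak frames by a factor of a few, as in
    real dynamic acquisitions. ``count_scaled=False`` applies a constant CV
    to every frame — a cruder model useful for isolating estimator
    behaviour from the noise profile.
    """
    if count_scaled:
        counts = (np.maximum(tac.activity, 1e-12) * tac.schedule.durations
                  * np.exp(-C11_DECAY * tac.mid_times))
        cv = noise_cv * np.sqrt(counts.max() / counts)
    else:
        cv = np.full(len(tac.activity), noise_cv)
    noisy = tac.activity * (1.0 + cv * rng.standard_normal(len(tac.activity)))
    return TimeActivityCurve(tac.schedule, noisy, source=tac.source)


# ---------------------------------------------------------------------------
# cohorts and presets
# ---------------------------------------------------------------------------

def load_presets(path: str | Path | None = None) -> dict:
    """Load cohort preset definitions (group templates and default sizes)."""
    if path is None:
        text = resources.files("warmpet").joinpath("presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def cohort_from_preset(patient_group: str, seed: int = 0,
                       n_patients: int | None = None, n_hc: int | None = None,
                       noise_cv: float = 0.10,
                       presets: dict | None = None) -> CohortSpec:
    """Two-group study design: one patient group versus healthy controls."""
    presets = presets or load_presets()
    if patient_group not in presets["groups"]:
        raise FormatError(f"unknown preset group {patient_group!r} "
                          f"(known: {sorted(presets['groups'])})")
    groups = {patient_group: presets["groups"][patient_group],
              "HC": presets["groups"]["HC"]}
    n_per_group = {
        patient_group: n_patients or presets["default_n"][patient_group],
        "HC": n_hc or presets["default_n"]["HC"],
    }
    return CohortSpec(groups=groups, n_per_group=n_per_group, seed=seed,
                      noise_cv=noise_cv)


#: Correlation of a subject's regional deviations around the group template.
#: Amyloid burden and global perfusion are subject-level traits: a heavy
#: binder is heavy in every cortical region, so regional draws share a
#: subject factor rather than being independent.
SUBJECT_TRAIT_CORRELATION = 0.7


def _draw_subject_kinetics(template: dict, rng: np.random.Generator,
                           corr: float = SUBJECT_TRAIT_CORRELATION) -> dict:
    """Draw per-region (r1, bpnd) for one subject from the group template."""
    g_bpnd = rng.standard_normal()
    g_r1 = rng.standard_normal()
    resid = np.sqrt(1.0 - corr ** 2)
    drawn = {}
    for region, p in template.items():
        z_b = corr * g_bpnd + resid * rng.standard_normal()
        z_r = corr * g_r1 + resid * rng.standard_normal()
        bpnd = max(0.0, p["bpnd_mean"] + p["bpnd_sd"] * z_b)
        r1 = max(0.1, p["r1_mean"] + p["r1_sd"] * z_r)
        drawn[region] = {"bpnd": bpnd, "r1": r1}
    return drawn


def simulate_cohort_tacs(cohort: CohortSpec,
                         schedule: FrameSchedule | None = None
                         ) -> tuple[dict, pd.DataFrame]:
    """Simulate per-subject, per-region TACs for a whole cohort.

    Returns ``(tacs, truth)``: ``tacs[(group, subject_id)][region]`` is a
    TimeActivityCurve; ``truth`` is a DataFrame with one row per
    subject x region recording the ground-truth parameters.

    The subject's reference realisation is the noiseless reference template
    scaled by the subject's cerebellar flow draw; target regions are
    simulated against that noiseless reference with their own (r1, bpnd)
    and then receive independent frame noise. R1 is therefore relative
    delivery with respect to the subject's own cerebellum, as in the
    regional quantification.
    """
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(cohort.seed)
    t = _fine_grid(schedule)
    fine_ref = _reference_fine(t, DEFAULT_K1_REF, cohort.k2_ref)

    tacs: dict = {}
    truth_rows = []
    for group in sorted(cohort.n_per_group):
        template = cohort.groups[group]
        for subj in range(cohort.n_per_group[group]):
            subject_id = f"{group}{subj:03d}"
            drawn = _draw_subject_kinetics(template, rng)
            cerb_flow = drawn[cohort.reference_region]["r1"]
            subj_fine_ref = cerb_flow * fine_ref
            per_region: dict[str, TimeActivityCurve] = {}
            for region, params in drawn.items():
                if region == cohort.reference_region:
                    spec = KineticSpec(r1_true=1.0, bpnd_true=params["bpnd"],
                                       k2_ref=cohort.k2_ref)
                else:
                    spec = KineticSpec(r1_true=params["r1"],
                                       bpnd_true=params["bpnd"],
                                       k2_ref=cohort.k2_ref)
                fine = _target_fine(subj_fine_ref, t, spec)
                activity = _frame_average(fine, t, schedule)
                tac = TimeActivityCurve(schedule, activity, source=region)
                if cohort.noise_cv > 0:
                    tac = apply_frame_noise(tac, cohort.noise_cv, rng)
                per_region[region] = tac
                truth_rows.append({
                    "subject_id": subject_id, "group": group, "region": region,
                    "bpnd_true": params["bpnd"],
                    "r1_true": 1.0 if region == cohort.reference_region
                    else params["r1"],
                    "cerb_flow": cerb_flow,
                    "k2_ref": cohort.k2_ref, "noise_cv": cohort.noise_cv,
                })
            tacs[(group, subject_id)] = per_region
    return tacs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# 4D phantoms
# ---------------------------------------------------------------------------

def _block_layout(grid_dims: tuple[int, int, int],
                  regions=STANDARD_REGIONS) -> RegionMask:
    """Six cuboid regions arranged in a 3 x 2 grid with background gaps."""
    nx, ny, nz = grid_dims
    if nx < 8 or ny < 8 or nz < 4:
        raise WarmPetError(f"grid {grid_dims} too small for 6 block regions "
                           "(need at least 8 x 8 x 4)")
    labels = np.zeros(grid_dims, dtype=np.int32)
    bx, by = (nx - 2) // 3, (ny - 1) // 2
    bz = max(1, nz - 2)
    for i, region in enumerate(regions):
        cx, cy = i % 3, i // 3
        x0 = 1 + cx * bx
        y0 = 1 + cy * by
        labels[x0:x0 + bx - 1, y0:y0 + by - 1, 1:1 + bz] = i + 1
    return RegionMask(labels, {i + 1: r for i, r in enumerate(regions)})


def build_phantom(cohort: CohortSpec, schedule: FrameSchedule | None = None,
                  grid_dims: tuple[int, int, int] = (16, 16, 16)
                  ) -> tuple[list[DynamicImage], RegionMask, pd.DataFrame]:
    """4D block phantoms for a simulated cohort.

    Returns one DynamicImage per subject (all sharing one RegionMask of six
    cuboid regions) and the ground-truth table. Each voxel of a region
    carries that subject/region's noiseless TAC with independent
    multiplicative frame noise, so region means converge on the noiseless
    curve while voxelwise maps see realistic scatter.
    """
    schedule = schedule or default_schedule()
    mask = _block_layout(grid_dims)
    for group, template in cohort.groups.items():
        missing = [r for r in template if r not in mask.region_names]
        if missing:
            raise WarmPetError(f"group {group!r} defines regions {missing} "
                               "absent from the phantom layout")
    rng = np.random.default_rng(cohort.seed)
    t = _fine_grid(schedule)
    fine_ref = _reference_fine(t, DEFAULT_K1_REF, cohort.k2_ref)

    images: list[DynamicImage] = []
    truth_rows = []
    n_frames = len(schedule)
    for group in sorted(cohort.n_per_group):
        template = cohort.groups[group]
        for subj in range(cohort.n_per_group[group]):
            subject_id = f"{group}{subj:03d}"
            drawn = _draw_subject_kinetics(template, rng)
            cerb_flow = drawn[cohort.reference_region]["r1"]
            subj_fine_ref = cerb_flow * fine_ref
            voxels = np.zeros(grid_dims + (n_frames,))
            for region, params in drawn.items():
                if region == cohort.reference_region:
                    spec = KineticSpec(r1_true=1.0, bpnd_true=params["bpnd"],
                                       k2_ref=cohort.k2_ref)
                else:
                    spec = KineticSpec(r1_true=params["r1"],
                                       bpnd_true=params["bpnd"],
                                       k2_ref=cohort.k2_ref)
                fine = _target_fine(subj_fine_ref, t, spec)
                activity = _frame_average(fine, t, schedule)
                idx = mask.indices(region)
                n_vox = int(np.count_nonzero(idx))
                if cohort.noise_cv > 0:
                    counts = (np.maximum(activity, 1e-12) * schedule.durations
                              * np.exp(-C11_DECAY * schedule.mid_times))
                    cv = cohort.noise_cv * np.sqrt(counts.max() / counts)
                    noise = 1.0 + cv[None, :] * rng.standard_normal(
                        (n_vox, n_frames))
                else:
                    noise = np.ones((n_vox, n_frames))
                voxels[idx] = activity[None, :] * noise
                truth_rows.append({
                    "subject_id": subject_id, "group": group, "region": region,
                    "bpnd_true": params["bpnd"],
                    "r1_true": 1.0 if region == cohort.reference_region
                    else params["r1"],
                    "cerb_flow": cerb_flow,
                    "k2_ref": cohort.k2_ref, "noise_cv": cohort.noise_cv,
                })
            images.append(DynamicImage(voxels, schedule))
    return images, mask, pd.DataFrame(truth_rows)
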