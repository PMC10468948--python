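"""Ground-truthed synthetic cohort and raw-measurement simulators.

The generator emulates the structure of a 110-patient liver-biopsy cohort:
NASH-CRN steatosis grades 0–3 and fibrosis stages F0–F4 drawn with the
study's demographic proportions, a fibrosis-dependent elevation of free
tissue water that drives the observed T1 upward with stage, and — per
patient — the three raw measurement modalities the analysis consumes:

* a multi-echo MRS peak-area series (TE = 30/40/60/80 ms) decaying
  mono-exponentially with additive Gaussian area noise;
* a 10-point magnitude inversion-recovery series with Rician noise;
* a grayscale biopsy image with planted white fat vacuoles at a known
  area fraction.

Every latent quantity (fat-to-water mass ratio, tissue compartments, T1,
T2s, vacuole area fraction) is stored on the record, so noise-free forward
simulation followed by the inverse analysis stages must reproduce the truth
exactly — that round trip is the package's principal self-check.

The fibrosis→water mapping keeps the bound-water compartment fixed and
moves free water against non-water tissue; in the change-partition language
of the correction model this is the k = 1 scenario, under which the
T1-based correction is exact in the noise-free limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ModelConstants
from .dia import area_to_volume_fraction, volume_to_mass_fraction
from .water_model import (TissueState, mass_ratio_from_tmff, observed_t1,
                          pdff_from_mass_ratio, signal_ratio_factor,
                          tmff_from_mass_ratio)

__all__ = ["CohortConfig", "PatientRecord", "EchoSeries", "InversionSeries",
           "BiopsyImage", "generate_cohort", "simulate_echo_series",
           "simulate_ir_series", "render_biopsy_image", "cohort_to_frame",
           "DEFAULT_TE_MS", "DEFAULT_TI_MS"]

#: Echo times of the multi-echo MRS protocol, ms.
DEFAULT_TE_MS = (30.0, 40.0, 60.0, 80.0)
#: Inversion times of the IR protocol, ms (10 points spanning the null).
DEFAULT_TI_MS = (100.0, 200.0, 400.0, 700.0, 1000.0, 1400.0, 1900.0,
                 2600.0, 3600.0, 5000.0)

#: Study cohort composition (counts out of 110).
STAGE_COUNTS = (24, 30, 24, 21, 12)      # fibrosis F0..F4
GRADE_COUNTS = (27, 44, 19, 20)          # steatosis S0..S3
INFLAMMATION_COUNTS = (66, 24, 20)       # none/mild, moderate, severe
INFLAMMATION_LEVELS = ("none/mild", "moderate", "severe")

#: Pathologist's visual-assessment bands per CRN steatosis grade (percent).
GRADE_VA_BANDS = ((0.0, 5.0), (5.0, 33.0), (33.0, 66.0), (66.0, 90.0))


def _normalize(counts) -> tuple[float, ...]:
    total = float(sum(counts))
    return tuple(c / total for c in counts)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults encode the emulated study conditions.

    ``water_elevation_per_stage`` adds to the healthy free-water fraction by
    fibrosis stage: flat through F0–F2 and rising at F3/F4, mirroring the
    near-constant then elevated T1 trend across stages.
    ``va_to_area_scale`` maps the pathologist's percent-of-hepatocytes
    estimate to a true vacuole area fraction (visual assessment reads
    several-fold higher than morphometry; the regression slope between the
    two is about 1/4).
    """

    n_patients: int = 110
    stage_proportions: tuple[float, ...] = _normalize(STAGE_COUNTS)
    grade_proportions: tuple[float, ...] = _normalize(GRADE_COUNTS)
    inflammation_proportions: tuple[float, ...] = _normalize(
        INFLAMMATION_COUNTS)
    water_elevation_per_stage: tuple[float, ...] = (0.0, 0.0, 0.0, 0.03, 0.06)
    water_noise_sd: float = 0.01
    va_to_area_scale: float = 0.25
    t2_water_mean_ms: float = 46.0
    t2_water_sd_ms: float = 4.0
    t2_fat_mean_ms: float = 68.0
    t2_fat_sd_ms: float = 6.0
    mrs_area_noise_sd: float = 2.0      # area units; reference water area 100
    ir_noise_sd: float = 25.0           # signal units; amplitude a = 1000
    image_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        for name in ("stage_proportions", "grade_proportions",
                     "inflammation_proportions"):
            p = getattr(self, name)
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if len(self.stage_proportions) != 5:
            raise ValueError("need proportions for fibrosis stages 0-4")
        if len(self.grade_proportions) != 4:
            raise ValueError("need proportions for steatosis grades 0-3")
        if len(self.water_elevation_per_stage) != 5:
            raise ValueError("need a water increment per fibrosis stage 0-4")


@dataclass(frozen=True)
class EchoSeries:
    """Per-TE fat and water peak areas from one voxel."""

    te_ms: tuple[float, ...]
    fat_area: tuple[float, ...]
    water_area: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.te_ms) == len(self.fat_area) == len(self.water_area)):
            raise ValueError("te_ms, fat_area, water_area lengths differ")
        if any(b <= a for a, b in zip(self.te_ms, self.te_ms[1:])):
            raise ValueError("te_ms must be strictly increasing")
        if any(v < 0 for v in self.fat_area + self.water_area):
            raise ValueError("areas must be >= 0")


@dataclass(frozen=True)
class InversionSeries:
    """Magnitude signal at each inversion time."""

    ti_ms: tuple[float, ...]
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ti_ms) != len(self.signal):
            raise ValueError("ti_ms and signal lengths differ")
        if any(b <= a for a, b in zip(self.ti_ms, self.ti_ms[1:])):
            raise ValueError("ti_ms must be strictly increasing")
        if any(v < 0 for v in self.signal):
            raise ValueError("magnitude signal must be >= 0")


@dataclass(frozen=True)
class BiopsyImage:
    """Rendered grayscale biopsy with pixel-level ground truth."""

    pixels: np.ndarray
    ground_truth_area_fraction: float
    fragment_masks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if np.any((self.pixels < 0) | (self.pixels > 1)):
            raise ValueError("pixel values must be in [0, 1]")
        if not 0.0 <= self.ground_truth_area_fraction <= 1.0:
            raise ValueError("ground_truth_area_fraction outside [0, 1]")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic subject with complete latent ground truth."""

    patient_id: int
    fibrosis_stage: int
    steatosis_grade: int
    inflammation_level: str
    va_percent: float
    true_area_fraction: float
    true_mass_ratio: float
    tissue_state: TissueState
    true_T1_ms: float
    true_T2_fat_ms: float
    true_T2_water_ms: float
    true_pdff: float
    true_tmff: float

    def __post_init__(self) -> None:
        if not 0 <= self.fibrosis_stage <= 4:
            raise ValueError("fibrosis_stage must be 0-4")
        if not 0 <= self.steatosis_grade <= 3:
            raise ValueError("steatosis_grade must be 0-3")
        if self.true_mass_ratio < 0:
            raise ValueError("true_mass_ratio must be >= 0")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig,
                    constants: ModelConstants | None = None,
                    ) -> list[PatientRecord]:
    """Draw a fully ground-truthed cohort; deterministic for a fixed seed.

    Per patient: fibrosis stage, steatosis grade and inflammation level are
    sampled from the configured proportions; the free-water tissue fraction
    is the healthy value plus the stage increment plus individual noise
    (clipped to keep the compartments a valid partition); the observed T1
    follows from the fast-exchange forward model; the visual-assessment
    percentage is drawn within the CRN band of the grade and scaled to a
    vacuole area fraction, from which the fat-to-water mass ratio is derived
    through the morphometry conversion chain evaluated at the patient's own
    tissue water.
    """
    constants = constants or ModelConstants()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    for pid in range(config.n_patients):
        stage = int(rng.choice(5, p=config.stage_proportions))
        grade = int(rng.choice(4, p=config.grade_proportions))
        inflammation = INFLAMMATION_LEVELS[int(
            rng.choice(3, p=config.inflammation_proportions))]

        l_b = constants.L_B_healthy
        l_w = (constants.L_W_healthy
               + config.water_elevation_per_stage[stage]
               + rng.normal(0.0, config.water_noise_sd))
        l_w = float(np.clip(l_w, 0.0, 1.0 - l_b))
        tissue = TissueState(L_W=l_w, L_B=l_b, L_N=1.0 - l_w - l_b)
        t1 = observed_t1(tissue.W_F, constants)

        lo, hi = GRADE_VA_BANDS[grade]
        va = float(rng.uniform(lo, hi))
        area = va / 100.0 * config.va_to_area_scale
        vol = area_to_volume_fraction(area, constants.area_to_volume_factor)
        tmff_true = volume_to_mass_fraction(vol, constants)
        r_m = (0.0 if tmff_true == 0.0
               else mass_ratio_from_tmff(tmff_true, l_w))
        pdff_true = pdff_from_mass_ratio(r_m, constants)

        t2_w = float(max(rng.normal(config.t2_water_mean_ms,
                                    config.t2_water_sd_ms), 10.0))
        t2_f = float(max(rng.normal(config.t2_fat_mean_ms,
                                    config.t2_fat_sd_ms), 10.0))
        records.append(PatientRecord(
            patient_id=pid, fibrosis_stage=stage, steatosis_grade=grade,
            inflammation_level=inflammation, va_percent=va,
            true_area_fraction=area, true_mass_ratio=r_m,
            tissue_state=tissue, true_T1_ms=float(t1),
            true_T2_fat_ms=t2_f, true_T2_water_ms=t2_w,
            true_pdff=float(pdff_true),
            true_tmff=float(tmff_from_mass_ratio(r_m, l_w))))
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten the cohort ground truth into one row per patient."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "fibrosis_stage": r.fibrosis_stage,
            "steatosis_grade": r.steatosis_grade,
            "inflammation_level": r.inflammation_level,
            "va_percent": r.va_percent,
            "true_area_fraction": r.true_area_fraction,
            "true_mass_ratio": r.true_mass_ratio,
            "L_W": r.tissue_state.L_W,
            "L_B": r.tissue_state.L_B,
            "L_N": r.tissue_state.L_N,
            "true_T1_ms": r.true_T1_ms,
            "true_T2_fat_ms": r.true_T2_fat_ms,
            "true_T2_water_ms": r.true_T2_water_ms,
            "true_pdff": r.true_pdff,
            "true_tmff": r.true_tmff,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Raw-measurement simulators
# ---------------------------------------------------------------------------

def simulate_echo_series(patient: PatientRecord,
                         constants: ModelConstants | None = None,
                         noise_sd: float = 0.0, seed: int = 0,
                         te_ms=DEFAULT_TE_MS,
                         reference_water_area: float = 100.0) -> EchoSeries:
    """Forward-simulate the multi-echo fat/water peak-area series.

    The water amplitude is normalised so the noiseless water area at the
    shortest TE equals ``reference_water_area``; the fat-to-water TE=0
    amplitude ratio is the signal ratio implied by the patient's true mass
    ratio.  Gaussian noise of standard deviation ``noise_sd`` (area units)
    is added independently per point, with negative draws clipped to zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    constants = constants or ModelConstants()
    te = np.asarray(te_ms, dtype=float)
    a_w = reference_water_area * math.exp(te[0] / patient.true_T2_water_ms)
    r_s = signal_ratio_factor(constants) * patient.true_mass_ratio
    a_f = r_s * a_w
    water = a_w * np.exp(-te / patient.true_T2_water_ms)
    fat = a_f * np.exp(-te / patient.true_T2_fat_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        water = water + rng.normal(0.0, noise_sd, te.size)
        fat = fat + rng.normal(0.0, noise_sd, te.size)
    water = np.clip(water, 0.0, None)
    fat = np.clip(fat, 0.0, None)
    return EchoSeries(te_ms=tuple(te), fat_area=tuple(fat),
                      water_area=tuple(water))


def simulate_ir_series(patient: PatientRecord, ti_ms=DEFAULT_TI_MS,
                       noise_sd: float = 0.0, seed: int = 0,
                       amplitude: float = 1000.0,
                       inversion_factor: float = 2.0) -> InversionSeries:
    """Forward-simulate the magnitude inversion-recovery series.

    Noiseless model ``|a (1 − b exp(−TI/T1))|`` with the patient's true T1;
    noise is Rician (magnitude of the complex signal plus i.i.d. Gaussian
    noise on both channels), the appropriate model for magnitude MR data.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ti = np.asarray(ti_ms, dtype=float)
    if ti.size < 2 or np.any(np.diff(ti) <= 0):
        raise ValueError("ti_ms must be strictly increasing")
    ideal = amplitude * (1.0 - inversion_factor * np.exp(
        -ti / patient.true_T1_ms))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        real = ideal + rng.normal(0.0, noise_sd, ti.size)
        imag = rng.normal(0.0, noise_sd, ti.size)
        mag = np.hypot(real, imag)
    else:
        mag = np.abs(ideal)
    return InversionSeries(ti_ms=tuple(ti), signal=tuple(mag))


# ---------------------------------------------------------------------------
# Biopsy image rendering
# ---------------------------------------------------------------------------

_BACKGROUND_LEVEL = 0.05
_TISSUE_LEVEL = 0.45
_VACUOLE_LEVEL = 0.97
_VACUOLE_RADIUS_PX = (2.0, 12.0)        # log-uniform draw range
_PLACEMENT_TOLERANCE = 0.005            # 0.5 percentage points


def render_biopsy_image(patient: PatientRecord | None = None,
                        width: int = 512, height: int = 512,
                        target_area_fraction: float | None = None,
                        n_fragments: int = 1, seed: int = 0) -> BiopsyImage:
    """Render a synthetic biopsy: elliptical tissue fragments with planted
    non-overlapping bright circular vacuoles at a known area fraction.

    Vacuoles are added until the white-pixel share of the biopsy mask is
    within 0.5 percentage points of the target (the patient's true vacuole
    area fraction when a record is given); the achieved share is stored as
    ground truth.  Raises ``ValueError`` when the target cannot be reached
    without overlap at the requested canvas size.
    """
    if target_area_fraction is None:
        if patient is None:
            raise ValueError("need a patient record or an explicit target")
        target_area_fraction = patient.true_area_fraction
    if not 0.0 <= target_area_fraction <= 0.6:
        raise ValueError("target_area_fraction must be in [0, 0.6]")
    if width * height < 10_000:
        raise ValueError("canvas must have at least 10^4 pixels")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")

    rng = np.random.default_rng(seed)
    img = np.full((height, width), _BACKGROUND_LEVEL, dtype=float)
    yy, xx = np.mgrid[0:height, 0:width]
    masks: list[np.ndarray] = []
    # fragments tiled along x so they never merge
    slot_w = width / n_fragments
    for i in range(n_fragments):
        cx = slot_w * (i + 0.5)
        cy = height / 2.0
        ax = 0.42 * slot_w
        ay = 0.42 * height
        mask = (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2) <= 1.0
        masks.append(mask)
        img[mask] = _TISSUE_LEVEL
    union = np.zeros_like(img, dtype=bool)
    for m in masks:
        union |= m
    biopsy_px = int(union.sum())

    occupied = np.zeros_like(union)     # planted vacuoles
    white_px = 0
    target_px = target_area_fraction * biopsy_px
    attempts = 0
    max_attempts = 20_000
    r_lo, r_hi = _VACUOLE_RADIUS_PX
    while target_px - white_px > _PLACEMENT_TOLERANCE * biopsy_px:
        if attempts > max_attempts:
            raise ValueError(
                "could not reach target vacuole fraction without overlap; "
                "try a larger canvas or fewer fragments")
        attempts += 1
        # keep single-vacuole overshoot below the tolerance band
        budget_px = target_px - white_px + _PLACEMENT_TOLERANCE * biopsy_px
        r_cap = min(r_hi, math.sqrt(budget_px / math.pi))
        if r_cap < r_lo:
            break
        r = math.exp(rng.uniform(math.log(r_lo), math.log(r_cap)))
        cx = rng.uniform(r, width - r)
        cy = rng.uniform(r, height - r)
        # work inside the disk's bounding box only
        x0, x1 = max(int(cx - r), 0), min(int(math.ceil(cx + r)) + 1, width)
        y0, y1 = max(int(cy - r), 0), min(int(math.ceil(cy + r)) + 1, height)
        ly, lx = np.mgrid[y0:y1, x0:x1]
        disk = (lx - cx) ** 2 + (ly - cy) ** 2 <= r ** 2
        if not disk.any():
            continue
        box = (slice(y0, y1), slice(x0, x1))
        if np.any(disk & ~union[box]) or np.any(disk & occupied[box]):
            continue
        occupied[box] |= disk
        img[box][disk] = _VACUOLE_LEVEL
        white_px += int(disk.sum())
    achieved = white_px / biopsy_px
    if abs(achieved - target_area_fraction) > _PLACEMENT_TOLERANCE:
        raise ValueError(
            "could not reach target vacuole fraction without overlap; "
            "try a larger canvas or fewer fragments")
    return BiopsyImage(pixels=img, ground_truth_area_fraction=achieved,
                       fragment_masks=tuple(masks))
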