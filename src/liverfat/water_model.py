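"""Biophysical fat/water signal model and T1-based tissue-water correction.

This is the analytic core of the package.  It links three quantities:

* **PDFF** — proton density fat fraction, the fat share of the MR-visible
  signal, ``S_F / (S_F + S_W)``;
* **TMFF** — tissue mass fat fraction, the histological endpoint,
  ``R_M L_W / (R_M L_W + 1)`` where ``R_M`` is the fat-to-water mass ratio
  and ``L_W`` the free-water tissue fraction;
* **T1** — the observed fat-suppressed longitudinal relaxation time, which
  under fast exchange between free and bound water pools encodes the free
  water fraction ``W_F``:  ``1/T1_obs = W_F/T1_free + (1-W_F)/T1_bound``.

The signal ratio and mass ratio are proportional, ``R_s = f · R_M`` with
``f = (rho_F D_W)/(rho_W D_F) ≈ 0.70``, so PDFF and TMFF are connected by
closed-form, mutually inverse maps.  At the healthy tissue water fraction
``L_W = 0.711`` the composite map is nearly the identity (PDFF ≈ TMFF); as
tissue water rises — as it does in fibrosis — PDFF progressively
underestimates TMFF.

For non-healthy tissue, the free-water tissue fraction is recovered from the
measured ``W_F`` via a three-compartment bookkeeping model parameterised by
``k``, the proportion of free-water change drawn from the non-water
compartment (``k = 0``: entirely from bound water; ``k = 1``: entirely from
non-water tissue):

    L_W_dagger = W_F_dagger (L_B + L_W - k L_W) / (1 - k W_F_dagger)

All fractions are dimensionless on [0, 1]; reporting in percent is the
caller's concern.  Scalar or ndarray inputs are accepted throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ModelConstants

__all__ = [
    "TissueState", "FatFractionPair",
    "signal_ratio_factor",
    "pdff_from_mass_ratio", "mass_ratio_from_pdff",
    "tmff_from_mass_ratio", "mass_ratio_from_tmff",
    "pdff_to_tmff", "tmff_to_pdff",
    "free_water_fraction_from_t1", "observed_t1",
    "tissue_water_nonhealthy", "tmff_mr",
    "model_curves",
]

DEFAULT_K_SWEEP = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

_FRAC_ATOL = 1e-9


@dataclass(frozen=True)
class TissueState:
    """Three-compartment tissue composition of one voxel.

    ``L_W`` (free water), ``L_B`` (bound water) and ``L_N`` (non-water
    tissue) partition the voxel; ``W_F = L_W/(L_W+L_B)`` is the free share of
    the water itself, the quantity T1 is sensitive to.  Fat and water masses
    ``M_F``, ``M_W`` are carried in arbitrary units — only their ratio
    ``R_M`` enters any observable.
    """

    L_W: float
    L_B: float
    L_N: float
    M_F: float = 0.0
    M_W: float = 1.0

    def __post_init__(self) -> None:
        for name in ("L_W", "L_B", "L_N"):
            v = getattr(self, name)
            if not -_FRAC_ATOL <= v <= 1.0 + _FRAC_ATOL:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.L_W + self.L_B + self.L_N
        if abs(total - 1.0) > _FRAC_ATOL:
            raise ValueError(f"compartments sum to {total}, expected 1")
        if self.M_F < 0 or self.M_W < 0:
            raise ValueError("masses must be non-negative")

    @property
    def W_F(self) -> float:
        """Free fraction of the water-containing tissue."""
        return self.L_W / (self.L_W + self.L_B)

    @property
    def W_B(self) -> float:
        return 1.0 - self.W_F

    @property
    def R_M(self) -> float:
        """Fat-to-water mass ratio."""
        return self.M_F / self.M_W


@dataclass(frozen=True)
class FatFractionPair:
    """A consistent (PDFF, TMFF, R_M, R_s) tuple for one tissue state."""

    pdff: float
    tmff: float
    R_M: float
    R_s: float

    def __post_init__(self) -> None:
        for name in ("pdff", "tmff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.R_M < 0 or self.R_s < 0:
            raise ValueError("signal/mass ratios must be non-negative")


# ---------------------------------------------------------------------------
# Signal model: mass ratio <-> signal ratio <-> PDFF
# ---------------------------------------------------------------------------

def signal_ratio_factor(constants: ModelConstants) -> float:
    """Proportionality between signal ratio and mass ratio, R_s = f · R_M.

    With the standard proton and mass densities this is
    (70.35 · 1.0)/(111.11 · 0.9) ≈ 0.7035, conventionally rounded to 0.7.
    """
    return (constants.rho_F * constants.D_W) / (constants.rho_W * constants.D_F)


def pdff_from_mass_ratio(R_M, constants: ModelConstants):
    """PDFF implied by a fat-to-water mass ratio: f·R_M / (f·R_M + 1)."""
    R_M = np.asarray(R_M, dtype=float)
    if np.any(R_M < 0):
        raise ValueError("R_M must be >= 0")
    R_s = signal_ratio_factor(constants) * R_M
    return _maybe_scalar(R_s / (R_s + 1.0))


def mass_ratio_from_pdff(pdff, constants: ModelConstants):
    """Exact inverse of :func:`pdff_from_mass_ratio` (undefined at PDFF=1)."""
    pdff = np.asarray(pdff, dtype=float)
    if np.any((pdff < 0) | (pdff > 1)):
        raise ValueError("pdff must be in [0, 1]")
    if np.any(pdff >= 1.0):
        raise ValueError("pdff = 1 has no finite mass ratio")
    f = signal_ratio_factor(constants)
    return _maybe_scalar(pdff / (f * (1.0 - pdff)))


def tmff_from_mass_ratio(R_M, L_W):
    """Tissue mass fat fraction: R_M·L_W / (R_M·L_W + 1)."""
    R_M = np.asarray(R_M, dtype=float)
    L_W = np.asarray(L_W, dtype=float)
    if np.any(R_M < 0):
        raise ValueError("R_M must be >= 0")
    if np.any((L_W <= 0) | (L_W > 1)):
        raise ValueError("L_W must be in (0, 1]")
    x = R_M * L_W
    return _maybe_scalar(x / (x + 1.0))


def mass_ratio_from_tmff(tmff, L_W):
    """Exact inverse of :func:`tmff_from_mass_ratio`: TMFF / (L_W·(1−TMFF))."""
    tmff = np.asarray(tmff, dtype=float)
    L_W = np.asarray(L_W, dtype=float)
    if np.any((tmff < 0) | (tmff > 1)):
        raise ValueError("tmff must be in [0, 1]")
    if np.any(tmff >= 1.0):
        raise ValueError("tmff = 1 has no finite mass ratio")
    if np.any((L_W <= 0) | (L_W > 1)):
        raise ValueError("L_W must be in (0, 1]")
    return _maybe_scalar(tmff / (L_W * (1.0 - tmff)))


def pdff_to_tmff(pdff, L_W, constants: ModelConstants):
    """Convert PDFF to TMFF at tissue water fraction ``L_W``.

    Composition of the two closed forms; at L_W = 0.711 this map is within
    one percentage point of the identity over the physiological range.
    """
    return tmff_from_mass_ratio(mass_ratio_from_pdff(pdff, constants), L_W)


def tmff_to_pdff(tmff, L_W, constants: ModelConstants):
    """Inverse of :func:`pdff_to_tmff`: the PDFF the scanner would report."""
    return pdff_from_mass_ratio(mass_ratio_from_tmff(tmff, L_W), constants)


# ---------------------------------------------------------------------------
# Fast-exchange two-pool T1 model
# ---------------------------------------------------------------------------

def free_water_fraction_from_t1(T1_obs_ms, constants: ModelConstants,
                                clip: bool = True):
    """Free water fraction W_F from the observed fat-suppressed T1.

    Linear solve of the fast-exchange relaxation-rate mixture:
    ``W_F = (1/T1_obs − 1/T1_bound) / (1/T1_free − 1/T1_bound)``.
    Observed T1 outside (T1_bound, T1_free) yields W_F outside [0, 1]; such
    values are clipped with a warning (noisy fits can overshoot the pool
    T1 bounds) unless ``clip=False``.
    """
    T1_obs = np.asarray(T1_obs_ms, dtype=float)
    if np.any(T1_obs <= 0):
        raise ValueError("T1_obs_ms must be > 0")
    r_free = 1.0 / constants.T1_free
    r_bound = 1.0 / constants.T1_bound
    if r_free == r_bound:
        raise ValueError("T1_free = T1_bound: two-pool model is degenerate")
    w = (1.0 / T1_obs - r_bound) / (r_free - r_bound)
    if clip and np.any((w < 0) | (w > 1)):
        warnings.warn("W_F outside [0, 1] clipped (T1 outside pool bounds)",
                      stacklevel=2)
        w = np.clip(w, 0.0, 1.0)
    return _maybe_scalar(w)


def observed_t1(W_F, constants: ModelConstants):
    """Forward companion: observed T1 for a given free water fraction."""
    W_F = np.asarray(W_F, dtype=float)
    if np.any((W_F < 0) | (W_F > 1)):
        raise ValueError("W_F must be in [0, 1]")
    rate = W_F / constants.T1_free + (1.0 - W_F) / constants.T1_bound
    return _maybe_scalar(1.0 / rate)


# ---------------------------------------------------------------------------
# Three-compartment non-healthy tissue water estimate
# ---------------------------------------------------------------------------

def tissue_water_nonhealthy(W_F_dagger, constants: ModelConstants,
                            k: float | None = None, clip: bool = True):
    """Free-water tissue fraction of non-healthy liver from measured W_F.

    Evaluates ``W_F† (L_B + L_W − k L_W) / (1 − k W_F†)`` with the healthy
    compartments (L_W, L_B) and the change-partition constant ``k`` taken
    from ``constants`` unless overridden.  For the healthy free-water
    fraction W_F = L_W/(L_W+L_B) the expression returns L_W identically for
    every k.  Results above 1 (possible at high k and W_F) are clipped with a
    warning.
    """
    W_F_dagger = np.asarray(W_F_dagger, dtype=float)
    if np.any((W_F_dagger < 0) | (W_F_dagger > 1)):
        raise ValueError("W_F_dagger must be in [0, 1]")
    k_val = constants.k if k is None else float(k)
    if not 0.0 <= k_val <= 1.0:
        raise ValueError("k must be in [0, 1]")
    denom = 1.0 - k_val * W_F_dagger
    if np.any(denom <= 0):
        raise ValueError("1 - k*W_F_dagger must be > 0")
    L_W, L_B = constants.L_W_healthy, constants.L_B_healthy
    lw = W_F_dagger * (L_B + L_W - k_val * L_W) / denom
    if clip and np.any(lw > 1.0):
        warnings.warn("L_W_dagger > 1 clipped to 1", stacklevel=2)
        lw = np.clip(lw, 0.0, 1.0)
    return _maybe_scalar(lw)


def tmff_mr(pdff, T1_obs_ms, constants: ModelConstants,
            k_values=DEFAULT_K_SWEEP) -> dict[float, float]:
    """MR-derived tissue mass fat fraction, corrected for tissue water.

    Chains the three stages — T1 → W_F† (fast exchange), W_F† → L_W†
    (compartment bookkeeping at each k), then PDFF → TMFF at the
    patient-specific L_W† — returning ``{k: TMFF_MR}`` over the requested
    sweep.  At the healthy T1 the result is independent of k.
    """
    w_f = free_water_fraction_from_t1(T1_obs_ms, constants)
    out: dict[float, float] = {}
    for k in k_values:
        lw = tissue_water_nonhealthy(w_f, constants, k=k)
        lw = max(float(np.asarray(lw)), 1e-12)  # guard degenerate W_F = 0
        out[float(k)] = float(pdff_to_tmff(pdff, lw, constants))
    return out


# ---------------------------------------------------------------------------
# Model curves (PDFF-vs-TMFF family; L_W-vs-T1 family)
# ---------------------------------------------------------------------------

def model_curves(constants: ModelConstants,
                 tmff_grid=None, lw_values=(0.6, 0.7, 0.711, 0.8, 0.9, 1.0),
                 t1_grid_ms=None, k_values=DEFAULT_K_SWEEP,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate the two model-curve families for plotting.

    Returns ``(pdff_vs_tmff, lw_vs_t1)``: the scanner-reported PDFF as a
    function of true TMFF for a range of tissue water contents, and the
    inferred free-water tissue fraction as a function of observed T1 for the
    k sweep (curves converge at the healthy point).
    """
    if tmff_grid is None:
        tmff_grid = np.linspace(0.0, 0.5, 101)
    tmff_grid = np.asarray(tmff_grid, dtype=float)
    rows = {"tmff": tmff_grid}
    for lw in lw_values:
        rows[f"pdff_Lw_{lw:g}"] = np.asarray(
            tmff_to_pdff(tmff_grid, lw, constants))
    curve_a = pd.DataFrame(rows)

    if t1_grid_ms is None:
        healthy_t1 = observed_t1(
            constants.L_W_healthy /
            (constants.L_W_healthy + constants.L_B_healthy), constants)
        t1_grid_ms = np.linspace(0.8 * healthy_t1, 1.4 * healthy_t1, 101)
    t1_grid_ms = np.asarray(t1_grid_ms, dtype=float)
    w_f = np.asarray(free_water_fraction_from_t1(t1_grid_ms, constants))
    rows_b = {"t1_ms": t1_grid_ms, "W_F": w_f}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping expected at grid edges
        for k in k_values:
            rows_b[f"Lw_k_{k:g}"] = np.asarray(
                tissue_water_nonhealthy(w_f, constants, k=k))
    curve_b = pd.DataFrame(rows_b)
    return curve_a, curve_b


def _maybe_scalar(x: np.ndarray):
    return float(x) if np.ndim(x) == 0 else x
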