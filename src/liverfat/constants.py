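"""Physical constants for the fat/water signal and tissue-water models.

Every literature constant used downstream lives in :class:`ModelConstants`,
so that the signal model, the water-compartment model and the histology
conversion all draw from a single validated source.

Units follow the conventions of quantitative liver MR: proton densities in
mmol/l, mass densities in g/ml, relaxation times in ms, tissue fractions
dimensionless on [0, 1].

Two longitudinal relaxation constants (``T1_free``, ``T1_bound``) and the
healthy bound-water fraction (``L_B_healthy``) have no authoritative
published value bundled here; the shipped defaults are order-of-magnitude
placeholders (free water relaxes over seconds, bound water over a few
hundred ms) and are flagged as such via :attr:`ModelConstants.PLACEHOLDER_FIELDS`.
Quantitative work should set them explicitly from a calibration source.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelConstants", "ConfigurationError", "load_constants"]


class ConfigurationError(ValueError):
    """A constants value violates its physical-range invariant."""


@dataclass(frozen=True)
class ModelConstants:
    """Literature constants of the fat/water MR signal and tissue-water models.

    Parameters
    ----------
    rho_F, rho_W
        Proton densities of fat and water (mmol/l).
    D_F, D_W
        Mass densities of fat and water (g/ml).
    T1_free, T1_bound
        Longitudinal relaxation times of free and bound water (ms) used by
        the fast-exchange two-pool model.  Placeholder defaults — confirm
        before quantitative use.
    L_W_healthy
        Free-water tissue fraction of healthy liver (dimensionless).
    L_B_healthy
        Bound-water tissue fraction of healthy liver.  Placeholder default.
    k
        Proportion of a change in free tissue water attributed to the
        non-water compartment (rather than bound water), in [0, 1].
    area_to_volume_factor
        Geometric factor converting a 2-D area fraction of spherical
        inclusions to a 3-D volume fraction (sphere-in-cube / circle-in-square
        reading gives 2/3; the literal printed-formula reading gives 4/3).
    S_H
        Signal per mmol of hydrogen (arbitrary units).  Cancels in every
        ratio; carried only so the absolute signal equation can be written.
    """

    rho_F: float = 70.35
    rho_W: float = 111.11
    D_F: float = 0.9
    D_W: float = 1.0
    T1_free: float = 4000.0
    T1_bound: float = 250.0
    L_W_healthy: float = 0.711
    L_B_healthy: float = 0.08
    k: float = 0.0
    area_to_volume_factor: float = 2.0 / 3.0
    S_H: float = 1.0

    #: Fields whose defaults are placeholders with no bundled literature value.
    PLACEHOLDER_FIELDS = ("T1_free", "T1_bound", "L_B_healthy")

    def __post_init__(self) -> None:
        for name in ("rho_F", "rho_W", "D_F", "D_W", "T1_free", "T1_bound",
                     "area_to_volume_factor", "S_H"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not self.T1_free > self.T1_bound:
            raise ConfigurationError("T1_free must be > T1_bound")
        for name in ("L_W_healthy", "L_B_healthy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.L_W_healthy + self.L_B_healthy > 1.0:
            raise ConfigurationError("L_W_healthy + L_B_healthy must be <= 1")
        if not 0.0 <= self.k <= 1.0:
            raise ConfigurationError("k must be in [0, 1]")

    # -- provenance -------------------------------------------------------

    def non_default_fields(self) -> dict[str, float]:
        """Fields whose value differs from the shipped default."""
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v != f.default:
                out[f.name] = v
        return out

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def replace(self, **changes: float) -> "ModelConstants":
        return dataclasses.replace(self, **changes)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelConstants)}


def load_constants(config_source: str | Path | Mapping[str, Any] | None = None,
                   ) -> ModelConstants:
    """Build :class:`ModelConstants` from a config file, mapping, or defaults.

    ``config_source`` may be a mapping, a path to a flat YAML/JSON file whose
    keys are exactly the field names, a YAML/JSON string, or ``None`` (all
    defaults).  Unknown keys raise :class:`ConfigurationError`; missing keys
    take the documented defaults.
    """
    if config_source is None:
        data: Mapping[str, Any] = {}
    elif isinstance(config_source, Mapping):
        data = config_source
    else:
        text = None
        if isinstance(config_source, Path) or (
                isinstance(config_source, str) and "\n" not in config_source
                and Path(config_source).is_file()):
            text = Path(config_source).read_text()
        else:
            text = str(config_source)
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(
                "constants config must be a flat key/value mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigurationError(
            f"unknown constants field(s): {', '.join(sorted(unknown))}")
    try:
        numeric = {key: float(val) for key, val in data.items()}
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"non-numeric constants value: {exc}") from exc
    return ModelConstants(**numeric)
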