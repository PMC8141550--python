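"""YAML configuration schema and validation for the analysis pipeline.

Validation is schema-complete: every violation is collected and reported at
once (not first-error-only), unknown keys get a nearest-key suggestion, and
every default that was applied is recorded so the run manifest can expose
it.
"""

from __future__ import annotations

import difflib
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .synthetic import ChlorideSpec, SyntheticConfig
from .synthetic import NA1_SELECTION, NA2_SELECTION, GATE_ANCHOR_A, GATE_ANCHOR_B

__all__ = [
    "AnalysisConfig",
    "ConfigValidationError",
    "validate_config",
    "load_config",
]


class ConfigValidationError(ValueError):
    """Carries the complete list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GateConfig(_Model):
    anchor_a: str = GATE_ANCHOR_A
    anchor_b: str = GATE_ANCHOR_B
    axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    lateral_radius_nm: float = Field(1.2, gt=0)
    min_dwell_ns: float = Field(0.0, ge=0)


class SiteConfig(_Model):
    name: str
    coordinating: str
    entry_cutoff_nm: float = Field(0.30, gt=0)
    exit_cutoff_nm: float = Field(0.50, gt=0)
    min_dwell_ns: float = Field(1.0, ge=0)

    @model_validator(mode="after")
    def _hysteresis(self) -> "SiteConfig":
        if not self.exit_cutoff_nm > self.entry_cutoff_nm:
            raise ValueError(
                f"site {self.name}: hysteresis rule violated "
                f"(exit_cutoff_nm {self.exit_cutoff_nm} must exceed "
                f"entry_cutoff_nm {self.entry_cutoff_nm})"
            )
        return self


class GridConfig(_Model):
    spacing_nm: float = Field(0.1, gt=0)
    origin_nm: Optional[tuple[float, float, float]] = None   # None = box origin
    shape: Optional[tuple[int, int, int]] = None             # None = cover box
    density_sample_interval_ns: float = Field(0.005, gt=0)
    displacement_lag_ns: float = Field(0.010, gt=0)


class KineticsConfig(_Model):
    grid_dt_ns: float = Field(0.1, gt=0)
    bootstrap: bool = True
    n_boot: int = Field(200, ge=100)


class GeometryConfig(_Model):
    resolution_ns: float = Field(0.1, gt=0)
    window_ns: float = Field(1.0, gt=0)
    rmsd_stride_ns: float = Field(10.0, gt=0)
    pair_superpose: bool = True
    mass_weighted_centroid: bool = False


class SyntheticBlock(_Model):
    """Desk-scale synthetic study; see SyntheticConfig for semantics."""

    mode: Literal["hybrid", "spatial"] = "hybrid"
    n_replicas: int = Field(51, ge=1)
    duration_ns: float = Field(150.0, gt=0)
    dt_frame_ns: float = Field(0.05, gt=0)
    box_nm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    n_ions: int = Field(20, ge=0)
    concentration_molar: float = Field(0.15, gt=0)
    diffusion_coeff: float = Field(1.3, gt=0)
    entry_rate_per_ns: float = Field(0.12160906747839564, gt=0)  # ln2 / 5.7 ns
    na1_kon: Optional[float] = 4.2e7      # M^-1 s^-1; None drops the site
    na2_kon: Optional[float] = 1.9e7
    order_coupling: bool = False
    chloride_enabled: bool = False
    chloride_escape_rate: float = Field(0.002, gt=0)
    write_trajectories: bool = False

    def to_synthetic_config(self, seed: int) -> SyntheticConfig:
        cfg = SyntheticConfig(
            mode=self.mode,
            n_replicas=self.n_replicas,
            duration=self.duration_ns,
            dt_frame=self.dt_frame_ns,
            box=self.box_nm,
            n_ions=self.n_ions,
            concentration=self.concentration_molar,
            diffusion_coeff=self.diffusion_coeff,
            entry_rate=self.entry_rate_per_ns,
            chloride=ChlorideSpec(
                enabled=self.chloride_enabled, escape_rate=self.chloride_escape_rate
            ),
            order_coupling=self.order_coupling,
            seed=seed,
        )
        sites = []
        for s in cfg.sites:
            if s.name == "NA1":
                if self.na1_kon is None:
                    continue
                s.k_on_true = self.na1_kon
            if s.name == "NA2":
                if self.na2_kon is None:
                    continue
                s.k_on_true = self.na2_kon
            sites.append(s)
        cfg.sites = sites
        return cfg


class RealBlock(_Model):
    topology: str
    trajectories: list[str]
    concentration_molar: float = Field(0.15, gt=0)
    trajectory_format: Optional[str] = None


def _default_sites() -> list[SiteConfig]:
    return [
        SiteConfig(name="NA1", coordinating=NA1_SELECTION),
        SiteConfig(name="NA2", coordinating=NA2_SELECTION),
    ]


class AnalysisConfig(_Model):
    seed: int = 1
    output_dir: str = "ionbind_out"
    log_level: str = "INFO"
    ion_name: str = "NA"
    fit_selection: str = "CA"
    synthetic: Optional[SyntheticBlock] = None
    real: Optional[RealBlock] = None
    gate: GateConfig = Field(default_factory=GateConfig)
    sites: list[SiteConfig] = Field(default_factory=_default_sites)
    grid: GridConfig = Field(default_factory=GridConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)

    @model_validator(mode="after")
    def _exactly_one_input(self) -> "AnalysisConfig":
        if (self.synthetic is None) == (self.real is None):
            raise ValueError(
                "exactly one of the 'synthetic' and 'real' input blocks must be present"
            )
        return self


def _collect_defaults(model: BaseModel, provided: Any, prefix: str = "") -> list[str]:
    """Field paths whose value came from a schema default, not the file."""
    out: list[str] = []
    if not isinstance(provided, dict):
        provided = {}
    for name in type(model).model_fields:
        path = f"{prefix}{name}"
        value = getattr(model, name)
        if name not in provided:
            if value is not None:
                out.append(path)
            continue
        if isinstance(value, BaseModel):
            out.extend(_collect_defaults(value, provided.get(name), prefix=path + "."))
    return out


def _suggest(errors: ValidationError, data: Any) -> list[str]:
    msgs = []
    for err in errors.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        msg = f"{loc}: {err['msg']}"
        if err["type"] == "extra_forbidden":
            bad = str(err["loc"][-1])
            parent = data
            for p in err["loc"][:-1]:
                if isinstance(parent, dict):
                    parent = parent.get(p, {})
                elif isinstance(parent, list) and isinstance(p, int) and p < len(parent):
                    parent = parent[p]
            candidates = _known_keys(err["loc"][:-1])
            close = difflib.get_close_matches(bad, candidates, n=1)
            if close:
                msg += f" (did you mean {close[0]!r}?)"
        msgs.append(msg)
    return msgs


def _known_keys(loc: tuple) -> list[str]:
    model: type[BaseModel] = AnalysisConfig
    for p in loc:
        if isinstance(p, int):
            continue
        fld = model.model_fields.get(str(p))
        if fld is None:
            break
        ann = fld.annotation
        # unwrap Optional[...] and list[...]
        for arg in getattr(ann, "__args__", (ann,)):
            base = arg
            if hasattr(base, "__origin__") and base.__origin__ is list:
                base = base.__args__[0]
            if isinstance(base, type) and issubclass(base, BaseModel):
                model = base
                break
    return list(model.model_fields)


def validate_config(path: str | Path) -> tuple[AnalysisConfig, list[str]]:
    """Parse + validate a YAML config.

    Returns (config, applied_defaults); raises
    :class:`ConfigValidationError` with the complete violation list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigValidationError([f"YAML parse error: {exc}"]) from exc
    if data is None:
        data = {}
    return load_config(data)


def load_config(data: dict) -> tuple[AnalysisConfig, list[str]]:
    """Validate an already-parsed config mapping."""
    try:
        cfg = AnalysisConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigValidationError(_suggest(exc, data)) from exc
    return cfg, _collect_defaults(cfg, data)
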