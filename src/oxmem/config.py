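"""Run configuration and the two canonical end-to-end recipes.

A RunConfig is loaded from YAML; unknown keys are rejected before any
work, all randomness flows through the single seed, and every output
carries a provenance sidecar (config hash + seed), so re-running an
identical config reproduces identical outputs for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    recipe: str = "composition"          # composition | umbrella
    output_dir: str = "oxmem_out"
    seed: int = 0
    log_level: str = "info"
    composition_table: str | None = None  # CSV path; None = packaged default
    # umbrella recipe parameters
    z_start: float = 4.0
    z_end: float = -4.0
    window_spacing: float = 0.2
    force_constant: float = 100.0        # kJ/mol/nm^2
    samples_per_window: int = 20_000
    temperature: float = 298.0           # K, for kT and permeability
    bin_width: float = 0.05
    trim_fraction: float = 0.0           # generated samples need no trim
    barrier_height: float = 26.0         # kJ/mol, synthetic PMF barrier
    well_depth: float = 5.0              # kJ/mol, interfacial wells
    diffusion_nm2_ps: float = 5e-4       # synthetic D(z) plateau
    correlation_time_ps: float = 1.0
    force_series_length: int = 20_000
    force_series_dt: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar(cfg: RunConfig, path: Path, **extra) -> None:
    meta = {"config_hash": cfg.config_hash, "seed": cfg.seed,
            "config": cfg.to_dict(), **extra}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))


def _double_well_pmf(cfg: RunConfig):
    """Synthetic membrane-like free-energy profile: central barrier with
    two interfacial wells, decaying to zero in bulk water."""
    b, w = cfg.barrier_height, cfg.well_depth

    def G(z):
        z = np.asarray(z, float)
        return (b * np.exp(-z ** 2 / (2 * 0.8 ** 2))
                - w * np.exp(-(z - 2.2) ** 2 / (2 * 0.35 ** 2))
                - w * np.exp(-(z + 2.2) ** 2 / (2 * 0.35 ** 2)))
    return G


def run_pipeline(config: RunConfig) -> dict:
    """Execute a recipe; returns a manifest of written artifacts."""
    import pandas as pd
    from . import composition as comp_mod
    from . import pmf as pmf_mod
    from . import synthetic as syn
    from .units import kT as kT_of

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    if config.recipe == "composition":
        table = (pd.read_csv(config.composition_table)
                 if config.composition_table else None)
        native = comp_mod.build_native_composition(table)
        ferro = comp_mod.apply_ferroptosis_substitution(
            native, seed=config.seed)
        for label, comp in (("native", native), ("ferroptosis", ferro)):
            summary = comp_mod.composition_summary(comp)
            p = out / f"{label}_by_species.csv"
            summary["by_species"].to_csv(p, index=False)
            _sidecar(config, p)
            manifest[f"{label}_by_species"] = str(p)
            p = out / f"{label}_totals.json"
            p.write_text(json.dumps({
                **summary["totals"],
                "chol_pl_ratio": summary[
                    "cholesterol_phospholipid_ratio"]}, indent=1))
            _sidecar(config, p)
            manifest[f"{label}_totals"] = str(p)
        p = out / "hpd_mole_percent.json"
        p.write_text(json.dumps(comp_mod.hpd_mole_percent(ferro), indent=1))
        _sidecar(config, p)
        manifest["hpd_mole_percent"] = str(p)
        return manifest

    if config.recipe == "umbrella":
        kT = kT_of(config.temperature)
        sched = pmf_mod.make_window_schedule(
            config.z_start, config.z_end, config.window_spacing,
            config.force_constant)
        G = _double_well_pmf(config)
        windows, truth = syn.gen_umbrella_samples(
            G, sched.centers, sched.force_constant,
            config.samples_per_window, kT, seed=config.seed)
        if config.trim_fraction > 0:
            windows = [pmf_mod.equilibration_trim(w, config.trim_fraction)
                       for w in windows]
        profile = pmf_mod.wham(windows, kT, bin_width=config.bin_width)
        p = out / "pmf.csv"
        pd.DataFrame({"z_nm": profile.z, "dG_kJ_mol": profile.dG,
                      "uncertainty": profile.uncertainty}).to_csv(
            p, index=False, float_format="%.6f")
        _sidecar(config, p)
        manifest["pmf"] = str(p)

        fwin, _ = syn.gen_force_series(
            config.diffusion_nm2_ps, config.temperature,
            config.correlation_time_ps, config.force_series_length,
            config.force_series_dt, seed=config.seed + 1,
            centers=sched.centers)
        dprof = pmf_mod.diffusion_from_force_autocorrelation(
            fwin, config.temperature)
        p = out / "diffusion_profile.csv"
        pd.DataFrame({"z_nm": dprof.z, "D_nm2_ps": dprof.D}).to_csv(
            p, index=False, float_format="%.8g")
        _sidecar(config, p)
        manifest["diffusion_profile"] = str(p)

        lo = max(profile.z.min(), dprof.z.min(),
                 min(config.z_start, config.z_end))
        hi = min(profile.z.max(), dprof.z.max(),
                 max(config.z_start, config.z_end))
        perm = pmf_mod.permeability(profile, dprof, T=config.temperature,
                                    bounds=(lo, hi))
        p = out / "permeability.json"
        p.write_text(json.dumps({
            "P_cm_s": perm.P, "T_K": perm.T, "bounds_nm": list(perm.bounds),
            "barrier_over_bulk_kJ_mol": profile.barrier_height("bulk"),
            "barrier_over_minimum_kJ_mol":
                profile.barrier_height("minimum")}, indent=1))
        _sidecar(config, p)
        manifest["permeability"] = str(p)
        return manifest

    raise ConfigError(f"unknown recipe {config.recipe!r}")
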