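"""Run configuration: TOML loading with strict validation.

A run config is one TOML file with flat ``key = value`` sections
(``generator``, ``mixture`` with a ``[[mixture.species]]`` array,
``screening``, ``histogram``, ``fit``, ``titration``, ``report``) plus a
top-level master ``seed``, ``n_traces`` and optional ``outdir``.  Unknown
keys anywhere are rejected, and every section is validated against its
module's type invariants at load time.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from smbjdna.generator import (
    EnvironmentCondition,
    GeneratorConfig,
    MixtureSpec,
    SpeciesModel,
)
from smbjdna.screening import ScreeningConfig

__all__ = ["RunConfig", "FitOptions", "TitrationOptions", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class FitOptions:
    k: int = 1
    poisson_weighted: bool = False
    baseline: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("fit.k must be >= 1")


@dataclass(frozen=True)
class TitrationOptions:
    c_min_M: float = 2e-15
    c_max_M: float = 0.45e-6
    n_points: int = 9
    n_traces: int = 3000
    repeats: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.c_min_M < self.c_max_M:
            raise ConfigError("require 0 < titration.c_min_M < titration.c_max_M")
        if self.n_points < 2:
            raise ConfigError("titration.n_points must be >= 2")
        if self.n_traces < 1 or self.repeats < 1:
            raise ConfigError("titration.n_traces and titration.repeats must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of every pipeline stage's parameters."""

    generator: GeneratorConfig = GeneratorConfig()
    mixture: Optional[MixtureSpec] = None
    screening: ScreeningConfig = ScreeningConfig()
    fit: FitOptions = FitOptions()
    titration: TitrationOptions = TitrationOptions()
    seed: int = 0
    n_traces: int = 5000
    repeats: int = 3
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_traces < 1:
            raise ConfigError("n_traces must be >= 1")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")


def _check_keys(section: Dict, allowed: Tuple[str, ...], where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{where}]: {sorted(unknown)}")


_SPECIES_KEYS = (
    "name",
    "mu",
    "conductance_g0",
    "sigma_between",
    "plateau_length_mean",
    "plateau_length_sd",
    "capture_affinity",
    "topology",
    "mu_kcl",
    "conductance_g0_kcl",
    "concentration_M",
)


def _parse_species(raw: Dict, idx: int) -> Tuple[SpeciesModel, float]:
    _check_keys(raw, _SPECIES_KEYS, f"mixture.species #{idx}")
    raw = dict(raw)
    conc = raw.pop("concentration_M", None)
    if conc is None:
        raise ConfigError(f"mixture.species #{idx}: concentration_M is required")
    if "conductance_g0" in raw:
        if "mu" in raw:
            raise ConfigError(f"mixture.species #{idx}: give mu or conductance_g0, not both")
        raw["mu"] = math.log10(raw.pop("conductance_g0"))
    if "mu" not in raw:
        raise ConfigError(f"mixture.species #{idx}: mu or conductance_g0 is required")
    if "conductance_g0_kcl" in raw:
        raw["mu_kcl"] = math.log10(raw.pop("conductance_g0_kcl"))
    try:
        return SpeciesModel(**raw), float(conc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"mixture.species #{idx}: {exc}") from exc


def _parse_mixture(raw: Dict) -> MixtureSpec:
    _check_keys(raw, ("species", "environment", "kcl_mM", "p_junction"), "mixture")
    species_raw = raw.get("species", [])
    if not species_raw:
        raise ConfigError("mixture requires at least one [[mixture.species]] entry")
    components = tuple(
        _parse_species(sp, i) for i, sp in enumerate(species_raw)
    )
    env_name = raw.get("environment", "PBS")
    kcl = raw.get("kcl_mM", 100.0 if env_name == "PBS_KCl" else 0.0)
    try:
        env = EnvironmentCondition(env_name, float(kcl))
        return MixtureSpec(
            components=components,
            environment=env,
            p_junction=float(raw.get("p_junction", 0.125)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


_GENERATOR_KEYS = (
    "beta",
    "ceiling",
    "floor",
    "noise_sd",
    "plateau_slope",
    "bias",
    "sampling_rate",
    "retraction_rate",
    "capture_alpha",
    "seed",
)
_SCREENING_KEYS = ("residual_threshold", "window", "bins_per_decade", "amplitude_threshold")
_FIT_KEYS = ("k", "poisson_weighted", "baseline")
_TITRATION_KEYS = ("c_min_M", "c_max_M", "n_points", "n_traces", "repeats")
_TOP_KEYS = (
    "generator",
    "mixture",
    "screening",
    "histogram",
    "fit",
    "titration",
    "seed",
    "n_traces",
    "repeats",
    "outdir",
)


def parse_config(doc: Dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a parsed TOML document."""
    _check_keys(doc, _TOP_KEYS, "top level")

    gen_raw = dict(doc.get("generator", {}))
    _check_keys(gen_raw, _GENERATOR_KEYS, "generator")

    scr_raw = dict(doc.get("screening", {}))
    _check_keys(scr_raw, _SCREENING_KEYS, "screening")
    # The composite histogram shares the screening binning convention; a
    # [histogram] section may override the window / bin count for both.
    hist_raw = dict(doc.get("histogram", {}))
    _check_keys(hist_raw, ("window", "bins_per_decade"), "histogram")
    for key in ("window", "bins_per_decade"):
        if key in hist_raw and key not in scr_raw:
            scr_raw[key] = hist_raw[key]
    if "window" in scr_raw:
        scr_raw["window"] = tuple(scr_raw["window"])

    fit_raw = dict(doc.get("fit", {}))
    _check_keys(fit_raw, _FIT_KEYS, "fit")
    tit_raw = dict(doc.get("titration", {}))
    _check_keys(tit_raw, _TITRATION_KEYS, "titration")

    mixture = _parse_mixture(doc["mixture"]) if "mixture" in doc else None

    try:
        return RunConfig(
            generator=GeneratorConfig(**gen_raw),
            mixture=mixture,
            screening=ScreeningConfig(**scr_raw),
            fit=FitOptions(**fit_raw),
            titration=TitrationOptions(**tit_raw),
            seed=int(doc.get("seed", 0)),
            n_traces=int(doc.get("n_traces", 5000)),
            repeats=int(doc.get("repeats", 3)),
            outdir=doc.get("outdir"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration file."""
    with open(path, "rb") as fh:
        try:
            doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    return parse_config(doc)
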