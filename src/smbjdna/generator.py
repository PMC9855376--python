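"""Synthetic SMBJ retraction-trace generator.

Emulates the statistical structure of break-junction conductance
measurements on DNA solutions: most retraction events show a bare
exponential tunneling decay (a straight line on a semi-log plot, slope
``-beta`` decades/nm); a minority -- controlled by ``p_junction`` -- form a
molecular junction and hold a conductance plateau at a species-specific
level before breaking down to the current noise floor of the preamplifier.

All conductances are dimensionless ``G/G0`` (``G0 = 2e^2/h``); conversion
to siemens is a single explicit operation in :mod:`smbjdna.histogram`.
Plateau levels live on the log10 scale ("decades"), where both the
trace-to-trace spread and the per-sample noise are specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from smbjdna.units import CONDUCTANCE_QUANTUM_S

__all__ = [
    "Trace",
    "SpeciesModel",
    "EnvironmentCondition",
    "MixtureSpec",
    "GeneratorConfig",
    "NoJunctionSpeciesError",
    "capture_weights",
    "apply_environment",
    "simulate_trace",
    "simulate_ensemble",
    "PBS",
    "PBS_KCL",
]

#: Lower current limit of the emulated preamplifier, amperes.
NOISE_FLOOR_A = 10e-12

#: Topologies that can bridge two electrodes.  A parallel quadruplex has
#: both thiol linkers on the same end and cannot span the gap.
JUNCTION_FORMING_TOPOLOGIES = frozenset({"duplex", "antiparallel_quad"})

VALID_TOPOLOGIES = frozenset({"duplex", "antiparallel_quad", "parallel_quad"})


class NoJunctionSpeciesError(ValueError):
    """Raised when no component of a mixture can form a junction."""


@dataclass(frozen=True)
class Trace:
    """One conductance-distance retraction event.

    ``distance`` is in nm, starting at 0 and increasing by
    ``retraction_rate / sampling_rate`` per sample; ``conductance`` is
    dimensionless G/G0.  ``label`` carries the ground-truth species name for
    synthetic junction traces (``None`` for tunneling-only traces and for
    real data).
    """

    distance: np.ndarray
    conductance: np.ndarray
    bias: float
    sampling_rate: float
    retraction_rate: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distance, dtype=float)
        g = np.asarray(self.conductance, dtype=float)
        if d.ndim != 1 or g.ndim != 1 or d.size == 0 or d.size != g.size:
            raise ValueError(
                "distance and conductance must be 1-D arrays of equal, nonzero length"
            )
        object.__setattr__(self, "distance", d)
        object.__setattr__(self, "conductance", g)

    def __len__(self) -> int:
        return int(self.distance.size)

    @property
    def log_conductance(self) -> np.ndarray:
        """log10(G/G0) per sample."""
        return np.log10(self.conductance)


@dataclass(frozen=True)
class SpeciesModel:
    """Junction parameters of one DNA conformation.

    Parameters
    ----------
    mu
        Mean plateau level, log10(G/G0).
    sigma_between
        Trace-to-trace spread of the plateau level, decades.
    plateau_length_mean, plateau_length_sd
        Plateau length distribution, nm (normal, truncated > 0).
    capture_affinity
        Dimensionless propensity to be captured in a junction, used by
        :func:`capture_weights` together with concentration.
    topology
        ``duplex``, ``antiparallel_quad`` or ``parallel_quad``; the parallel
        topology never forms a junction.
    mu_kcl
        Optional plateau level under the KCl environment (duplexes shift
        slightly with the cation composition).
    """

    name: str
    mu: float
    sigma_between: float = 0.15
    plateau_length_mean: float = 0.3
    plateau_length_sd: float = 0.1
    capture_affinity: float = 1.0
    topology: str = "duplex"
    mu_kcl: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma_between < 0:
            raise ValueError("sigma_between must be >= 0")
        if self.plateau_length_mean <= 0:
            raise ValueError("plateau_length_mean must be > 0")
        if self.plateau_length_sd < 0:
            raise ValueError("plateau_length_sd must be >= 0")
        if self.capture_affinity < 0:
            raise ValueError("capture_affinity must be >= 0")
        if self.topology not in VALID_TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class EnvironmentCondition:
    """Buffer condition: phosphate buffer with or without added KCl."""

    name: str = "PBS"
    kcl_mM: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("PBS", "PBS_KCl"):
            raise ValueError("environment name must be 'PBS' or 'PBS_KCl'")
        if self.kcl_mM < 0:
            raise ValueError("kcl_mM must be >= 0")
        if self.name == "PBS" and self.kcl_mM != 0:
            raise ValueError("PBS implies kcl_mM = 0")


PBS = EnvironmentCondition("PBS", 0.0)
PBS_KCL = EnvironmentCondition("PBS_KCl", 100.0)


@dataclass(frozen=True)
class MixtureSpec:
    """Concentration-weighted species mixture under an environment.

    ``components`` is a sequence of ``(SpeciesModel, concentration_molar)``
    pairs.  ``p_junction`` is the probability that a retraction event forms
    any molecular junction at all.
    """

    components: tuple
    environment: EnvironmentCondition = PBS
    p_junction: float = 0.125

    def __post_init__(self) -> None:
        comps = tuple((sp, float(c)) for sp, c in self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        for sp, c in comps:
            if not isinstance(sp, SpeciesModel):
                raise TypeError("components must pair SpeciesModel with concentration")
            if c < 0:
                raise ValueError("concentrations must be >= 0")
        if not 0.0 <= self.p_junction <= 1.0:
            raise ValueError("p_junction must lie in [0, 1]")
        object.__setattr__(self, "components", comps)

    @property
    def species(self) -> tuple:
        return tuple(sp for sp, _ in self.components)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.components], dtype=float)


def _default_floor(bias: float) -> float:
    # 10 pA at the working bias, expressed as G/G0
    return NOISE_FLOOR_A / bias / CONDUCTANCE_QUANTUM_S


@dataclass(frozen=True)
class GeneratorConfig:
    """Physical and sampling parameters of the synthetic instrument.

    Defaults: 0.1 V bias, 40 kHz sampling at 80 nm/s retraction (2 pm per
    sample), tunneling decay 6 decades/nm, saturation ceiling 0.1 G0 and a
    noise floor equal to 10 pA at the working bias (~1.29e-6 G0 at 0.1 V).
    """

    beta: float = 6.0
    ceiling: float = 0.1
    floor: Optional[float] = None
    noise_sd: float = 0.05
    plateau_slope: float = -0.3
    bias: float = 0.1
    sampling_rate: float = 40_000.0
    retraction_rate: float = 80.0
    capture_alpha: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.bias <= 0:
            raise ValueError("bias must be > 0")
        if self.floor is None:
            object.__setattr__(self, "floor", _default_floor(self.bias))
        if not self.ceiling > self.floor > 0:
            raise ValueError("require ceiling > floor > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate <= 0 or self.retraction_rate <= 0:
            raise ValueError("sampling_rate and retraction_rate must be > 0")
        if self.capture_alpha <= 0:
            raise ValueError("capture_alpha must be > 0")

    @property
    def step_nm(self) -> float:
        """Distance advanced per sample, nm."""
        return self.retraction_rate / self.sampling_rate

    @property
    def log_floor(self) -> float:
        return math.log10(self.floor)

    @property
    def log_ceiling(self) -> float:
        return math.log10(self.ceiling)


def capture_weights(mixture: MixtureSpec, alpha: float = 0.08) -> np.ndarray:
    """Per-species junction-capture probabilities for a mixture.

    The capture weight of component *i* is ``(affinity_i * c_i) ** alpha``,
    normalised over junction-forming components.  The small compression
    exponent (default 0.08) makes capture strongly sublinear in
    concentration, so a trace minority species still appears in an
    appreciable fraction of junctions -- the regime in which a titration
    over ~16 orders of magnitude of concentration ratio keeps both species
    detectable.  Components with parallel-quadruplex topology get weight 0:
    with both thiol linkers on one end they cannot bridge the electrodes.

    Raises
    ------
    NoJunctionSpeciesError
        If every component has zero effective weight.
    """
    raw = np.zeros(len(mixture.components))
    for i, (sp, c) in enumerate(mixture.components):
        if sp.topology not in JUNCTION_FORMING_TOPOLOGIES:
            continue
        eff = sp.capture_affinity * c
        if eff > 0:
            raw[i] = eff ** alpha
    total = raw.sum()
    if total <= 0:
        raise NoJunctionSpeciesError("no junction-forming species in mixture")
    return raw / total


def apply_environment(mixture: MixtureSpec) -> MixtureSpec:
    """Apply the buffer environment to a mixture.

    Under ``PBS_KCl``, potassium destabilises the antiparallel quadruplex
    topology in favour of the parallel one, which cannot form a junction:
    every ``antiparallel_quad`` species is converted to ``parallel_quad``.
    Duplex species with a configured ``mu_kcl`` take that plateau level.
    Under plain PBS the mixture is returned unchanged.
    """
    if mixture.environment.name != "PBS_KCl":
        return mixture
    new_components = []
    for sp, c in mixture.components:
        if sp.topology == "antiparallel_quad":
            sp = replace(sp, topology="parallel_quad")
        elif sp.topology == "duplex" and sp.mu_kcl is not None:
            sp = replace(sp, mu=sp.mu_kcl)
        new_components.append((sp, c))
    return replace(mixture, components=tuple(new_components))


def _draw_plateau_length(sp: SpeciesModel, rng: np.random.Generator) -> float:
    """Normal plateau length truncated to > 0 by redrawing."""
    for _ in range(1000):
        length = rng.normal(sp.plateau_length_mean, sp.plateau_length_sd)
        if length > 0:
            return length
    raise RuntimeError("plateau length distribution almost entirely <= 0")


def _junction_log_trace(
    sp: SpeciesModel, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Noiseless log10-conductance skeleton for a junction-forming event."""
    if not config.log_floor < sp.mu < config.log_ceiling:
        raise ValueError(
            f"species {sp.name!r}: plateau level mu={sp.mu} outside the "
            f"generator window [{config.log_floor:.3f}, {config.log_ceiling:.3f}]"
        )
    step = config.step_nm
    level = rng.normal(sp.mu, sp.sigma_between) if sp.sigma_between > 0 else sp.mu
    length = _draw_plateau_length(sp, rng)
    n_plat = max(1, round(length * config.sampling_rate / config.retraction_rate))

    # Plateau tilt is centred on the drawn level so the plateau's mean
    # log-conductance equals the level (no tilt-induced histogram bias).
    offsets = (np.arange(n_plat) - (n_plat - 1) / 2.0) * step
    plateau = level + config.plateau_slope * offsets
    p_start = plateau[0]

    # Phase 1: tunneling decay from the ceiling down to the plateau start.
    drop = config.log_ceiling - p_start
    n1 = max(0, math.ceil(drop / (config.beta * step))) if drop > 0 else 0
    decay_in = config.log_ceiling - config.beta * step * np.arange(n1)
    decay_in = decay_in[decay_in > p_start]

    # Phase 3: breakdown from the plateau end to the noise floor.
    p_end = plateau[-1]
    n3 = max(1, math.ceil((p_end - config.log_floor) / (config.beta * step)))
    decay_out = p_end - config.beta * step * np.arange(1, n3 + 1)
    # end at the first sample at/below the floor, clamped to the floor
    below = np.nonzero(decay_out <= config.log_floor)[0]
    if below.size:
        decay_out = decay_out[: below[0] + 1]
        decay_out[-1] = config.log_floor

    return np.concatenate([decay_in, plateau, decay_out])


def _tunneling_log_trace(config: GeneratorConfig) -> np.ndarray:
    """Noiseless pure tunneling decay, ceiling to floor."""
    step = config.step_nm
    span = config.log_ceiling - config.log_floor
    n = math.ceil(span / (config.beta * step)) + 1
    logs = config.log_ceiling - config.beta * step * np.arange(n)
    below = np.nonzero(logs <= config.log_floor)[0]
    logs = logs[: below[0] + 1]
    logs[-1] = config.log_floor
    return logs


def simulate_trace(
    mixture: MixtureSpec,
    config: GeneratorConfig,
    rng: np.random.Generator,
    *,
    force_junction: Optional[bool] = None,
    force_species: Optional[SpeciesModel] = None,
) -> Trace:
    """Draw one retraction trace from a mixture.

    With probability ``1 - p_junction`` the trace is a bare exponential
    tunneling decay, ``log10 G(d) = log10(ceiling) - beta * d`` plus noise,
    truncated at the floor.  Otherwise a species is drawn according to
    :func:`capture_weights`, a plateau level from ``Normal(mu,
    sigma_between)`` and a plateau length from the species' truncated
    normal; the trace decays to the plateau, holds it (with the configured
    tilt), then breaks down to the floor.  If no component of the mixture
    can form a junction, every trace is a tunneling decay.

    ``force_junction`` / ``force_species`` bypass the random event and
    species draws (used by tests and calibration); they do not perturb the
    remaining draw sequence.
    """
    if force_species is not None:
        junction = True
        species = force_species
    else:
        try:
            weights = capture_weights(mixture, config.capture_alpha)
        except NoJunctionSpeciesError:
            weights = None
        if force_junction is None:
            junction = weights is not None and rng.random() < mixture.p_junction
        else:
            junction = force_junction and weights is not None
        species = None
        if junction:
            idx = rng.choice(len(weights), p=weights)
            species = mixture.species[idx]

    if junction and species is not None:
        logs = _junction_log_trace(species, config, rng)
        label = species.name
    else:
        logs = _tunneling_log_trace(config)
        label = None

    if config.noise_sd > 0:
        logs = logs + rng.normal(0.0, config.noise_sd, logs.size)
    logs = np.clip(logs, config.log_floor, config.log_ceiling)

    distance = np.arange(logs.size) * config.step_nm
    return Trace(
        distance=distance,
        conductance=10.0 ** logs,
        bias=config.bias,
        sampling_rate=config.sampling_rate,
        retraction_rate=config.retraction_rate,
        label=label,
    )


def simulate_ensemble(
    n: int,
    mixture: MixtureSpec,
    config: GeneratorConfig,
    seed: Optional[int] = None,
) -> list:
    """Simulate ``n`` independent retraction traces from one seeded stream.

    The same ``(n, mixture, config, seed)`` always yields a bitwise
    identical ensemble.  When ``seed`` is None the configured
    ``config.seed`` is used.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [simulate_trace(mixture, config, rng) for _ in range(n)]
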