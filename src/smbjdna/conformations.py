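"""Conformation assignment and concentration-ratio titration.

Guanine-rich DNA sequences populate two conformations with well separated
junction conductances: the B-form duplex (low, a few 1e-4 G0) and the
G-quadruplex (high, a few 1e-3 G0).  Fitted histogram peaks are labelled
against a reference table of single-conformation control values, and the
ratio of the two fitted peak amplitudes serves as the readout of a
titration of the quadruplex:duplex concentration ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from smbjdna.generator import (
    GeneratorConfig,
    MixtureSpec,
    SpeciesModel,
    EnvironmentCondition,
    PBS,
    apply_environment,
    simulate_ensemble,
)
from smbjdna.histogram import (
    PeakInitializationError,
    PeakSet,
    build_histogram,
    fit_gaussian_peaks,
    make_edges,
    peak_presence_threshold,
)
from smbjdna.screening import ScreeningConfig, screen_ensemble

__all__ = [
    "ReferenceEntry",
    "ReferenceTable",
    "TitrationPoint",
    "default_reference_table",
    "default_titration_grid",
    "default_mixture",
    "assign_conformations",
    "peak_height_ratio",
    "run_titration",
    "DS_GGCGAGCGCC",
    "G3T3G3_QUAD",
    "DUPLEX_LABEL",
    "QUAD_LABEL",
]

DUPLEX_LABEL = "duplex"
QUAD_LABEL = "G-quadruplex"
UNASSIGNED = "unassigned"

# Single-conformation control species: a 10-bp GC-rich B-form duplex
# (ds(GGCGAGCGCC), 3.03e-4 G0) and the three-tetrad antiparallel
# G-quadruplex formed by G3-T3-G3 (3.77e-3 G0).
DS_GGCGAGCGCC = SpeciesModel(
    name="ds(GGCGAGCGCC)", mu=math.log10(3.03e-4), topology="duplex"
)
G3T3G3_QUAD = SpeciesModel(
    name="(G3-T3-G3)-G-quad", mu=math.log10(3.77e-3), topology="antiparallel_quad"
)


def default_mixture(
    c_quad: float = 0.45e-6,
    c_duplex: float = 0.45e-6,
    environment: EnvironmentCondition = PBS,
    p_junction: float = 0.125,
) -> MixtureSpec:
    """The package's default study mixture.

    Equal 0.45 uM concentrations of the G3-T3-G3 quadruplex and the
    ds(GGCGAGCGCC) duplex control in PBS, with a 12.5% junction-formation
    probability per retraction event.
    """
    return MixtureSpec(
        components=((G3T3G3_QUAD, c_quad), (DS_GGCGAGCGCC, c_duplex)),
        environment=environment,
        p_junction=p_junction,
    )


@dataclass(frozen=True)
class ReferenceEntry:
    """One conformation's reference conductance with a log-scale tolerance."""

    name: str
    conductance_g0: float
    tolerance_decades: float

    def __post_init__(self) -> None:
        if self.conductance_g0 <= 0:
            raise ValueError("conductance_g0 must be > 0")
        if self.tolerance_decades <= 0:
            raise ValueError("tolerance_decades must be > 0")

    @property
    def mu_log(self) -> float:
        return math.log10(self.conductance_g0)


@dataclass(frozen=True)
class ReferenceTable:
    """Unique-by-name reference conductances for conformation assignment."""

    entries: tuple

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        if not entries:
            raise ValueError("reference table must be nonempty")
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("reference entries must be unique by name")
        object.__setattr__(self, "entries", entries)


def default_reference_table(tolerance_decades: float = 0.35) -> ReferenceTable:
    """Reference table from the single-conformation duplex / quadruplex controls.

    The 0.35-decade default tolerance comfortably covers the spread of
    reported duplex values (1.6-3.4e-4 G0) and quadruplex values
    (3.5-3.8e-3 G0) around each control while staying well below the
    ~1.1-decade separation between the two classes.
    """
    return ReferenceTable(
        entries=(
            ReferenceEntry(DUPLEX_LABEL, 3.03e-4, tolerance_decades),
            ReferenceEntry(QUAD_LABEL, 3.77e-3, tolerance_decades),
        )
    )


def assign_conformations(peaks: PeakSet, table: ReferenceTable) -> List[str]:
    """Label each fitted peak with the nearest in-tolerance reference.

    Assignment is one-to-one, greedy by smallest log-distance; distance
    ties break toward the lower-conductance reference.  Peaks with no
    reference within tolerance are labelled ``"unassigned"``.
    """
    labels = [UNASSIGNED] * len(peaks)
    candidates = []
    for i, peak in enumerate(peaks):
        for entry in table.entries:
            dist = abs(peak.mu_log - entry.mu_log)
            if dist <= entry.tolerance_decades:
                candidates.append((dist, entry.mu_log, i, entry.name))
    used_peaks: set = set()
    used_refs: set = set()
    for dist, ref_mu, i, name in sorted(candidates):
        if i in used_peaks or name in used_refs:
            continue
        labels[i] = name
        used_peaks.add(i)
        used_refs.add(name)
    return labels


def peak_height_ratio(
    peaks: PeakSet,
    labels: Sequence[str],
    quad_label: str = QUAD_LABEL,
    duplex_label: str = DUPLEX_LABEL,
) -> float:
    """Ratio of fitted amplitudes, quadruplex peak over duplex peak."""
    quads = [p for p, l in zip(peaks, labels) if l == quad_label]
    duplexes = [p for p, l in zip(peaks, labels) if l == duplex_label]
    if len(quads) != 1 or len(duplexes) != 1:
        raise ValueError("ratio undefined: need exactly one quadruplex and one duplex peak")
    return quads[0].amplitude / duplexes[0].amplitude


@dataclass(frozen=True)
class TitrationPoint:
    """One grid point of the concentration-ratio titration."""

    c_quad: float
    c_duplex: float
    ratio: float
    peak_height_ratio: Optional[float]
    both_detected: bool
    n_selected: int
    error: Optional[str] = None


def default_titration_grid(
    c_min: float = 2e-15,
    c_max: float = 0.45e-6,
    n_points: int = 9,
) -> List[Tuple[float, float]]:
    """Both sweep directions of the titration grid.

    One species is swept over ``n_points`` log-spaced concentrations from
    2 fM to 0.45 uM while the other is held at 0.45 uM, in both directions;
    the end points span ~16.7 orders of magnitude of concentration ratio.
    """
    sweep = np.geomspace(c_min, c_max, n_points)
    grid = [(float(c), c_max) for c in sweep]
    grid += [(c_max, float(c)) for c in sweep if c != c_max]
    return grid


def _titrate_one(
    c_quad: float,
    c_duplex: float,
    quad: SpeciesModel,
    duplex: SpeciesModel,
    environment: EnvironmentCondition,
    p_junction: float,
    config: GeneratorConfig,
    screening: ScreeningConfig,
    edges: np.ndarray,
    table: ReferenceTable,
    n_traces: int,
    seeds: Sequence[int],
):
    """One grid point: repeats of simulate -> screen -> histogram -> fit -> assign."""
    mixture = apply_environment(
        MixtureSpec(
            components=((quad, c_quad), (duplex, c_duplex)),
            environment=environment,
            p_junction=p_junction,
        )
    )
    ratios = []
    detected_flags = []
    n_selected = 0
    for seed in seeds:
        traces = simulate_ensemble(n_traces, mixture, config, seed=seed)
        selected, _, _ = screen_ensemble(traces, screening)
        n_selected += len(selected)
        hist = build_histogram(selected, edges)
        peaks = fit_gaussian_peaks(hist, k=2)
        labels = assign_conformations(peaks, table)
        present = peak_presence_threshold(hist)
        by_label = {l: p for p, l in zip(peaks, labels)}
        both = (
            QUAD_LABEL in by_label
            and DUPLEX_LABEL in by_label
            and by_label[QUAD_LABEL].amplitude >= present
            and by_label[DUPLEX_LABEL].amplitude >= present
        )
        detected_flags.append(both)
        if QUAD_LABEL in by_label and DUPLEX_LABEL in by_label:
            ratios.append(peak_height_ratio(peaks, labels))
    both_detected = bool(detected_flags) and all(detected_flags)
    mean_ratio = float(np.mean(ratios)) if ratios and both_detected else None
    return mean_ratio, both_detected, n_selected


def run_titration(
    grid: Sequence[Tuple[float, float]],
    quad: SpeciesModel = G3T3G3_QUAD,
    duplex: SpeciesModel = DS_GGCGAGCGCC,
    *,
    environment: EnvironmentCondition = PBS,
    p_junction: float = 0.125,
    config: GeneratorConfig = GeneratorConfig(),
    screening: ScreeningConfig = ScreeningConfig(),
    edges: Optional[np.ndarray] = None,
    table: Optional[ReferenceTable] = None,
    n_traces: int = 3000,
    repeats: int = 2,
    seed: int = 0,
) -> List[TitrationPoint]:
    """Full titration: the end-to-end pipeline at every (c_quad, c_duplex) point.

    Each point is averaged over ``repeats`` independent measurements whose
    seeds are derived deterministically from the master ``seed``.  A stage
    failure at one point flags that point without aborting the grid.
    """
    grid = list(grid)
    if len(grid) < 2:
        raise ValueError("titration grid needs at least 2 points")
    if any(c <= 0 for pair in grid for c in pair):
        raise ValueError("all concentrations must be > 0")
    if edges is None:
        edges = make_edges(*screening.window, screening.bins_per_decade)
    if table is None:
        table = default_reference_table()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid))
    points: List[TitrationPoint] = []
    for (c_quad, c_duplex), child in zip(grid, children):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(repeats)]
        try:
            mean_ratio, both, n_sel = _titrate_one(
                c_quad,
                c_duplex,
                quad,
                duplex,
                environment,
                p_junction,
                config,
                screening,
                edges,
                table,
                n_traces,
                seeds,
            )
            err = None
        except (PeakInitializationError, ValueError) as exc:
            mean_ratio, both, n_sel, err = None, False, 0, str(exc)
        points.append(
            TitrationPoint(
                c_quad=c_quad,
                c_duplex=c_duplex,
                ratio=c_quad / c_duplex,
                peak_height_ratio=mean_ratio,
                both_detected=both,
                n_selected=n_sel,
                error=err,
            )
        )
    return points
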