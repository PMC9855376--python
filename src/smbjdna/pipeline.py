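"""End-to-end orchestration: simulate -> screen -> histogram -> fit -> report.

The report is a plain JSON-serialisable dictionary.  One master seed
deterministically derives per-repeat seeds through ``SeedSequence.spawn``,
so "N independent measurements" are reproducible and the serialised report
is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import json
import logging
import time
from typing import Dict, List, Optional

import numpy as np

from smbjdna.config import RunConfig
from smbjdna.conformations import assign_conformations, default_reference_table
from smbjdna.generator import apply_environment, simulate_ensemble
from smbjdna.histogram import (
    PeakInitializationError,
    PeakSet,
    build_histogram,
    fit_gaussian_peaks,
    g0_to_microsiemens,
    make_edges,
    summarize_repeats,
)
from smbjdna.screening import screen_ensemble

__all__ = ["PipelineStageError", "run_pipeline", "derive_repeat_seeds"]

logger = logging.getLogger("smbjdna")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def derive_repeat_seeds(master_seed: int, n: int) -> List[int]:
    """Deterministic per-repeat seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _timed(stage: str, fn, *args, **kwargs):
    start = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:  # surfaced with the stage name
        raise PipelineStageError(stage, exc) from exc
    logger.info("stage %s: %.2f s", stage, time.perf_counter() - start)
    return out


def _peak_row(peak, label: Optional[str]) -> Dict:
    row = {
        "mu_log": round(peak.mu_log, 6),
        "sigma_log": round(peak.sigma_log, 6),
        "amplitude": round(peak.amplitude, 3),
        "conductance_g0": float(f"{peak.conductance_g0:.6g}"),
        "microsiemens": float(f"{g0_to_microsiemens(peak.conductance_g0):.6g}"),
    }
    if label is not None:
        row["conformation"] = label
    return row


def run_pipeline(config: RunConfig, seed: Optional[int] = None) -> Dict:
    """Run the full analysis for ``config.repeats`` independent measurements.

    Each repeat simulates ``config.n_traces`` traces from the configured
    mixture, screens them, builds the composite histogram and fits
    ``config.fit.k`` Gaussian peaks.  Peaks are labelled against the default
    conformation reference table and summarised across repeats.  A repeat
    in which no peak can be fit (for example a KCl run where no species
    forms junctions) is reported as ``peaks: []`` rather than raising.
    """
    if config.mixture is None:
        raise PipelineStageError("configure", ValueError("run config has no [mixture]"))
    master_seed = config.seed if seed is None else seed
    mixture = _timed("environment", apply_environment, config.mixture)
    edges = make_edges(*config.screening.window, config.screening.bins_per_decade)
    table = default_reference_table()

    repeat_seeds = derive_repeat_seeds(master_seed, config.repeats)
    repeats_out: List[Dict] = []
    peaksets: List[PeakSet] = []
    for i, rep_seed in enumerate(repeat_seeds):
        traces = _timed(
            f"simulate[{i}]", simulate_ensemble, config.n_traces, mixture,
            config.generator, rep_seed,
        )
        selected, fraction, _ = _timed(f"screen[{i}]", screen_ensemble, traces, config.screening)
        logger.info("repeat %d: selection fraction %.3f", i, fraction)
        hist = _timed(f"histogram[{i}]", build_histogram, selected, edges)
        rep: Dict = {
            "seed": rep_seed,
            "n_traces": config.n_traces,
            "n_selected": len(selected),
            "selection_fraction": round(fraction, 6),
        }
        try:
            peaks = fit_gaussian_peaks(
                hist,
                config.fit.k,
                poisson_weighted=config.fit.poisson_weighted,
                baseline=config.fit.baseline,
            )
            labels = assign_conformations(peaks, table)
            rep["peaks"] = [_peak_row(p, l) for p, l in zip(peaks, labels)]
            peaksets.append(peaks)
        except (PeakInitializationError, ValueError) as exc:
            rep["peaks"] = []
            rep["message"] = f"no peaks: {exc}"
        repeats_out.append(rep)

    report: Dict = {
        "seed": master_seed,
        "environment": mixture.environment.name,
        "species": [sp.name for sp in mixture.species],
        "repeats": repeats_out,
    }
    if peaksets and len({len(ps) for ps in peaksets}) == 1 and len(peaksets) == len(repeat_seeds):
        summary = summarize_repeats(peaksets)
        report["peak_summary"] = [
            {
                "mean_g0": float(f"{m:.6g}"),
                "std_g0": float(f"{s:.6g}"),
                "mean_microsiemens": float(f"{g0_to_microsiemens(m):.6g}"),
                "n_repeats": summary.n_repeats,
            }
            for m, s in zip(summary.mean_g0, summary.std_g0)
        ]
    else:
        report["peak_summary"] = []
        if not peaksets:
            report["message"] = "no peaks"
    return report


def report_to_json(report: Dict) -> str:
    """Stable serialisation of a pipeline report."""
    return json.dumps(report, indent=2, sort_keys=False)
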