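"""Composite semi-log conductance histograms and Gaussian peak fitting.

All selected traces are added together, sample by sample, into one
histogram over log10(G/G0).  Peaks are fit as a sum of Gaussians *in log
scale*; a fitted centre ``mu_log`` corresponds to the most probable
junction conductance ``10**mu_log`` G0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from smbjdna.generator import Trace
from smbjdna.units import CONDUCTANCE_QUANTUM_S

__all__ = [
    "ConductanceHistogram",
    "GaussianPeak",
    "PeakSet",
    "PeakInitializationError",
    "RunSummary",
    "make_edges",
    "build_histogram",
    "fit_gaussian_peaks",
    "peak_presence_threshold",
    "summarize_repeats",
    "g0_to_microsiemens",
]

#: Minimum separation (decades) between initial peak guesses.
MIN_PEAK_SEPARATION = 0.5


class PeakInitializationError(ValueError):
    """Fewer separable local maxima than requested peaks."""


def make_edges(low: float = -5.5, high: float = -1.0, bins_per_decade: int = 40) -> np.ndarray:
    """Half-open bin edges over log10(G/G0), width ``1/bins_per_decade``."""
    n_bins = int(round((high - low) * bins_per_decade))
    if n_bins < 1:
        raise ValueError("empty histogram window")
    return low + np.arange(n_bins + 1) / bins_per_decade


@dataclass(frozen=True)
class ConductanceHistogram:
    """Composite counts over log10(G/G0) bins from all selected traces."""

    edges: np.ndarray
    counts: np.ndarray
    n_traces: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
        if counts.shape != (edges.size - 1,):
            raise ValueError("counts length must be len(edges) - 1")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted Gaussian peak of the log-conductance histogram."""

    mu_log: float
    sigma_log: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    @property
    def conductance_g0(self) -> float:
        """Most probable conductance, G/G0."""
        return 10.0 ** self.mu_log


@dataclass(frozen=True)
class PeakSet:
    """Fitted peaks sorted by ascending centre, with convergence status."""

    peaks: tuple
    converged: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]


@dataclass(frozen=True)
class RunSummary:
    """Repeat statistics of matched peak positions.

    ``positions_g0[i][j]`` is the conductance (G0) of matched peak ``i`` in
    repeat ``j``; means and sample standard deviations are per matched peak,
    on the linear G0 scale.
    """

    positions_g0: tuple
    mean_g0: tuple
    std_g0: tuple
    n_repeats: int


def _multi_gaussian(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        amp, mu, sigma = params[i : i + 3]
        y = y + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return y


def build_histogram(traces: Sequence[Trace], edges: np.ndarray) -> ConductanceHistogram:
    """Sum per-sample bin assignments of the selected traces.

    Bins are half-open ``[edge_i, edge_{i+1})``; samples outside the edge
    range are ignored.  The count total therefore equals the number of
    in-window samples across the traces (count conservation).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for t in traces:
        y = t.log_conductance
        y = y[(y >= edges[0]) & (y < edges[-1])]
        c, _ = np.histogram(y, bins=edges)
        counts += c
    return ConductanceHistogram(edges=edges, counts=counts, n_traces=len(traces))


def _initial_guesses(centers: np.ndarray, counts: np.ndarray, k: int):
    """Pick the k most prominent local maxima separated by >= 0.5 decades."""
    smooth = counts.astype(float)
    if smooth.size >= 5:
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(smooth, kernel, mode="same")
    maxima, _ = signal.find_peaks(smooth)
    order = maxima[np.argsort(smooth[maxima])[::-1]]
    chosen: List[int] = []
    for idx in order:
        if smooth[idx] <= 0:
            break
        if all(abs(centers[idx] - centers[j]) >= MIN_PEAK_SEPARATION for j in chosen):
            chosen.append(int(idx))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise PeakInitializationError("initialization failed; reduce k")
    return sorted(chosen, key=lambda i: centers[i])


def fit_gaussian_peaks(
    hist: ConductanceHistogram,
    k: int = 1,
    *,
    poisson_weighted: bool = False,
    baseline: bool = True,
    init: Optional[Sequence] = None,
) -> PeakSet:
    """Nonlinear least squares of a sum of ``k`` Gaussians to the histogram.

    The fit is performed in (bin centre, count) space.  Initial centres are
    the ``k`` most prominent local maxima separated by at least 0.5 decades.
    By default the objective is unweighted least squares on counts;
    ``poisson_weighted=True`` weights each bin by ``1/sqrt(max(count, 1))``.

    A constant offset term is included by default: selected traces carry
    their tunneling-decay segments into the histogram, which deposit a
    nearly flat pedestal across the window; without the offset a Gaussian
    broadens to absorb that pedestal and its centre is biased.  Amplitudes
    are therefore peak heights *above* the pedestal.  ``baseline=False``
    drops the offset (appropriate for pedestal-free histograms).

    ``init`` optionally supplies explicit ``(amplitude, mu_log, sigma_log)``
    triples (one per peak) in place of the automatic initialisation.

    Returns the peaks sorted by ascending centre; ``converged`` reports
    whether the optimiser succeeded (on failure the initial guesses are not
    returned -- an exception propagates instead).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if int(np.count_nonzero(hist.counts)) < 3 * k:
        raise ValueError(f"histogram has fewer than {3 * k} nonempty bins")
    centers = hist.bin_centers
    counts = hist.counts.astype(float)
    bin_width = float(np.mean(np.diff(hist.edges)))
    span = centers[-1] - centers[0]
    if init is not None:
        if len(init) != k:
            raise ValueError("init must supply one (amplitude, mu, sigma) triple per peak")
        guesses = [(float(a), float(m), float(s)) for a, m, s in init]
    else:
        guess_idx = _initial_guesses(centers, counts, k)
        guesses = [(max(counts[i], 1.0), float(centers[i]), 0.15) for i in guess_idx]

    p0, lower, upper = [], [], []
    for amp, mu, sig in guesses:
        p0 += [amp, mu, sig]
        lower += [0.0, centers[0] - span, bin_width / 2.0]
        upper += [np.inf, centers[-1] + span, 2.0 * span]
    if baseline:
        p0.append(float(np.median(counts)))
        lower.append(0.0)
        upper.append(np.inf)

    def model(x, *params):
        if baseline:
            return _multi_gaussian(x, *params[:-1]) + params[-1]
        return _multi_gaussian(x, *params)

    sigma = np.sqrt(np.maximum(counts, 1.0)) if poisson_weighted else None
    popt, _ = curve_fit(
        model,
        centers,
        counts,
        p0=p0,
        sigma=sigma,
        bounds=(lower, upper),
        maxfev=20_000,
    )
    peaks = []
    for i in range(k):
        amp, mu, sig = popt[3 * i : 3 * i + 3]
        peaks.append(GaussianPeak(mu_log=float(mu), sigma_log=float(sig), amplitude=float(amp)))
    peaks.sort(key=lambda p: p.mu_log)
    return PeakSet(peaks=tuple(peaks), converged=True)


def peak_presence_threshold(hist: ConductanceHistogram) -> float:
    """Minimum fitted amplitude for a peak to count as detected.

    A peak is "present" when its fitted height above the pedestal exceeds
    five times the Poisson counting noise of a typical bin (the median
    nonzero bin count is dominated by the tunneling pedestal, so its square
    root estimates the per-bin shot noise).  This guards the titration
    detection logic against fitting noise bumps.
    """
    nonzero = hist.counts[hist.counts > 0]
    if nonzero.size == 0:
        return np.inf
    return 5.0 * float(np.sqrt(np.median(nonzero)))


def summarize_repeats(repeats: Sequence[PeakSet]) -> RunSummary:
    """Mean and sample standard deviation of peak positions across repeats.

    Peaks are matched one-to-one across repeats by nearest ``mu_log``; for
    one-dimensional positions this is the order-preserving matching of the
    sorted peak lists, so every repeat must contain the same number of
    peaks.
    """
    if not repeats:
        raise ValueError("need at least one repeat")
    ks = {len(ps) for ps in repeats}
    if len(ks) != 1:
        raise ValueError("peaks cannot be matched one-to-one across repeats")
    k = ks.pop()
    positions = []
    means = []
    stds = []
    for i in range(k):
        g = np.array([ps[i].conductance_g0 for ps in repeats])
        positions.append(tuple(float(v) for v in g))
        means.append(float(g.mean()))
        stds.append(float(g.std(ddof=1)) if g.size > 1 else 0.0)
    return RunSummary(
        positions_g0=tuple(positions),
        mean_g0=tuple(means),
        std_g0=tuple(stds),
        n_repeats=len(repeats),
    )


def g0_to_microsiemens(value: float) -> float:
    """Convert a conductance in G/G0 units to microsiemens.

    Uses the conductance quantum ``G0 = 2 e^2 / h`` computed from physical
    constants (~77.48 uS).
    """
    if value < 0:
        raise ValueError("conductance must be >= 0")
    return value * CONDUCTANCE_QUANTUM_S * 1e6
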