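# smbjdna

Single-molecule break-junction (SMBJ) conductance analysis for DNA
conformation sensing.

## The problem

Guanine-rich DNA sequences coexist in solution as B-form duplexes and
G-quadruplexes. In an SMBJ experiment a gold STM tip is driven into a gold
substrate and retracted (~80 nm/s) while the current is recorded at fixed
bias; when a thiolated DNA molecule bridges the closing gap the
conductance–distance trace holds a plateau instead of decaying
exponentially. Accumulating the samples of thousands of screened traces
into a histogram over log10(G/G0) (G0 = 2e²/h ≈ 77.48 µS) reveals the most
probable junction conductance of each species. The two conformations
differ by roughly an order of magnitude — duplexes near a few 10⁻⁴ G0,
quadruplexes near a few 10⁻³ G0 — so peak positions identify conformations
and peak amplitudes track their relative abundance, down to extreme
minority fractions.

`smbjdna` implements that analysis chain for anyone who wants to study,
teach or stress-test it without an instrument:

* a **seeded synthetic trace generator** — exponential tunneling decays
  (slope −β decades/nm), species-specific plateaus with between-trace
  spread, a 10 pA noise floor, junction formation in a configurable
  fraction of events, a compressive concentration→capture model, and a KCl
  environment switch that flips antiparallel quadruplexes to the
  junction-incompetent parallel topology;
* the **two-criterion trace filter**: reject traces whose semi-log line
  fit has an RMS residual below threshold (pure tunneling), then require a
  spike in the per-trace log-conductance histogram (a plateau);
* **composite histogramming and Gaussian peak fitting** in log scale, with
  repeat statistics (mean ± sample SD of peak positions);
* **conformation assignment** against reference conductances and the
  **titration experiment**: peak-amplitude ratio versus quadruplex:duplex
  concentration ratio across ~16 orders of magnitude.

## Worked example

```python
from smbjdna import (GeneratorConfig, default_mixture, simulate_ensemble,
                     screen_ensemble, build_histogram, fit_gaussian_peaks,
                     make_edges, assign_conformations, default_reference_table,
                     g0_to_microsiemens)

config = GeneratorConfig()
traces = simulate_ensemble(5000, default_mixture(), config, seed=1)
selected, fraction, _ = screen_ensemble(traces)
print(f"selected {len(selected)}/5000 traces ({100 * fraction:.1f}%)")

hist = build_histogram(selected, make_edges())
peaks = fit_gaussian_peaks(hist, k=2)
labels = assign_conformations(peaks, default_reference_table())
for peak, label in zip(peaks, labels):
    print(f"{label:13s}  {peak.conductance_g0:.2e} G0  "
          f"({g0_to_microsiemens(peak.conductance_g0):.3f} uS, "
          f"width {peak.sigma_log:.2f} decades)")
```

prints

```
selected 624/5000 traces (12.5%)
duplex         2.94e-04 G0  (0.023 uS, width 0.16 decades)
G-quadruplex   3.65e-03 G0  (0.283 uS, width 0.15 decades)
```

12.5% of the simulated retraction events formed a junction and survived
both screening criteria — the selection fraction typical of these
measurements. The two fitted peaks recover the generator's plateau levels
(3.03 × 10⁻⁴ and 3.77 × 10⁻³ G0) to well within one peak width and are
labelled with the conformation whose reference conductance they match.

The same chain is available from a shell via the `smbjdna` CLI
(`simulate`, `screen`, `hist`, `fit`, `titrate`, `report`), driven by a
TOML run config and a master seed; see `smbjdna --help`.

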