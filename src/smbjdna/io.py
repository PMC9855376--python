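"""Trace container file format (``smbj-traces/1``).

One file per ensemble.  Header lines prefixed ``#`` carry ``key=value``
metadata (the first must declare ``format=smbj-traces/1``); then blocks,
one per trace, each beginning ``TRACE <id> [label=<name>]`` followed by
two-column rows ``distance_nm<TAB>conductance_g0``.  UTF-8, ``.`` decimal
separator.  Serialization is deterministic -- stable metadata ordering and
9-significant-digit numeric formatting -- so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from smbjdna.generator import Trace

__all__ = ["FORMAT_VERSION", "write_traceset", "load_traceset", "TracesetFormatError"]

FORMAT_VERSION = "smbj-traces/1"

_REQUIRED_META = ("bias_V", "sampling_rate_hz", "retraction_rate_nm_s")


class TracesetFormatError(ValueError):
    """Malformed trace container file."""


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def write_traceset(
    traces: Sequence[Trace], metadata: Dict[str, object], path
) -> None:
    """Write an ensemble to ``path`` in the ``smbj-traces/1`` format.

    ``bias_V``, ``sampling_rate_hz`` and ``retraction_rate_nm_s`` are taken
    from the first trace when not supplied in ``metadata``.  Metadata keys
    after ``format`` are written in sorted order.
    """
    meta = dict(metadata)
    meta.setdefault("format", FORMAT_VERSION)
    if meta["format"] != FORMAT_VERSION:
        raise TracesetFormatError(f"unsupported format version {meta['format']!r}")
    if traces:
        first = traces[0]
        meta.setdefault("bias_V", _fmt(first.bias))
        meta.setdefault("sampling_rate_hz", _fmt(first.sampling_rate))
        meta.setdefault("retraction_rate_nm_s", _fmt(first.retraction_rate))
    lines: List[str] = [f"# format={FORMAT_VERSION}"]
    for key in sorted(k for k in meta if k != "format"):
        lines.append(f"# {key}={meta[key]}")
    for i, trace in enumerate(traces):
        header = f"TRACE {i}"
        if trace.label is not None:
            header += f" label={trace.label}"
        lines.append(header)
        for d, g in zip(trace.distance, trace.conductance):
            lines.append(f"{_fmt(d)}\t{_fmt(g)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_traceset(path) -> Tuple[List[Trace], Dict[str, str]]:
    """Read an ensemble written by :func:`write_traceset`.

    Returns ``(traces, metadata)``.  Malformed rows are reported with their
    1-based line numbers.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()

    meta: Dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        body = lines[i][1:].strip()
        if "=" not in body:
            raise TracesetFormatError(f"line {i + 1}: metadata line without '='")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
        i += 1

    if meta.get("format") != FORMAT_VERSION:
        raise TracesetFormatError(
            f"missing or unknown format version (expected {FORMAT_VERSION!r}, "
            f"got {meta.get('format')!r})"
        )

    bias = float(meta.get("bias_V", "nan"))
    fs = float(meta.get("sampling_rate_hz", "nan"))
    v = float(meta.get("retraction_rate_nm_s", "nan"))

    traces: List[Trace] = []
    cur_label = None
    cur_d: List[float] = []
    cur_g: List[float] = []
    cur_line = 0

    def flush() -> None:
        if cur_line == 0:
            return
        if not cur_d:
            raise TracesetFormatError(f"line {cur_line}: trace block with no samples")
        traces.append(
            Trace(
                distance=np.array(cur_d),
                conductance=np.array(cur_g),
                bias=bias,
                sampling_rate=fs,
                retraction_rate=v,
                label=cur_label,
            )
        )

    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if line.startswith("TRACE"):
            flush()
            cur_d, cur_g = [], []
            cur_line = i + 1
            parts = line.split()
            cur_label = None
            for part in parts[2:]:
                if part.startswith("label="):
                    cur_label = part[len("label="):]
        else:
            fields = line.split("\t")
            if len(fields) != 2:
                raise TracesetFormatError(
                    f"line {i + 1}: expected two tab-separated columns"
                )
            try:
                cur_d.append(float(fields[0]))
                cur_g.append(float(fields[1]))
            except ValueError as exc:
                raise TracesetFormatError(f"line {i + 1}: non-numeric row") from exc
        i += 1
    flush()
    return traces, meta
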