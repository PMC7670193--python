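"""CSV I/O for process traces.

The on-disk schema is a plain CSV with header columns ``time_s, Ts_K,
Tb_K, Pc_cap_Pa, Pc_pir_Pa``; extra columns are preserved on passthrough.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import TraceError
from .rp_estimation import ProcessTrace, TRACE_COLUMNS

__all__ = ["read_trace", "write_trace"]


def read_trace(path: str | Path) -> ProcessTrace:
    """Read and validate a process-trace CSV."""
    path = Path(path)
    if not path.exists():
        raise TraceError(f"trace file not found: {path}")
    data = pd.read_csv(path)
    return ProcessTrace(data=data, metadata={"source": str(path)})


def write_trace(trace: ProcessTrace, path: str | Path) -> None:
    """Write a process trace to CSV (full float precision)."""
    ordered = list(TRACE_COLUMNS) + [
        c for c in trace.data.columns if c not in TRACE_COLUMNS
    ]
    trace.data[ordered].to_csv(path, index=False, float_format="%.12g")
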