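"""CSV input/output for strain traces, valve events and cohort tables.

All files are plain UTF-8 CSV with a header row; ``#``-prefixed metadata
lines (seed, config hash, package version) may precede the header and
are ignored on read.  Formats:

* strain traces, long format: ``subject_id, segment_id, time_s, strain_pct``
* valve events: ``subject_id, t_mvc_s, t_avo_s, t_avc_s, t_mvo_s``
* cohort table: ``subject_id, group`` plus covariate and outcome columns
  (cuff pressure lives here as ``sbp_mmhg`` / ``dbp_mmhg``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pressure import ValveEvents
from .work import StrainTrace

__all__ = [
    "write_table",
    "read_table",
    "traces_to_frame",
    "frame_to_traces",
    "events_to_frame",
    "frame_to_events",
]

_FLOAT_FMT = "%.10g"


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> Path:
    """Write a table as CSV with optional ``#`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV table, skipping ``#`` metadata lines."""
    return pd.read_csv(path, comment="#")


def traces_to_frame(traces_by_subject: Mapping[str, list[StrainTrace]]) -> pd.DataFrame:
    """Long-format frame of all subjects' segmental strain traces."""
    parts = []
    for sid, traces in traces_by_subject.items():
        for tr in traces:
            parts.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "segment_id": tr.segment_id,
                        "time_s": tr.times,
                        "strain_pct": tr.strain,
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> dict[str, list[StrainTrace]]:
    """Group a long-format strain table back into per-subject trace lists."""
    out: dict[str, list[StrainTrace]] = {}
    for (sid, seg), grp in df.groupby(["subject_id", "segment_id"], sort=True):
        grp = grp.sort_values("time_s")
        out.setdefault(str(sid), []).append(
            StrainTrace(
                segment_id=int(seg),
                times=np.asarray(grp["time_s"], dtype=float),
                strain=np.asarray(grp["strain_pct"], dtype=float),
            )
        )
    return out


def events_to_frame(events_by_subject: Mapping[str, ValveEvents]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": sid,
                "t_mvc_s": ev.t_mvc,
                "t_avo_s": ev.t_avo,
                "t_avc_s": ev.t_avc,
                "t_mvo_s": ev.t_mvo,
            }
            for sid, ev in events_by_subject.items()
        ]
    )


def frame_to_events(df: pd.DataFrame) -> dict[str, ValveEvents]:
    return {
        str(row.subject_id): ValveEvents(
            float(row.t_mvc_s), float(row.t_avo_s), float(row.t_avc_s),
            float(row.t_mvo_s)
        )
        for row in df.itertuples(index=False)
    }
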