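"""CSV dialects for sources, measurement sequences, and reports.

All interchange is plain CSV with explicit headers; data volumes in this
domain are tiny and inspectability matters.

* Source CSV: ``source_id, role, A64, A66, A67, A68, A70`` (percent).
* Sequence CSV: ``time, kind, sample_id, R64, R66, R68, R70`` (raw 67:xx
  ratios).
* Paired CSV: ``sample_id, value_a, value_b``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .calibration import BracketingSequence, SequenceEvent
from .compare import BlandAltmanResult
from .core import AbundanceVector, RatioSet
from .errors import ConfigError

_SOURCE_COLS = ["source_id", "role", "A64", "A66", "A67", "A68", "A70"]
_SEQ_COLS = ["time", "kind", "sample_id", "R64", "R66", "R68", "R70"]


def write_sources_csv(
    path: str | Path,
    sources: Mapping[str, AbundanceVector],
    roles: Mapping[str, str] | None = None,
) -> None:
    rows = []
    for sid, av in sources.items():
        row = {"source_id": sid, "role": (roles or {}).get(sid, "")}
        for m in (64, 66, 67, 68, 70):
            row[f"A{m}"] = av[m]
        rows.append(row)
    pd.DataFrame(rows, columns=_SOURCE_COLS).to_csv(path, index=False)


def read_sources_csv(path: str | Path) -> tuple[dict[str, AbundanceVector], dict[str, str]]:
    df = pd.read_csv(path)
    missing = set(_SOURCE_COLS) - set(df.columns)
    if missing:
        raise ConfigError(f"source CSV missing columns {sorted(missing)}")
    sources, roles = {}, {}
    for _, row in df.iterrows():
        sid = str(row["source_id"])
        sources[sid] = AbundanceVector(
            {m: float(row[f"A{m}"]) for m in (64, 66, 67, 68, 70)}
        )
        roles[sid] = str(row["role"])
    return sources, roles


def sequence_to_frame(seq: BracketingSequence) -> pd.DataFrame:
    rows = []
    for ev in seq.events:
        row = {"time": ev.time, "kind": ev.kind, "sample_id": ev.sample_id}
        for m in (64, 66, 68, 70):
            row[f"R{m}"] = ev.ratios[m]
        rows.append(row)
    return pd.DataFrame(rows, columns=_SEQ_COLS)


def write_sequence_csv(path: str | Path, seq: BracketingSequence) -> None:
    sequence_to_frame(seq).to_csv(path, index=False)


def read_sequence_csv(
    path: str | Path, standard_true: AbundanceVector
) -> BracketingSequence:
    df = pd.read_csv(path)
    missing = set(_SEQ_COLS) - set(df.columns)
    if missing:
        raise ConfigError(f"sequence CSV missing columns {sorted(missing)}")
    events = []
    for _, row in df.iterrows():
        events.append(
            SequenceEvent(
                time=float(row["time"]),
                kind=str(row["kind"]),
                sample_id=str(row["sample_id"]),
                ratios=RatioSet({m: float(row[f"R{m}"]) for m in (64, 66, 68, 70)}),
            )
        )
    return BracketingSequence(events=events, standard_true=standard_true)


def bland_altman_frame(result: BlandAltmanResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bias": result.bias,
                "sd": result.sd,
                "loa_low": result.loa_low,
                "loa_high": result.loa_high,
                "n": result.n,
                "k": result.k,
                "shapiro_p": result.shapiro_p,
            }
        ]
    )
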