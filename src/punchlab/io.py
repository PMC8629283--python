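"""CSV readers/writers for sensor streams and punch-event tables.

Every file written here carries a header comment with the seed and a config
hash, so any table can be traced back to the run that produced it; readers
skip ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import CHANNEL_NAMES, ForceCurve, ImuSegment

STREAM_COLUMNS = ("time_s", *CHANNEL_NAMES, "pad_force_N")


def config_hash(config_obj) -> str:
    """Short stable hash of a JSON-serializable config object."""
    payload = json.dumps(config_obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(seed=None, cfg_hash=None) -> str:
    parts = []
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config_sha={cfg_hash}")
    return f"# {' '.join(parts)}\n" if parts else ""


def write_stream_csv(
    path,
    segment: ImuSegment,
    force: ForceCurve,
    *,
    seed=None,
    cfg_hash=None,
) -> None:
    """Write a combined IMU + pad-force stream as CSV.

    Columns: ``time_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps, pad_force_N``.
    """
    n = min(segment.n_samples, force.force.size)
    df = pd.DataFrame(
        np.column_stack(
            [segment.times[:n], segment.channels[:, :n].T, force.force[:n]]
        ),
        columns=STREAM_COLUMNS,
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_stream_csv(path, hand: str = "right") -> tuple[ImuSegment, ForceCurve]:
    """Read a stream CSV back into an IMU segment and a force curve."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in STREAM_COLUMNS if c not in df]
    if missing:
        raise ValueError(f"stream CSV lacks columns {missing}")
    times = df["time_s"].to_numpy()
    if times.size < 2:
        raise ValueError("stream CSV needs at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(times)))
    channels = df[list(CHANNEL_NAMES)].to_numpy().T
    segment = ImuSegment(
        rate=rate, channels=channels, hand=hand, start_time=float(times[0])
    )
    force = ForceCurve(
        rate=rate,
        force=np.clip(df["pad_force_N"].to_numpy(), 0.0, None),
        start_time=float(times[0]),
    )
    return segment, force


def write_table_csv(path, df: pd.DataFrame, *, seed=None, cfg_hash=None) -> None:
    """Write any result table with the provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
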