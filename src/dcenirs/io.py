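"""File interchange: CSV (default) and HDF5 containers.

There is no standard on-disk format for DTOF stacks, so two documented
dialects are provided:

* CSV: a ``# key=value`` comment header (bin_width_ns, t_start_ns) followed by
  one frame per row, first column the frame time in seconds;
* HDF5: datasets ``counts`` (frames x bins) and ``frame_times_s``, with
  ``bin_width_ns`` and ``t_start_ns`` as attributes.

Concentration and absorption curves are CSV with unit-bearing headers
(``time_s,value,unit``); study tables are plain CSV; ground truth rides in
sidecar JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dtof import DTOF, DTOFStack, ConcentrationCurve, InputError


def write_stack_csv(stack: DTOFStack, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# bin_width_ns={stack.bin_width_ns!r}\n")
        fh.write(f"# t_start_ns={stack.t_start_ns!r}\n")
        for t, row in zip(stack.frame_times_s, stack.counts):
            fh.write(",".join([repr(float(t))] + [repr(float(c)) for c in row]) + "\n")


def read_stack_csv(path) -> DTOFStack:
    path = Path(path)
    meta = {}
    times, rows = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = float(val)
                continue
            parts = line.split(",")
            times.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    if "bin_width_ns" not in meta:
        raise InputError(f"{path}: missing '# bin_width_ns=' header")
    return DTOFStack(np.asarray(rows), meta["bin_width_ns"], np.asarray(times),
                     meta.get("t_start_ns", 0.0))


def write_stack_h5(stack: DTOFStack, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=stack.counts)
        f.create_dataset("frame_times_s", data=stack.frame_times_s)
        f.attrs["bin_width_ns"] = stack.bin_width_ns
        f.attrs["t_start_ns"] = stack.t_start_ns


def read_stack_h5(path) -> DTOFStack:
    import h5py

    with h5py.File(path, "r") as f:
        return DTOFStack(
            f["counts"][...], float(f.attrs["bin_width_ns"]),
            f["frame_times_s"][...], float(f.attrs["t_start_ns"]),
        )


def write_irf_csv(irf: DTOF, path) -> None:
    df = pd.DataFrame({"time_ns": irf.bin_centers_ns, "counts": irf.counts})
    df.to_csv(path, index=False)


def read_irf_csv(path) -> DTOF:
    df = pd.read_csv(path)
    if len(df) < 2:
        raise InputError(f"{path}: IRF needs at least two bins")
    widths = np.diff(df["time_ns"].to_numpy())
    return DTOF(df["counts"].to_numpy(), float(widths[0]),
                float(df["time_ns"].iloc[0]), role="IRF")


def write_curve_csv(curve: ConcentrationCurve, path) -> None:
    pd.DataFrame(
        {"time_s": curve.times_s, "value": curve.values_um, "unit": "uM",
         "role": curve.role}
    ).to_csv(path, index=False)


def read_curve_csv(path, role: str | None = None) -> ConcentrationCurve:
    df = pd.read_csv(path)
    role = role or (df["role"].iloc[0] if "role" in df else "arterial")
    return ConcentrationCurve(df["time_s"].to_numpy(), df["value"].to_numpy(), role)


def write_study_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_study_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"day": str})


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, allow_nan=True) + "\n")
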