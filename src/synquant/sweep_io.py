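"""Tabular sweep I/O: one CSV per sweep plus a JSON protocol descriptor.

Vendor formats (ABF, NWB) are out of scope; an adapter only needs to
produce, per sweep, a ``time_s,signal`` CSV and an entry in the protocol
descriptor:

.. code-block:: json

    {"sampling_rate_hz": 50000.0,
     "sweeps": [{"file": "tc.csv", "label": "tc", "role": "tc",
                 "step": {"onset_s": 0.1, "duration_s": 0.5, "amplitude": -66.7}},
                {"file": "ppr0.csv", "label": "ppr0", "role": "ppr",
                 "stim_times_s": [0.1, 0.15]}]}

``role`` groups sweeps into the protocol slots used by
:func:`synquant.ephys.compute_intrinsic_properties` (``rmp``, ``tc``,
``ir``, ``sag``, ``ff``) or marks paired-pulse sweeps (``ppr``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from synquant.ephys import StepStimulus, Sweep


def write_sweeps(
    directory: str | Path,
    sweeps: dict[str, Sweep | list[Sweep]],
    ppr_sweeps: list[Sweep] | None = None,
) -> Path:
    """Write labeled sweeps as CSVs + ``protocol.json``; returns the JSON path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    rate = None

    def emit(sw: Sweep, role: str) -> None:
        nonlocal rate
        rate = sw.sampling_rate
        fname = f"{sw.label or role}.csv"
        pd.DataFrame({"time_s": sw.time, "signal": sw.signal}).to_csv(
            directory / fname, index=False
        )
        entry: dict = {"file": fname, "label": sw.label or role, "role": role}
        if sw.stimulus is not None:
            entry["step"] = {
                "onset_s": sw.stimulus.onset,
                "duration_s": sw.stimulus.duration,
                "amplitude": sw.stimulus.amplitude,
            }
        if sw.stim_times:
            entry["stim_times_s"] = list(sw.stim_times)
        entries.append(entry)

    for role, value in sweeps.items():
        for sw in value if isinstance(value, list) else [value]:
            emit(sw, role)
    for sw in ppr_sweeps or []:
        emit(sw, "ppr")

    proto_path = directory / "protocol.json"
    proto_path.write_text(
        json.dumps({"sampling_rate_hz": rate, "sweeps": entries}, indent=1)
    )
    return proto_path


def read_sweeps(
    protocol_path: str | Path,
) -> tuple[dict[str, Sweep | list[Sweep]], list[Sweep]]:
    """Read a protocol descriptor back into labeled sweeps.

    Returns ``(intrinsic_sweeps, ppr_sweeps)`` where the first maps protocol
    roles to a Sweep (``rmp``/``tc``/``sag``) or list of Sweeps
    (``ir``/``ff``).
    """
    protocol_path = Path(protocol_path)
    proto = json.loads(protocol_path.read_text())
    rate = float(proto["sampling_rate_hz"])
    grouped: dict[str, list[Sweep]] = {}
    for entry in proto["sweeps"]:
        df = pd.read_csv(protocol_path.parent / entry["file"])
        stim = None
        if "step" in entry:
            s = entry["step"]
            stim = StepStimulus(s["onset_s"], s["duration_s"], s["amplitude"])
        sw = Sweep(
            time=df["time_s"].to_numpy(),
            signal=df["signal"].to_numpy(),
            sampling_rate=rate,
            stimulus=stim,
            stim_times=list(entry.get("stim_times_s", [])),
            label=entry.get("label", ""),
        )
        grouped.setdefault(entry["role"], []).append(sw)

    ppr = grouped.pop("ppr", [])
    out: dict[str, Sweep | list[Sweep]] = {}
    for role, sws in grouped.items():
        out[role] = sws if role in ("ir", "ff") else sws[0]
    return out, ppr
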