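"""Plain-text readers and writers for every pipeline artifact.

Traces are one-column CSV with ``# key=value`` header comments carrying the
sampling rate and channel; event logs are ``onset_s,intensity_uA`` rows;
region tables, pairings and weighted edge lists are ordinary CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dyads import DyadPairing
from .exceptions import InputError
from .preprocess import RawTrace, StimulusEvent


def write_trace(path, trace: RawTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={trace.sampling_rate}\n")
        fh.write(f"# channel={trace.channel}\n")
        fh.write("value\n")
        np.savetxt(fh, trace.values, fmt="%.10g")


def read_trace(path) -> RawTrace:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        values = pd.read_csv(fh)["value"].to_numpy(dtype=float)
    if "sampling_rate_hz" not in meta:
        raise InputError(f"{path}: missing '# sampling_rate_hz=' header")
    return RawTrace(
        values=values,
        sampling_rate=float(meta["sampling_rate_hz"]),
        channel=meta.get("channel", "pupil"),
    )


def write_events(path, events) -> None:
    pd.DataFrame(
        {"onset_s": [e.onset for e in events], "intensity_uA": [e.intensity for e in events]}
    ).to_csv(path, index=False)


def read_events(path) -> list:
    df = pd.read_csv(path)
    return [
        StimulusEvent(onset=float(r.onset_s), intensity=float(r.intensity_uA))
        for r in df.itertuples()
    ]


def write_region_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_region_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pairing(path, pairing: DyadPairing) -> None:
    pd.DataFrame(pairing.pairs, columns=["obs_id", "dem_id"]).to_csv(path, index=False)


def read_pairing(path) -> DyadPairing:
    df = pd.read_csv(path)
    return DyadPairing(zip(df["obs_id"], df["dem_id"]))


def write_edge_list(path, edges) -> None:
    pd.DataFrame(edges, columns=["source", "target", "weight"]).to_csv(path, index=False)


def read_edge_list(path) -> list:
    df = pd.read_csv(path)
    return list(zip(df["source"], df["target"], df["weight"].astype(float)))


def read_region_list(path) -> list:
    """One region acronym per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
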