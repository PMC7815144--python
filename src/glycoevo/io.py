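"""CSV/JSON output writers and readers for simulation results.

Canonical outputs of a run, written into an output directory:

* ``tracks.csv`` — long-format tracked-cell time series (time, cell_id,
  FBP, ATP, Pi, V, H, H_max, Glc);
* ``population.csv`` — per-interval population summaries;
* ``events.csv`` — per-interval demographic event counts;
* ``run_meta.json`` — the fully resolved configuration, seed, package
  version and total event counts.

CSV files use the RFC-4180 dialect with '.' decimals and carry a leading
comment line naming the units (mM, min, L).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from glycoevo.engine import RunResult, TrackRecord

__all__ = ["write_outputs", "read_tracks", "tracks_frame"]

_TRACK_UNITS = ("# units: time min; FBP, ATP, Pi, Glc mM; V L; "
                "H, H_max dimensionless\n")
_POP_UNITS = ("# units: time min; Glc mM; vmax mM/min; k 1/min; "
              "N, counts dimensionless\n")


def tracks_frame(tracks: list[TrackRecord]) -> pd.DataFrame:
    """Concatenate track records into one long-format table."""
    if not tracks:
        return pd.DataFrame(columns=["time", "cell_id", "FBP", "ATP", "Pi",
                                     "V", "H", "H_max", "Glc"])
    frames = []
    for tr in tracks:
        df = tr.to_frame()
        df["H_max"] = tr.H_max if tr.H_max is not None else np.nan
        frames.append(df[["time", "cell_id", "FBP", "ATP", "Pi", "V", "H",
                          "H_max", "Glc"]])
    return pd.concat(frames, ignore_index=True)


def write_outputs(result: RunResult, outdir: str | Path,
                  config_dump: dict | None = None) -> dict[str, Path]:
    """Write the canonical CSV/JSON outputs of a run; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tracks_path = outdir / "tracks.csv"
    with open(tracks_path, "w", newline="") as fh:
        fh.write(_TRACK_UNITS)
        tracks_frame(result.tracks).to_csv(fh, index=False,
                                           float_format="%.17g")
    paths["tracks"] = tracks_path

    pop_path = outdir / "population.csv"
    pop_cols = ["time", "N", "Glc", "mean_vmax_up", "mean_vmax_lo",
                "mean_k_atp", "mean_k_p", "n_type1"]
    with open(pop_path, "w", newline="") as fh:
        fh.write(_POP_UNITS)
        result.summary[pop_cols].to_csv(fh, index=False)
    paths["population"] = pop_path

    events_path = outdir / "events.csv"
    with open(events_path, "w", newline="") as fh:
        fh.write("# units: time min; counts per demographic interval\n")
        result.summary[["time", "births", "deaths", "washouts"]].to_csv(
            fh, index=False)
    paths["events"] = events_path

    meta = {
        "status": result.status,
        "package_version": _version(),
        "final_N": int(result.population.N),
        "final_time": float(result.population.t),
        "totals": {
            "births": int(result.population.births),
            "deaths": int(result.population.deaths),
            "washouts": int(result.population.washouts),
        },
    }
    if result.env is not None:
        meta["environment"] = {
            "mode": result.env.mode, "V_ch": result.env.V_ch,
            "D": result.env.D, "d": result.env.d,
        }
    if config_dump is not None:
        meta["config"] = config_dump
        if "seed" in config_dump:
            meta["seed"] = config_dump["seed"]
    meta_path = outdir / "run_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["meta"] = meta_path
    return paths


def read_tracks(path: str | Path) -> list[TrackRecord]:
    """Read ``tracks.csv`` back into track records (exact round trip)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=True):
        tracks.append(TrackRecord(
            cell_id=int(cid),
            time=grp["time"].to_numpy(),
            FBP=grp["FBP"].to_numpy(),
            ATP=grp["ATP"].to_numpy(),
            Pi=grp["Pi"].to_numpy(),
            V=grp["V"].to_numpy(),
            H=grp["H"].to_numpy(),
            Glc=grp["Glc"].to_numpy(),
            H_max=grp["H_max"].to_numpy(),
        ))
    return tracks


def _version() -> str:
    from glycoevo import __version__

    return __version__
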