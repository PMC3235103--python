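"""Readers and writers for the plain-text assay formats.

All tables are TSV/CSV with an optional single ``#``-prefixed provenance
header line (config hash, seed, package version); readers skip comment
lines. Schemas:

- OD plate TSV: ``time_h`` then one column per well.
- flow events CSV: ``sample_id,event_id,fluorescence`` (long format).
- cell measurement TSV: ``cell_id,colony_id,ploidy,L_um,W_um``.
- competition TSV: ``replicate_id,day,T_generations,n_nonfluor,n_fluor``.
- evolution TSV: ``day,strain,frequency,diploid_fraction``.
- well map CSV: ``well_id,colony_id,ploidy[,generation]``.
- coverage TSV: ``chromosome,mapped_sites,ref_sites``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import CellMeasurement, CompetitionAssay, FlowSample, ODSeries

__all__ = [
    "write_table",
    "read_table",
    "write_od_plate",
    "read_od_plate",
    "write_flow_events",
    "read_flow_events",
    "write_cells",
    "read_cells",
    "write_competition",
    "read_competition",
    "read_well_map",
    "read_coverage",
]

_FLOAT_FMT = "%.10g"

PathLike = Union[str, Path]


def write_table(
    df: pd.DataFrame, path: PathLike, provenance: Optional[str] = None, sep: str = "\t"
) -> None:
    """Write a DataFrame with an optional one-line provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_table(path: PathLike, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_od_plate(
    path: PathLike, plate: Sequence[ODSeries], provenance: Optional[str] = None
) -> None:
    if not plate:
        raise ValueError("empty plate")
    times = plate[0].times
    for s in plate[1:]:
        if not np.array_equal(s.times, times):
            raise ValueError("all wells must share one time grid")
    df = pd.DataFrame({"time_h": times})
    for s in plate:
        df[s.well_id] = s.od
    write_table(df, path, provenance)


def read_od_plate(path: PathLike) -> list[ODSeries]:
    df = read_table(path)
    if "time_h" not in df.columns:
        raise ValueError("OD plate TSV needs a time_h column")
    t = df["time_h"].to_numpy(dtype=float)
    return [
        ODSeries(well_id=c, times=t, od=df[c].to_numpy(dtype=float))
        for c in df.columns
        if c != "time_h"
    ]


def write_flow_events(
    path: PathLike, samples: Sequence[FlowSample], provenance: Optional[str] = None
) -> None:
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "event_id": np.arange(s.events.size),
                    "fluorescence": s.events,
                }
            )
        )
    write_table(pd.concat(frames, ignore_index=True), path, provenance, sep=",")


def read_flow_events(path: PathLike, arrested: bool = False) -> list[FlowSample]:
    df = read_table(path, sep=",")
    if "fluorescence" not in df.columns:
        raise ValueError("flow CSV needs a fluorescence column")
    if "sample_id" not in df.columns:
        df["sample_id"] = "S1"
    return [
        FlowSample(sample_id=str(sid), events=g["fluorescence"].to_numpy(float), arrested=arrested)
        for sid, g in df.groupby("sample_id", sort=True)
    ]


def write_cells(
    path: PathLike, cells: Sequence[CellMeasurement], provenance: Optional[str] = None
) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "colony_id": [c.colony_id for c in cells],
            "ploidy": [c.ploidy for c in cells],
            "L_um": [c.L for c in cells],
            "W_um": [c.W for c in cells],
        }
    )
    write_table(df, path, provenance)


def read_cells(path: PathLike) -> list[CellMeasurement]:
    df = read_table(path)
    out = []
    for _, row in df.iterrows():
        ploidy = row.get("ploidy")
        if ploidy is not None and not (isinstance(ploidy, float) and math.isnan(ploidy)):
            ploidy = int(ploidy)
        else:
            ploidy = None
        out.append(
            CellMeasurement(
                cell_id=str(row["cell_id"]),
                colony_id=str(row["colony_id"]),
                ploidy=ploidy,
                L=float(row["L_um"]),
                W=float(row["W_um"]),
            )
        )
    return out


def write_competition(
    path: PathLike,
    assays: Sequence[CompetitionAssay],
    dilution: float = 101.0,
    provenance: Optional[str] = None,
) -> None:
    rows = []
    log2d = math.log2(dilution)
    for a in assays:
        for T, nn, nf in zip(a.T, a.n_nonfluor, a.n_fluor):
            rows.append(
                {
                    "replicate_id": a.replicate_id,
                    "day": T / log2d,
                    "T_generations": T,
                    "n_nonfluor": int(nn),
                    "n_fluor": int(nf),
                }
            )
    write_table(pd.DataFrame(rows), path, provenance)


def read_competition(path: PathLike, dilution: float = 101.0) -> list[CompetitionAssay]:
    df = read_table(path)
    if "replicate_id" not in df.columns:
        df["replicate_id"] = "R1"
    if "T_generations" not in df.columns:
        df["T_generations"] = df["day"].astype(float) * math.log2(dilution)
    out = []
    for rid, g in df.groupby("replicate_id", sort=True):
        g = g.sort_values("T_generations")
        out.append(
            CompetitionAssay(
                replicate_id=str(rid),
                T=g["T_generations"].to_numpy(float),
                n_nonfluor=g["n_nonfluor"].to_numpy(int),
                n_fluor=g["n_fluor"].to_numpy(int),
            )
        )
    return out


def read_well_map(path: PathLike) -> pd.DataFrame:
    df = read_table(path, sep=",")
    if "well_id" not in df.columns or "colony_id" not in df.columns:
        raise ValueError("well map needs well_id and colony_id columns")
    return df


def read_coverage(path: PathLike) -> pd.DataFrame:
    df = read_table(path)
    required = {"chromosome", "mapped_sites", "ref_sites"}
    if not required.issubset(df.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    return df
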