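"""Readers and writers for the plain-text formats the analysis consumes.

BED and bedGraph are 0-based half-open on disk and in memory. The pairs TSV
uses 1-based positions on disk (the convention of pairs-style Hi-C text
formats) and is converted to 0-based at this layer; missing arms/positions
(repeat-only alignments) are '.' and 0 on disk.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import Intervals

PAIRS_COLUMNS = [
    "read_id",
    "arm1", "pos1", "mapq1", "repeat1", "te1",
    "arm2", "pos2", "mapq2", "repeat2", "te2",
]


def read_bed(path) -> pd.DataFrame:
    """BED3+ -> DataFrame(arm, start, end[, name]). Comment lines ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "arm", 1: "start", 2: "end", 3: "name"})
    keep = [c for c in ("arm", "start", "end", "name") if c in df.columns]
    return df[keep]


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("arm", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> dict[str, pd.DataFrame]:
    """bedGraph -> per-arm DataFrame(start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["arm", "start", "end", "value"], dtype={"arm": str},
    )
    return {
        str(arm): g[["start", "end", "value"]].reset_index(drop=True)
        for arm, g in df.groupby("arm", sort=False)
    }


def write_bedgraph(tracks: Mapping[str, pd.DataFrame], path) -> None:
    frames = []
    for arm, df in tracks.items():
        out = df[["start", "end", "value"]].copy()
        out.insert(0, "arm", arm)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", header=False, index=False
    )


def intervals_to_bed(ivs: Mapping[str, Intervals]) -> pd.DataFrame:
    rows = [
        (arm, int(s), int(e))
        for arm, iv in ivs.items()
        for s, e in iv
    ]
    return pd.DataFrame(rows, columns=["arm", "start", "end"])


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    """Write a pairs table; positions converted to 1-based, missing ends '.'/0."""
    out = pairs[PAIRS_COLUMNS].copy()
    for i in (1, 2):
        missing = out[f"arm{i}"].isna()
        pos = out[f"pos{i}"].to_numpy().copy()
        pos = np.where(missing, -1, pos) + 1  # 1-based; missing -> 0
        out[f"pos{i}"] = pos
        out[f"arm{i}"] = out[f"arm{i}"].fillna(".")
        out[f"repeat{i}"] = out[f"repeat{i}"].fillna(".")
        out[f"te{i}"] = out[f"te{i}"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> pd.DataFrame:
    """Read a pairs table back to the in-memory (0-based) convention."""
    df = pd.read_csv(path, sep="\t", dtype={"arm1": str, "arm2": str,
                                            "repeat1": str, "repeat2": str})
    for i in (1, 2):
        arm = df[f"arm{i}"].replace(".", np.nan)
        df[f"arm{i}"] = arm.astype(object).where(arm.notna(), None)
        rep = df[f"repeat{i}"].replace(".", np.nan)
        df[f"repeat{i}"] = rep.astype(object).where(rep.notna(), None)
        df[f"pos{i}"] = df[f"pos{i}"].astype(np.int64) - 1  # 0 (missing) -> -1
        df[f"te{i}"] = df[f"te{i}"].astype(bool)
    return df


def write_report(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """TSV report with a '#'-comment header carrying run metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            blob = json.dumps(meta, sort_keys=True, default=str)
            digest = hashlib.sha1(blob.encode()).hexdigest()[:12]
            fh.write(f"# config_hash: {digest}\n")
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_arms_tsv(path) -> list[tuple[str, str, int]]:
    """Plain arm table: name, chromosome, length."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["name", "chromosome", "length"],
                     dtype={"name": str, "chromosome": str})
    return list(df.itertuples(index=False, name=None))
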