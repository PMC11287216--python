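"""Readers and writers for the pipeline's delimited-text formats.

Dialect: tab-separated, UTF-8, ``#`` comment lines, header row required.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import AniMatrix, ClusteringInputError, MagRecord


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_mags(path) -> list:
    """MAG metadata table -> MagRecords. Required columns: mag_id, depth_cm,
    completeness_pct, contamination_pct, read_fraction_pct; optional taxonomy."""
    df = read_table(path)
    required = {"mag_id", "depth_cm", "completeness_pct", "contamination_pct",
                "read_fraction_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ClusteringInputError(f"MAG table missing column(s): {sorted(missing)}")
    return [
        MagRecord(
            mag_id=str(r["mag_id"]),
            depth_cm=float(r["depth_cm"]),
            completeness_pct=float(r["completeness_pct"]),
            contamination_pct=float(r["contamination_pct"]),
            read_fraction_pct=float(r["read_fraction_pct"]),
            taxonomy=str(r.get("taxonomy", "") or ""),
        )
        for r in df.to_dict("records")
    ]


def write_mags(mags, path) -> None:
    write_table(
        pd.DataFrame(
            [
                {
                    "mag_id": m.mag_id,
                    "depth_cm": m.depth_cm,
                    "completeness_pct": m.completeness_pct,
                    "contamination_pct": m.contamination_pct,
                    "read_fraction_pct": m.read_fraction_pct,
                    "taxonomy": m.taxonomy,
                }
                for m in mags
            ]
        ),
        path,
    )


def read_markers(path) -> dict:
    """Marker table -> {mag_id: marker set}. Accepts long format (mag_id,
    marker_id) or a wide presence/absence matrix (mag_id + one 0/1 column
    per marker)."""
    df = read_table(path)
    if "marker_id" in df.columns:
        out: dict = {}
        for r in df.itertuples(index=False):
            out.setdefault(str(r.mag_id), set()).add(str(r.marker_id))
        return {k: frozenset(v) for k, v in out.items()}
    if "mag_id" not in df.columns:
        raise ClusteringInputError("marker table needs mag_id column")
    marker_cols = [c for c in df.columns if c != "mag_id"]
    return {
        str(r["mag_id"]): frozenset(c for c in marker_cols if bool(r[c]) and float(r[c]) != 0)
        for r in df.to_dict("records")
    }


def write_markers(marker_sets: dict, path) -> None:
    rows = [
        {"mag_id": mag, "marker_id": m}
        for mag in sorted(marker_sets)
        for m in sorted(marker_sets[mag])
    ]
    write_table(pd.DataFrame(rows, columns=["mag_id", "marker_id"]), path)


def read_ani(path) -> AniMatrix:
    """ANI matrix from either dialect: square (first column = mag_id, header
    of mag ids) or fastANI-style long format (query, reference, ani)."""
    df = read_table(path)
    cols_lower = [c.lower() for c in df.columns]
    if {"query", "reference", "ani"} <= set(cols_lower):
        df.columns = cols_lower
        return AniMatrix.from_pairs(
            [(str(r.query), str(r.reference), float(r.ani)) for r in df.itertuples(index=False)]
        )
    first = df.columns[0]
    mag_ids = [str(x) for x in df[first]]
    if list(df.columns[1:]) != mag_ids:
        raise ClusteringInputError(
            "square ANI matrix header must repeat the mag_id column"
        )
    return AniMatrix(mag_ids=mag_ids, values=df[df.columns[1:]].to_numpy(dtype=float))


def write_ani(ani: AniMatrix, path) -> None:
    df = pd.DataFrame(ani.values, columns=ani.mag_ids)
    df.insert(0, "mag_id", ani.mag_ids)
    write_table(df, path)


def write_otus(otus, path) -> None:
    depths = sorted({d for o in otus for d in o.abundance_by_depth})
    rows = []
    for o in sorted(otus, key=lambda o: o.otu_id):
        row = {
            "otu_id": o.otu_id,
            "representative_mag_id": o.representative_mag_id,
            "member_mag_ids": ",".join(sorted(o.member_mag_ids)),
        }
        for d in depths:
            row[f"abundance_pct_{d:g}cm"] = o.abundance_by_depth.get(d, 0.0)
        rows.append(row)
    write_table(pd.DataFrame(rows), path)


def write_calls(calls: dict, path) -> None:
    rows = []
    for otu_id in sorted(calls):
        c = calls[otu_id]
        rows.append(
            {
                "otu_id": otu_id,
                "oxygen_class": c.oxygen_class,
                "carbon_class": c.carbon_class,
                "pathways": ",".join(
                    f"{p}({conf})" if conf != "high" else p
                    for p, conf in sorted(c.pathways.items())
                ),
                "donors": ",".join(sorted(c.donors)),
                "acceptors": ",".join(sorted(c.acceptors)),
            }
        )
    write_table(pd.DataFrame(rows), path)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(x):
    if isinstance(x, (frozenset, set)):
        return sorted(x)
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
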