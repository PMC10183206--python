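"""Readers and writers for every tabular and graph artifact.

CSV dialect: comma-separated, UTF-8, header row required.  Timestamps
are stored internally as integer seconds since the Unix epoch,
timezone-naive (local feeder time); readers accept both epoch-seconds
and ISO-8601 columns.  Networks round-trip through GraphML or an edge
CSV losslessly (weights to 1e-9 or better).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger("flocknet.io")

VISIT_COLUMNS = ["timestamp", "tag_id", "antenna_id"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class PedigreeError(FormatError):
    """Raised for cyclic or referentially broken pedigrees."""


def _parse_timestamps(raw: pd.Series, fmt: str) -> pd.Series:
    """Parse a timestamp column to integer epoch seconds.

    fmt: 'epoch', 'iso', or 'auto' (epoch if numeric, else ISO-8601).
    Raises FormatError naming the first offending line (1-based, header
    is line 1).
    """
    if fmt == "epoch":
        vals = pd.to_numeric(raw, errors="coerce")
    elif fmt == "iso":
        dt = pd.to_datetime(raw, errors="coerce", format="ISO8601")
        vals = dt.astype("int64").where(dt.notna()) // 10**9
    elif fmt == "auto":
        num = pd.to_numeric(raw, errors="coerce")
        dt = pd.to_datetime(raw, errors="coerce", format="ISO8601")
        iso = dt.astype("int64").where(dt.notna()) // 10**9
        vals = num.where(num.notna(), iso)
    else:
        raise FormatError(f"unknown timestamp format {fmt!r}")
    bad = vals.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise FormatError(
            f"unparseable timestamp {raw[bad.idxmax()]!r} at line {line}"
        )
    return vals.astype("int64")


def read_visit_log(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read an RFID visit log CSV into a VisitLog DataFrame.

    The dialect maps internal names to file columns, e.g.
    ``{"timestamp": "DateTime", "tag_id": "Transponder",
    "antenna_id": "Unit", "timestamp_format": "iso"}``.  Output is
    sorted by timestamp with byte-identical duplicate rows collapsed
    (count logged).  Ties (simultaneous detections) are accepted.
    """
    path = Path(path)
    dialect = dict(dialect or {})
    fmt = dialect.pop("timestamp_format", "auto")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and not len(df.columns):
        logger.warning("empty visit log %s", path)
        return pd.DataFrame(columns=VISIT_COLUMNS)
    rename = {dialect.get(k, k): k for k in VISIT_COLUMNS}
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.rename(columns=rename)[VISIT_COLUMNS]
    if df.empty:
        logger.warning("visit log %s has a header but no rows", path)
        return pd.DataFrame(columns=VISIT_COLUMNS)
    if (df["tag_id"] == "").any():
        line = int((df["tag_id"] == "").idxmax()) + 2
        raise FormatError(f"{path}: empty tag_id at line {line}")
    n_before = len(df)
    df = df.drop_duplicates()
    n_dup = n_before - len(df)
    if n_dup:
        logger.info("collapsed %d duplicate visit rows in %s", n_dup, path)
    df = df.assign(timestamp=_parse_timestamps(df["timestamp"], fmt))
    df = df.sort_values(["timestamp", "tag_id"], kind="mergesort")
    return df.reset_index(drop=True)


def write_visit_log(visits: pd.DataFrame, path) -> None:
    visits[VISIT_COLUMNS].to_csv(path, index=False)


def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"individual_id", "sex", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise FormatError(f"{path}: duplicate individual_id {dup!r}")
    if not df["sex"].isin([0, 1]).all():
        raise FormatError(f"{path}: sex must be coded 0 (female) / 1 (male)")
    if "death_year" in df.columns:
        closed = df["death_year"].notna()
        if (df.loc[closed, "death_year"] < df.loc[closed, "cohort"]).any():
            raise FormatError(f"{path}: death_year before cohort")
    return df


def write_individuals(individuals: pd.DataFrame, path) -> None:
    individuals.to_csv(path, index=False)


def validate_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Check closure and acyclicity; return the table with a founder flag.

    A founder is a row with both parents null.  Any named parent must
    itself be a row (closed pedigree); any ancestry cycle is an error
    reported with one offending path.
    """
    ids = set(pedigree["individual_id"])
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for col in ("sire_id", "dam_id"):
        for child, parent in zip(pedigree["individual_id"], pedigree[col]):
            if pd.isna(parent) or parent == "":
                continue
            if parent not in ids:
                raise PedigreeError(
                    f"parent {parent!r} of {child!r} is not in the pedigree "
                    "and carries no founder row"
                )
            g.add_edge(parent, child)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(a for a, _ in cycle) + " -> " + cycle[-1][1]
        raise PedigreeError(f"pedigree contains an ancestry cycle: {path}")
    out = pedigree.copy()
    out["founder"] = out["sire_id"].isna() & out["dam_id"].isna()
    return out


def read_pedigree(path) -> pd.DataFrame:
    """Read and validate a pedigree CSV (individual/sire/dam/cohort)."""
    df = pd.read_csv(path)
    required = {"individual_id", "sire_id", "dam_id", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return validate_pedigree(df)


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    cols = ["individual_id", "sire_id", "dam_id", "cohort"]
    pedigree[cols].to_csv(path, index=False)


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write a weighted social network as GraphML or an edge-list CSV.

    The edge CSV keeps an explicit vertex table section-free by writing
    isolated-vertex-free networks only (the degree>0 filter upstream
    guarantees this); GraphML preserves node attributes.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edge_csv":
        rows = [
            {"individual_a": a, "individual_b": b,
             "weight": repr(float(d.get("weight", 1.0)))}
            for a, b, d in network.edges(data=True)
        ]
        nodes = pd.DataFrame({"individual_a": list(network.nodes),
                              "individual_b": "", "weight": ""})
        pd.concat([pd.DataFrame(rows, columns=["individual_a", "individual_b",
                                               "weight"]), nodes]) \
            .to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        out.add_nodes_from(g.nodes(data=True))
        for a, b, d in g.edges(data=True):
            out.add_edge(a, b, weight=float(d.get("weight", 1.0)))
        return out
    if format == "edge_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        g = nx.Graph()
        for _, r in df.iterrows():
            if r["individual_b"] == "":
                g.add_node(r["individual_a"])
            else:
                g.add_edge(r["individual_a"], r["individual_b"],
                           weight=float(r["weight"]))
        return g
    raise FormatError(f"unsupported network format {format!r}")
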