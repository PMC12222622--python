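"""Readers/writers for the canonical long-format count table and results.

The canonical on-disk format is tidy long-format CSV/TSV (UTF-8, header
required) with columns ``time, species, habitat, community, count``.  The
community-to-habitat nesting travels with the counts; zero rows are
optional and reconstructed on read.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CommunityMap, CountTable
from .partition import PartitionResult

__all__ = [
    "REQUIRED_COLUMNS",
    "read_counts",
    "write_counts",
    "results_to_frame",
    "results_to_records",
]

REQUIRED_COLUMNS = ("time", "species", "habitat", "community", "count")


def _sep_for(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "tsv" if str(path).lower().endswith((".tsv", ".tab")) else "csv"
    try:
        return {"csv": ",", "tsv": "\t"}[fmt]
    except KeyError:
        raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}") from None


def read_counts(
    path, fmt: str | None = None, census_order: Sequence | None = None
) -> tuple[list[CountTable], CommunityMap]:
    """Read an ordered census series and its community map.

    Missing (species, community) combinations are filled with zero.
    Census order is the sorted unique ``time`` labels unless an explicit
    ``census_order`` is supplied.
    """
    df = pd.read_csv(path, sep=_sep_for(path, fmt))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df = df.copy()
    for col in ("species", "habitat", "community"):
        df[col] = df[col].astype(str)

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != np.floor(counts))
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise ValueError(
            f"{path}: count must be a nonnegative integer; offending row "
            f"(time={row['time']!r}, species={row['species']!r}, "
            f"community={row['community']!r}, count={row['count']!r})"
        )
    df["count"] = counts.astype(np.int64)

    dup = df.duplicated(subset=["time", "species", "community"], keep=False)
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (time, species, community) key; first "
            f"offender (time={row['time']!r}, species={row['species']!r}, "
            f"community={row['community']!r})"
        )

    hab_per_comm = df.groupby("community")["habitat"].agg(lambda s: tuple(sorted(set(s))))
    conflicted = hab_per_comm[hab_per_comm.map(len) > 1]
    if len(conflicted):
        comm, habs = conflicted.index[0], conflicted.iloc[0]
        raise ValueError(
            f"{path}: community {comm!r} is listed under two habitats {habs}; "
            "every community must map to exactly one habitat"
        )

    communities = tuple(sorted(df["community"].unique()))
    cmap = CommunityMap(
        communities, tuple(hab_per_comm[c][0] for c in communities)
    )
    species = tuple(sorted(df["species"].unique()))

    times = list(pd.unique(df["time"]))
    if census_order is None:
        order = sorted(times) if _sortable(times) else times
    else:
        order = list(census_order)
        if set(order) != set(times):
            raise ValueError(
                f"{path}: census_order does not match the file's time labels"
            )

    tables = []
    for t in order:
        sub = df[df["time"] == t]
        if sub.empty:
            raise ValueError(f"{path}: census_order label {t!r} absent from file")
        mat = (
            sub.pivot(index="species", columns="community", values="count")
            .reindex(index=species, columns=communities)
            .fillna(0)
            .to_numpy()
        )
        tables.append(CountTable(mat, species, cmap, census=t))
    return tables, cmap


def _sortable(values) -> bool:
    try:
        sorted(values)
        return True
    except TypeError:
        return False


def write_counts(
    tables: Sequence[CountTable], path, fmt: str | None = None, include_zeros: bool = True
) -> None:
    """Write an ordered census series in the canonical long format."""
    rows = []
    for table in tables:
        cm = table.cmap
        for i, sp in enumerate(table.species_ids):
            for k, comm in enumerate(cm.community_ids):
                c = int(table.counts[i, k])
                if c == 0 and not include_zeros:
                    continue
                rows.append(
                    {
                        "time": table.census,
                        "species": sp,
                        "habitat": cm.habitat_ids[k],
                        "community": comm,
                        "count": c,
                    }
                )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep=_sep_for(path, fmt), index=False
    )


def results_to_records(
    results_by_component: dict[str, list[PartitionResult]],
    bounds: dict | None = None,
) -> list[dict]:
    """Tidy records, one per interval x component x term (incl. total).

    ``bounds`` may map ``(interval_index, component, term)`` to
    ``(lower, upper)`` bootstrap bounds; absent entries emit null bounds.
    """
    records = []
    components = list(results_by_component)
    n_intervals = len(results_by_component[components[0]])
    for idx in range(n_intervals):
        for comp in components:
            res = results_by_component[comp][idx]
            values = dict(res.terms)
            values["total"] = res.total
            hill = res.hill_factors
            for term, value in values.items():
                lo = hi = None
                if bounds is not None:
                    lo_hi = bounds.get((idx, comp, term))
                    if lo_hi is not None:
                        lo, hi = float(lo_hi[0]), float(lo_hi[1])
                records.append(
                    {
                        "interval": list(res.interval),
                        "component": comp,
                        "term": term,
                        "value_nats": value,
                        "hill_factor": hill[term],
                        "lower": lo,
                        "upper": hi,
                        "phi": res.phi,
                    }
                )
    return records


def results_to_frame(
    results_by_component: dict[str, list[PartitionResult]],
    bounds: dict | None = None,
) -> pd.DataFrame:
    """Records as a tidy :class:`pandas.DataFrame` (CSV-ready)."""
    records = results_to_records(results_by_component, bounds=bounds)
    df = pd.DataFrame.from_records(records)
    df[["interval_from", "interval_to"]] = pd.DataFrame(
        df["interval"].tolist(), index=df.index
    )
    cols = [
        "interval_from",
        "interval_to",
        "component",
        "term",
        "value_nats",
        "hill_factor",
        "lower",
        "upper",
        "phi",
    ]
    return df[cols]


def write_results_json(records: list[dict], path, metadata: dict | None = None) -> None:
    payload = {"metadata": metadata or {}, "results": records}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
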