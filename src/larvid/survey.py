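"""Ecological summaries: species-by-station tables and standardised abundance.

Only individuals whose final assignment reaches species rank populate the
species table (shallower finals are reported separately); ``n`` is each
species' individual count and ``St`` the number of stations where it
occurred.  Abundances standardise counts by the volume of water each net
haul filtered, in individuals per 1,000 m³.  Stations are ordered north to
south (latitude descending) in reports.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .consensus import ConsensusAssignment
from .synthdata import StationRecord
from .taxonomy import RANKS, Taxonomy

__all__ = [
    "StationRecord",
    "abundance_per_1000m3",
    "read_stations",
    "species_station_table",
    "species_station_table_from_marginals",
    "station_abundance",
    "widespread_species",
]


def abundance_per_1000m3(count: int, volume_m3: float) -> float:
    """Standardised abundance: individuals per 1,000 m³ of filtered water."""
    if volume_m3 <= 0:
        raise ValueError(f"volume must be > 0 m³, got {volume_m3}")
    return 1000.0 * count / volume_m3


def read_stations(path) -> list[StationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        StationRecord(str(r.station), float(r.latitude), float(r.volume_m3))
        for r in df.itertuples()
    ]


def _station_order(stations: Sequence[StationRecord]) -> list[str]:
    return [s.station for s in sorted(stations, key=lambda s: -s.latitude)]


def species_station_table(
    assignments: Sequence[ConsensusAssignment],
    query_stations: Mapping[str, str],
    stations: Sequence[StationRecord],
    taxonomy: Optional[Taxonomy] = None,
) -> pd.DataFrame:
    """Species × station count table over species-final assignments.

    Rows carry the full lineage plus ``n`` (total individuals) and ``St``
    (stations of occurrence), then one count column per station in
    north-to-south order.  Queries finalised above species rank are ignored
    here.  Unknown station ids raise.
    """
    station_ids = _station_order(stations)
    known = set(station_ids)
    counts: dict[tuple, pd.Series] = {}
    for a in assignments:
        if a.final_rank != "species":
            continue
        st = query_stations.get(a.query_id)
        if st is None:
            raise ValueError(f"query {a.query_id!r} has no station")
        if st not in known:
            raise ValueError(f"query {a.query_id!r}: unknown station {st!r}")
        lin = a.lineage
        if lin is None and taxonomy is not None:
            lin = taxonomy.lineage_of(a.final_taxon)
        if lin is None:
            raise ValueError(f"query {a.query_id!r}: no lineage for {a.final_taxon!r}")
        key = tuple(lin)
        row = counts.setdefault(key, pd.Series(0, index=station_ids, dtype=int))
        row[st] += 1
    rows = []
    for key in sorted(counts):
        row = counts[key]
        rows.append(
            {
                **dict(zip(RANKS, key)),
                "n": int(row.sum()),
                "St": int((row > 0).sum()),
                **row.to_dict(),
            }
        )
    return pd.DataFrame(rows, columns=list(RANKS) + ["n", "St"] + station_ids)


def species_station_table_from_marginals(marginals: pd.DataFrame) -> pd.DataFrame:
    """Expand per-species (n, St) marginals into a full species × station
    table by spreading each species over its first St stations (all surplus
    individuals at the first).  Marginals are preserved exactly."""
    req = set(RANKS) | {"n", "St"}
    if not req <= set(marginals.columns):
        raise ValueError(f"marginals need columns {sorted(req)}")
    max_st = int(marginals["St"].max())
    station_ids = [f"St{i + 1}" for i in range(max_st)]
    rows = []
    for r in marginals.itertuples():
        n, st = int(r.n), int(r.St)
        if not 1 <= st <= n:
            raise ValueError(f"{r.species}: St={st} incompatible with n={n}")
        per = [n - st + 1] + [1] * (st - 1) + [0] * (max_st - st)
        rows.append(
            {**{rank: getattr(r, rank) for rank in RANKS},
             "n": n, "St": st, **dict(zip(station_ids, per))}
        )
    return pd.DataFrame(rows, columns=list(RANKS) + ["n", "St"] + station_ids)


def widespread_species(table: pd.DataFrame, min_stations: int) -> list[str]:
    """Species occurring at strictly more than ``min_stations`` stations,
    most widespread first (ties alphabetical)."""
    if min_stations < 0:
        raise ValueError("min_stations must be ≥ 0")
    sub = table[table["St"] > min_stations]
    sub = sub.sort_values(["St", "species"], ascending=[False, True])
    return list(sub["species"])


def station_abundance(
    table: pd.DataFrame, stations: Sequence[StationRecord]
) -> pd.DataFrame:
    """Per-station totals and standardised abundance (individuals/1,000 m³)."""
    by_id = {s.station: s for s in stations}
    rows = []
    for st in _station_order(stations):
        count = int(table[st].sum()) if st in table.columns else 0
        rows.append(
            {
                "station": st,
                "latitude": by_id[st].latitude,
                "volume_m3": by_id[st].volume_m3,
                "individuals": count,
                "per_1000m3": abundance_per_1000m3(count, by_id[st].volume_m3),
            }
        )
    return pd.DataFrame(rows)
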