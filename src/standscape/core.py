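"""Genotype data model and I/O for stand-structured SNP panels.

The sampling unit is a *stand*: a contiguous cluster of plants separated
from other clusters by tens of meters.  Each sampled plant carries biallelic
SNP calls encoded as allele-b dosage (0, 1, 2; -1 for missing).  This module
holds the marker map, the genotype table, multilocus-genotype (MLG)
identification with a missing-data-tolerant identity rule, per-stand
censuses, detection of MLGs shared between stands, and GENEPOP export for
interoperability with classical population-genetics software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "Marker",
    "MarkerMap",
    "StandInfo",
    "GenotypeTable",
    "MLGTable",
    "StandCensus",
    "SharedMLG",
    "read_marker_map",
    "read_genotype_table",
    "write_genotype_table",
    "read_stand_table",
    "write_stand_table",
    "identify_mlgs",
    "stand_census",
    "shared_mlgs_between_stands",
    "export_genepop",
    "read_genepop",
]


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chromosome: int
    position: int  # 1-based bp
    allele_a: str
    allele_b: str


class MarkerMap:
    """Ordered SNP marker map over numbered chromosomes.

    Markers must be sorted by (chromosome, position) with strictly
    increasing positions within each chromosome and unique ids.  Dosage
    counts copies of ``allele_b``; the a/b orientation is fixed by the map
    and never inferred from data.
    """

    def __init__(self, markers: Sequence[Marker]):
        markers = list(markers)
        if not markers:
            raise ValueError("marker map must contain at least one marker")
        ids = [m.marker_id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        for prev, cur in zip(markers, markers[1:]):
            if cur.chromosome < prev.chromosome:
                raise ValueError("markers must be sorted by chromosome")
            if cur.chromosome == prev.chromosome and cur.position <= prev.position:
                raise ValueError(
                    "positions must be strictly increasing within a chromosome"
                )
        self.markers = markers
        self.marker_ids = ids
        self.chromosomes = np.array([m.chromosome for m in markers], dtype=int)
        self.positions = np.array([m.position for m in markers], dtype=np.int64)
        self._index = {mid: i for i, mid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.markers)

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    def chromosome_slices(self) -> dict[int, slice]:
        """Contiguous marker-index slice for each chromosome, in map order."""
        out: dict[int, slice] = {}
        start = 0
        for i in range(1, len(self.chromosomes) + 1):
            if i == len(self.chromosomes) or self.chromosomes[i] != self.chromosomes[start]:
                out[int(self.chromosomes[start])] = slice(start, i)
                start = i
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chrom": self.chromosomes,
                "pos": self.positions,
                "allele_a": [m.allele_a for m in self.markers],
                "allele_b": [m.allele_b for m in self.markers],
            }
        )


@dataclass(frozen=True)
class StandInfo:
    """Stand metadata: planar coordinates in meters and habitat class."""

    stand_id: str
    site_type: str  # "rural" | "urban"
    x: float
    y: float

    def __post_init__(self):
        if self.site_type not in ("rural", "urban"):
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("stand coordinates must be finite")


class GenotypeTable:
    """Plants x markers dosage matrix with per-sample metadata.

    ``calls`` is an int8 array of allele-b dosages with ``MISSING`` (-1) for
    no-calls; ``meta`` is a DataFrame indexed 0..n-1 with columns
    sample_id, stand_id, year, transect_index (nullable integer).
    """

    def __init__(self, meta: pd.DataFrame, calls: np.ndarray, marker_map: MarkerMap):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2 or calls.shape[1] != len(marker_map):
            raise ValueError("calls shape does not match marker map")
        if len(meta) != calls.shape[0]:
            raise ValueError("metadata and calls row counts differ")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {calls[i, j]} for sample "
                f"{meta['sample_id'].iloc[i]!r} at marker "
                f"{marker_map.marker_ids[j]!r}"
            )
        if meta["sample_id"].duplicated().any():
            dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        self.meta = meta.reset_index(drop=True)
        self.calls = calls
        self.marker_map = marker_map

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.meta["sample_id"].tolist()

    @property
    def stand_ids(self) -> np.ndarray:
        return self.meta["stand_id"].to_numpy()

    def stand_groups(self) -> dict[str, np.ndarray]:
        """Row indices per stand, preserving input order of stands."""
        groups: dict[str, list[int]] = {}
        for i, sid in enumerate(self.meta["stand_id"]):
            groups.setdefault(sid, []).append(i)
        return {k: np.array(v, dtype=int) for k, v in groups.items()}

    def subset(self, rows: Iterable[int]) -> "GenotypeTable":
        rows = np.asarray(list(rows), dtype=int)
        return GenotypeTable(self.meta.iloc[rows], self.calls[rows], self.marker_map)

    def __repr__(self) -> str:
        return (
            f"<GenotypeTable {self.n_samples} samples x {len(self.marker_map)} "
            f"markers, {self.meta['stand_id'].nunique()} stands>"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "stand_id", "year", "transect_index"]


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    required = {"marker_id", "chrom", "pos", "allele_a", "allele_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker map must have columns {sorted(required)}")
    return MarkerMap(
        [
            Marker(r.marker_id, int(r.chrom), int(r.pos), str(r.allele_a), str(r.allele_b))
            for r in df.itertuples()
        ]
    )


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False)


def read_genotype_table(path, marker_map: MarkerMap) -> GenotypeTable:
    """Read a TSV genotype table and canonicalize marker column order.

    Expected columns: sample_id, stand_id, year, transect_index, then one
    column per marker id (in any order) with values 0/1/2/NA.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stand_id": str})
    for col in _META_COLS[:3]:
        if col not in df.columns:
            raise ValueError(f"genotype table missing required column {col!r}")
    if "transect_index" not in df.columns:
        df["transect_index"] = pd.NA
    marker_cols = [c for c in df.columns if c not in _META_COLS]
    unknown = set(marker_cols) - set(marker_map.marker_ids)
    if unknown:
        raise ValueError(f"unknown marker column(s): {sorted(unknown)[:5]}")
    missing_cols = set(marker_map.marker_ids) - set(marker_cols)
    if missing_cols:
        raise ValueError(f"marker column(s) absent from file: {sorted(missing_cols)[:5]}")
    calls = np.full((len(df), len(marker_map)), MISSING, dtype=np.int8)
    for j, mid in enumerate(marker_map.marker_ids):
        col = pd.to_numeric(df[mid], errors="coerce")
        vals = col.to_numpy(dtype=float)
        called = ~np.isnan(vals)
        ok = np.isin(vals[called], (0.0, 1.0, 2.0))
        if not ok.all():
            row = np.flatnonzero(called)[np.flatnonzero(~ok)[0]]
            raise ValueError(
                f"invalid dosage {df[mid].iloc[row]!r} in row "
                f"{df['sample_id'].iloc[row]!r}, column {mid!r}"
            )
        calls[called, j] = vals[called].astype(np.int8)
    meta = df[_META_COLS].copy()
    meta["year"] = meta["year"].astype(int)
    meta["transect_index"] = meta["transect_index"].astype("Int64")
    return GenotypeTable(meta, calls, marker_map)


def write_genotype_table(table: GenotypeTable, path) -> None:
    out = table.meta.copy()
    calls = table.calls.astype(object)
    calls[table.calls == MISSING] = pd.NA
    for j, mid in enumerate(table.marker_map.marker_ids):
        out[mid] = calls[:, j]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_stand_table(path) -> list[StandInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"stand_id": str})
    return [
        StandInfo(r.stand_id, str(r.site_type), float(r.x), float(r.y))
        for r in df.itertuples()
    ]


def write_stand_table(stands: Sequence[StandInfo], path) -> None:
    pd.DataFrame(
        {
            "stand_id": [s.stand_id for s in stands],
            "site_type": [s.site_type for s in stands],
            "x": [s.x for s in stands],
            "y": [s.y for s in stands],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Multilocus genotypes
# ---------------------------------------------------------------------------


@dataclass
class MLGTable:
    """Partition of samples into multilocus genotypes (MLGs).

    Two well-called samples share an MLG when they agree at every marker at
    which both are called; merging proceeds by transitive closure so a
    sparse missing call cannot split an otherwise identical group.  Samples
    below the call-rate threshold are left as singletons.
    """

    mlg_of: dict[str, str]  # sample_id -> mlg_id
    canonical: dict[str, np.ndarray]  # mlg_id -> consensus dosage vector
    members: dict[str, list[str]]  # mlg_id -> sample ids
    n_unique: int
    n_fully_homozygous: int

    def mlg_ids_for_stand(self, table: GenotypeTable, stand_id: str) -> list[str]:
        rows = table.meta["stand_id"] == stand_id
        sids = table.meta.loc[rows, "sample_id"]
        seen: list[str] = []
        for s in sids:
            m = self.mlg_of[s]
            if m not in seen:
                seen.append(m)
        return seen


def identify_mlgs(table: GenotypeTable, min_call_rate: float = 0.95) -> MLGTable:
    """Partition samples into MLGs under the wildcard identity rule.

    Samples with call rate >= ``min_call_rate`` are merged whenever they are
    compatible (equal wherever both called), with transitive closure.
    Low-call-rate samples never merge with anything.
    """
    if table.n_samples == 0:
        raise ValueError("need at least one sample")
    calls = table.calls
    n, L = calls.shape
    called = calls != MISSING
    eligible = called.sum(axis=1) >= min_call_rate * L

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # exact-duplicate grouping first (cheap), then wildcard comparisons
    key_of: dict[bytes, int] = {}
    for i in range(n):
        k = calls[i].tobytes()
        if k in key_of:
            if eligible[i] and eligible[key_of[k]]:
                union(key_of[k], i)
        else:
            key_of[k] = i
    reps = sorted(set(find(i) for i in range(n) if eligible[i]))
    for a_pos, i in enumerate(reps):
        block = np.array([j for j in reps[a_pos + 1 :]], dtype=int)
        if block.size == 0:
            continue
        both = called[i][None, :] & called[block]
        diff = (calls[i][None, :] != calls[block]) & both
        compat = ~diff.any(axis=1)
        for j in block[compat]:
            union(i, int(j))

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    sample_ids = table.sample_ids
    mlg_of: dict[str, str] = {}
    canonical: dict[str, np.ndarray] = {}
    members: dict[str, list[str]] = {}
    n_hom = 0
    for k, root in enumerate(sorted(groups)):
        idx = groups[root]
        mid = f"MLG{k + 1:04d}"
        cons = np.full(L, MISSING, dtype=np.int8)
        sub = calls[idx]
        for j in range(L):
            col = sub[:, j]
            vals = col[col != MISSING]
            if vals.size:
                cons[j] = vals[0]
        canonical[mid] = cons
        members[mid] = [sample_ids[i] for i in idx]
        for i in idx:
            mlg_of[sample_ids[i]] = mid
        if not np.any(cons == 1):
            n_hom += 1
    return MLGTable(mlg_of, canonical, members, len(groups), n_hom)


@dataclass
class StandCensus:
    stand_id: str
    n_sampled: int
    n_mlgs: int
    monotypic: bool
    n_heterozygous: int  # individuals with >=1 heterozygous call


def stand_census(table: GenotypeTable, mlg_table: MLGTable | None = None) -> list[StandCensus]:
    """Per-stand sample/MLG/heterozygote census.

    Monotypy is judged on the MLG partition (wildcard rule), so one missing
    call cannot break a monotypic classification.  An individual counts as
    heterozygous if it carries at least one dosage-1 call.
    """
    if mlg_table is None:
        mlg_table = identify_mlgs(table)
    out = []
    for sid, rows in table.stand_groups().items():
        if rows.size == 0:
            continue
        sub_ids = [table.sample_ids[i] for i in rows]
        mlgs = {mlg_table.mlg_of[s] for s in sub_ids}
        het = int(np.any(table.calls[rows] == 1, axis=1).sum())
        out.append(StandCensus(sid, rows.size, len(mlgs), len(mlgs) == 1, het))
    return out


@dataclass(frozen=True)
class SharedMLG:
    mlg_id: str
    stand_a: str
    stand_b: str
    distance_km: float


def shared_mlgs_between_stands(
    table: GenotypeTable, mlg_table: MLGTable, stands: Sequence[StandInfo]
) -> list[SharedMLG]:
    """MLGs observed in more than one stand, with planar stand distances."""
    coord = {s.stand_id: (s.x, s.y) for s in stands}
    stands_of: dict[str, set[str]] = {}
    for s, m in mlg_table.mlg_of.items():
        row = table.meta.index[table.meta["sample_id"] == s][0]
        stands_of.setdefault(m, set()).add(table.meta["stand_id"].iloc[row])
    out: list[SharedMLG] = []
    for m in sorted(stands_of):
        present = sorted(stands_of[m])
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                (xa, ya), (xb, yb) = coord[a], coord[b]
                d = math.hypot(xa - xb, ya - yb) / 1000.0
                out.append(SharedMLG(m, a, b, d))
    return out


# ---------------------------------------------------------------------------
# GENEPOP interoperability
# ---------------------------------------------------------------------------


def export_genepop(table: GenotypeTable, path, title: str = "standscape export") -> None:
    """Write a GENEPOP file: one POP block per stand, 2-digit allele codes.

    Allele a is coded 01, allele b 02; a missing call becomes 0000.
    """
    lines = [title]
    lines.extend(table.marker_map.marker_ids)
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    for sid, rows in table.stand_groups().items():
        lines.append("POP")
        for i in rows:
            geno = " ".join(code[int(d)] for d in table.calls[i])
            lines.append(f"{table.sample_ids[i]} ,  {geno}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path, marker_map: MarkerMap, year: int = 0) -> GenotypeTable:
    """Read a GENEPOP file written by :func:`export_genepop`.

    Stand ids are not stored in GENEPOP; POP blocks become POP1, POP2, ...
    unless sample ids carry them elsewhere.
    """
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    raw = [ln for ln in raw if ln.strip()]
    body = raw[1:]
    marker_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        marker_ids.extend(m.strip() for m in body[i].split(","))
        i += 1
    if marker_ids != marker_map.marker_ids:
        raise ValueError("GENEPOP marker list does not match marker map")
    decode = {"0101": 0, "0102": 1, "0201": 1, "0202": 2, "0000": MISSING}
    meta_rows = []
    calls_rows = []
    pop = 0
    for ln in body[i:]:
        if ln.strip().upper() == "POP":
            pop += 1
            continue
        name, geno = ln.split(",", 1)
        codes = geno.split()
        if len(codes) != len(marker_map):
            raise ValueError(f"wrong number of genotypes for {name.strip()!r}")
        calls_rows.append([decode[c] for c in codes])
        meta_rows.append((name.strip(), f"POP{pop}", year, pd.NA))
    meta = pd.DataFrame(meta_rows, columns=_META_COLS)
    meta["transect_index"] = meta["transect_index"].astype("Int64")
    return GenotypeTable(meta, np.array(calls_rows, dtype=np.int8), marker_map)
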