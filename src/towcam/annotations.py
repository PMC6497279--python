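"""Data model and I/O for per-frame annotations, taxonomy and trawl catch tables.

The sampling unit of a towed-camera survey is the video *frame*: each annotated
frame carries the identity and count of every organism visible in it, plus an
optional visual estimate of sediment composition.  Frames are indexed 1-based
and contiguously within a transect; frames that could not be annotated (poor
visibility, hardware dropouts) are kept in the sequence but flagged
``usable=False`` and excluded from analysis denominators.

Annotation files are plain CSV (UTF-8, header row required) in a wide layout:
one row per frame, metadata columns first, then one column per taxon.  Sediment
percentage columns are distinguished by a ``sed_`` prefix.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "FrameRecord",
    "TaxonomyEntry",
    "CatchRecord",
    "TransectMeta",
    "DEFAULT_SEDIMENT_CLASSES",
    "DEFAULT_SEDIMENT_SYNONYMS",
    "SEDIMENT_PREFIX",
    "read_frame_annotations",
    "write_frame_annotations",
    "frames_to_table",
    "read_catch_records",
    "aggregate_counts",
    "taxa_filters",
    "expand_subsampled_catch",
]

#: Canonical sediment vocabulary (the set used for reporting).
DEFAULT_SEDIMENT_CLASSES: tuple[str, ...] = ("clay", "silt", "sand", "gravel", "shell")

#: Synonyms applied on read.  Field annotations sometimes use "shells" and
#: "boulders"; boulders are folded into gravel by default (coarsest class).
DEFAULT_SEDIMENT_SYNONYMS: dict[str, str] = {"shells": "shell", "boulders": "gravel"}

#: Column prefix that marks a sediment-percentage column in annotation CSVs.
SEDIMENT_PREFIX = "sed_"

_META_COLUMNS = ("transect_id", "frame_index", "time_s", "usable")


@dataclass
class FrameRecord:
    """One annotated video frame.

    Parameters
    ----------
    transect_id : str
        Label of the transect the frame belongs to.
    frame_index : int
        1-based position of the frame in the transect's sequence.
    counts : dict
        Mapping taxon label -> non-negative organism count.  Zero-count taxa
        may be present or absent; they are equivalent.
    time_s : float, optional
        Seconds since the start of the transect.
    sediment_pct : dict, optional
        Mapping sediment class -> visual percentage estimate in [0, 100].
    usable : bool
        Whether the frame could be annotated.  Unusable frames are skipped by
        subsampling and excluded from occupancy denominators.
    """

    transect_id: str
    frame_index: int
    counts: dict[str, int] = field(default_factory=dict)
    time_s: float | None = None
    sediment_pct: dict[str, float] | None = None
    usable: bool = True

    def __post_init__(self) -> None:
        if self.frame_index < 1:
            raise ValidationError(
                f"frame_index must be >= 1, got {self.frame_index} "
                f"(transect {self.transect_id!r})"
            )
        for taxon, n in self.counts.items():
            if n < 0:
                raise ValidationError(
                    f"negative count {n} for taxon {taxon!r} in frame "
                    f"({self.transect_id!r}, {self.frame_index})"
                )
        if self.sediment_pct is not None:
            for cls, pct in self.sediment_pct.items():
                if not 0.0 <= pct <= 100.0:
                    raise ValidationError(
                        f"sediment percentage {pct} for {cls!r} outside [0, 100] "
                        f"in frame ({self.transect_id!r}, {self.frame_index})"
                    )

    @property
    def n_organisms(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def occupied(self) -> bool:
        return self.n_organisms > 0


@dataclass(frozen=True)
class TaxonomyEntry:
    """Maps an observed taxon label to species / order / class ranks."""

    common_name: str
    scientific_name: str
    rank_map: Mapping[str, str]

    def __post_init__(self) -> None:
        for rank in ("order", "class"):
            if not self.rank_map.get(rank):
                raise ValidationError(
                    f"taxonomy entry {self.common_name!r} lacks a {rank} label"
                )

    def resolve(self, rank: str) -> str:
        if rank not in self.rank_map:
            raise KeyError(rank)
        return self.rank_map[rank]


@dataclass
class CatchRecord:
    """One station x taxon entry of a beam-trawl catch table."""

    station_id: str
    taxon: str
    count: float
    estimated: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(
                f"negative catch count {self.count} at station {self.station_id!r}"
            )


@dataclass
class TransectMeta:
    """Tow metadata for one transect (used by the layback correction)."""

    transect_id: str
    depth_m: float
    heading: str
    cable_length_m: float
    tow_speed_ms: float

    def __post_init__(self) -> None:
        if self.depth_m <= 0 or self.cable_length_m <= 0 or self.tow_speed_ms <= 0:
            raise ValidationError("depth, cable length and tow speed must be positive")
        if self.cable_length_m < self.depth_m:
            raise ValidationError(
                f"cable ({self.cable_length_m} m) shorter than depth "
                f"({self.depth_m} m): layback undefined"
            )
        if self.heading not in ("north", "south"):
            raise ValidationError(f"heading must be 'north' or 'south', got {self.heading!r}")


def _canonical_sediment(label: str, synonyms: Mapping[str, str]) -> str:
    label = label.strip().lower()
    return synonyms.get(label, label)


def read_frame_annotations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sediment_synonyms: Mapping[str, str] | None = None,
) -> list[FrameRecord]:
    """Read a wide annotation CSV into a sorted list of :class:`FrameRecord`.

    Parameters
    ----------
    path : path-like
        CSV with required columns ``transect_id`` and ``frame_index``,
        optional ``time_s`` and ``usable``, sediment columns prefixed
        ``sed_``, and one integer column per taxon.
    schema : mapping, optional
        Renames input columns to the canonical names before interpretation,
        e.g. ``{"tow": "transect_id", "img": "frame_index"}``.
    sediment_synonyms : mapping, optional
        Sediment-label synonym table applied after stripping the prefix;
        defaults to :data:`DEFAULT_SEDIMENT_SYNONYMS`.

    Returns
    -------
    list of FrameRecord, sorted by ``(transect_id, frame_index)``.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        On duplicate ``(transect_id, frame_index)`` pairs or negative counts.
    """
    synonyms = DEFAULT_SEDIMENT_SYNONYMS if sediment_synonyms is None else sediment_synonyms
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    for col in ("transect_id", "frame_index"):
        if col not in df.columns:
            raise SchemaError(f"annotation file {path} is missing required column {col!r}")

    dup = df.duplicated(subset=["transect_id", "frame_index"])
    if dup.any():
        pairs = df.loc[dup, ["transect_id", "frame_index"]].itertuples(index=False)
        raise ValidationError(
            "duplicate (transect, frame) pairs: " + ", ".join(map(str, map(tuple, pairs)))
        )

    sediment_cols = [c for c in df.columns if c.startswith(SEDIMENT_PREFIX)]
    taxon_cols = [c for c in df.columns if c not in _META_COLUMNS and c not in sediment_cols]

    for col in taxon_cols:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(
                f"negative count in column {col!r} at row(s) {list(bad)} of {path}"
            )

    records: list[FrameRecord] = []
    for rec in df.to_dict("records"):
        counts = {c: int(rec[c]) for c in taxon_cols if rec[c] > 0}
        sediment = None
        if sediment_cols:
            sediment = {
                _canonical_sediment(c[len(SEDIMENT_PREFIX):], synonyms): float(rec[c])
                for c in sediment_cols
                if pd.notna(rec[c])
            }
            if not sediment:
                sediment = None
        records.append(
            FrameRecord(
                transect_id=str(rec["transect_id"]),
                frame_index=int(rec["frame_index"]),
                counts=counts,
                time_s=float(rec["time_s"]) if "time_s" in rec and pd.notna(rec["time_s"]) else None,
                sediment_pct=sediment,
                usable=bool(rec["usable"]) if "usable" in rec else True,
            )
        )
    records.sort(key=lambda r: (r.transect_id, r.frame_index))
    return records


def frames_to_table(records: Sequence[FrameRecord]) -> pd.DataFrame:
    """Convert records to the wide CSV layout (inverse of the reader)."""
    taxa = sorted({t for r in records for t in r.counts})
    sed = sorted({s for r in records if r.sediment_pct for s in r.sediment_pct})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "transect_id": r.transect_id,
            "frame_index": r.frame_index,
            "time_s": r.time_s,
            "usable": r.usable,
        }
        for s in sed:
            row[SEDIMENT_PREFIX + s] = (r.sediment_pct or {}).get(s)
        for t in taxa:
            row[t] = r.counts.get(t, 0)
        rows.append(row)
    cols = ["transect_id", "frame_index", "time_s", "usable"]
    cols += [SEDIMENT_PREFIX + s for s in sed] + taxa
    return pd.DataFrame(rows, columns=cols)


def write_frame_annotations(records: Sequence[FrameRecord], path: str | Path) -> None:
    """Write records as a wide annotation CSV; round-trips through the reader."""
    frames_to_table(records).to_csv(path, index=False)


def read_catch_records(path: str | Path) -> list[CatchRecord]:
    """Read a long-format catch CSV (station_id, taxon, count[, estimated])."""
    df = pd.read_csv(path)
    for col in ("station_id", "taxon", "count"):
        if col not in df.columns:
            raise SchemaError(f"catch file {path} is missing required column {col!r}")
    return [
        CatchRecord(
            station_id=str(r.station_id),
            taxon=str(r.taxon),
            count=float(r.count),
            estimated=bool(getattr(r, "estimated", False)),
        )
        for r in df.itertuples(index=False)
    ]


def _counts_from(records: Iterable) -> dict[str, float]:
    """Pool counts from FrameRecords, CatchRecords or a plain mapping."""
    if isinstance(records, Mapping):
        return {str(k): float(v) for k, v in records.items()}
    pooled: dict[str, float] = {}
    for r in records:
        if isinstance(r, FrameRecord):
            for taxon, n in r.counts.items():
                pooled[taxon] = pooled.get(taxon, 0.0) + n
        elif isinstance(r, CatchRecord):
            pooled[r.taxon] = pooled.get(r.taxon, 0.0) + r.count
        else:
            raise TypeError(f"cannot pool counts from {type(r).__name__}")
    return pooled


def aggregate_counts(
    records,
    taxonomy: Mapping[str, TaxonomyEntry] | None = None,
    rank: str = "taxon",
) -> pd.Series:
    """Pool counts and aggregate them to a taxonomic rank.

    ``records`` may be a sequence of :class:`FrameRecord`, a sequence of
    :class:`CatchRecord`, or a plain ``{taxon: count}`` mapping.  With
    ``rank="taxon"`` labels pass through unchanged and no taxonomy is needed;
    for ``species``, ``order`` or ``class`` every observed label must resolve
    through ``taxonomy``.  The output total always equals the input total.
    """
    pooled = _counts_from(records)
    if rank == "taxon":
        return pd.Series(pooled, dtype=float).sort_index()
    if rank not in ("species", "order", "class"):
        raise ValueError(f"unknown rank {rank!r}; expected taxon/species/order/class")
    if taxonomy is None:
        raise ValueError(f"a taxonomy is required to aggregate at rank {rank!r}")
    missing = sorted(t for t in pooled if t not in taxonomy)
    if missing:
        raise ValidationError(
            f"taxa not resolvable at rank {rank!r}: {', '.join(missing)}"
        )
    out: dict[str, float] = {}
    for taxon, n in pooled.items():
        label = taxonomy[taxon].resolve(rank)
        out[label] = out.get(label, 0.0) + n
    return pd.Series(out, dtype=float).sort_index()


def taxa_filters(vector: pd.Series | Mapping[str, float], min_count: int) -> tuple[pd.Series, dict[str, int]]:
    """Filter an abundance vector by a minimum count.

    Returns the sub-vector of taxa with ``count >= min_count`` together with a
    summary ``{"n_taxa_nonzero": ..., "n_taxa_above": ...}``.  With
    ``min_count=0`` the vector is returned unchanged.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    v = pd.Series(vector, dtype=float)
    summary = {
        "n_taxa_nonzero": int((v > 0).sum()),
        "n_taxa_above": int((v >= min_count).sum()),
    }
    # counts are non-negative, so min_count=0 keeps every taxon (identity)
    return v[v >= min_count], summary


def expand_subsampled_catch(
    tray_count: int,
    n_trays: int,
    station_id: str = "",
    taxon: str = "",
) -> CatchRecord:
    """Estimate a total catch from one fully counted tray of ``n_trays``.

    Very large single-species catches are split into equal trays and only one
    tray is counted; the total is the tray count times the number of trays.
    The returned record is flagged ``estimated=True``.
    """
    if n_trays < 1:
        raise ValueError(f"n_trays must be >= 1, got {n_trays}")
    if tray_count < 0:
        raise ValidationError(f"tray_count must be >= 0, got {tray_count}")
    return CatchRecord(
        station_id=station_id,
        taxon=taxon,
        count=float(tray_count * n_trays),
        estimated=True,
    )
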