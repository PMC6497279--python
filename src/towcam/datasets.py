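"""Packaged reference tables from a Mid-Atlantic wind-energy-area benthic survey.

Three small tables are shipped with the package:

* ``catch_table()`` — organism totals per taxon for the beam-trawl survey,
  the fully annotated single-transect test set, and the every-30th-frame
  subsamples of all seven camera transects.
* ``transect_summary()`` — per-transect mean depth, usable frame counts and
  the published class-level diversity values.
* ``station_summary()`` — per-station depth and diversity of the fifteen
  beam-trawl stations.
* ``default_taxonomy()`` — species / order / class assignments for every
  taxon appearing in the catch table.

Known internal inconsistencies of the published tables are preserved as
printed rather than silently repaired: the test-set column sums to 343
although the survey text reports 339 organisms in 13 species (the column has
14 nonzero entries), the transect column has 22 nonzero taxa where the text
says 23 groups, and 15 beam-trawl taxa reach 5 individuals where the text
says 14.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotations import TaxonomyEntry

__all__ = [
    "catch_table",
    "transect_summary",
    "station_summary",
    "default_taxonomy",
    "load_taxonomy",
    "catch_column",
    "deterministic_survey_frames",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("towcam.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def catch_table() -> pd.DataFrame:
    """Per-taxon organism totals; columns ``beam_trawl``, ``test_set``, ``transects_1_7``."""
    return _read("table2_counts.csv")


def catch_column(column: str) -> pd.Series:
    """One abundance vector from the catch table, indexed by common name."""
    df = catch_table()
    if column not in df.columns:
        raise KeyError(column)
    return pd.Series(df[column].to_numpy(dtype=float), index=df["common_name"])


def transect_summary() -> pd.DataFrame:
    """Published per-transect depth, frames and class-level diversity (plus 'All' row)."""
    return _read("table1_transects.csv")


def station_summary() -> pd.DataFrame:
    """Published per-station depth and diversity for beam-trawl stations (plus 'All' row)."""
    return _read("table3_stations.csv")


def default_taxonomy() -> dict[str, TaxonomyEntry]:
    """Default taxonomy for all catch-table taxa, keyed by both common and scientific name.

    The survey reported its frame counts grouped into taxonomic classes but
    never enumerated the grouping; these are standard assignments and can be
    overridden by loading a user taxonomy CSV with the same columns.
    """
    return _taxonomy_from_frame(_read("taxonomy.csv"))


def load_taxonomy(path) -> dict[str, TaxonomyEntry]:
    """Load a user taxonomy CSV (columns: common_name, scientific_name, species, order, class)."""
    return _taxonomy_from_frame(pd.read_csv(path))


def deterministic_survey_frames() -> list:
    """Synthetic, fully deterministic frame-annotation stand-in for the camera survey.

    Builds one :class:`~towcam.annotations.FrameRecord` per published usable
    frame (4393 in total across the seven transects) and distributes each
    taxon's published transect-wide total over the frame slots with a fixed
    stride, so the pooled counts reproduce the published per-taxon totals
    exactly (3035 organisms).  No randomness is involved; the spatial
    arrangement is artificial and only the pooled composition is meaningful.
    """
    from .annotations import FrameRecord

    summary = transect_summary()
    summary = summary[summary["transect_id"] != "All"]
    slots: list[tuple[str, int]] = []
    for row in summary.itertuples(index=False):
        slots.extend((row.transect_id, i + 1) for i in range(int(row.frames)))
    n_slots = len(slots)

    counts: dict[tuple[str, int], dict[str, int]] = {}
    col = catch_column("transects_1_7")
    j = 0
    stride = 997  # coprime with the slot count; spreads organisms over transects
    for taxon, total in col.items():
        for _ in range(int(total)):
            slot = slots[(j * stride) % n_slots]
            frame_counts = counts.setdefault(slot, {})
            frame_counts[taxon] = frame_counts.get(taxon, 0) + 1
            j += 1
    return [
        FrameRecord(transect_id=t, frame_index=i, counts=counts.get((t, i), {}))
        for t, i in slots
    ]


def _taxonomy_from_frame(df: pd.DataFrame) -> dict[str, TaxonomyEntry]:
    out: dict[str, TaxonomyEntry] = {}
    for _, row in df.iterrows():
        entry = TaxonomyEntry(
            common_name=row["common_name"],
            scientific_name=row["scientific_name"],
            rank_map={
                "species": row["species"],
                "order": row["order"],
                "class": row["class"],
            },
        )
        out[entry.common_name] = entry
        out[entry.scientific_name] = entry
    return out
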