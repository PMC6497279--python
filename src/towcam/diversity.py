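"""Diversity indices for abundance vectors at any taxonomic rank.

Two indices are used throughout the package, both functions of the taxon
proportions ``p_i = n_i / N``:

* Shannon's H' = -sum(p_i * log(p_i)), the entropy of a random organism's
  identity (natural log by default, so H' is in nats);
* Hill's N2 = 1 / sum(p_i**2), the inverse Simpson concentration, read as the
  effective number of *abundant* taxa.  N2 is insensitive to rare taxa, which
  makes it the index of choice when annotation effort (and hence the tail of
  rare detections) varies between samples.

With H' in nats the Hill ordering ``exp(H') >= N2 >= 1`` holds for every
abundance vector.  Empty vectors (no organisms) yield NaN with a warning
rather than an exception, so that sparse subsamples propagate cleanly through
replicate tables.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import FrameRecord, TaxonomyEntry, aggregate_counts

__all__ = ["DiversityResult", "shannon", "hills_n2", "diversity_result", "diversity_by_group"]


@dataclass(frozen=True)
class DiversityResult:
    """Diversity summary of one abundance vector."""

    H: float
    N2: float
    S: int
    n: float
    rank: str = "taxon"
    log_base: float = np.e


def _proportions(vector) -> np.ndarray:
    """Positive proportions of an abundance vector; empty array if no organisms."""
    v = np.asarray(pd.Series(vector, dtype=float).to_numpy(), dtype=float)
    if np.any(v < 0):
        raise ValueError("abundance vector has negative entries")
    v = v[v > 0]
    total = v.sum()
    if total == 0:
        return np.empty(0)
    return v / total


def shannon(vector, log_base: float = np.e) -> float:
    """Shannon diversity H' = -sum(p log p), with 0*log(0) taken as 0.

    Returns NaN (with a warning) for a vector with no organisms.
    """
    if log_base <= 1:
        raise ValueError("log_base must be > 1")
    p = _proportions(vector)
    if p.size == 0:
        warnings.warn("Shannon H' undefined for an empty abundance vector", stacklevel=2)
        return float("nan")
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def hills_n2(vector) -> float:
    """Hill's N2 = 1/sum(p^2); NaN (with warning) for an empty vector."""
    p = _proportions(vector)
    if p.size == 0:
        warnings.warn("Hill's N2 undefined for an empty abundance vector", stacklevel=2)
        return float("nan")
    return float(1.0 / (p ** 2).sum())


def diversity_result(vector, rank: str = "taxon", log_base: float = np.e) -> DiversityResult:
    """Compute H', N2, richness and total for one abundance vector."""
    v = pd.Series(vector, dtype=float)
    p = _proportions(v)
    if p.size == 0:
        return DiversityResult(
            H=float("nan"), N2=float("nan"), S=0, n=0.0, rank=rank, log_base=log_base
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DiversityResult(
            H=shannon(v, log_base),
            N2=hills_n2(v),
            S=int((v > 0).sum()),
            n=float(v.sum()),
            rank=rank,
            log_base=log_base,
        )


def diversity_by_group(
    records: Sequence,
    taxonomy: Mapping[str, TaxonomyEntry] | None = None,
    rank: str = "taxon",
    group_by: str = "transect",
    log_base: float = np.e,
    pooled_mode: str = "pooled",
) -> pd.DataFrame:
    """Per-group diversity table with a pooled ``All`` row.

    ``records`` are frame records (grouped by ``transect_id``) or catch
    records (grouped by ``station_id``).  The ``All`` row is computed from the
    pooled counts by default; ``pooled_mode="mean"`` instead averages the
    per-group indices, which is useful when comparing against summaries whose
    pooling rule is unknown.

    Returns a DataFrame with columns group, rank, n, S, H, N2, log_base.
    """
    if group_by not in ("transect", "station"):
        raise ValueError(f"group_by must be 'transect' or 'station', got {group_by!r}")
    if pooled_mode not in ("pooled", "mean"):
        raise ValueError(f"pooled_mode must be 'pooled' or 'mean', got {pooled_mode!r}")
    if not records:
        raise ValueError("records is empty")

    key = "transect_id" if group_by == "transect" else "station_id"
    groups: dict[str, list] = {}
    for r in records:
        groups.setdefault(getattr(r, key), []).append(r)

    rows = []
    per_group: list[DiversityResult] = []
    for gid in sorted(groups):
        vec = aggregate_counts(groups[gid], taxonomy, rank)
        res = diversity_result(vec, rank=rank, log_base=log_base)
        per_group.append(res)
        rows.append(_row(gid, res))

    pooled_vec = aggregate_counts(records, taxonomy, rank)
    if pooled_mode == "pooled":
        all_res = diversity_result(pooled_vec, rank=rank, log_base=log_base)
    else:
        defined = [r for r in per_group if np.isfinite(r.H)]
        all_res = DiversityResult(
            H=float(np.mean([r.H for r in defined])) if defined else float("nan"),
            N2=float(np.mean([r.N2 for r in defined])) if defined else float("nan"),
            S=int((pooled_vec > 0).sum()),
            n=float(pooled_vec.sum()),
            rank=rank,
            log_base=log_base,
        )
    rows.append(_row("All", all_res))
    return pd.DataFrame(rows)


def _row(group: str, res: DiversityResult) -> dict:
    return {
        "group": group,
        "rank": res.rank,
        "n": res.n,
        "S": res.S,
        "H": res.H,
        "N2": res.N2,
        "log_base": res.log_base,
    }
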