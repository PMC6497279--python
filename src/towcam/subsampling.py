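"""Systematic and random frame-subsampling designs.

A fully annotated frame sequence is expensive to produce, so the central
question is how few frames can be annotated before diversity estimates
degrade.  Two designs are supported:

* **systematic** — every k-th frame starting from a random start in
  ``[1, k]``; one annotation pass at a fixed interval, the design actually
  used in production surveys;
* **random** — simple random subsets of a given size, drawn without
  replacement, at sizes spaced evenly on a log10 axis.

Running a design yields a tidy *diversity curve*: one row per
(interval-or-size, replicate) with the Shannon H' and Hill N2 of the pooled
counts of the selected frames.  Unusable frames are excluded before selection,
so indices always refer to positions in the usable-frame sequence.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import FrameRecord, TaxonomyEntry
from .diversity import diversity_result

__all__ = [
    "SubsampleDesign",
    "systematic_select",
    "random_select",
    "log_spaced_sizes",
    "default_systematic_intervals",
    "run_design",
    "split_halves",
]


@dataclass(frozen=True)
class SubsampleDesign:
    """Specification of a subsampling experiment.

    ``kind="systematic"`` uses ``intervals`` (frame strides); each replicate
    redraws the random start frame.  ``kind="random"`` uses ``sizes`` (number
    of frames); each replicate redraws the subset.
    """

    kind: str
    intervals: tuple[int, ...] = ()
    sizes: tuple[int, ...] = ()
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("systematic", "random"):
            raise ValueError(f"kind must be 'systematic' or 'random', got {self.kind!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.kind == "systematic":
            if not self.intervals or any(k < 1 for k in self.intervals):
                raise ValueError("systematic design needs intervals >= 1")
        else:
            if not self.sizes or any(n < 1 for n in self.sizes):
                raise ValueError("random design needs sizes >= 1")


def systematic_select(n_frames: int, interval: int, start: int) -> np.ndarray:
    """Indices ``{start, start+k, start+2k, ...}`` within ``[1, n_frames]``.

    The realized sample size is ``floor((n_frames - start)/interval) + 1``.
    """
    if not 1 <= interval <= n_frames:
        raise ValueError(f"interval must be in [1, {n_frames}], got {interval}")
    if not 1 <= start <= interval:
        raise ValueError(f"start must be in [1, interval={interval}], got {start}")
    return np.arange(start, n_frames + 1, interval)


def random_select(n_frames: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` distinct frame indices in ``[1, n_frames]``, uniform without replacement."""
    if not 1 <= n <= n_frames:
        raise ValueError(f"sample size must be in [1, {n_frames}], got {n}")
    return np.sort(rng.choice(n_frames, size=n, replace=False) + 1)


def log_spaced_sizes(n_min: int = 31, n_max: int = 1778, k: int = 36) -> list[int]:
    """``k`` integer sample sizes spaced evenly in log10 between the endpoints.

    Endpoints are exact; interior values are ``round(10**x)`` on the even log
    grid.  Duplicate integers after rounding are removed with a warning.
    """
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if n_min >= n_max:
        raise ValueError(f"n_min ({n_min}) must be < n_max ({n_max})")
    if k < 2:
        raise ValueError("k must be >= 2")
    grid = np.linspace(np.log10(n_min), np.log10(n_max), k)
    sizes = np.round(10.0 ** grid).astype(int)
    sizes[0], sizes[-1] = n_min, n_max
    unique = sorted(set(int(s) for s in sizes))
    if len(unique) < k:
        warnings.warn(
            f"log-spaced grid produced {k - len(unique)} duplicate size(s); "
            f"{len(unique)} unique sizes retained",
            stacklevel=2,
        )
    return unique


def default_systematic_intervals(k_min: int = 5, k_max: int = 300, n: int = 40) -> list[int]:
    """``n`` unique integer intervals approximately log-spaced over ``[k_min, k_max]``.

    Used as the default systematic design grid; the log spacing matches the
    log10 axis on which stabilization is assessed.
    """
    if n > k_max - k_min + 1:
        raise ValueError("not enough integers in the range for the requested count")
    dense = np.unique(np.round(np.geomspace(k_min, k_max, 8 * n)).astype(int))
    idx = np.unique(np.round(np.linspace(0, len(dense) - 1, n)).astype(int))
    chosen = sorted(set(dense[idx]) | {k_min, k_max})
    # pad from the dense grid if endpoint forcing or rounding collapsed values
    for v in dense:
        if len(chosen) >= n:
            break
        if v not in chosen:
            chosen.append(int(v))
    return sorted(chosen)[:n] if len(chosen) > n else sorted(chosen)


def _usable(records: Sequence[FrameRecord]) -> list[FrameRecord]:
    return [r for r in records if r.usable]


def _counts_matrix(records: Sequence[FrameRecord]) -> tuple[np.ndarray, list[str]]:
    """Dense (n_frames, n_taxa) count matrix over the usable-frame sequence."""
    taxa = sorted({t for r in records for t in r.counts})
    mat = np.zeros((len(records), len(taxa)), dtype=float)
    col = {t: j for j, t in enumerate(taxa)}
    for i, r in enumerate(records):
        for t, n in r.counts.items():
            mat[i, col[t]] = n
    return mat, taxa


def _aggregate_columns(
    mat: np.ndarray,
    taxa: list[str],
    taxonomy: Mapping[str, TaxonomyEntry] | None,
    rank: str,
) -> tuple[np.ndarray, list[str]]:
    if rank == "taxon" or not taxa:
        return mat, taxa
    if taxonomy is None:
        raise ValueError(f"a taxonomy is required to aggregate at rank {rank!r}")
    labels = [taxonomy[t].resolve(rank) for t in taxa]
    out_labels = sorted(set(labels))
    col = {lab: j for j, lab in enumerate(out_labels)}
    out = np.zeros((mat.shape[0], len(out_labels)), dtype=float)
    for j, lab in enumerate(labels):
        out[:, col[lab]] += mat[:, j]
    return out, out_labels


def run_design(
    records: Sequence[FrameRecord],
    design: SubsampleDesign,
    taxonomy: Mapping[str, TaxonomyEntry] | None = None,
    rank: str = "taxon",
) -> pd.DataFrame:
    """Run a subsampling design and return the tidy diversity curve.

    Columns: ``kind``, ``interval`` (NaN for random designs), ``size_nominal``,
    ``n_frames`` (realized), ``replicate``, ``H``, ``N2``,
    ``fraction_of_total`` (percent of usable frames selected).
    """
    usable = _usable(records)
    if not usable:
        raise ValueError("no usable frames")
    n_total = len(usable)
    mat, taxa = _counts_matrix(usable)
    mat, _ = _aggregate_columns(mat, taxa, taxonomy, rank)
    rng = np.random.default_rng(design.seed)

    rows = []
    if design.kind == "systematic":
        cells = [("systematic", k, None) for k in design.intervals]
    else:
        for n in design.sizes:
            if n > n_total:
                raise ValueError(f"requested size {n} exceeds usable frames ({n_total})")
        cells = [("random", None, n) for n in design.sizes]

    for kind, interval, size in cells:
        for rep in range(design.n_reps):
            if kind == "systematic":
                start = int(rng.integers(1, interval + 1))
                idx = systematic_select(n_total, interval, start)
                nominal = interval
            else:
                idx = random_select(n_total, size, rng)
                nominal = size
            vec = mat[idx - 1].sum(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = diversity_result(vec, rank=rank)
            rows.append(
                {
                    "kind": kind,
                    "interval": interval if interval is not None else np.nan,
                    "size_nominal": nominal,
                    "n_frames": int(len(idx)),
                    "replicate": rep,
                    "H": res.H,
                    "N2": res.N2,
                    "fraction_of_total": 100.0 * len(idx) / n_total,
                }
            )
    return pd.DataFrame(rows)


def split_halves(records: Sequence[FrameRecord]) -> tuple[list[FrameRecord], list[FrameRecord]]:
    """Split one transect's frame sequence into first and second halves.

    The first half gets ``floor(N/2)`` frames, the second the remainder, so
    the sizes differ by at most one.
    """
    recs = sorted(records, key=lambda r: r.frame_index)
    if len(recs) < 2:
        raise ValueError("need at least 2 frames to split")
    if len({r.transect_id for r in recs}) > 1:
        raise ValueError("split_halves expects frames from a single transect")
    half = len(recs) // 2
    return recs[:half], recs[half:]
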