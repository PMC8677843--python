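"""Stratified train/validation/test partition using hotspot bins as strata.

The split mimics the study design: units are partitioned 70/15/15 with the
seven Gi* bins of the response as strata, so each partition preserves the
spatial-cluster composition of the full map.  Per-stratum counts use
largest-remainder rounding, which guarantees every partition's count is
within one unit of the exact fractional allocation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitAssignment", "stratified_split", "DEFAULT_FRACTIONS"]

PARTITIONS = ("train", "valid", "test")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class SplitAssignment:
    """Per-unit partition labels plus the stratum each unit came from."""

    ids: list[str]
    partition: np.ndarray  # values from PARTITIONS
    stratum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"partition": self.partition, "stratum": self.stratum},
            index=pd.Index(self.ids, name="unit_id"),
        )

    def mask(self, which: str) -> np.ndarray:
        if which not in PARTITIONS:
            raise ValueError(f"unknown partition {which!r}")
        return self.partition == which


def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    ideal = fractions * n
    counts = np.floor(ideal).astype(int)
    short = n - counts.sum()
    # distribute leftovers by descending fractional remainder; ties go to the
    # earlier partition (train first) for determinism
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def stratified_split(
    table: pd.DataFrame,
    strata,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Seeded stratified random split into train/valid/test.

    ``strata`` is a column name or an array of per-unit stratum labels.
    Within each stratum, counts are fixed by largest-remainder rounding of
    the fractions and membership by a seeded shuffle, so the same seed always
    reproduces the same assignment.  Strata with fewer units than partitions
    go entirely to train (with a warning) rather than producing sub-singleton
    partitions.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(PARTITIONS):
        raise ValueError(f"need {len(PARTITIONS)} fractions, got {len(fractions)}")
    if (fractions <= 0).any():
        raise ValueError("fractions must be positive")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions.sum()}")

    labels = table[strata].to_numpy() if isinstance(strata, str) else np.asarray(strata)
    if len(labels) != len(table):
        raise ValueError("strata length does not match table")

    rng = np.random.default_rng(seed)
    partition = np.empty(len(table), dtype=object)
    # iterate strata in sorted order so the assignment is independent of row order
    for lab in sorted(pd.unique(labels), key=lambda v: str(v)):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < len(PARTITIONS):
            warnings.warn(
                f"stratum {lab!r} has only {len(idx)} unit(s); all assigned to train",
                stacklevel=2,
            )
            partition[idx] = "train"
            continue
        counts = _largest_remainder(len(idx), fractions)
        shuffled = rng.permutation(idx)
        start = 0
        for part, cnt in zip(PARTITIONS, counts):
            partition[shuffled[start : start + cnt]] = part
            start += cnt
    return SplitAssignment(
        ids=list(table["unit_id"]),
        partition=partition.astype(str),
        stratum=labels,
    )
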