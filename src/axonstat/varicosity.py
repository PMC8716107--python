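"""Varicosity typing and exceedance statistics.

Varicosities are binned by vesicle content into four types: I (no vesicles),
II (small vesicles only, 26-67 nm diameter), III (large vesicles only,
90-238 nm), IV (both).  The dataset-level statistic tested against the null
model is the exceedance count C(T, k): the number of axons containing more
than k varicosities of type T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import AxonRecord, ValidationError, VTYPES, type_counts

SMALL_BIN = (26.0, 67.0)
LARGE_BIN = (90.0, 238.0)


def classify_varicosity(
    vesicle_diameters: Sequence[float],
    small_bin: tuple[float, float] = SMALL_BIN,
    large_bin: tuple[float, float] = LARGE_BIN,
    min_minority_count: int = 1,
) -> str | None:
    """Assign a varicosity type from its vesicle diameters (nm).

    No vesicles -> I; only small-bin -> II; only large-bin -> III; both bins
    occupied (minority bin holding at least ``min_minority_count`` vesicles)
    -> IV.  Diameters in the 67-90 nm gap or beyond either bin do not vote;
    a non-empty list with every diameter out-of-bin is unassigned (None) with
    a warning.
    """
    diams = list(vesicle_diameters)
    if any(d <= 0 for d in diams):
        raise ValidationError("vesicle diameters must be positive")
    if not diams:
        return "I"
    n_small = sum(small_bin[0] <= d <= small_bin[1] for d in diams)
    n_large = sum(large_bin[0] <= d <= large_bin[1] for d in diams)
    if n_small == 0 and n_large == 0:
        warnings.warn(
            f"all {len(diams)} vesicle diameters fall outside both bins; "
            "varicosity left unassigned"
        )
        return None
    if n_small and n_large and min(n_small, n_large) >= min_minority_count:
        return "IV"
    return "II" if n_small >= n_large else "III"


def classify_axon(axon: AxonRecord, **kwargs) -> AxonRecord:
    """Assign ``vtype`` in place for every varicosity of an axon."""
    for v in axon.varicosities:
        v.vtype = classify_varicosity(v.vesicle_diameters, **kwargs)
    return axon


@dataclass
class TypeFrequencies:
    """Pooled varicosity-type counts and fractions over a dataset."""

    counts: np.ndarray  # ints, one per type I..IV
    f: np.ndarray       # fractions, sums to 1

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "TypeFrequencies":
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (4,) or counts.sum() <= 0 or (counts < 0).any():
            raise ValidationError(f"invalid type counts {counts}")
        return cls(counts=counts, f=counts / counts.sum())

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.f, index=list(VTYPES), name="fraction")


def pool_frequencies(axons: Iterable[AxonRecord]) -> TypeFrequencies:
    """Pooled type frequencies over all classified varicosities of all axons.

    Pooling ignores per-axon eligibility: every classified varicosity counts.
    """
    counts = np.zeros(4, dtype=int)
    for axon in axons:
        counts += type_counts(axon.type_sequence())
    if counts.sum() == 0:
        raise ValidationError("no classified varicosities to pool")
    return TypeFrequencies.from_counts(counts)


@dataclass
class ExceedanceTable:
    """Observed exceedance counts C(T, k) over eligible axons.

    ``counts[t, k-1]`` is the number of eligible axons (those with at least
    ``min_varicosities`` classified varicosities) whose count of type-T
    varicosities strictly exceeds k, for k = 1..k_max.
    """

    counts: np.ndarray            # shape (4, k_max), ints
    k_max: int
    min_varicosities: int
    axon_sizes: list[int]         # classified-varicosity counts of eligible axons
    eligible_axon_ids: list[str] = field(default_factory=list)

    @property
    def n_axons(self) -> int:
        return len(self.axon_sizes)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"vtype": VTYPES[t], "k": k + 1, "c_obs": int(self.counts[t, k])}
            for t in range(4)
            for k in range(self.k_max)
        ]
        return pd.DataFrame(rows)


def exceedance_counts(
    axons: Iterable[AxonRecord],
    k_max: int,
    min_varicosities: int = 3,
) -> ExceedanceTable:
    """Exceedance table over axons with >= ``min_varicosities`` classified
    varicosities (strict '>' at each threshold k)."""
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    sizes: list[int] = []
    ids: list[str] = []
    per_axon_counts: list[np.ndarray] = []
    for axon in axons:
        counts = type_counts(axon.type_sequence())
        if counts.sum() >= min_varicosities:
            sizes.append(int(counts.sum()))
            ids.append(axon.axon_id)
            per_axon_counts.append(counts)
    if not sizes:
        raise ValidationError(
            f"no axon has >= {min_varicosities} classified varicosities")
    table = exceedance_from_counts(np.array(per_axon_counts), k_max)
    return ExceedanceTable(
        counts=table, k_max=k_max, min_varicosities=min_varicosities,
        axon_sizes=sizes, eligible_axon_ids=ids,
    )


def exceedance_from_counts(per_axon_counts: np.ndarray, k_max: int) -> np.ndarray:
    """C(T, k) from an (n_axons, 4) matrix of per-axon type counts."""
    per_axon_counts = np.atleast_2d(per_axon_counts)
    ks = np.arange(1, k_max + 1)
    # (axons, types, k): count_T > k
    return (per_axon_counts[:, :, None] > ks[None, None, :]).sum(axis=0)
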