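"""Wasserstein comparison of interaction-fingerprint histograms.

A fingerprint histogram counts tuples ⟨ligand id, amino-acid type,
interaction type⟩. To compare a predicted histogram **u** with the
native histogram **v**, their bins are first unified — the support is
the union of the tuples of both, placed on consecutive integers in
canonical lexicographic order — so a method is penalized both for
missing native interaction types and for hallucinating non-native ones.
The distance is then the 1-Wasserstein (earth mover's) distance between
the two normalized discrete distributions, which on a 1-D integer
support equals the sum over bins of the absolute CDF difference.

Across a set of methods, the per-method distances are min–max
normalized into the Wasserstein matching score
``WM = 1 − (EMD − EMD_min) / (EMD_max − EMD_min)`` in [0, 1], higher
better; the best method scores 1, the worst 0.

Note: a 1-D embedding of categorical tuples makes the distance depend
on the bin order; the canonical lexicographic order is fixed here and
recorded in report provenance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

FingerprintTuple = tuple[str, str, str]  # (ligand id, residue type, interaction type)


class EmptyHistogramError(ValueError):
    """Both histograms are empty: the distance is undefined."""


@dataclass
class PlifHistogram:
    """Multiset of fingerprint tuples with integer counts."""

    counts: Counter = field(default_factory=Counter)

    def add(self, key: FingerprintTuple, n: int = 1) -> None:
        if n < 0:
            raise ValueError("counts must be non-negative")
        self.counts[tuple(key)] += n

    @classmethod
    def from_counts(cls, counts: Mapping[FingerprintTuple, int]) -> "PlifHistogram":
        hist = cls()
        for key, n in counts.items():
            hist.add(key, n)
        return hist

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return self.total > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlifHistogram):
            return NotImplemented
        return {k: v for k, v in self.counts.items() if v} == {
            k: v for k, v in other.counts.items() if v
        }


def unify_bins(
    u: PlifHistogram, v: PlifHistogram
) -> tuple[list[FingerprintTuple], np.ndarray, np.ndarray]:
    """Common support and per-histogram probability weights.

    The support is the union of both histograms' tuples in lexicographic
    order on consecutive integer positions 0..B−1; weights are counts
    normalized to unit mass, with absent tuples at weight 0.
    """
    if not u and not v:
        raise EmptyHistogramError("both histograms are empty")
    support = sorted(set(u.counts) | set(v.counts))
    support = [s for s in support if u.counts.get(s, 0) or v.counts.get(s, 0)]
    wu = np.array([u.counts.get(s, 0) for s in support], dtype=float)
    wv = np.array([v.counts.get(s, 0) for s in support], dtype=float)
    if wu.sum() > 0:
        wu /= wu.sum()
    if wv.sum() > 0:
        wv /= wv.sum()
    return support, wu, wv


def plif_emd(
    u: PlifHistogram, v: PlifHistogram, normalize: bool = True
) -> float:
    """1-Wasserstein distance between two fingerprint histograms.

    On the unified integer support the optimal transport cost has the
    closed form ``sum_b |CDF_u(b) − CDF_v(b)|`` (unit spacing between
    adjacent bins). With ``normalize=False`` raw counts are transported
    instead of probability mass (sensitivity analysis only; the result
    is then scale-dependent).
    """
    support, wu, wv = unify_bins(u, v)
    if not normalize:
        wu = np.array([u.counts.get(s, 0) for s in support], dtype=float)
        wv = np.array([v.counts.get(s, 0) for s in support], dtype=float)
    return float(np.abs(np.cumsum(wu - wv)[:-1]).sum()) if len(support) > 1 else 0.0


def plif_wm(emd_by_method: Mapping[str, Optional[float]]) -> dict[str, Optional[float]]:
    """Min–max normalized Wasserstein matching scores across methods.

    Methods whose distance is undefined (None/NaN) are excluded from the
    min/max and reported as None. When all defined distances coincide,
    every method scores 1.0.
    """
    if not emd_by_method:
        raise ValueError("no methods given")
    defined = {
        m: e for m, e in emd_by_method.items()
        if e is not None and np.isfinite(e)
    }
    if not defined:
        raise ValueError("no method has a defined distance")
    lo, hi = min(defined.values()), max(defined.values())
    out: dict[str, Optional[float]] = {}
    for m, e in emd_by_method.items():
        if m in defined:
            out[m] = 1.0 if hi == lo else float(1.0 - (defined[m] - lo) / (hi - lo))
        else:
            out[m] = None
    return out


def pool_emds(per_target_emds: Iterable[Optional[float]]) -> Optional[float]:
    """Mean of the defined per-target distances (None if none defined)."""
    vals = [e for e in per_target_emds if e is not None and np.isfinite(e)]
    return float(np.mean(vals)) if vals else None
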