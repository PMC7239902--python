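"""Kuncheva's stability index over collections of equal-size feature subsets.

For m subsets S_1..S_m of size k drawn from an l-feature universe, the index
is the mean over all unordered pairs (i < j) of the chance-corrected overlap

    (|S_i n S_j| * l - k^2) / (k * (l - k)).

The k^2/l term is the expected overlap of two independent uniformly random
k-subsets, so the index is ~0 for random selections, 1 when every subset is
identical, and reaches -1 for disjoint subsets when k = l/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class SubsetCollection:
    """m feature subsets of equal cardinality k from an l-feature universe."""

    subsets: tuple[frozenset, ...]
    n_features: int

    def __post_init__(self):
        if len(self.subsets) < 2:
            raise ValueError("need at least two subsets (m >= 2)")
        sizes = {len(s) for s in self.subsets}
        if len(sizes) != 1:
            raise ValueError(f"subsets must share one cardinality, got sizes {sorted(sizes)}")
        k = sizes.pop()
        if not 0 < k < self.n_features:
            raise ValueError(f"need 0 < k < l, got k={k}, l={self.n_features}")
        universe = frozenset().union(*self.subsets)
        if len(universe) > self.n_features:
            raise ValueError("subsets reference more features than the universe holds")

    @property
    def m(self) -> int:
        return len(self.subsets)

    @property
    def k(self) -> int:
        return len(self.subsets[0])


def kuncheva_index(subsets: Iterable[Sequence] | SubsetCollection,
                   n_features: int | None = None) -> float:
    """Chance-corrected mean pairwise similarity of equal-size feature subsets.

    Parameters
    ----------
    subsets
        An iterable of feature-id collections (each of the same size), or a
        prepared :class:`SubsetCollection`.
    n_features
        Size l of the full feature universe (required unless a
        :class:`SubsetCollection` is given).

    Returns
    -------
    float in [-1, 1]; 1 iff all subsets are identical.
    """
    if isinstance(subsets, SubsetCollection):
        coll = subsets
    else:
        if n_features is None:
            raise ValueError("n_features (l) is required")
        coll = SubsetCollection(tuple(frozenset(s) for s in subsets), int(n_features))

    ids = sorted(frozenset().union(*coll.subsets))
    index = {fid: j for j, fid in enumerate(ids)}
    member = np.zeros((coll.m, len(ids)), dtype=np.int64)
    for i, s in enumerate(coll.subsets):
        member[i, [index[fid] for fid in s]] = 1

    overlap = member @ member.T
    iu = np.triu_indices(coll.m, k=1)
    l, k = coll.n_features, coll.k
    pairwise = (overlap[iu] * l - k * k) / (k * (l - k))
    return float(pairwise.mean())
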