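"""Partition of scored sites into low- and high-temperature sets.

Sites are ranked by ascending temperature score; the lowest ``fraction`` of
sites forms the low-temperature set, the highest ``fraction`` the
high-temperature set, and the remainder is set aside.  With the default
fraction 0.40 and an odd number of sites the low set takes the floor and the
high set the ceiling (207 sites -> 82 low, 83 high), which balances distinct
temperature histories against set size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = ["SitePartition", "partition_sites"]


@dataclass(frozen=True)
class SitePartition:
    fraction: float
    ranking: tuple[str, ...]  # site ids by ascending score (ties by id)
    low_set: frozenset[str]
    high_set: frozenset[str]
    middle_set: frozenset[str]

    @property
    def n_sites(self) -> int:
        return len(self.ranking)


def partition_sites(scores: Mapping[str, float], fraction: float = 0.40) -> SitePartition:
    """Split sites into low / middle / high temperature sets by score rank.

    Parameters
    ----------
    scores : mapping site_id -> temperature score S.
    fraction : share of sites in each extreme set; must be in (0, 0.5].

    Ties in S are broken by site_id so the partition is deterministic.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 scored sites")
    ranking = tuple(sorted(scores, key=lambda s: (scores[s], s)))
    n_low = math.floor(fraction * n)
    n_high = math.ceil(fraction * n)
    low = frozenset(ranking[:n_low])
    high = frozenset(ranking[n - n_high:])
    middle = frozenset(ranking[n_low:n - n_high])
    return SitePartition(
        fraction=fraction, ranking=ranking, low_set=low, high_set=high, middle_set=middle
    )
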