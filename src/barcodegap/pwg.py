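"""The pairwise-distance (barcoding gap) discrimination criterion.

A species (or section) is *discriminated* when the minimum inter-group
distance involving it is strictly larger than its maximum intra-group
distance — a per-group barcoding gap.  Singletons have no intra-group
distance; by default they are excluded from the rate denominator
(``singleton_policy="exclude"``), or their intra distance can be treated as
zero (``"zero_intra"``).  The discrimination rate is the percentage of
non-excluded groups that pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .alignments import SpeciesPartition
from .distances import DistanceMatrix, GroupDistanceSummary, partition_distances

__all__ = [
    "GroupDecision",
    "pwg_decide",
    "evaluate_pwg",
    "discrimination_rate",
]

logger = logging.getLogger(__name__)

SINGLETON_POLICIES = ("exclude", "zero_intra")


@dataclass
class GroupDecision:
    """Outcome of the gap criterion for one group."""

    group_label: str
    n_members: int
    max_intra: float
    min_inter: float
    discriminated: bool
    reason: str  # gap_present | gap_absent | singleton_excluded | undefined_distances

    @property
    def excluded(self) -> bool:
        """True when the group does not enter the rate denominator."""
        return self.reason in ("singleton_excluded", "undefined_distances")


def pwg_decide(
    summary: GroupDistanceSummary, singleton_policy: str = "exclude"
) -> GroupDecision:
    """Apply the gap criterion (strict ``min_inter > max_intra``) to one group."""
    if singleton_policy not in SINGLETON_POLICIES:
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    max_intra = summary.max_intra
    min_inter = summary.min_inter
    if math.isnan(min_inter):
        logger.warning(
            "group %r: all inter-group distances undefined; excluded",
            summary.group_label,
        )
        return GroupDecision(
            summary.group_label, summary.n_members, max_intra, min_inter,
            discriminated=False, reason="undefined_distances",
        )
    if math.isnan(max_intra):
        if summary.n_members == 1 and singleton_policy == "zero_intra":
            max_intra = 0.0
        elif summary.n_members == 1:
            return GroupDecision(
                summary.group_label, summary.n_members, max_intra, min_inter,
                discriminated=False, reason="singleton_excluded",
            )
        else:
            # >=2 members but every intra pair undefined (saturation)
            return GroupDecision(
                summary.group_label, summary.n_members, max_intra, min_inter,
                discriminated=False, reason="undefined_distances",
            )
    ok = min_inter > max_intra
    return GroupDecision(
        summary.group_label, summary.n_members, max_intra, min_inter,
        discriminated=ok, reason="gap_present" if ok else "gap_absent",
    )


def discrimination_rate(decisions: Sequence) -> float:
    """Percent of non-excluded groups that were discriminated.

    Works for any decision objects exposing ``discriminated`` and
    ``excluded`` (both the gap-criterion and the tree-criterion decisions).
    """
    counted = [d for d in decisions if not d.excluded]
    if not counted:
        raise ValueError("no groups enter the rate denominator")
    return 100.0 * sum(d.discriminated for d in counted) / len(counted)


def evaluate_pwg(
    dm: DistanceMatrix,
    part: SpeciesPartition,
    singleton_policy: str = "exclude",
) -> tuple[list[GroupDecision], float]:
    """Convenience: per-group decisions plus the overall rate."""
    summaries, _ = partition_distances(dm, part)
    decisions = [pwg_decide(s, singleton_policy) for s in summaries]
    return decisions, discrimination_rate(decisions)
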