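"""Anchoring assembly scaffolds to linkage groups via mapped markers.

Marker-to-assembly alignment hits are filtered with the standard
linkage-map anchoring rules (top hits by score, best alignment coverage,
identity >= 90%, coverage >= 80%), then each scaffold is assigned the
linkage group most of its retained markers vote for.  Ties are reported
as conflicts, never silently resolved.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

__all__ = ["MarkerHit", "LGAssignment", "filter_marker_hits",
           "assign_linkage_groups", "anchoring_summary"]


@dataclass
class MarkerHit:
    marker_id: str
    linkage_group: str
    target_id: str
    identity: float       # percent
    coverage: float       # percent of marker length aligned
    score: float
    tstart: int = 0
    tend: int = 0

    def __post_init__(self):
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity and coverage must be in [0, 100]")


@dataclass
class LGAssignment:
    target_id: str
    assigned_lg: str | None
    vote_counts: dict[str, int]
    status: str  # unambiguous | majority | conflicted


def filter_marker_hits(hits: list[MarkerHit], min_identity: float = 90.0,
                       min_coverage: float = 80.0, top: int = 5
                       ) -> list[MarkerHit]:
    """Apply the marker-hit retention rules per marker.

    Per marker: rank hits by score and keep the top ``top`` (ties at the
    last rank all kept); among those, keep the hit(s) with maximal
    alignment coverage (several targets sharing it are all retained);
    finally drop anything below the identity/coverage thresholds.
    The operation is idempotent.
    """
    by_marker: dict[str, list[MarkerHit]] = defaultdict(list)
    for h in hits:
        by_marker[h.marker_id].append(h)
    retained: list[MarkerHit] = []
    for marker, hs in by_marker.items():
        hs = sorted(hs, key=lambda h: h.score, reverse=True)
        if len(hs) > top:
            cut_score = hs[top - 1].score
            hs = [h for h in hs if h.score >= cut_score]
        best_cov = max(h.coverage for h in hs)
        hs = [h for h in hs if h.coverage == best_cov]
        retained.extend(h for h in hs
                        if h.identity >= min_identity and h.coverage >= min_coverage)
    return retained


def assign_linkage_groups(retained_hits: list[MarkerHit]) -> list[LGAssignment]:
    """Per-target plurality vote over the linkage groups of its markers.

    A (marker, target) pair votes once however many hits connect it.
    A tie for the maximum leaves the target conflicted and unassigned.
    """
    votes: dict[str, Counter] = defaultdict(Counter)
    seen: set[tuple[str, str]] = set()
    for h in retained_hits:
        key = (h.marker_id, h.target_id)
        if key in seen:
            continue
        seen.add(key)
        votes[h.target_id][h.linkage_group] += 1
    out = []
    for target, counter in votes.items():
        ranked = counter.most_common()
        top_lg, top_n = ranked[0]
        if len(ranked) == 1:
            status, assigned = "unambiguous", top_lg
        elif ranked[1][1] == top_n:
            status, assigned = "conflicted", None
        else:
            status, assigned = "majority", top_lg
        out.append(LGAssignment(target, assigned, dict(counter), status))
    return out


def anchoring_summary(assignments: list[LGAssignment],
                      retained_hits: list[MarkerHit],
                      n_markers_total: int,
                      assembly_lengths: dict[str, int]
                      ) -> tuple[float, float]:
    """(fraction of markers placed, fraction of assembly length anchored).

    A marker counts as placed when it has a retained hit on a target
    that received an assignment; anchored length sums the lengths of
    assigned targets.
    """
    assigned = {a.target_id for a in assignments if a.assigned_lg is not None}
    placed = {h.marker_id for h in retained_hits if h.target_id in assigned}
    frac_markers = len(placed) / n_markers_total if n_markers_total else 0.0
    total_len = sum(assembly_lengths.values())
    anchored_len = sum(l for t, l in assembly_lengths.items() if t in assigned)
    frac_length = anchored_len / total_len if total_len else 0.0
    return frac_markers, frac_length


def assignments_table(assignments: list[LGAssignment]) -> pd.DataFrame:
    rows = [(a.target_id, a.assigned_lg or "", a.status,
             ";".join(f"{lg}:{n}" for lg, n in sorted(a.vote_counts.items())))
            for a in assignments]
    return pd.DataFrame(rows, columns=["target_id", "assigned_lg", "status", "votes"])
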