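"""Pseudo-scaffolds from chained read placements (B-chromosome analysis).

Reads derived from a supernumerary B chromosome map back to scattered
homologous regions of the A-chromosome assembly.  Placements on the same
target are chained across gaps strictly smaller than ``max_gap``
(default 10 kb) into pseudo-scaffolds, whose spans are then summarized
per linkage group to describe the B chromosome's homology composition.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

__all__ = ["PseudoScaffold", "chain_placements", "homology_composition"]


@dataclass
class PseudoScaffold:
    target_id: str
    start: int
    end: int
    n_reads: int
    assigned_lg: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start


def chain_placements(placements: list[tuple[str, int, int]],
                     max_gap: int = 10_000) -> list[PseudoScaffold]:
    """Merge per-target read placements across gaps < ``max_gap`` (strict).

    Placements are (target, start, end) intervals; order does not
    matter.  Output intervals are disjoint per target with pairwise
    gaps >= max_gap, and member counts are conserved.
    """
    by_target: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for target, start, end in placements:
        if end < start:
            raise ValueError(f"negative-length interval ({target}, {start}, {end})")
        by_target[target].append((start, end))
    out: list[PseudoScaffold] = []
    for target in sorted(by_target):
        ivs = sorted(by_target[target])
        cur_s, cur_e = ivs[0]
        n = 1
        for s, e in ivs[1:]:
            if s - cur_e < max_gap:
                cur_e = max(cur_e, e)
                n += 1
            else:
                out.append(PseudoScaffold(target, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        out.append(PseudoScaffold(target, cur_s, cur_e, n))
    return out


def homology_composition(pseudo_scaffolds: list[PseudoScaffold],
                         lg_assignments: dict[str, str | None]
                         ) -> pd.DataFrame:
    """Summed pseudo-scaffold span per linkage group.

    Targets with no (or None) assignment fall into the "unassigned"
    bucket.  Spans conserve the total; fractions sum to 1.
    """
    spans: dict[str, int] = defaultdict(int)
    for ps in pseudo_scaffolds:
        lg = lg_assignments.get(ps.target_id) or "unassigned"
        ps.assigned_lg = None if lg == "unassigned" else lg
        spans[lg] += ps.span
    total = sum(spans.values())
    rows = [(lg, spans[lg], spans[lg] / total if total else 0.0)
            for lg in sorted(spans)]
    return pd.DataFrame(rows, columns=["linkage_group", "span", "fraction"])
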