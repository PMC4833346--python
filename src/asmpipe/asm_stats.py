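"""Assembly QC statistics: Nx/Lx, GC window profiles, clone-end concordance.

Clone-end (BES-style) pairs validate long-range contiguity: a pair is
"proper" when both ends land on the same scaffold, in convergent
orientation, separated by the library insert range (default 50-250 kb).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq import encode

__all__ = ["EndPair", "nx_stats", "gc_windows", "classify_end_pairs"]

CATEGORIES = ("same_scaffold_proper", "same_scaffold_improper",
              "different_scaffold", "orphan")


@dataclass
class EndPair:
    """Placements of the two ends of one clone; either end may be unaligned."""

    pair_id: str
    end1: tuple[str, int, int, str] | None  # (target, start, end, strand)
    end2: tuple[str, int, int, str] | None


def nx_stats(lengths, x_percent: float = 50.0) -> tuple[int, int]:
    """(Nx, Lx): length at which the descending cumulative sum first
    reaches x% of the total, and the number of records needed."""
    lengths = sorted(int(l) for l in lengths)
    if not lengths:
        raise ValueError("empty length list")
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    threshold = x_percent / 100.0 * sum(lengths)
    cum = 0
    for i, l in enumerate(reversed(lengths)):
        cum += l
        if cum >= threshold:
            return l, i + 1
    raise AssertionError("unreachable")  # pragma: no cover


def gc_windows(sequences: dict[str, str], window: int = 20_000,
               max_n_fraction: float = 0.25, stride: int | None = None
               ) -> pd.DataFrame:
    """Per-window GC% over an assembly.

    Windows tile each sequence (``stride`` defaults to ``window``,
    i.e. non-overlapping); a window is discarded when its N fraction
    *exceeds* ``max_n_fraction``.  GC is computed over non-N bases only.
    Returns columns (sequence_id, start, end, gc_percent).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    stride = stride or window
    rows = []
    for name, seq in sequences.items():
        arr = encode(seq)
        for start in range(0, max(len(arr) - window, 0) + 1, stride):
            w = arr[start:start + window]
            if len(w) < window:
                break
            n_count = int(np.count_nonzero(w >= 4))
            if n_count / window > max_n_fraction:
                continue
            non_n = window - n_count
            if non_n == 0:
                continue
            gc = int(np.count_nonzero((w == 1) | (w == 2)))
            rows.append((name, start, start + window, 100.0 * gc / non_n))
    return pd.DataFrame(rows, columns=["sequence_id", "start", "end", "gc_percent"])


def gc_distribution(windows: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """Normalized distribution of window GC% (sums to 1)."""
    if windows.empty:
        return pd.DataFrame(columns=["gc_bin", "fraction"])
    bins = np.floor(windows["gc_percent"] / bin_width) * bin_width
    counts = bins.value_counts().sort_index()
    return pd.DataFrame({"gc_bin": counts.index.to_numpy(),
                         "fraction": (counts / counts.sum()).to_numpy()})


def classify_end_pairs(pairs: list[EndPair], d_min: int = 50_000,
                       d_max: int = 250_000) -> pd.DataFrame:
    """Classify clone-end pairs into proper / improper / split / orphan.

    Separation is measured between the outermost aligned coordinates of
    the two ends (insert-size semantics); "proper orientation" means the
    ends are on opposite strands pointing toward each other.
    Returns one row per category with counts and fractions.
    """
    seen = set()
    counts = Counter({c: 0 for c in CATEGORIES})
    for p in pairs:
        if p.pair_id in seen:
            raise ValueError(f"duplicate pair_id {p.pair_id!r}")
        seen.add(p.pair_id)
        counts[_classify(p, d_min, d_max)] += 1
    total = sum(counts.values())
    return pd.DataFrame({
        "category": list(CATEGORIES),
        "count": [counts[c] for c in CATEGORIES],
        "fraction": [counts[c] / total if total else 0.0 for c in CATEGORIES],
    })


def _classify(p: EndPair, d_min: int, d_max: int) -> str:
    if p.end1 is None or p.end2 is None:
        return "orphan"
    t1, s1, e1, str1 = p.end1
    t2, s2, e2, str2 = p.end2
    if t1 != t2:
        return "different_scaffold"
    separation = max(e1, e2) - min(s1, s2)
    left, right = (p.end1, p.end2) if s1 <= s2 else (p.end2, p.end1)
    convergent = left[3] == "+" and right[3] == "-"
    if convergent and d_min <= separation <= d_max:
        return "same_scaffold_proper"
    return "same_scaffold_improper"
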