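"""Tandem monomer scanning: telomere-style array detection and density.

Occurrences of an exact monomer (e.g. the vertebrate telomeric unit
TTAGGG) are located on one or both strands, chained into perfect tandem
arrays or interrupted "trains" (runs broken by short spacers), and
summarized as positional density profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq import revcomp

__all__ = ["Occurrence", "RepeatArray", "scan_monomer", "tandem_arrays",
           "density_profile"]


@dataclass(frozen=True)
class Occurrence:
    position: int
    strand: str


@dataclass
class RepeatArray:
    sequence_id: str | None
    start: int
    end: int
    monomer: str
    copy_number: int
    interrupted: bool
    strand: str


def scan_monomer(sequence: str, monomer: str, both_strands: bool = False
                 ) -> list[Occurrence]:
    """All exact occurrences of the monomer (overlapping ones included).

    With ``both_strands``, occurrences of the reverse complement are
    reported at their forward-strand positions with strand '-'; a
    palindromic monomer is reported once, on '+'.
    """
    if len(monomer) < 4:
        raise ValueError("monomer length must be >= 4")
    if "N" in monomer.upper():
        raise ValueError("monomer must not contain N")
    monomer = monomer.upper()
    occ = [Occurrence(p, "+") for p in _find_all(sequence, monomer)]
    if both_strands:
        rc = revcomp(monomer)
        if rc != monomer:
            occ.extend(Occurrence(p, "-") for p in _find_all(sequence, rc))
    occ.sort(key=lambda o: (o.position, o.strand))
    return occ


def _find_all(haystack: str, needle: str):
    p = haystack.find(needle)
    while p != -1:
        yield p
        p = haystack.find(needle, p + 1)


def tandem_arrays(occurrences: list[Occurrence], monomer_length: int,
                  max_spacer: int = 0, min_copies: int = 2,
                  monomer: str = "", sequence_id: str | None = None
                  ) -> list[RepeatArray]:
    """Chain monomer occurrences into arrays and interrupted trains.

    Occurrences are first de-overlapped leftmost-greedily per strand
    (self-overlapping monomers match at every offset).  Consecutive
    copies spaced exactly ``monomer_length`` apart extend a perfect
    array; a gap of up to ``max_spacer`` bases between copies keeps the
    run together as an interrupted train.  Runs below ``min_copies``
    are not reported.
    """
    arrays: list[RepeatArray] = []
    for strand in "+-":
        pos = sorted(o.position for o in occurrences if o.strand == strand)
        taken: list[int] = []
        last_end = -1
        for p in pos:
            if p >= last_end:
                taken.append(p)
                last_end = p + monomer_length
        run: list[int] = []
        interrupted = False
        for p in taken:
            if run and p == run[-1] + monomer_length:
                run.append(p)
            elif run and 0 < p - (run[-1] + monomer_length) <= max_spacer:
                run.append(p)
                interrupted = True
            else:
                _flush(arrays, run, interrupted, monomer_length, min_copies,
                       monomer, strand, sequence_id)
                run, interrupted = [p], False
        _flush(arrays, run, interrupted, monomer_length, min_copies,
               monomer, strand, sequence_id)
    arrays.sort(key=lambda a: a.start)
    return arrays


def _flush(arrays, run, interrupted, monomer_length, min_copies, monomer,
           strand, sequence_id):
    if len(run) >= min_copies:
        arrays.append(RepeatArray(
            sequence_id=sequence_id, start=run[0],
            end=run[-1] + monomer_length, monomer=monomer,
            copy_number=len(run), interrupted=interrupted, strand=strand))


def density_profile(occurrences: list[Occurrence], sequence_length: int,
                    window: int) -> np.ndarray:
    """Occurrence counts per non-overlapping window; counts sum to the
    number of occurrences."""
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows = -(-sequence_length // window) if sequence_length else 0
    pos = np.array([o.position for o in occurrences], dtype=int)
    if pos.size == 0:
        return np.zeros(max(n_windows, 0), dtype=int)
    return np.bincount(pos // window, minlength=n_windows)
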