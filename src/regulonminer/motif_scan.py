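"""Mismatch-tolerant motif scanning and composite binding-site assembly.

The CbrB upstream activating sequence (UAS) is not a palindrome: it is a
chain of 6-bp subsites, TGTTAC read directly (type F) or its reverse
complement GTAACA (type R), whose centres sit 20-25 bp apart so that
successive sites fall on (approximately) the same face of the DNA helix.
This module provides:

* :func:`scan_hexamer` -- Hamming scan of a 6-mer over a sequence;
* :func:`find_subsites` -- F/R subsite hits on the analysed strand;
* :func:`find_sigma54`  -- GG-N10-GC sigma-54 promoter elements;
* :func:`find_ihf`      -- degenerate IUPAC consensus hits (IHF);
* :func:`assemble_composites` -- maximal subsite chains under spacing,
  helical-phasing and global mismatch-budget constraints.

Centres of even-length motifs are fractional: a hexamer starting at ``s``
has centre ``s + 2.5`` and a 14-bp sigma-54 element has centre ``s + 6.5``.
Spacing is always measured centre-to-centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from .core_io import ConfigError

F_MOTIF = "TGTTAC"
R_MOTIF = "GTAACA"
SIGMA54_LENGTH = 14


@dataclass(frozen=True)
class SubsiteHit:
    """One F- or R-type subsite match on the analysed strand."""

    kind: str            # 'F' or 'R'
    start: int           # 0-based on the analysed strand
    mismatches: int
    observed: str        # the matched 6-mer

    @property
    def center(self) -> float:
        return self.start + 2.5


@dataclass(frozen=True)
class SigmaPromoterHit:
    """A GG-N10-GC sigma-54 promoter element (14 bp)."""

    start: int
    anchor_mismatches: int
    strand: str = "+"
    length: int = SIGMA54_LENGTH

    @property
    def center(self) -> float:
        return self.start + 6.5


@dataclass(frozen=True)
class IHFHit:
    """A match to the degenerate IHF consensus."""

    start: int
    end: int             # exclusive
    consensus: str
    mismatches: int

    @property
    def center(self) -> float:
        return (self.start + self.end - 1) / 2.0


@dataclass(frozen=True)
class CompositeSite:
    """A chain of >=2 subsites satisfying spacing/phase/budget constraints.

    ``rank`` is 'primary' for the chain selected by the tie-break rule
    (more subsites, then fewer mismatches, then leftmost) within a group of
    overlapping chains, and 'secondary' for the others.
    """

    subsites: tuple[SubsiteHit, ...]
    spacings: tuple[float, ...]
    total_mismatches: int
    phase_deviations: tuple[float, ...]
    span: tuple[int, int]               # [start, end) on the analysed strand
    rank: str = "primary"

    @property
    def n_subsites(self) -> int:
        return len(self.subsites)

    @property
    def start(self) -> int:
        return self.span[0]


def _window_mismatches(seq: str, length: int) -> np.ndarray | None:
    """Stack of all windows of ``length`` as a (n, length) byte matrix."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    if arr.size < length:
        return None
    return np.lib.stride_tricks.sliding_window_view(arr, length)


def scan_hexamer(seq: str, motif: str, max_mm: int) -> list[tuple[int, int]]:
    """All start positions where ``motif`` matches within ``max_mm`` mismatches.

    An ``N`` in the sequence never matches a motif base and therefore counts
    as a mismatch.  Returns ``(start, mismatches)`` pairs in ascending start
    order; sequences shorter than the motif yield an empty list.
    """
    if len(motif) != 6 or set(motif) - set("ACGT"):
        raise ConfigError(f"motif {motif!r} must be a 6-mer over ACGT")
    if not 0 <= max_mm <= 6:
        raise ConfigError(f"max_mm {max_mm} outside 0..6")
    windows = _window_mismatches(seq.upper(), 6)
    if windows is None:
        return []
    pattern = np.frombuffer(motif.encode("ascii"), dtype="S1")
    mm = (windows != pattern).sum(axis=1)
    starts = np.nonzero(mm <= max_mm)[0]
    return [(int(s), int(mm[s])) for s in starts]


def find_subsites(
    seq: str,
    max_mm_per_site: int = 2,
    motif_f: str = F_MOTIF,
    motif_r: str = R_MOTIF,
) -> list[SubsiteHit]:
    """F- and R-type subsite hits on the analysed strand, sorted by start.

    Because the R motif is the reverse complement of the F motif, scanning a
    single strand with both motifs covers binding in either orientation:
    an F site on the opposite strand appears here as an R hit.
    """
    seq = seq.upper()
    hits = [
        SubsiteHit("F", s, mm, seq[s : s + 6])
        for s, mm in scan_hexamer(seq, motif_f, max_mm_per_site)
    ] + [
        SubsiteHit("R", s, mm, seq[s : s + 6])
        for s, mm in scan_hexamer(seq, motif_r, max_mm_per_site)
    ]
    hits.sort(key=lambda h: (h.start, h.kind))
    return hits


def find_sigma54(seq: str, anchor_mm: int = 0) -> list[SigmaPromoterHit]:
    """All 14-mer windows whose GG (pos 1-2) and GC (pos 13-14) anchors match.

    ``anchor_mm`` is the total number of mismatches tolerated across the four
    anchor bases; the ten interior bases are unconstrained.
    """
    if anchor_mm not in (0, 1, 2):
        raise ConfigError(f"anchor_mm {anchor_mm} must be 0, 1 or 2")
    windows = _window_mismatches(seq.upper(), SIGMA54_LENGTH)
    if windows is None:
        return []
    mm = (
        (windows[:, 0] != b"G").astype(np.int64)
        + (windows[:, 1] != b"G")
        + (windows[:, 12] != b"G")
        + (windows[:, 13] != b"C")
    )
    starts = np.nonzero(mm <= anchor_mm)[0]
    return [SigmaPromoterHit(int(s), int(mm[s])) for s in starts]


def _iupac_sets(consensus: str) -> list[frozenset[bytes]]:
    sets = []
    for code in consensus.upper():
        try:
            bases = ambiguous_dna_values[code]
        except KeyError:
            raise ConfigError(f"invalid IUPAC code {code!r} in consensus") from None
        sets.append(frozenset(b.encode("ascii") for b in bases))
    return sets


def find_ihf(
    seq: str, consensus: str = "WATCAANNNNTTR", max_mm: int = 0
) -> list[IHFHit]:
    """Windows matching a degenerate IUPAC consensus within ``max_mm``.

    IUPAC class membership counts as a match (``W`` matches A or T, ``N``
    matches anything); an ``N`` in the *sequence* only matches consensus
    positions whose class contains all four bases.
    """
    length = len(consensus)
    windows = _window_mismatches(seq.upper(), length)
    if windows is None:
        return []
    mm = np.zeros(windows.shape[0], dtype=np.int64)
    for i, allowed in enumerate(_iupac_sets(consensus)):
        if len(allowed) == 4:
            continue  # N-class positions match everything except sequence N
            # (handled below: sequence N is in no 4-base class anyway)
        col = windows[:, i]
        ok = np.zeros(windows.shape[0], dtype=bool)
        for b in allowed:
            ok |= col == b
        mm += ~ok
    starts = np.nonzero(mm <= max_mm)[0]
    return [IHFHit(int(s), int(s) + length, consensus, int(mm[s])) for s in starts]


def phase_deviation(distance: float, period: float = 10.5) -> float:
    """Distance of ``distance`` from the nearest integer number of helical turns."""
    r = distance % period
    return min(r, period - r)


def assemble_composites(
    subsites: list[SubsiteHit],
    min_sites: int = 2,
    spacing: tuple[float, float] = (20.0, 25.0),
    budget: int = 2,
    phase_period: float = 10.5,
    phase_tol: float = 4.0,
) -> list[CompositeSite]:
    """Maximal subsite chains under spacing, phasing and mismatch constraints.

    A chain is valid when every consecutive centre-to-centre distance lies in
    ``[spacing[0], spacing[1]]``, every such distance is within ``phase_tol``
    of an integer number of ``phase_period`` turns, and the summed mismatches
    of its subsites do not exceed ``budget`` (the global cap; the per-site
    cap is applied upstream by :func:`find_subsites`).

    Only maximal chains (not a contiguous sub-chain of another valid chain)
    are reported.  Overlapping chains are ranked: more subsites, then fewer
    total mismatches, then leftmost start; within each overlap group the
    winner is 'primary' and the rest 'secondary'.  Output is sorted by start.
    """
    hits = sorted(subsites, key=lambda h: (h.center, h.kind))
    n = len(hits)
    if n == 0:
        return []

    smin, smax = spacing

    def edge_ok(i: int, j: int) -> bool:
        d = hits[j].center - hits[i].center
        return smin <= d <= smax and phase_deviation(d, phase_period) <= phase_tol

    successors: list[list[int]] = [
        [j for j in range(i + 1, n) if edge_ok(i, j)] for i in range(n)
    ]

    chains: list[tuple[int, ...]] = []

    def extend(path: list[int], mm: int) -> None:
        extended = False
        for j in successors[path[-1]]:
            if mm + hits[j].mismatches <= budget:
                extended = True
                path.append(j)
                extend(path, mm + hits[j].mismatches)
                path.pop()
        if not extended and len(path) >= min_sites:
            chains.append(tuple(path))

    for i in range(n):
        if hits[i].mismatches <= budget:
            extend([i], hits[i].mismatches)

    # drop chains that are contiguous sub-chains of another collected chain
    chain_set = set(chains)
    maximal = []
    for c in chain_set:
        contained = any(
            other != c
            and len(other) > len(c)
            and any(other[k : k + len(c)] == c for k in range(len(other) - len(c) + 1))
            for other in chain_set
        )
        if not contained:
            maximal.append(c)

    def build(indices: tuple[int, ...], rank: str) -> CompositeSite:
        sites = tuple(hits[i] for i in indices)
        spacings = tuple(
            sites[k + 1].center - sites[k].center for k in range(len(sites) - 1)
        )
        return CompositeSite(
            subsites=sites,
            spacings=spacings,
            total_mismatches=sum(s.mismatches for s in sites),
            phase_deviations=tuple(
                phase_deviation(d, phase_period) for d in spacings
            ),
            span=(sites[0].start, sites[-1].start + 6),
            rank=rank,
        )

    prelim = [build(c, "primary") for c in maximal]
    prelim.sort(key=lambda c: (-c.n_subsites, c.total_mismatches, c.start))

    selected: list[CompositeSite] = []
    out: list[CompositeSite] = []
    for comp in prelim:
        overlapping = any(
            comp.span[0] < s.span[1] and s.span[0] < comp.span[1] for s in selected
        )
        if overlapping:
            out.append(
                CompositeSite(
                    subsites=comp.subsites,
                    spacings=comp.spacings,
                    total_mismatches=comp.total_mismatches,
                    phase_deviations=comp.phase_deviations,
                    span=comp.span,
                    rank="secondary",
                )
            )
        else:
            selected.append(comp)
            out.append(comp)
    out.sort(key=lambda c: (c.start, c.rank, -c.n_subsites))
    return out


def composite_score(c: CompositeSite, budget: int = 2) -> float:
    """Deterministic ranking score: ``n_subsites - total_mismatches/(budget+1)``.

    Higher is better; agrees with the lexicographic order (more subsites,
    then fewer mismatches) whenever total mismatches stay within the budget.
    """
    return c.n_subsites - c.total_mismatches / (budget + 1)
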