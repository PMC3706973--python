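"""Core sequence types and in silico restriction digestion.

Coordinates are 0-based, half-open throughout.  A :class:`Duplex` models a
(possibly partially single-stranded) double-stranded DNA molecule as a
*sense* sequence spanning the full footprint of the molecule, with each
strand occupying a sub-interval of that span.  This makes restriction
fragments with 5' overhangs representable without any special casing: an
overhang is simply a region covered by one strand only.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def _validate(seq: str) -> str:
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise InvalidSequenceError(f"invalid DNA characters: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving)."""
    _validate(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G+C among unambiguous bases.

    ``N`` bases are excluded from both numerator and denominator.  Raises
    on an empty sequence or a sequence consisting only of ``N``.
    """
    _validate(seq)
    s = seq.upper()
    if not s:
        raise ValueError("gc_content of empty sequence is undefined")
    n_unambig = len(s) - s.count("N")
    if n_unambig == 0:
        raise ValueError("gc_content undefined: sequence is all N")
    return (s.count("G") + s.count("C")) / n_unambig


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        label = f" ({self.name})" if self.name else ""
        return f"{self.contig}:{self.start}-{self.end}{label}"


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type IIS (or ordinary) restriction enzyme.

    Cut offsets are signed base counts measured 3' of the last base of the
    recognition sequence on the strand carrying the recognition site.  Equal
    offsets define a blunt cutter; ``top_cut_offset < bottom_cut_offset``
    leaves a 5' overhang.
    """

    name: str
    recognition: str
    top_cut_offset: int
    bottom_cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")
        _validate(self.recognition)

    @property
    def is_blunt(self) -> bool:
        return self.top_cut_offset == self.bottom_cut_offset


#: Standard catalog geometries for the two probe-trimming enzymes.
MLYI = RestrictionEnzyme("MlyI", "GAGTC", 5, 5)
BSAI = RestrictionEnzyme("BsaI", "GGTCTC", 1, 5)


@dataclass
class Duplex:
    """A double-stranded DNA molecule, possibly with recessed strand ends.

    ``sense`` is the top-strand sequence over the molecule's full span.  The
    top strand covers ``sense[top_lo:top_hi]``; the bottom strand is the
    reverse complement of ``sense[bot_lo:bot_hi]``.  A fully double-stranded
    blunt molecule has all four bounds at the defaults.
    """

    sense: str
    top_lo: int = 0
    top_hi: int | None = None
    bot_lo: int = 0
    bot_hi: int | None = None
    phos_top5: bool = False
    phos_bot5: bool = False

    def __post_init__(self) -> None:
        _validate(self.sense)
        n = len(self.sense)
        if self.top_hi is None:
            self.top_hi = n
        if self.bot_hi is None:
            self.bot_hi = n
        for lo, hi in ((self.top_lo, self.top_hi), (self.bot_lo, self.bot_hi)):
            if not (0 <= lo <= hi <= n):
                raise ValueError("strand bounds outside duplex span")

    @property
    def length(self) -> int:
        """Full span of the molecule in base pairs."""
        return len(self.sense)

    @property
    def top(self) -> str:
        """Top strand, 5'->3'."""
        return self.sense[self.top_lo : self.top_hi]

    @property
    def bottom(self) -> str:
        """Bottom strand, 5'->3'."""
        return revcomp(self.sense[self.bot_lo : self.bot_hi])

    def end_annotation(self, side: str) -> dict:
        """Describe one end (``'left'`` or ``'right'``) of the duplex.

        Returns ``{'kind': 'blunt'}`` or ``{'kind': "5_overhang", 'strand':
        'top'|'bottom', 'seq': <sense-coordinate bases>}``.  3' recessed ends
        do not arise from the enzymes modelled here but would be reported as
        overhangs of the protruding strand.
        """
        if side == "left":
            t, b = self.top_lo, self.bot_lo
            if t == b:
                return {"kind": "blunt"}
            if t < b:  # top strand protrudes at its 5' end
                return {"kind": "5_overhang", "strand": "top", "seq": self.sense[t:b]}
            return {"kind": "3_overhang", "strand": "bottom", "seq": self.sense[b:t]}
        if side == "right":
            t, b = self.top_hi, self.bot_hi
            if t == b:
                return {"kind": "blunt"}
            if b > t:  # bottom strand protrudes at its 5' end
                return {"kind": "5_overhang", "strand": "bottom", "seq": self.sense[t:b]}
            return {"kind": "3_overhang", "strand": "top", "seq": self.sense[b:t]}
        raise ValueError("side must be 'left' or 'right'")


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[tuple[int, str]]:
    """All recognition-site occurrences on either strand of ``seq``.

    Positions are 0-based indices of the first base of the occurrence on the
    top strand; overlapping occurrences are all reported.  ``N`` never
    matches.  Results are sorted by position.
    """
    _validate(seq)
    s = seq.upper()
    hits: list[tuple[int, str]] = []
    # For palindromic recognition sequences every position is reported on
    # both strands, matching the physical picture of two bound orientations.
    patterns = [
        (enzyme.recognition.upper(), "+"),
        (revcomp(enzyme.recognition).upper(), "-"),
    ]
    for pat, strand in patterns:
        start = s.find(pat)
        while start != -1:
            hits.append((start, strand))
            start = s.find(pat, start + 1)
    return sorted(hits)


def _cut_coordinates(
    pos: int, strand: str, enzyme: RestrictionEnzyme
) -> tuple[int, int]:
    """(top_cut, bottom_cut) span coordinates for one site occurrence.

    A cut coordinate ``c`` means the phosphodiester bond between positions
    ``c - 1`` and ``c`` of that strand (in sense coordinates) is broken.
    """
    m = len(enzyme.recognition)
    if strand == "+":
        return pos + m + enzyme.top_cut_offset, pos + m + enzyme.bottom_cut_offset
    # Site on the bottom strand: geometry mirrors leftwards.  The enzyme's
    # "top strand" is the duplex bottom strand here.
    return pos - enzyme.bottom_cut_offset, pos - enzyme.top_cut_offset


def digest(
    duplex: Duplex,
    enzymes: list[RestrictionEnzyme] | tuple[RestrictionEnzyme, ...],
    skipped: list[dict] | None = None,
) -> list[Duplex]:
    """Cut ``duplex`` at every site of every enzyme.

    Fragments are returned 5'->3' along the top strand with overhang-aware
    strand bounds; newly created 5' ends are flagged phosphorylated.  Sites
    whose cut positions fall outside the molecule are skipped; a record is
    appended to ``skipped`` when a list is supplied.  Total base count on
    each strand is conserved.
    """
    n = len(duplex.sense)
    cuts: set[tuple[int, int]] = set()
    for enzyme in enzymes:
        for pos, strand in find_sites(duplex.sense, enzyme):
            t, b = _cut_coordinates(pos, strand, enzyme)
            if not (duplex.top_lo <= t <= duplex.top_hi and duplex.bot_lo <= b <= duplex.bot_hi):
                if skipped is not None:
                    skipped.append(
                        {"enzyme": enzyme.name, "pos": pos, "strand": strand,
                         "top_cut": t, "bottom_cut": b}
                    )
                continue
            cuts.add((t, b))
    ordered = sorted(cuts)
    # Drop degenerate cuts coinciding with the existing ends.
    ordered = [
        (t, b)
        for t, b in ordered
        if (t, b) != (duplex.top_lo, duplex.bot_lo)
        and (t, b) != (duplex.top_hi, duplex.bot_hi)
    ]
    # Cut pairs whose overhang footprints cross cannot both be applied
    # (both bonds of the later one no longer exist); leftmost wins.
    monotone: list[tuple[int, int]] = []
    for t, b in ordered:
        if monotone and b < monotone[-1][1]:
            if skipped is not None:
                skipped.append(
                    {"enzyme": None, "pos": None, "strand": None,
                     "top_cut": t, "bottom_cut": b, "reason": "crossing"}
                )
            continue
        monotone.append((t, b))
    ordered = monotone
    if not ordered:
        return [duplex]
    bounds = [(duplex.top_lo, duplex.bot_lo)] + ordered + [(duplex.top_hi, duplex.bot_hi)]
    fragments: list[Duplex] = []
    for i in range(len(bounds) - 1):
        (t0, b0), (t1, b1) = bounds[i], bounds[i + 1]
        lo = min(t0, b0)
        hi = max(t1, b1)
        fragments.append(
            Duplex(
                sense=duplex.sense[lo:hi],
                top_lo=t0 - lo,
                top_hi=t1 - lo,
                bot_lo=b0 - lo,
                bot_hi=b1 - lo,
                phos_top5=duplex.phos_top5 if i == 0 else True,
                phos_bot5=duplex.phos_bot5 if i == len(bounds) - 2 else True,
            )
        )
    return fragments
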