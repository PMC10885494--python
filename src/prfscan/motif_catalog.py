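"""Slippery-site motif classes and overlap-window scanning.

Ten motif classes are recognised.  Eight describe backward (-1) slippage --
*six*, *threethree*, *fivetwo*, *twofive*, *twofour*, *threetwotwo*, *five*
and *twoonefour* -- and two describe forward (+1) slippage, *four* and
*three*.  A class name encodes its template as run lengths of identical
nucleotides: *threethree* is the canonical heptamer core XXXYYY, *fivetwo*
is XXXXXYY (e.g. GGGGGAA), and so on.  Adjacent runs must use different
nucleotides; any base may fill any run.

Every motif is right-anchored at the last base of the ribosome's P-site
codon, so a 7-nt template starts one base before the E-site codon (the
classic X XXY YYZ register), a 6-nt template covers the E and P codons
exactly, and the forward 3/4-nt templates end at the P-site codon end.

Because some templates are subsets of others (every *six* is a
*threethree*), classification returns the matching class with the lowest
probability of occurring in random sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genbank_io import CodonUsageTable
from .orf_geometry import GenePair

MOTIF_CATALOG_VERSION = "1"

BACKWARD, FORWARD = -1, 1


@dataclass(frozen=True)
class MotifClass:
    name: str
    code: int
    direction: int  # -1 backward, +1 forward
    runs: tuple[int, ...]

    @property
    def span(self) -> int:
        return sum(self.runs)

    def matches(self, window: str) -> bool:
        """Right-anchored template match on a window of length >= span."""
        if len(window) < self.span:
            return False
        s = window[len(window) - self.span :]
        i = 0
        prev = None
        for run in self.runs:
            group = s[i : i + run]
            base = group[0]
            if base not in "ACGT" or group.count(base) != run:
                return False
            if prev is not None and base == prev:
                return False
            prev = base
            i += run
        return True


#: the ten classes; codes are stable and appear as the MOTIF feature value
MOTIF_CLASSES: tuple[MotifClass, ...] = (
    MotifClass("six", 0, BACKWARD, (6,)),
    MotifClass("threethree", 1, BACKWARD, (3, 3)),
    MotifClass("fivetwo", 2, BACKWARD, (5, 2)),
    MotifClass("twofive", 3, BACKWARD, (2, 5)),
    MotifClass("twofour", 4, BACKWARD, (2, 4)),
    MotifClass("threetwotwo", 5, BACKWARD, (3, 2, 2)),
    MotifClass("five", 6, BACKWARD, (5,)),
    MotifClass("twoonefour", 7, BACKWARD, (2, 1, 4)),
    MotifClass("four", 8, FORWARD, (4,)),
    MotifClass("three", 9, FORWARD, (3,)),
)

MOTIF_BY_NAME = {m.name: m for m in MOTIF_CLASSES}

WINDOW_LEN = 7  # longest template span


def random_probability(motif: MotifClass) -> float:
    """Probability that an iid uniform window of length ``span`` matches.

    The first run can use any of the 4 bases and each subsequent run any of
    the 3 bases differing from its neighbour: 4 * 3^(g-1) matching strings
    out of 4^span.
    """
    g = len(motif.runs)
    return 4 * 3 ** (g - 1) / 4**motif.span


def _precedence_key(motif: MotifClass) -> tuple:
    # lower random probability wins; ties to the longer span, then the code
    return (random_probability(motif), -motif.span, motif.code)


def classify_window(
    window: str,
    directions: tuple[int, ...] = (BACKWARD, FORWARD),
    max_span: int | None = None,
) -> MotifClass | None:
    """Classify a 7-nt window ending at a P-site codon boundary.

    Windows containing anything outside A/C/G/T (including N) never match.
    Among all right-anchored template matches the class with the lowest
    random-occurrence probability takes precedence.  ``max_span`` limits the
    classes considered to those fitting in the available sequence (used when
    the window is clipped by the overlap region's 5' edge).
    """
    hits = [
        m
        for m in MOTIF_CLASSES
        if m.direction in directions
        and (max_span is None or m.span <= max_span)
        and m.matches(window)
    ]
    if not hits:
        return None
    return min(hits, key=_precedence_key)


@dataclass
class SlipperyCandidate:
    """A motif hit inside an overlap window, in view-space coordinates.

    ``p_site_end`` is the half-open boundary just past the last base of the
    P-site codon; the motif occupies ``[position, p_site_end)``.
    """

    position: int
    motif: MotifClass
    direction: int
    p_site_end: int
    a0_codon: str
    a1_codon: str


def scan_overlap(
    pair: GenePair, usage: CodonUsageTable
) -> list[SlipperyCandidate]:
    """Scan a pair's overlap window for slippery-site candidates.

    The window is walked codon by codon on gene_a's frame; each P-site
    boundary is classified with the classes matching the pair's frame
    offset.  Forward candidates additionally require the +1-frame A-site
    codon to be more abundant than the in-frame one (A1 > A0), since
    shifting onto a rarer codon is unfavourable.  Candidates whose motif
    would poke out of the window are suppressed.
    """
    seq = pair.view.seq
    w_start, w_end = pair.window
    a_start = pair.a_interval[0]
    out: list[SlipperyCandidate] = []
    # first codon boundary on gene_a's grid with a full codon in the window
    p = a_start + ((w_start + 3 - a_start + 2) // 3) * 3
    # the last admissible P-site boundary leaves the stop codon in the
    # A site (N = 0); the stop itself can never occupy the P site
    while p <= w_end - 3:
        lo = max(0, p - WINDOW_LEN)
        window = seq[lo:p].rjust(WINDOW_LEN, "N")
        motif = classify_window(
            window, directions=(pair.frame_offset,), max_span=p - w_start
        )
        if motif is not None:
            a0 = seq[p : p + 3]
            a1_start = p + pair.frame_offset
            a1 = seq[a1_start : a1_start + 3]
            ok = (
                len(a0) == 3
                and len(a1) == 3
                and a1_start >= 0
                and "N" not in a0
                and "N" not in a1
            )
            if ok and pair.frame_offset == FORWARD:
                ok = usage[a1] > usage[a0]
            if ok:
                out.append(
                    SlipperyCandidate(
                        position=p - motif.span,
                        motif=motif,
                        direction=pair.frame_offset,
                        p_site_end=p,
                        a0_codon=a0,
                        a1_codon=a1,
                    )
                )
        p += 3
    return out
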