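"""Gene-pair geometry for frameshift candidacy.

Two jobs live here.  First, *truth extraction*: a ``join``-annotated CDS is
split into its two fragments, the separation between them decides whether it
looks like a backward (-1) or forward (+1) ribosomal frameshift, or neither
(introns, inteins and other discontinuities are separated by far more than
10 nt).  Second, *candidate enumeration*: adjacent same-strand genes whose
reading frames overlap in a way that could hide a frameshift are paired up,
and the overlap search window is computed -- the stretch of sequence that is
simultaneously upstream of the 5' gene's in-frame stop codon and free of
stop codons in the 3' gene's frame.

All frame arithmetic happens on the coding strand: minus-strand features are
mapped through a reverse-complement view of the locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genbank_io import (
    STOP_CODONS,
    CdsFeature,
    GenomeRecord,
    reverse_complement,
)

log = logging.getLogger(__name__)

#: joined fragments further apart than this are not frameshifts
MAX_JOIN_SEPARATION = 10

#: how far past the 5' gene's stop codon the 3' gene may start and the pair
#: still count as adjacent (mirrors the 10-bp rule used for joins)
ADJACENCY_TOLERANCE = 10

#: stop-codon search is abandoned this many codons past a gene's annotated
#: end (fragments of split genes park their stop shortly downstream)
MAX_STOP_EXTENSION_CODONS = 200

REJECTED = "rejected"


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class StrandView:
    """Coding-strand view of a locus.

    For '+' this is the identity; for '-' positions are mirrored so that all
    downstream arithmetic (frames, windows, motif scanning) can assume the
    ribosome reads left to right.
    """

    strand: str
    length: int
    seq: str

    def interval(self, s: int, e: int) -> tuple[int, int]:
        if self.strand == "+":
            return s, e
        return self.length - e, self.length - s

    def boundary_to_genome(self, p: int) -> int:
        """Map a view-space boundary back to a genomic boundary."""
        if self.strand == "+":
            return p
        return self.length - p


def strand_view(record: GenomeRecord, strand: str) -> StrandView:
    seq = record.sequence if strand == "+" else reverse_complement(record.sequence)
    return StrandView(strand=strand, length=len(record.sequence), seq=seq)


@dataclass
class JoinGeometry:
    """The two fragments of a joined CDS plus the inferred shift direction."""

    upstream_fragment: CdsFeature
    downstream_fragment: CdsFeature
    separation_d: int
    direction: int | str  # -1, +1 or "rejected"

    @property
    def accepted(self) -> bool:
        return self.direction in (-1, 1)

    def junction(self, view: StrandView) -> int:
        """View-space boundary where the upstream fragment ends."""
        s, e = self.upstream_fragment.segments[0]
        return view.interval(s, e)[1]


def direction_from_separation(d: int) -> int | str:
    """Map fragment separation to a shift direction.

    Separations of 0 nt annotate backward (-1) shifts and 1 nt forward (+1)
    shifts; annotation practice wobbles by whole codons, so the mapping is
    taken mod 3 up to 10 nt.  A one-base overlap (d = -1) is the other common
    way a -1 shift is written (the slipped ribosome re-reads one base, as in
    the SARS-CoV-2 orf1ab join) and is accepted as backward.
    """
    if d == -1:
        return -1
    if d < -1 or d > MAX_JOIN_SEPARATION:
        return REJECTED
    r = d % 3
    if r == 0:
        return -1
    if r == 1:
        return 1
    return REJECTED


def split_joined(feature: CdsFeature) -> JoinGeometry:
    """Split a two-segment joined CDS into consecutive pseudo-genes."""
    if not feature.joined or len(feature.segments) == 1:
        raise ContractError("split_joined requires a joined feature")
    if len(feature.segments) != 2:
        raise ContractError(
            f"joined features with {len(feature.segments)} segments are not "
            "supported (only two-fragment joins can be frameshifts)"
        )
    (s1, e1), (s2, e2) = feature.segments  # reading order
    if feature.strand == "+":
        d = s2 - e1
    else:
        # on the minus strand reading runs right to left genomically, so the
        # gap sits between seg1's genomic start and seg2's genomic end
        d = s1 - e2
    direction = direction_from_separation(d)
    if direction == REJECTED:
        log.warning(
            "join %s separated by %d nt rejected as a frameshift",
            feature.one_based_segments(), d,
        )
    tag = f"join{feature.source_order}"
    up = CdsFeature(
        segments=[(s1, e1)], strand=feature.strand,
        product=feature.product, source_order=feature.source_order,
        origin=tag,
    )
    down = CdsFeature(
        segments=[(s2, e2)], strand=feature.strand,
        product=feature.product, source_order=feature.source_order,
        origin=tag,
    )
    return JoinGeometry(
        upstream_fragment=up, downstream_fragment=down,
        separation_d=d, direction=direction,
    )


@dataclass
class GenePair:
    """Consecutive same-strand genes whose overlap admits a frameshift.

    Intervals are in view space (coding strand).  ``frame_offset`` is the
    frame of gene_b relative to gene_a (-1 or +1); ``window`` is the
    half-open interval in which a shift out of gene_a's frame into gene_b's
    frame is tenable; ``a_stop_end`` is the boundary just past gene_a's
    in-frame stop codon (which for split fragments lies downstream of the
    annotated fragment end).
    """

    gene_a: CdsFeature
    gene_b: CdsFeature
    strand: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    window: tuple[int, int]
    frame_offset: int
    a_stop_end: int
    view: StrandView

    @property
    def is_join_pair(self) -> bool:
        return (
            self.gene_a.origin is not None
            and self.gene_a.origin == self.gene_b.origin
        )

    @property
    def junction(self) -> int:
        """View-space junction boundary for split pseudo-pairs."""
        return self.a_interval[1]

    def pair_id(self) -> str:
        return f"{self.strand}:{self.a_interval[0]}-{self.b_interval[1]}"


def _find_frame_stop(seq: str, start: int, min_pos: int) -> int | None:
    """First stop codon on ``start``'s codon grid beginning at >= min_pos."""
    q = start
    if min_pos > start:
        q = start + ((min_pos - start + 2) // 3) * 3
    limit = min(len(seq) - 3, min_pos + 3 * MAX_STOP_EXTENSION_CODONS)
    while q <= limit:
        if seq[q : q + 3] in STOP_CODONS:
            return q
        q += 3
    return None


def _upstream_frame_clear(seq: str, b_start: int) -> int:
    """First base after the nearest 5' in-frame stop in gene_b's frame."""
    r = b_start - 3
    while r >= 0:
        if seq[r : r + 3] in STOP_CODONS:
            return r + 3
        r -= 3
    return b_start % 3  # frame start of the contig


def compute_overlap_window(
    a_iv: tuple[int, int], b_iv: tuple[int, int], seq: str
) -> tuple[tuple[int, int], int, int] | None:
    """Overlap search window for a candidate gene pair, in view space.

    Returns ``(window, frame_offset, a_stop_end)`` or None when the
    geometry rules a frameshift out: same frame, no in-frame stop for
    gene_a, the pair not adjacent, or an empty window.
    """
    (a_start, a_end), (b_start, b_end) = a_iv, b_iv
    delta = (b_start - a_start) % 3
    if delta == 0:
        return None
    frame_offset = -1 if delta == 2 else 1
    q = _find_frame_stop(seq, a_start, max(a_start, a_end - 3))
    if q is None:
        return None
    stop_end = q + 3
    if b_start > stop_end + ADJACENCY_TOLERANCE:
        return None
    w_start = max(_upstream_frame_clear(seq, b_start), a_start)
    if w_start >= stop_end:
        return None
    return (w_start, stop_end), frame_offset, stop_end


def enumerate_pairs(
    features: list[CdsFeature], record: GenomeRecord
) -> list[GenePair]:
    """Pair up consecutive same-strand genes with a non-empty overlap window.

    Features are sorted internally (output does not depend on input order);
    adjacent features on opposite strands are skipped, since a ribosome
    cannot shift between genes read from different strands.
    """
    views = {s: strand_view(record, s) for s in "+-"}
    ordered = sorted(features, key=lambda f: (f.start, f.end))
    pairs: list[GenePair] = []
    for fa, fb in zip(ordered, ordered[1:]):
        if fa.strand != fb.strand:
            continue
        strand = fa.strand
        view = views[strand]
        if strand == "-":
            fa, fb = fb, fa  # 5' gene in reading direction
        a_iv = view.interval(fa.start, fa.end)
        b_iv = view.interval(fb.start, fb.end)
        got = compute_overlap_window(a_iv, b_iv, view.seq)
        if got is None:
            continue
        window, frame_offset, stop_end = got
        pairs.append(
            GenePair(
                gene_a=fa, gene_b=fb, strand=strand,
                a_interval=a_iv, b_interval=b_iv,
                window=window, frame_offset=frame_offset,
                a_stop_end=stop_end, view=view,
            )
        )
    return pairs


def split_features_for_training(
    record: GenomeRecord,
) -> tuple[list[CdsFeature], dict[str, JoinGeometry]]:
    """Replace accepted joined CDSs with their fragment pseudo-genes.

    Returns the flattened feature list plus a map from the pseudo-genes'
    origin tag to the JoinGeometry (junction and true direction).
    """
    feats: list[CdsFeature] = []
    joins: dict[str, JoinGeometry] = {}
    for f in record.features:
        if not f.joined:
            feats.append(f)
            continue
        if len(f.segments) != 2:
            log.warning(
                "skipping %d-segment join in %s",
                len(f.segments), record.locus_id,
            )
            continue
        geom = split_joined(f)
        if not geom.accepted:
            continue
        feats.append(geom.upstream_fragment)
        feats.append(geom.downstream_fragment)
        joins[geom.upstream_fragment.origin] = geom
    return feats, joins
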