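"""GenBank input/output and genome-wide codon statistics.

Coding genes live in GenBank files as ``CDS`` features.  A gene that is
translated through a programmed ribosomal frameshift is conventionally
annotated with a discontinuous location using the ``join`` keyword, e.g.
``join(200..300,301..400)``.  This module reads and writes the subset of
the GenBank dialect that matters for frameshift analysis (locations with
``join``/``complement``, the ``/product`` qualifier and the sequence) and
tabulates relative codon usage over all annotated genes.

Coordinates are stored internally as 0-based half-open intervals; GenBank's
1-based inclusive coordinates are converted at the I/O boundary.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ALL_CODONS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


class GenBankParseError(ValueError):
    """Raised when a record or feature location cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(seq: str) -> str:
    """Uppercase DNA alphabet; RNA input (U) is converted to T."""
    return seq.upper().replace("U", "T")


@dataclass
class CdsFeature:
    """A coding feature with one or more located segments.

    ``segments`` are 0-based half-open intervals ordered 5'->3' in reading
    direction (for minus-strand features the first segment is therefore the
    one with the *higher* genomic coordinates).
    """

    segments: list[tuple[int, int]]
    strand: str = "+"
    joined: bool = False
    product: str = ""
    source_order: int = 0
    origin: str | None = None  # provenance tag for split pseudo-genes

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("CdsFeature requires at least one segment")
        for s, e in self.segments:
            if s > e:
                raise ValueError(f"segment start {s} > end {e}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.joined = len(self.segments) > 1

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate."""
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate (exclusive)."""
        return max(e for _, e in self.segments)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def one_based_segments(self) -> list[tuple[int, int]]:
        """Original GenBank coordinates (1-based inclusive)."""
        return [(s + 1, e) for s, e in self.segments]


@dataclass
class GenomeRecord:
    """One GenBank locus: identifier, sequence and its CDS features."""

    locus_id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = canonicalize(self.sequence)
        if not self.sequence:
            raise ValueError("empty sequence")
        for f in self.features:
            if f.start < 0 or f.end > len(self.sequence):
                raise GenBankParseError(
                    f"feature {f.one_based_segments()} out of bounds for "
                    f"{self.locus_id} (length {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CodonUsageTable:
    """Relative frequency of each of the 64 codons over all annotated genes.

    Stop codons are counted like any other codon, so with one stop per gene
    they come out rare -- which is deliberate: a ribosome waiting on a stop
    codon behaves like one waiting on a rare codon.
    """

    freq: dict[str, float]
    total_codons: int

    def __getitem__(self, codon: str) -> float:
        return self.freq[codon]


def _location_to_feature(feat, order: int, locus: str) -> CdsFeature:
    loc = feat.location
    if loc is None:
        raise GenBankParseError(
            f"malformed location for CDS #{order} in {locus}"
        )
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    strands = {p.strand for p in parts}
    if len(strands) != 1 or None in strands:
        raise GenBankParseError(
            f"mixed or missing strand for CDS #{order} in {locus}"
        )
    strand = "+" if parts[0].strand >= 0 else "-"
    for p in parts:
        if str(p.start).lstrip("<>") != str(p.start) or str(p.end).lstrip("<>") != str(p.end):
            log.warning("fuzzy boundary in %s CDS #%d dropped", locus, order)
    segs = [(int(p.start), int(p.end)) for p in parts]
    # Biopython already orders complement(join(...)) parts in transcription
    # order, which is the reading-direction order we store.
    product = feat.qualifiers.get("product", [""])[0]
    return CdsFeature(
        segments=segs, strand=strand, product=product, source_order=order
    )


def parse_genbank(text: str) -> list[GenomeRecord]:
    """Parse GenBank flat-file content into one GenomeRecord per locus."""
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # locus-line pedantry
        bio_records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    if not bio_records:
        raise GenBankParseError("no LOCUS...ORIGIN...// block found")
    for rec in bio_records:
        feats = []
        order = 0
        for f in rec.features:
            if f.type != "CDS":
                continue
            feats.append(_location_to_feature(f, order, rec.id))
            order += 1
        records.append(
            GenomeRecord(
                locus_id=rec.id or rec.name,
                sequence=str(rec.seq),
                features=feats,
            )
        )
    return records


def read_genbank(path) -> list[GenomeRecord]:
    with open(path) as fh:
        return parse_genbank(fh.read())


def _feature_to_biopython(f: CdsFeature) -> SeqFeature:
    strand = 1 if f.strand == "+" else -1
    # parts are handed over in reading order; Biopython renders the genomic
    # complement(join(...)) form and restores reading order on parsing
    parts = [SimpleLocation(s, e, strand=strand) for s, e in f.segments]
    loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
    quals = {}
    if f.product:
        quals["product"] = [f.product]
    return SeqFeature(loc, type="CDS", qualifiers=quals)


def write_genbank(record: GenomeRecord) -> str:
    """Emit a GenBank flat file (LOCUS/FEATURES/ORIGIN) for one record."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.locus_id,
        name=record.locus_id[:16],
        description="",
        annotations={"molecule_type": "DNA"},
    )
    rec.features = [_feature_to_biopython(f) for f in record.features]
    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()


def feature_sequence(record: GenomeRecord, feature: CdsFeature) -> str:
    """Spliced, strand-resolved nucleotide sequence of a feature."""
    if feature.strand == "+":
        return "".join(record.sequence[s:e] for s, e in feature.segments)
    return "".join(
        reverse_complement(record.sequence[s:e]) for s, e in feature.segments
    )


def compute_codon_usage(record: GenomeRecord) -> CodonUsageTable:
    """Tabulate in-frame codon frequencies over every annotated CDS.

    Trailing partial codons (joined features legitimately have segment
    lengths that are not multiples of three) are dropped, and codons
    containing N are skipped.
    """
    counts = dict.fromkeys(ALL_CODONS, 0)
    total = 0
    for feat in record.features:
        seq = feature_sequence(record, feat)
        if len(seq) < 3:
            continue
        if len(seq) % 3:
            log.debug(
                "CDS #%d in %s: dropping %d-nt partial codon",
                feat.source_order, record.locus_id, len(seq) % 3,
            )
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] += 1
            total += 1
    if total == 0:
        raise ValueError(
            "codon usage requires annotated coding genes (no usable CDS "
            f"found in {record.locus_id})"
        )
    freq = {c: n / total for c, n in counts.items()}
    return CodonUsageTable(freq=freq, total_codons=total)
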