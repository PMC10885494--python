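"""Synthetic GenBank corpora with planted frameshift signal.

The generator emulates the signal structure of a real phage training corpus:
every planted frameshift gene is a two-fragment ``join`` whose junction
carries a slippery motif, a strong GC hairpin starting 3 nt past the A-site
codon, an upstream Shine-Dalgarno-like sequence, and an in-frame stop codon
a short distance downstream.  Honest negatives are decoy gene pairs whose
overlap window contains a motif but none of the supporting signal, plus
whatever motifs occur by chance.  Genomes are generated in families (mutated
copies of a founder, with the frameshift cassette conserved) so that
MinHash clustering and taxon-aware holdouts are non-trivial.

Every planted coordinate is recorded in a truth table; generation is fully
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genbank_io import CdsFeature, GenomeRecord, reverse_complement
from .motif_catalog import MOTIF_BY_NAME, MOTIF_CLASSES, MotifClass

#: stop used throughout the generator
STOP = "TAA"

BACKWARD_CLASSES = tuple(m for m in MOTIF_CLASSES if m.direction == -1)


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic corpus."""

    n_genomes: int = 30
    n_families: int = 5
    genome_length: int = 10000
    gc: float = 0.64  # actinobacteriophage-like GC content
    genes_per_genome: int = 8
    prf_per_genome: int = 1
    motif: str | None = None  # None cycles through the backward classes
    direction: int = -1
    hairpin_stem: int = 12
    hairpin_gc: float = 1.0
    plant_rbs: bool = True
    junction_n: int = 15  # nt from P-site end to the bypassed stop
    decoy_pairs_per_genome: int = 3
    mutation_rate: float = 0.02  # within-family divergence
    prf_strand: str = "+"
    seed: int = 0

    def validate(self) -> None:
        n, stem = self.junction_n, self.hairpin_stem
        if self.direction == -1:
            if n != stem + 3 and n < 2 * stem + 15:
                raise FixtureError(
                    "junction_n must put the in-frame stop in the hairpin "
                    f"loop (= hairpin_stem + 3 = {stem + 3}) or past the "
                    f"hairpin (>= {2 * stem + 15})"
                )
            if n % 3:
                raise FixtureError("junction_n must be a multiple of 3")


def _rand_bases(rng, n: int, gc: float, alphabet: str = "ACGT") -> str:
    if n <= 0:
        return ""
    if alphabet == "ACGT":
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    elif alphabet == "ACG":  # T-free: cannot form a stop codon in any frame
        p = [1 - gc, gc / 2, gc / 2]
    elif alphabet == "AC":
        p = [1 - gc, gc]
    else:
        raise ValueError(alphabet)
    idx = rng.choice(len(alphabet), size=n, p=np.array(p) / sum(p))
    return "".join(alphabet[i] for i in idx)


def _rand_codons(rng, n_codons: int, gc: float) -> str:
    out = []
    while len(out) < n_codons:
        c = _rand_bases(rng, 3, gc)
        if c not in ("TAA", "TAG", "TGA"):
            out.append(c)
    return "".join(out)


def motif_exemplar(rng, motif: MotifClass) -> str:
    """A random instance of a motif template, T-free, adjacent runs distinct."""
    bases = []
    prev = None
    for run in motif.runs:
        choices = [b for b in "ACG" if b != prev]
        b = choices[int(rng.integers(len(choices)))]
        bases.append(b * run)
        prev = b
    return "".join(bases)


def _hairpin(rng, stem: int, loop: str, gc: float) -> str:
    """Perfect inverted repeat; a pure-GC stem cannot create stop codons."""
    if gc >= 1.0:
        s = "".join(rng.choice(["G", "C"], size=stem))
    else:
        s = _rand_bases(rng, stem, gc)
    return s + loop + reverse_complement(s)


@dataclass
class _Builder:
    rng: object
    gc: float
    seq: list = field(default_factory=list)
    features: list = field(default_factory=list)
    truth: list = field(default_factory=list)
    protected: list = field(default_factory=list)

    @property
    def pos(self) -> int:
        return sum(len(s) for s in self.seq)

    def emit(self, s: str) -> int:
        start = self.pos
        self.seq.append(s)
        return start

    def gap(self) -> None:
        self.emit(_rand_bases(self.rng, int(self.rng.integers(60, 121)), self.gc))


def _ordinary_gene(b: _Builder, strand: str = "+") -> None:
    rng = b.rng
    n_codons = int(rng.integers(60, 151))
    sd = "AGGAGG" + _rand_bases(rng, int(rng.integers(5, 9)), 0.3, "AC")
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    gene = "ATG" + _rand_codons(rng, n_codons, b.gc) + stop
    element = sd + gene
    if strand == "-":
        element = reverse_complement(element)
        start = b.emit(element)
        s, e = start, start + len(gene)  # gene at the 5' end after revcomp
        b.features.append(CdsFeature(segments=[(s, e)], strand="-", product="hypothetical protein"))
    else:
        start = b.emit(element)
        s = start + len(sd)
        b.features.append(
            CdsFeature(segments=[(s, s + len(gene))], strand="+", product="hypothetical protein")
        )


def _guard_region(rng, motif_seq: str, plant_rbs: bool) -> str:
    """The 18 nt ending at the P-site boundary: optional SD + filler + motif.

    T-free so no stop codon can arise in any frame near the slippery site;
    the filler base before the motif differs from the motif's first base so
    the planted class cannot be upgraded by an accidental longer run.
    """
    span = len(motif_seq)
    f2 = 11 - span  # puts the SD's 3' end 5 nt before the E-site codon
    if plant_rbs:
        filler = _rand_bases(rng, max(f2 - 1, 0), 0.5, "AC")
        prefix = "C" + "AGGAGG" + filler
    else:
        prefix = _rand_bases(rng, 18 - span - 1, 0.5, "AC")
    last = "C" if motif_seq[0] != "C" else "A"
    return prefix + last + motif_seq


def _prf_cassette(b: _Builder, spec: FixtureSpec, motif: MotifClass, genome_id: str) -> None:
    """Plant one frameshift gene: joined fragments, motif, hairpin, SD, stop."""
    rng = b.rng
    direction = spec.direction
    stem = spec.hairpin_stem
    body = "ATG" + _rand_codons(rng, int(rng.integers(25, 41)), b.gc)
    guard = _guard_region(rng, motif_exemplar(rng, motif), spec.plant_rbs)
    assert len(guard) == 18

    if direction == -1:
        a_site = _rand_bases(rng, 3, b.gc, "ACG")
        n = spec.junction_n
        if n == stem + 3:
            loop = STOP + _rand_bases(rng, 3, 0.5, "AC")
            after = a_site + _hairpin(rng, stem, loop, spec.hairpin_gc)
        else:  # stop past the hairpin
            hp = _hairpin(rng, stem, _rand_bases(rng, 6, 0.5, "AC"), spec.hairpin_gc)
            filler = _rand_bases(rng, n - 3 - len(hp), 0.5, "AC")
            after = a_site + hp + filler + STOP
    else:
        # forward shifts pause on a rare codon; the rarest codons in any
        # annotated genome are the stops, so the A-site codon is the stop
        a_site = STOP
        after = a_site + _hairpin(
            rng, stem, _rand_bases(rng, 6, 0.5, "AC"), spec.hairpin_gc
        )

    head = body + guard  # P-site boundary at the end of the guard
    # fragment 2 reads on from the junction; its own stop sits k codons later
    tail_len = int(rng.integers(60, 91)) * 3
    element_wo_tail = head + after
    # positions relative to element start
    p = len(head)
    x = p - 1 if direction == -1 else p  # fragment 1 end boundary
    x2 = x if direction == -1 else x + 1  # fragment 2 start (forward skips 1)
    b_len_so_far = len(element_wo_tail) - x2
    pad = (-(b_len_so_far + 3)) % 3  # align fragment 2's stop to its frame
    tail = _rand_bases(rng, tail_len + pad, b.gc, "ACG") + STOP
    element = element_wo_tail + tail

    b.gap()
    if spec.prf_strand == "-":
        start = b.emit(reverse_complement(element))
        L = len(element)
        seg1 = (start + L - x, start + L)  # fragment 1, higher genomic coords
        seg2 = (start, start + L - x2)
        feat = CdsFeature(
            segments=[seg1, seg2], strand="-", product="tail assembly chaperone"
        )
        junction_genomic = start + L - x
        b.protected.append((start, start + L))
    else:
        start = b.emit(element)
        seg1 = (start, start + x)
        seg2 = (start + x2, start + len(element))
        feat = CdsFeature(
            segments=[seg1, seg2], strand="+", product="tail assembly chaperone"
        )
        junction_genomic = start + x
        b.protected.append((start + len(body) - 9, start + len(element_wo_tail) + 9))
    b.features.append(feat)
    b.truth.append(
        {
            "genome": genome_id,
            "strand": spec.prf_strand,
            "junction": junction_genomic,  # 0-based boundary, genomic
            "direction": direction,
            "motif": motif.name,
        }
    )
    b.gap()


def _decoy_pair(b: _Builder, spec: FixtureSpec) -> None:
    """Two overlapping genes with a bare motif and no supporting signal."""
    rng = b.rng
    motif = BACKWARD_CLASSES[int(rng.integers(len(BACKWARD_CLASSES)))]
    body = "ATG" + _rand_codons(rng, int(rng.integers(25, 41)), b.gc)
    guard = _guard_region(rng, motif_exemplar(rng, motif), plant_rbs=False)
    n_d = 3 * int(rng.integers(2, 16))  # stop 6-45 nt past the P-site
    mid = _rand_bases(rng, n_d, 0.3, "AC") + STOP
    head = body + guard
    p = len(head)
    x = p - 1
    tail_len = int(rng.integers(40, 71)) * 3
    b_len_so_far = len(head) + len(mid) - x
    pad = (-(b_len_so_far + 3)) % 3
    tail = _rand_bases(rng, tail_len + pad, b.gc, "ACG") + STOP
    element = head + mid + tail
    b.gap()
    start = b.emit(element)
    gene_a = CdsFeature(
        segments=[(start, start + p + n_d + 3)], strand="+", product="hypothetical protein"
    )
    gene_b = CdsFeature(
        segments=[(start + x, start + len(element))], strand="+", product="hypothetical protein"
    )
    b.features.extend([gene_a, gene_b])
    b.gap()


def make_genome(
    spec: FixtureSpec, seed: int, locus_id: str = "SYN1", motif_offset: int = 0
) -> tuple[GenomeRecord, pd.DataFrame, list[tuple[int, int]]]:
    """One synthetic genome plus its truth table and protected intervals.

    With ``spec.motif`` unset, backward plants cycle through the eight
    backward classes starting at ``motif_offset`` (corpora then exercise the
    whole catalog).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    b = _Builder(rng=rng, gc=spec.gc)
    motifs = []
    for i in range(spec.prf_per_genome):
        if spec.motif is not None:
            motifs.append(MOTIF_BY_NAME[spec.motif])
        elif spec.direction == -1:
            motifs.append(BACKWARD_CLASSES[(motif_offset + i) % len(BACKWARD_CLASSES)])
        else:
            motifs.append(MOTIF_BY_NAME["three"])
    if spec.direction == 1 and any(m.direction != 1 for m in motifs):
        raise FixtureError("forward plants need a forward motif (three/four)")
    if spec.direction == -1 and any(m.direction != -1 for m in motifs):
        raise FixtureError(f"motif {spec.motif} is not a backward class")

    plan = ["gene"] * spec.genes_per_genome
    plan += ["decoy"] * spec.decoy_pairs_per_genome
    rng.shuffle(plan)
    # spread the frameshift cassettes through the plan deterministically
    step = max(len(plan) // (len(motifs) + 1), 1)
    for i, m in enumerate(motifs):
        plan.insert(min((i + 1) * step, len(plan)), ("prf", m))

    b.gap()
    for item in plan:
        if item == "gene":
            strand = "-" if rng.random() < 0.3 else "+"
            _ordinary_gene(b, strand)
            b.gap()
        elif item == "decoy":
            _decoy_pair(b, spec)
        else:
            _prf_cassette(b, spec, item[1], locus_id)
    if b.pos < spec.genome_length:
        b.emit(_rand_bases(rng, spec.genome_length - b.pos, spec.gc))
    record = GenomeRecord(
        locus_id=locus_id, sequence="".join(b.seq), features=b.features
    )
    truth = pd.DataFrame(
        b.truth, columns=["genome", "strand", "junction", "direction", "motif"]
    )
    return record, truth, b.protected


def as_gene_calls(record: GenomeRecord) -> GenomeRecord:
    """The gene-caller view of a genome: joined CDSs become two plain genes.

    This is what prediction input looks like in practice -- a gene finder
    reports the two fragments of a frameshifted gene as separate ORFs and
    the predictor's job is to re-join them.
    """
    from .orf_geometry import split_features_for_training

    feats, _ = split_features_for_training(record)
    feats = [replace(f, segments=list(f.segments), origin=None) for f in feats]
    return GenomeRecord(
        locus_id=record.locus_id, sequence=record.sequence, features=feats
    )


def _mutate(
    rng, sequence: str, rate: float, protected: list[tuple[int, int]]
) -> str:
    seq = np.frombuffer(sequence.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    shield = np.zeros(len(seq), dtype=bool)
    for s, e in protected:
        shield[max(s, 0) : e] = True
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        if shield[i]:
            continue
        alts = bases[bases != seq[i]]
        seq[i] = alts[int(rng.integers(3))]
    return seq.tobytes().decode()


@dataclass
class Corpus:
    records: list[GenomeRecord]
    truth: pd.DataFrame
    grouping: dict[str, dict[str, str]]
    protected: dict[str, list[tuple[int, int]]]


def make_corpus(spec: FixtureSpec) -> Corpus:
    """A corpus of related genome families with conserved planted signal.

    Families are founders plus mutated copies (per-base substitution at
    ``mutation_rate`` outside the frameshift cassette), bracketing the 0.05
    Mash threshold: family members cluster together, families stay apart.
    """
    rng = np.random.default_rng(spec.seed)
    per_family = [spec.n_genomes // spec.n_families] * spec.n_families
    for i in range(spec.n_genomes % spec.n_families):
        per_family[i] += 1
    records: list[GenomeRecord] = []
    truths = []
    grouping: dict[str, dict[str, str]] = {}
    protected: dict[str, list[tuple[int, int]]] = {}
    for fam in range(spec.n_families):
        fam_name = f"FAM{fam + 1}"
        founder_seed = int(rng.integers(2**31))
        founder_id = f"{fam_name}G1"
        founder, truth, prot = make_genome(
            spec, founder_seed, founder_id, motif_offset=fam
        )
        records.append(founder)
        truths.append(truth)
        grouping[founder_id] = {"cluster": fam_name, "subcluster": fam_name}
        protected[founder_id] = prot
        for m in range(1, per_family[fam]):
            gid = f"{fam_name}G{m + 1}"
            mutated = _mutate(rng, founder.sequence, spec.mutation_rate, prot)
            rec = GenomeRecord(
                locus_id=gid,
                sequence=mutated,
                features=[replace(f, segments=list(f.segments)) for f in founder.features],
            )
            records.append(rec)
            t = truth.copy()
            t["genome"] = gid
            truths.append(t)
            grouping[gid] = {"cluster": fam_name, "subcluster": fam_name}
            protected[gid] = prot
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return Corpus(records=records, truth=truth, grouping=grouping, protected=protected)
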