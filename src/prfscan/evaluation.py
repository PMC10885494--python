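"""Taxon-aware leave-one-out validation and prediction scoring.

Phage collections are highly redundant: near-identical genomes recur, so a
naive per-genome holdout leaks training data.  Validation therefore runs at
a chosen grouping level -- externally supplied CLUSTER/SUBCLUSTER labels, a
computed MASH95 level (MinHash genome clustering at 95% identity, i.e. Mash
distance <= 0.05, sketch size 400, k = 16), or GENOME (each genome its own
group).  For every group a model is trained on the complement and predictions
are made on the held-out genomes; merged predictions are scored against the
``join`` annotations: a prediction on a joined gene within 10 nt of the
annotated junction is a true positive, anything else a false positive.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

from .classifier import (
    JUNCTION_TOLERANCE,
    LabeledSite,
    PairSites,
    Prediction,
    candidate_sites,
    predict_pair,
    train,
)
from .genbank_io import GenomeRecord, reverse_complement

log = logging.getLogger(__name__)

SKETCH_K = 16
SKETCH_SIZE = 400
MASH95_THRESHOLD = 0.05

LEVELS = ("CLUSTER", "SUBCLUSTER", "MASH95", "GENOME")


class ContractError(ValueError):
    pass


@dataclass
class Sketch:
    """Bottom-s MinHash sketch over canonical k-mers."""

    genome_id: str
    k: int
    s: int
    hashes: list[int]  # sorted ascending, at most s values


def _hash_kmer(kmer: str) -> int:
    # stable 64-bit hash (process-independent, unlike Python's hash())
    return int.from_bytes(
        hashlib.blake2b(kmer.encode(), digest_size=8).digest(), "big"
    )


def sketch_genome(
    record_or_seq, k: int = SKETCH_K, s: int = SKETCH_SIZE,
    genome_id: str | None = None,
) -> Sketch:
    """Sketch a genome with canonical k-mers (min of k-mer and its RC)."""
    if isinstance(record_or_seq, GenomeRecord):
        seq = record_or_seq.sequence
        gid = genome_id or record_or_seq.locus_id
    else:
        seq = str(record_or_seq).upper()
        gid = genome_id or ""
    hashes: set[int] = set()
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        canon = min(kmer, rc[n - k - i : n - i])
        hashes.add(_hash_kmer(canon))
    smallest = sorted(hashes)[:s]
    return Sketch(genome_id=gid, k=k, s=s, hashes=smallest)


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance d = -ln(2j/(1+j))/k from the merged-sketch Jaccard."""
    if a.k != b.k or a.s != b.s:
        raise ContractError("sketches must share k and sketch size")
    sa, sb = set(a.hashes), set(b.hashes)
    merged = sorted(sa | sb)[: min(a.s, len(sa | sb))]
    shared = sum(1 for h in merged if h in sa and h in sb)
    if not merged or shared == 0:
        return math.inf
    j = shared / len(merged)
    return -math.log(2 * j / (1 + j)) / a.k


def cluster_mash95(
    sketches: list[Sketch], threshold: float = MASH95_THRESHOLD
) -> dict[str, str]:
    """Single-linkage clusters of the distance graph at d <= threshold.

    Cluster labels are deterministic: each cluster is named after its
    lexicographically smallest member id.
    """
    ids = [s.genome_id for s in sketches]
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(sketches)):
        for j in range(i + 1, len(sketches)):
            if mash_distance(sketches[i], sketches[j]) <= threshold:
                ra, rb = find(ids[i]), find(ids[j])
                if ra != rb:
                    parent[rb] = ra
    members: dict[str, list[str]] = {}
    for g in ids:
        members.setdefault(find(g), []).append(g)
    labels = {}
    for root, group in members.items():
        name = min(group)
        for g in group:
            labels[g] = name
    return labels


@dataclass
class EvalSummary:
    level: str
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    precision_defined: bool = True

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 1.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 1.0

    @property
    def accuracy(self) -> float:
        total = self.TP + self.FP + self.TN + self.FN
        return (self.TP + self.TN) / total if total else 1.0

    def as_dict(self) -> dict:
        return {
            "level": self.level, "TP": self.TP, "FP": self.FP,
            "TN": self.TN, "FN": self.FN, "recall": self.recall,
            "precision": self.precision, "accuracy": self.accuracy,
            "precision_defined": self.precision_defined,
        }


def score_pair_predictions(
    pair_sites: list[PairSites],
    predictions: dict[str, Prediction],
    summary: EvalSummary,
    tol: int = JUNCTION_TOLERANCE,
) -> None:
    """Score one genome's predictions against its join annotations.

    ``predictions`` maps pair ids to the (at most one) prediction for that
    pair.  A joined pair scores TP when its prediction falls within ``tol``
    of the junction, FP+FN when it falls elsewhere, FN when absent.
    Non-joined pairs with candidates score TN without a prediction and FP
    with one.
    """
    for ps in pair_sites:
        key = (ps.genome_id, ps.pair.pair_id())
        pred = predictions.get(key)
        if ps.is_join:
            if (
                pred is not None
                and abs(pred.candidate.p_site_end - ps.junction) <= tol
            ):
                summary.TP += 1
            else:
                summary.FN += 1
                if pred is not None:
                    summary.FP += 1
        else:
            if pred is not None:
                summary.FP += 1
            elif ps.candidates:
                summary.TN += 1


def score_predictions(
    pair_sites_by_genome: dict[str, list[PairSites]],
    predictions: list[Prediction],
    level: str = "GENOME",
    tol: int = JUNCTION_TOLERANCE,
) -> EvalSummary:
    summary = EvalSummary(level=level)
    pred_map = {}
    for pred in predictions:
        pred_map[(pred.genome_id, pred.pair.pair_id())] = pred
    for gid, sites in pair_sites_by_genome.items():
        score_pair_predictions(sites, pred_map, summary, tol=tol)
    if summary.TP + summary.FP == 0:
        summary.precision_defined = False
    return summary


def _sites_to_labeled(sites_by_genome: dict[str, list[PairSites]], gids) -> list[LabeledSite]:
    out: list[LabeledSite] = []
    for gid in gids:
        for ps in sites_by_genome[gid]:
            for sc in ps.candidates:
                out.append(
                    LabeledSite(
                        features=sc.features, label=sc.label,
                        genome_id=gid, pair_id=ps.pair.pair_id(),
                        position=sc.candidate.p_site_end,
                    )
                )
    return out


@dataclass
class LooResult:
    summary: EvalSummary
    n_models: int
    groups: dict[str, str]
    predictions: list[Prediction] = field(default_factory=list)


def assign_groups(
    genomes: list[GenomeRecord],
    level: str,
    metadata: dict[str, dict[str, str]] | None = None,
) -> dict[str, str]:
    """Group label per genome at the requested leave-one-out level."""
    level = level.upper()
    if level not in LEVELS:
        raise ContractError(f"level must be one of {LEVELS}")
    if level == "GENOME":
        return {g.locus_id: g.locus_id for g in genomes}
    if level == "MASH95":
        sketches = [sketch_genome(g) for g in genomes]
        return cluster_mash95(sketches)
    if metadata is None:
        raise ContractError(f"{level} grouping requires metadata")
    key = level.lower()
    return {g.locus_id: metadata[g.locus_id][key] for g in genomes}


def loo_validate(
    genomes: list[GenomeRecord],
    level: str,
    metadata: dict[str, dict[str, str]] | None = None,
    seed: int = 0,
    tol: int = JUNCTION_TOLERANCE,
) -> LooResult:
    """Leave-one-group-out validation at the chosen taxonomic level.

    Features are computed once per genome and reused across folds; each fold
    trains a fresh model on the complement of one group and predicts on the
    held-out genomes.
    """
    groups = assign_groups(genomes, level, metadata)
    distinct = sorted(set(groups.values()))
    if len(distinct) < 2:
        raise ContractError(
            f"{level} level yields a single group; no training complement"
        )
    sites_by_genome = {
        g.locus_id: candidate_sites(g, split_joins=True) for g in genomes
    }
    order = [g.locus_id for g in genomes]
    predictions: list[Prediction] = []
    n_models = 0
    for group in distinct:
        held = [gid for gid in order if groups[gid] == group]
        rest = [gid for gid in order if groups[gid] != group]
        training = _sites_to_labeled(sites_by_genome, rest)
        model = train(training, seed=seed)
        n_models += 1
        for gid in held:
            for ps in sites_by_genome[gid]:
                pred = predict_pair(model, ps)
                if pred is not None:
                    predictions.append(pred)
    summary = score_predictions(sites_by_genome, predictions, level=level, tol=tol)
    return LooResult(
        summary=summary, n_models=n_models, groups=groups,
        predictions=predictions,
    )
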