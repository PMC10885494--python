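"""Training-set assembly, the 3-class gradient-boosted model, and prediction.

The model is a histogram-based gradient-boosted classification tree over the
eleven per-site features, predicting 0 (no frameshift), -1 (backward) or +1
(forward).  Hyperparameters follow the method's stated choices: scikit-learn
defaults except L2 regularization of 1.0, with early stopping disabled so
that training is deterministic for a fixed data order and seed.

Labels come from ``join``-annotated genes: each accepted join is split into
its fragment pseudo-pair, the pair's overlap window is scanned, and any
candidate whose P-site codon end lies within 10 nt of the annotated junction
inherits the join's direction.  Every other candidate -- including motifs
deeper inside a true overlap, whose exact slippery site is only a curator's
guess -- is labeled 0.

Within one gene pair at most one site is ever predicted: the candidate with
the highest class probability among those classified as shifting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier

from . import __version__
from .genbank_io import CdsFeature, CodonUsageTable, GenomeRecord, compute_codon_usage
from .motif_catalog import MOTIF_CATALOG_VERSION, SlipperyCandidate, scan_overlap
from .orf_geometry import GenePair, enumerate_pairs, split_features_for_training
from .signal_features import FEATURE_NAMES, FEATURE_SCHEMA_VERSION, SiteFeatures, build_features

log = logging.getLogger(__name__)

JUNCTION_TOLERANCE = 10  # nt

TSV_COLUMNS = (
    "genome", "gene_a", "gene_b", "strand", "position", "direction",
    "motif_name", "score", *FEATURE_NAMES,
)


@dataclass
class ScoredCandidate:
    candidate: SlipperyCandidate
    features: SiteFeatures
    label: int = 0


@dataclass
class PairSites:
    """All scored candidates of one gene pair, plus its truth if joined."""

    genome_id: str
    pair: GenePair
    candidates: list[ScoredCandidate] = field(default_factory=list)
    is_join: bool = False
    junction: int | None = None
    join_direction: int | None = None


@dataclass
class LabeledSite:
    features: SiteFeatures
    label: int
    genome_id: str
    pair_id: str
    position: int


@dataclass
class Prediction:
    genome_id: str
    pair: GenePair
    candidate: SlipperyCandidate
    features: SiteFeatures
    direction: int
    score: float

    @property
    def position(self) -> int:
        """1-based genomic coordinate of the motif's first (reading) base."""
        view = self.pair.view
        if view.strand == "+":
            return self.candidate.position + 1
        return view.length - self.candidate.position


def candidate_sites(
    record: GenomeRecord, *, split_joins: bool
) -> list[PairSites]:
    """Scan a genome into per-pair candidate feature sets.

    With ``split_joins`` true (training/validation), joined genes are split
    into fragment pseudo-pairs and their junction recorded; candidates near
    the junction are labeled with the join's direction.
    """
    if not record.features:
        log.warning("genome %s has no CDS features; skipped", record.locus_id)
        return []
    usage = compute_codon_usage(record)
    if split_joins:
        feats, joins = split_features_for_training(record)
    else:
        feats, joins = list(record.features), {}
    out: list[PairSites] = []
    for pair in enumerate_pairs(feats, record):
        ps = PairSites(genome_id=record.locus_id, pair=pair)
        if pair.is_join_pair and pair.gene_a.origin in joins:
            geom = joins[pair.gene_a.origin]
            ps.is_join = True
            ps.junction = geom.junction(pair.view)
            ps.join_direction = geom.direction
        for cand in scan_overlap(pair, usage):
            sc = ScoredCandidate(
                candidate=cand, features=build_features(cand, pair, usage)
            )
            if (
                ps.is_join
                and cand.direction == ps.join_direction
                and abs(cand.p_site_end - ps.junction) <= JUNCTION_TOLERANCE
            ):
                sc.label = ps.join_direction
            ps.candidates.append(sc)
        out.append(ps)
    return out


def assemble_training_set(genomes: list[GenomeRecord]) -> list[LabeledSite]:
    """Labeled sites from join-annotated genomes."""
    sites: list[LabeledSite] = []
    for record in genomes:
        for ps in candidate_sites(record, split_joins=True):
            for sc in ps.candidates:
                sites.append(
                    LabeledSite(
                        features=sc.features,
                        label=sc.label,
                        genome_id=ps.genome_id,
                        pair_id=ps.pair.pair_id(),
                        position=sc.candidate.p_site_end,
                    )
                )
    return sites


@dataclass
class PRFModel:
    clf: HistGradientBoostingClassifier
    feature_schema_version: str = FEATURE_SCHEMA_VERSION
    motif_catalog_version: str = MOTIF_CATALOG_VERSION
    class_counts: dict[int, int] = field(default_factory=dict)
    seed: int = 0
    tool_version: str = __version__

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(X)

    @property
    def classes(self) -> np.ndarray:
        return self.clf.classes_


class SchemaMismatchError(RuntimeError):
    pass


def train(dataset: list[LabeledSite], seed: int = 0) -> PRFModel:
    """Fit the 3-class model; deterministic for fixed data order and seed."""
    if not dataset:
        raise ValueError("empty training set")
    labels = sorted({s.label for s in dataset})
    if len(labels) < 2:
        raise ValueError(
            f"training requires at least two classes, got {labels}"
        )
    X = np.array([s.features.as_vector() for s in dataset])
    y = np.array([s.label for s in dataset])
    clf = HistGradientBoostingClassifier(
        l2_regularization=1.0, early_stopping=False, random_state=seed
    )
    clf.fit(X, y)
    counts = {int(k): int(v) for k, v in zip(*np.unique(y, return_counts=True))}
    return PRFModel(clf=clf, class_counts=counts, seed=seed)


def save_model(model: PRFModel, path) -> None:
    joblib.dump(
        {
            "clf": model.clf,
            "feature_schema_version": model.feature_schema_version,
            "motif_catalog_version": model.motif_catalog_version,
            "class_counts": model.class_counts,
            "seed": model.seed,
            "tool_version": model.tool_version,
        },
        path,
    )


def load_model(path) -> PRFModel:
    blob = joblib.load(path)
    if blob["feature_schema_version"] != FEATURE_SCHEMA_VERSION:
        raise SchemaMismatchError(
            f"model was trained with feature schema "
            f"{blob['feature_schema_version']}, this build uses "
            f"{FEATURE_SCHEMA_VERSION}"
        )
    if blob["motif_catalog_version"] != MOTIF_CATALOG_VERSION:
        raise SchemaMismatchError(
            f"model was trained with motif catalog "
            f"{blob['motif_catalog_version']}, this build uses "
            f"{MOTIF_CATALOG_VERSION}"
        )
    return PRFModel(
        clf=blob["clf"],
        feature_schema_version=blob["feature_schema_version"],
        motif_catalog_version=blob["motif_catalog_version"],
        class_counts=blob["class_counts"],
        seed=blob["seed"],
        tool_version=blob.get("tool_version", "unknown"),
    )


def predict_pair(
    model: PRFModel, ps: PairSites
) -> Prediction | None:
    """At most one prediction per gene pair.

    Among candidates whose predicted class is a shift, the one with the
    highest class probability wins; exact ties go to the candidate closer
    to the in-frame stop (smaller N), then the 5'-most one.
    """
    if not ps.candidates:
        return None
    X = np.array([sc.features.as_vector() for sc in ps.candidates])
    proba = model.predict_proba(X)
    classes = list(model.classes)
    best: tuple | None = None
    for sc, row in zip(ps.candidates, proba):
        k = int(np.argmax(row))
        direction = int(classes[k])
        if direction == 0:
            continue
        score = float(row[k])
        key = (-score, sc.features.N, sc.candidate.position)
        if best is None or key < best[0]:
            best = (key, sc, direction, score)
    if best is None:
        return None
    _, sc, direction, score = best
    return Prediction(
        genome_id=ps.genome_id,
        pair=ps.pair,
        candidate=sc.candidate,
        features=sc.features,
        direction=direction,
        score=score,
    )


def _merged_join_feature(pred: Prediction) -> CdsFeature:
    """Joined CDS for a predicted frameshift over a non-joined pair."""
    pair = pred.pair
    p = pred.candidate.p_site_end
    if pred.direction == -1:
        x1, x2 = p - 1, p - 1  # one annotation boundary, zero-nt separation
    else:
        x1, x2 = p, p + 1  # forward shifts skip one base
    # interval() is its own inverse, so these are genomic coordinates while
    # keeping reading order (segment 1 is read first on either strand)
    seg1 = pair.view.interval(pair.a_interval[0], x1)
    seg2 = pair.view.interval(x2, pair.b_interval[1])
    product = pair.gene_a.product or pair.gene_b.product
    return CdsFeature(
        segments=[seg1, seg2],
        strand=pair.strand,
        product=product or "predicted frameshifted gene",
        source_order=pair.gene_a.source_order,
    )


def predictions_to_frame(predictions: list[Prediction]) -> pd.DataFrame:
    rows = []
    for pred in predictions:
        feats = pred.features
        rows.append(
            {
                "genome": pred.genome_id,
                "gene_a": pred.pair.gene_a.one_based_segments()[0],
                "gene_b": pred.pair.gene_b.one_based_segments()[0],
                "strand": pred.pair.strand,
                "position": pred.position,
                "direction": pred.direction,
                "motif_name": pred.candidate.motif.name,
                "score": round(pred.score, 6),
                **{
                    name: getattr(feats, name)
                    for name in FEATURE_NAMES
                },
            }
        )
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


def predict_genome(
    model: PRFModel, record: GenomeRecord
) -> tuple[list[Prediction], GenomeRecord]:
    """Predict frameshifts over all candidate pairs of one genome.

    Returns the predictions plus a copy of the record in which each
    predicted pair of single-segment genes is merged into one joined CDS.
    """
    predictions: list[Prediction] = []
    for ps in candidate_sites(record, split_joins=False):
        pred = predict_pair(model, ps)
        if pred is not None:
            predictions.append(pred)
    replaced: dict[int, CdsFeature] = {}
    drop: set[int] = set()
    for pred in predictions:
        a, b = pred.pair.gene_a, pred.pair.gene_b
        if a.joined or b.joined:
            continue
        ia = next(i for i, f in enumerate(record.features) if f is a)
        ib = next(i for i, f in enumerate(record.features) if f is b)
        replaced[min(ia, ib)] = _merged_join_feature(pred)
        drop.add(max(ia, ib))
    feats: list[CdsFeature] = []
    for i, f in enumerate(record.features):
        if i in replaced:
            feats.append(replaced[i])
        elif i not in drop:
            feats.append(f)
    annotated = GenomeRecord(
        locus_id=record.locus_id, sequence=record.sequence, features=feats
    )
    return predictions, annotated
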