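import dataclasses

import joblib
import numpy as np
import pytest

from prfscan.classifier import (
    LabeledSite,
    SchemaMismatchError,
    assemble_training_set,
    candidate_sites,
    load_model,
    predict_genome,
    predict_pair,
    predictions_to_frame,
    save_model,
    train,
)
from prfscan.genbank_io import CdsFeature, GenomeRecord
from prfscan.signal_features import SiteFeatures
from prfscan.synthetic import as_gene_calls


def _toy_site(label: int, i: int) -> LabeledSite:
    pos = label != 0
    f = SiteFeatures(
        DIR=-1, RBS1=27 if pos else 0, RBS2=6.3 if pos else 0.0, MOTIF=2,
        A0=0.02, A1=0.03, LF50=0.9 if pos else 0.1, LF100=0.8 if pos else 0.1,
        HK50=0.9 if pos else 0.1, HK100=0.8 if pos else 0.1,
        N=15 if pos else 40,
    )
    return LabeledSite(features=f, label=label, genome_id="T", pair_id=str(i),
                       position=i)


def _toy_dataset(n=60):
    return [_toy_site(-1 if i % 3 == 0 else 0, i) for i in range(n)]


class TestAssemble:
    def test_positive_pairs_match_planted_count(self, corpus_small):
        sites = assemble_training_set(corpus_small.records)
        pos_pairs = {(s.genome_id, s.pair_id) for s in sites if s.label != 0}
        assert len(pos_pairs) == len(corpus_small.truth)

    def test_labels_only_near_junctions(self, corpus_small):
        for rec in corpus_small.records[:3]:
            for ps in candidate_sites(rec, split_joins=True):
                for sc in ps.candidates:
                    if sc.label != 0:
                        assert ps.is_join
                        assert abs(sc.candidate.p_site_end - ps.junction) <= 10
                    elif ps.is_join:
                        near = abs(sc.candidate.p_site_end - ps.junction) <= 10
                        same_dir = sc.candidate.direction == ps.join_direction
                        assert not (near and same_dir)

    def test_genome_without_cds_skipped(self):
        rec = GenomeRecord("NOCDS", "ACGT" * 100, [])
        assert assemble_training_set([rec]) == []


class TestTrain:
    def test_deterministic_across_runs(self):
        data = _toy_dataset()
        X = np.array([s.features.as_vector() for s in data])
        m1 = train(data, seed=3)
        m2 = train(data, seed=3)
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_separable_dataset_fits_exactly(self):
        data = _toy_dataset()
        model = train(data, seed=0)
        X = np.array([s.features.as_vector() for s in data])
        y = np.array([s.label for s in data])
        assert (model.clf.predict(X) == y).all()

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="two classes"):
            train([_toy_site(0, i) for i in range(10)], seed=0)

    def test_hyperparameters_as_stated(self):
        model = train(_toy_dataset(), seed=0)
        assert model.clf.l2_regularization == 1.0
        assert model.clf.early_stopping is False


@pytest.fixture(scope="module")
def corpus_model(corpus_small):
    return train(assemble_training_set(corpus_small.records), seed=1)


class TestPredictPair:
    def test_no_candidates_no_prediction(self, corpus_model, corpus_small):
        ps = candidate_sites(corpus_small.records[0], split_joins=True)[0]
        empty = dataclasses.replace(ps, candidates=[])
        assert predict_pair(corpus_model, empty) is None

    def test_single_best_candidate_returned(self, corpus_model, corpus_small):
        for rec in corpus_small.records:
            for ps in candidate_sites(rec, split_joins=True):
                pred = predict_pair(corpus_model, ps)
                if pred is None:
                    continue
                X = np.array([sc.features.as_vector() for sc in ps.candidates])
                proba = corpus_model.predict_proba(X)
                classes = list(corpus_model.classes)
                shift_scores = [
                    row[np.argmax(row)]
                    for row in proba
                    if classes[int(np.argmax(row))] != 0
                ]
                assert shift_scores, "prediction without a shifting candidate"
                assert pred.score == pytest.approx(max(shift_scores))
                w_start, w_end = ps.pair.window
                assert w_start <= pred.candidate.position < w_end

    def test_at_most_one_prediction_per_pair(self, corpus_model, corpus_small):
        # pairs with several shift-scoring candidates still yield one call
        found_multi = False
        for rec in corpus_small.records:
            for ps in candidate_sites(rec, split_joins=True):
                if not ps.is_join or len(ps.candidates) < 2:
                    continue
                found_multi = True
                assert predict_pair(corpus_model, ps) is not None
        assert found_multi


class TestSerialization:
    def test_round_trip_predictions_identical(self, corpus_model, tmp_path):
        X = np.array([s.features.as_vector() for s in _toy_dataset()])
        path = tmp_path / "model.joblib"
        save_model(corpus_model, path)
        back = load_model(path)
        assert np.array_equal(back.predict_proba(X), corpus_model.predict_proba(X))
        assert back.class_counts == corpus_model.class_counts

    def test_schema_mismatch_is_hard_error(self, corpus_model, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(corpus_model, path)
        blob = joblib.load(path)
        blob["feature_schema_version"] = "0-incompatible"
        joblib.dump(blob, path)
        with pytest.raises(SchemaMismatchError):
            load_model(path)
        blob["feature_schema_version"] = corpus_model.feature_schema_version
        blob["motif_catalog_version"] = "0-incompatible"
        joblib.dump(blob, path)
        with pytest.raises(SchemaMismatchError):
            load_model(path)


class TestPredictGenome:
    def test_no_pairs_leaves_annotation_unchanged(self, corpus_model):
        seq = "ATGAAACCC" + "TAA" + "C" * 200 + "ATGGGGCCC" + "TAA" + "C" * 40
        feats = [
            CdsFeature(segments=[(0, 12)], strand="+"),
            CdsFeature(segments=[(212, 224)], strand="+"),
        ]
        rec = GenomeRecord("FLAT", seq, feats)
        preds, annotated = predict_genome(corpus_model, rec)
        assert preds == []
        assert [f.segments for f in annotated.features] == [
            f.segments for f in rec.features
        ]

    def test_planted_prf_rejoined_near_truth(self, corpus_model, corpus_small):
        rec = corpus_small.records[0]
        truth = corpus_small.truth[corpus_small.truth.genome == rec.locus_id]
        calls = as_gene_calls(rec)
        preds, annotated = predict_genome(corpus_model, calls)
        assert len(preds) == 1
        joined = [f for f in annotated.features if f.joined]
        assert len(joined) == 1
        junction = int(truth.junction.iloc[0])
        assert abs(joined[0].segments[0][1] - junction) <= 10

    def test_rerun_is_byte_identical(self, corpus_model, corpus_small):
        calls = as_gene_calls(corpus_small.records[1])
        out = []
        for _ in range(2):
            preds, _ = predict_genome(corpus_model, calls)
            out.append(predictions_to_frame(preds).to_csv(sep="\t", index=False))
        assert out[0] == out[1]
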