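"""Train on a small synthetic corpus and predict a frameshift from gene calls.

Builds 8 related genomes with one planted backward frameshift gene each,
trains the 3-class gradient-boosted model on 7 of them, and predicts on the
held-out genome as a gene caller would see it (the joined gene split into
two plain CDS features).  The printed row is the single re-joined gene: its
motif class, the 1-based motif position, the shift direction and the class
probability, followed by where the truth table planted the junction.
"""

from prfscan import assemble_training_set, predict_genome, predictions_to_frame, train
from prfscan.synthetic import FixtureSpec, as_gene_calls, make_corpus

corpus = make_corpus(FixtureSpec(n_genomes=8, n_families=2, seed=7))
held_out, training = corpus.records[0], corpus.records[1:]

model = train(assemble_training_set(training), seed=7)
print(f"trained on {len(training)} genomes; classes: {model.class_counts}")

calls = as_gene_calls(held_out)  # joined annotations removed, as a gene caller sees it
predictions, annotated = predict_genome(model, calls)
print(predictions_to_frame(predictions)[
    ["genome", "position", "direction", "motif_name", "score", "N"]
].to_string(index=False))

truth = corpus.truth[corpus.truth.genome == held_out.locus_id]
print(f"planted junction (0-based boundary): {int(truth.junction.iloc[0])}, "
      f"motif {truth.motif.iloc[0]}")
n_joined = sum(f.joined for f in annotated.features)
print(f"re-joined CDS features written into the annotation: {n_joined}")
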