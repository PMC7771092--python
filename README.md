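# conceptnorm

Few-shot entity normalization: map textual entity mentions onto concepts of
an OBO ontology by training shallow neural networks to project
word-embedding representations of mentions onto hierarchy-encoded concept
vectors.

Three architectures share the same input (a padded matrix of the mention's
token embeddings) and the same regression target (the concept's vector,
with weight 1 on the concept itself and `decay^d` on each ancestor at `d`
is_a steps):

- **slfnn** — masked token averaging followed by a single dense linear layer;
- **cnn** — a shallow convolutional net: one width-1 filter per concept,
  max-pooling over token positions, leaky-ReLU;
- **cnorm** — both branches in parallel, combined by an elementwise
  averaging layer and trained end-to-end through a single log-cosh loss
  (Nadam optimizer).

Decoding is cosine nearest-neighbor search over the concept vectors. A
sieve combiner is also provided: keep the first model's predictions above a
confidence threshold, give the rest to the second model. Training data can
be augmented with weak supervision: every ontology label (and synonym)
becomes a training example for its own concept, which covers concepts that
have no gold example at all (the zero-shot case).

Evaluation reports the strict exact score and the Wang semantic-similarity
score, averaged over mentions, plus an error typology (over-generalization,
over-specification, off-path, partial).

The models are implemented directly in numpy (analytic gradients, Nadam,
log-cosh): they are small enough that a deep-learning framework would add
nothing but a dependency.

## Data formats

- Ontology: OBO 1.2/1.4 flat file (`[Term]` stanzas; `id`, `name`,
  `synonym`, `is_a`, `alt_id`, `is_obsolete`).
- Embeddings: word2vec text (`V D` header then one `token w1 .. wD` line
  per token) or word2vec binary.
- Corpus: BioNLP-ST standoff — `.txt` document, `.a1` entities
  (`Tn<TAB>Type start end[;start end]*<TAB>surface`), `.a2` normalizations
  (`Nn<TAB>Resource Annotation:Tk Referent:CONCEPT`).

## CLI

`conceptnorm` has four subcommands. A self-contained walk-through on
generated fixtures:

```sh
# 1. generate a toy ontology + embeddings + annotated corpus
conceptnorm synthesize --n-concepts 50 --embedding-dim 20 \
    --n-mentions 200 --examples-per-concept 5 --seed 1 --out fixtures/

# 2. train the averaging ensemble with weak supervision
conceptnorm train --ontology fixtures/ontology.obo \
    --embeddings fixtures/embeddings.txt \
    --corpus fixtures/corpus/train \
    --architecture cnorm --mode standard+weak --seed 1 --out run/model

# 3. predict concepts for the dev split
conceptnorm predict --ontology fixtures/ontology.obo \
    --embeddings fixtures/embeddings.txt \
    --corpus fixtures/corpus/dev \
    --model run/model/model.json --out run/preds

# 4. score against gold
conceptnorm evaluate --ontology fixtures/ontology.obo \
    --gold fixtures/corpus/dev \
    --predictions run/preds/predictions.tsv --out run/eval
```

`predict --fallback-model second/model.json` enables the sieve combination
(`--sieve-threshold`, default 0.4). `train`/`predict` accept `--config
file` with flat `key = value` lines (and `include` directives); explicit
flags override config keys. Every command writes a JSON manifest with the
configuration, seed, versions and input digests. Exit codes: 0 success, 2
validation error, 1 runtime error.

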