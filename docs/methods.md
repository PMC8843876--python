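# Methods

## Cleaning pipeline

Raw tables are cleaned in five ordered steps: (1) records whose SMILES
fails RDKit parsing are dropped; (2) records failing the organic filter
are dropped; (3) stereochemistry annotations are stripped; (4) of
multi-fragment (salt) records only the fragment with the most heavy
atoms is kept, ties broken by lexicographically smallest canonical
SMILES; (5) the RDKit-canonical SMILES is emitted. The report counts
removals at steps 1–2 and modifications at steps 3–4, so
`n_output = n_input − n_removed_invalid − n_removed_inorganic` always
holds.

Design choices where the procedure was genuinely open:

* **Organic filter.** Defined as "contains at least one carbon and only
  elements from a configurable allow-list" (default H, B, C, N, O, F,
  P, S, Cl, Br, I). The filter is evaluated on the fragment that
  desalting will keep, not the whole record — otherwise every
  inorganic-counterion salt (sodium acetate, amine hydrochlorides)
  would be discarded before the desalting step could rescue its organic
  part.
* **No charge neutralization.** The kept fragment retains its formal
  charges; neutralization is a separate curation decision this pipeline
  deliberately does not take.
* **No deduplication.** Molecules that collide on canonical SMILES
  after cleaning are kept (a warning is logged); merging labels of
  replicate measurements is left to the caller.
* Missing labels are preserved as NaN and masked out of the loss
  per task at training time.

## Augmentation

`randomize_smiles` applies a uniformly random permutation to the atom
numbering (RDKit `RenumberAtoms`) and writes the molecule out
non-canonically; the output always canonicalizes back to its parent.
`augment_dataset` emits variant 0 = the canonical original plus
`n_random` randomized variants per molecule, so N molecules yield
exactly `(n_random + 1)·N` records; with `positives_only`, molecules
whose binary label is 0 emit only their canonical record, which is how
a 41,127-molecule set with 1,443 positives and `n_random = 20` becomes
30,303 positive vs 39,684 negative records.

* **Duplicates among random draws are retained.** Redrawing until
  distinct could loop forever on small or symmetric molecules (ethanol
  has only a handful of spellings) and would break the exact count law.
* **Per-molecule random streams.** Each molecule's generator is seeded
  from (global seed, molecule_id), so augmentation is deterministic,
  order-independent and parallelizable.

## Vectorization

The character set is the set of distinct characters in the corpus,
sorted by code point (deterministic, permutation-invariant). Encoding
is strictly per character — two-character element tokens like `Cl`
occupy two one-hot rows — and padding is all-zero rows rather than a
pad symbol. `max_len` is the longest training string plus `extra_pad`
(default 5) positions of headroom, because a randomized spelling of a
molecule can be longer than its canonical one (estradiol's canonical
string has 32 characters; one of its renumbered spellings has 40).
Out-of-vocabulary characters or over-long strings at encode time raise;
nothing is truncated or masked silently.

## Models

All three architectures read the `(max_len, vocab)` one-hot matrix.

* `rnn1`: GRU/LSTM → mean pool over time → linear head.
* `rnn2`: two stacked recurrent layers → same readout.
* `cnn_rnn`: Conv1D (kernel 4, 64 channels, "same" padding by default)
  with ReLU → recurrent layer → mean pool → dense (128, ReLU) →
  dropout (0.2) → linear head. Pooling is applied before the dense
  layer; with a linear pooling operator the two orders differ only in
  where the ReLU sits, and pooling first is cheaper.

The classification head is a sigmoid per output trained with binary
cross-entropy on logits; regression uses a linear head and mean squared
error (squared error is the natural companion of the reported RMSE).
Regression targets are standardized per training fold (mean/sd fitted
on the training split, inverted at prediction) so Adam at learning rate
1e-3 behaves identically across label scales.

The layers run on a small reverse-mode autodiff engine written on
NumPy (`smilesaug.nn`): broadcast add/mul, matmul, slicing, pointwise
nonlinearities, a fused Conv1D and fused losses. Gradients are checked
against central finite differences (agreement ~1e-10) in the tests.
Gradient norms are clipped at 5 to guard against occasional recurrent
spikes.

### Training protocol

Defaults follow the standard protocol for this family of models:
200 epochs, batch size 64, Adam at 1e-3, 5-fold cross-validation with
checkpointing and early stopping (patience 20), and learning-rate decay
— implemented as multiplication by 0.5 after 10 epochs without
validation improvement, a plateau schedule chosen because "decay" by
itself underdetermines the rule. An internal validation split (10% of
the held-in molecules) drives early stopping; the checkpointed
best-validation weights are always restored.

* **Folds partition parent molecules**, never augmented records.
  Record-level splits would place near-duplicate spellings of test
  molecules in training and invalidate the evaluation.
* **Test-time prediction averages all variants** of a test molecule
  (arithmetic mean); a canonical-only mode is available via
  `aggregate_variants=False`.
* Seeds control fold assignment, weight initialization, batch shuffling
  and dropout. Beyond that, determinism is best-effort: BLAS reduction
  order may differ across platforms.
* A fold whose test molecules all share one class yields NaN
  classification metrics (recorded, not raised), since AUROC/AUPRC are
  undefined there.

## Metrics

RMSE and MAE for regression; AUROC (the Mann–Whitney statistic, ties
counting one half) and AUPRC (area under the precision–recall step
curve, no interpolation — linear PR interpolation is known to be
optimistic) for classification. The implementations delegate to
scikit-learn; the test suite cross-checks them against an exhaustive
pairwise oracle (AUROC) and an exhaustive threshold sweep (AUPRC) on
thousands of small random instances. Reported numbers are always
molecule-level, computed after variant averaging.

## Synthetic data

The fixture generator builds molecules from a small grammar over C/N/O:
a 3–12-atom main chain, optional branches on carbons, an optional ring
closure, with valence tracked during construction so every string is
valid by construction (no rejection on parse failures); duplicates are
removed on canonical SMILES. The label rule is
`0.8·(heavy atoms) + 1.5·(oxygen count) + N(0, 0.3)` — a deliberately
graph-level property, so every randomized spelling of a molecule
carries the identical label, mirroring the premise of the augmentation.
Classification sets threshold the latent property so a requested
positive fraction (within one molecule) is positive.

What this emulates: small labeled sets whose label is a smooth function
of composition. What it does not: real chemistry's functional-group
effects, activity cliffs, label noise structure, or the property
distributions of curated benchmarks. Passing tests therefore
demonstrate that the machinery is correct and that augmentation helps
in the small-data regime; they do not certify benchmark-level accuracy
on real datasets.

## Problem sizes used in tests and the acceptance script

Count-law checks run at the real benchmark cardinalities (1,127 / 642 /
1,513 / 4,200 / 41,127 molecules) since augmentation is cheap. Model
checks run on a 60-molecule fixture with the `cnn_rnn`-GRU model scaled
to kernel 3 / 16 channels / 24 hidden / 32 dense units, 25 epochs,
batch 32, 5 folds — sizes at which a NumPy training loop completes a
full cross-validation in seconds while leaving the small-data regime
(where augmentation matters) intact. The augmentation-benefit
comparison repeats the full CV at `n_random = 5` vs `n_random = 0`
across three seeds and compares mean CV RMSE directionally.

## Known limitations

* Character-level one-hot encoding cannot distinguish `Cl` from `C`+`l`
  by construction; it never arises because the vocabulary is built from
  the corpus, but models see two-character elements as two tokens.
* The NumPy training loop is single-threaded and intended for the
  small-molecule-count regime; it is a faithful but not fast
  implementation of the training protocol.
* Mean pooling runs over the full padded length (padding rows
  contribute after the convolution's bias); masked pooling would be a
  refinement.
* AUPRC on heavily imbalanced folds has high variance at small test
  sizes; per-fold values are reported alongside the mean for that
  reason.
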