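# Methods

## Model and assumptions

`nolscan` treats NoLS detection as window classification followed by
segment averaging. The assumptions inherited from the original detector
are: (i) the nucleolar targeting signal is local — 13 consecutive residues
carry enough information to score a position; (ii) residue identity
matters only through membership in 12 physicochemical groups; (iii) a
biologically meaningful signal spans at least 20 residues, enforced by
requiring 8 consecutive high-scoring windows rather than thresholding
single windows; and (iv) the signal is compositional (basic-residue-rich)
rather than strictly positional, which is why a feed-forward network on
one-hot features suffices.

The per-window scorer is a fully connected network, 156 (or 195) inputs →
one hidden layer of 10 logistic units → one logistic output. The original
hidden architecture was never published; one hidden layer of 10 units is
the smallest architecture that separates the synthetic corpus with margin
and trains in seconds, and both depth and width are configurable
(`Hyperparameters.hidden_sizes`).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `window_length` | 13 | residues | scored window |
| `alphabet_size` | 12 | groups | reduced alphabet |
| `consecutive_windows` | 8 | windows | averaged per segment |
| `score_threshold` | 0.8 | — | segment calling cutoff, inclusive ("at least") |
| `min_overlap_fraction` | 0.6 | — | benchmark match criterion, of the shorter interval |
| `max_test_nols_length` | 50 | residues | longest experimental NoLS admitted to benchmarking |

The derived candidate segment length is 13 + 8 − 1 = 20 residues, so every
called interval is ≥ 20 residues. All coordinates are 1-based inclusive.

**Reduced alphabet.** The original 12-group composition is unpublished.
The default (`basic12`) is {K,R}, {D,E}, {S,T}, {N,Q}, {I,L,V}, {F,Y},
{A}, {G}, {P}, {C}, {M}, {H,W}: the basic residues — the dominant NoLS
signal — form their own group, standard physicochemical classes are
merged, and the remaining residues stay singletons to reach exactly 12
groups (H and W are merged as the two large ring systems). Any alternative
12-group partition can be passed as a `ReducedAlphabet`; the alphabet is
embedded (with a checksum) in every saved model, so a model can never be
applied under the wrong encoding.

**Secondary structure.** The optional channel takes a precomputed
per-residue H/E/C string aligned to the sequence and appends a trailing
13 × 3 one-hot block per window (trailing rather than interleaved — a free
choice, fixed for reproducibility). No structure predictor is invoked;
the default is disabled.

## Training procedure

Weighted binary cross-entropy, minimized by mini-batch gradient descent
(default: learning rate 0.5 on one-hot inputs, batch 64, L2 10⁻⁴, ≤ 200
epochs). Class imbalance is handled by per-class weights giving both
classes equal effective weight by default, since realistic negative sets
(hundreds of background proteins) dwarf the positive set. A 10% validation
slice, split off deterministically, drives early stopping (patience 20)
with restoration of the best weights. Every random choice — weight
initialization, shuffling, the validation split — flows from a single
integer seed, so training is bit-reproducible. Non-finite losses abort
with diagnostics rather than silently saturating.

Models serialize to versioned JSON with full-precision floats (JSON
round-trips Python doubles exactly), so `load(save(m))` reproduces forward
outputs bit-identically; the file embeds the alphabet, feature
configuration and training metadata.

## Segment calling

Segment score *i* is the mean of window scores *i..i+7*, defined only
where all 8 windows exist; sequences shorter than 20 residues yield "no
NoLS" with a warning rather than an error so multi-FASTA batches never
abort. Positive segments (score ≥ 0.8, inclusive) that overlap **or
touch** are merged into one interval — merging only runs of consecutive
starts would let positive starts two apart (e.g. 1 and 3) emit overlapping
intervals, violating the non-overlap invariant; union of the covered
residues is the only consistent reading, and it is what the brute-force
oracle in the tests computes independently. The per-residue profile used
for plotting and FULL/COMPLETE reports assigns residue *i* the segment
score starting at *i* and repeats the final segment score for the last 19
residues, so the profile always has exactly sequence length (the trailing
convention is unstated upstream; repetition keeps the profile flat rather
than inventing a decay).

## Benchmark evaluation

Matching is many-to-many, then thresholded: an experimental NoLS is
detected if *any* prediction covers ≥ 60% of the shorter of the two
(inclusive lengths); a prediction is a true positive if it matches *any*
experimental NoLS. No one-to-one assignment is attempted — this is the
only reading that reproduces the published counts (TP = 22, FP = 6)
row-by-row. Specificity is per-protein (proteins with zero false-positive
segments / all proteins), the only definition consistent with the
published 21/27 = 78%. The "< 50 residues" admission filter is implemented
as inclusive length ≤ 50 because the benchmark retains a 51–100 signal
(inclusive length exactly 50); the strict variant is available via
`Parameters(strict_length_filter=True)`. Group metrics are rounded to 2
decimals and the overall summary to integer percent, matching the
conventional presentation; raw fractions are always available.

The packaged benchmark TSV stores, per experimental NoLS: organism,
taxon/host group, accession, protein name, the experimental interval, and
the semicolon-separated intervals the original human-trained detector
reported for that protein (empty when it reported none). The original
detector's weights are not available, so its per-protein predictions are
fixture data, not recomputed; what `nolscan` recomputes is the entire
evaluation on top of them.

## Synthetic data: what it does and does not show

The generator emulates exactly one property of real NoLSs — short
(15–40 residue) segments enriched in K/R (combined mass 0.55, split
55:45) on an i.i.d. uniform background — with motif residues drawn
i.i.d. from the enriched categorical. It does not model positional
structure within signals, realistic background composition, secondary
structure, homology between proteins, or divergent signals such as the
trypanosome NoLSs the human-trained detector misses. Passing end-to-end
tests therefore shows the pipeline is self-consistent (a scorer trained on
the generator's windows recovers its planted motifs through encoding,
scoring and calling), not that a freshly trained model matches the
original detector's accuracy on real proteomes.

Default study conditions for the end-to-end check: 2,000 positive + 2,000
negative windows (20% held out), one planted motif per 300-residue test
protein, 200 test proteins. At these sizes training takes ~0.5 s and the
full check a few seconds on one CPU; held-out window AUROC is ≈ 0.99 and
motif recovery ≈ 0.95–1.0 with a per-protein false-positive rate ≈ 0.1
across seeds.

## Numerical choices and degenerate inputs

- Logistic units use the numerically stable piecewise sigmoid; scores are
  exactly bounded in [0, 1] for finite weights.
- Threshold comparisons are inclusive (≥ 0.8, ≥ 60%).
- Ambiguous characters are removed, never substituted; every removal keeps
  its original coordinate so cleaned-sequence positions remain traceable.
- Empty FASTA input yields an empty batch, not an error; a record emptied
  by cleaning is an error naming the record; sequence text before any
  header is an error naming the line.
- Ties/adjacency in calling: touching positive segments merge (see above);
  identical profiles always give identical calls.

## Known limitations

- The bundled model is trained on synthetic data; for real predictions at
  published accuracy one would need the original training corpus, which is
  not redistributable here. The architecture, encoding and calling rule
  are faithful, and the model is retrainable on any labeled window set.
- The benchmark is small (31 signals) and its group rows smaller still;
  per-group metrics carry wide implicit confidence intervals.
- Only single-sequence, primary-structure inputs: no signal patches formed
  by residues distant in sequence, no alignments, no nucleotide input.
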