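# Methods

## Windows and the gap alphabet

All sequence handling uses 1-based, fully closed coordinates. A window of
half-width `n` around position `p` covers `[p−n, p+n]` and always has
length `2n+1`; positions outside the source sequence are filled with the
pad character `-`, which is a first-class fifth symbol of the alphabet
`Σ = {A, C, G, T, -}` and flows through every encoding. By construction
pads can only appear as a contiguous prefix and/or suffix run, and both
one-sided and two-sided truncation are supported. Input is normalized by
uppercasing and mapping RNA `U` to `T`; under the default `strict` policy
any other character is an error with its position, while the `mask` policy
maps ambiguity codes to `-` (not to a sixth symbol, keeping downstream
encodings 5-wide) with a logged warning.

## Tokenization and vocabularies

Windows are split into overlapping k-mers of size `k` with stride `s`
(defaults `k=3`, `s=1`), giving `L = ⌊(L₀−k)/s⌋ + 1` tokens. The canonical
gap-aware vocabulary contains every k-mer over A/C/G/T, every k-mer whose
gaps form a single run anchored at exactly one end, and the all-gap k-mer:
`4^k + 2·Σᵢ₌₁^{k−1} 4^i + 1` entries, i.e. 105 at `k=3`. The canonical
enumeration is used as the normative definition rather than the empirical
set observed in any particular corpus (a corpus-derived vocabulary is also
available); interior-gap patterns such as `A-C` are excluded because end
padding cannot produce them. Index 0 is reserved for unknown/pad so
embedding layers can mask it; strict embedding encoding refuses unknown
tokens, index encoding maps them to 0 and tallies them.

## GloVe embeddings and the two optimizers

Co-occurrence counts `Y_ij` tally, for every ordered pair of positions at
token distance 1..c within one window's token sequence, the pair of tokens
at those positions. The context distance is measured in tokens (not
nucleotides), contexts never cross window boundaries, and the default
`c = 30`. Increments are unweighted counts; the classical 1/distance decay
is available behind a flag (default off). Unknown/pad indices (0) are
skipped.

The objective is the weighted least-squares fit of `eᵢ·ẽⱼ + bᵢ + b̃ⱼ` to
`log Y_ij` over positive cells, with weight `f(y) = (y/y_max)^β` capped at
1 (`y_max = 100`, `β = 0.75`). Training visits each positive cell once per
epoch in a seeded shuffled order and takes one optimizer step per cell on
that cell's squared term, using the analytic partials. Parameters
initialize uniformly in `[−0.5/D, 0.5/D]`. Adagrad (learning rate 0.05,
the classical choice for this model) divides by the root of the running
*sum* of squared gradients, so its per-coordinate effective step is
non-increasing; RMSProp (α = 0.001, λ = 0.9, δ = 1e−8) uses the decaying
*average*, so the step can recover after a burst of large gradients — the
reason it is preferred here. The conceptual fixed history window of
RMSProp is implicit in the decay factor; no explicit truncation is
implemented. Early stopping triggers when the relative epoch improvement
falls below 1e−4 (disable by setting it to 0). The exported vector for a
token is its main vector `e`; `e + ẽ` export is available behind a flag.
Default dimension is `D = 300`; the desk-scale experiments below use
`D = 16`.

## The DCB classifier

The network is implemented entirely in numpy with hand-written
backpropagation; the test suite verifies every analytic gradient against
central finite differences (with and without dropout masks active) and
checks the vectorized layers against literal per-element reference
implementations of the dilated convolution and the LSTM recurrence.

Two index conventions exist for the one-sided dilated convolution: the
literal form places taps at offsets `r, 2r, …, Nr` from the output
position, while frameworks place them at `0, r, …, (N−1)r`. Both are
provided as reference functions; they are the same operator shifted by
`r`, and the trainable network uses the framework convention.

Architecture (defaults in parentheses): three parallel blocks of dilated
convolution (64 filters, kernel 3, dilation rates 1/2/3, ReLU, valid
padding — no padding is applied and a minimum input length is enforced)
→ max-pool (2) → dropout (0.2). With valid padding the three block outputs
differ in length, so they are right-cropped to the shortest length and
concatenated along channels (192 channels at default width); cropping
discards at most 3 trailing positions and keeps the channel-concatenation
semantics. Then a bidirectional LSTM (64 units per direction, full output
sequence) with dropout 0.2 applied to its output sequence (the placement
among input/recurrent/output variants being an implementation choice),
flattening, dense layers 256/128/64 (ReLU, dropout 0.5), and a 1-unit
sigmoid head. Forget-gate biases initialize to 1, other weights
Glorot-uniform from the seed.

Training: binary cross-entropy, Adam (lr 1e−3, β₁ 0.9, β₂ 0.999), batch
32, 10 epochs by default, optional validation split with patience-3 early
stopping and best-weights restore, optional inverse-prevalence class
weighting (off by default). All shuffling and dropout derive from one
seeded generator, so runs are bit-reproducible; inference applies no
dropout. The trainable-embedding encoder owns a `(W+1, D)` table whose
row 0 (pad) is frozen at zero.

## Ensemble and evaluation

The soft vote is the element-wise mean of the members' predicted
probabilities; by convexity of −log its log-loss never exceeds the worst
member's. Threshold metrics (Sn, Sp, Acc, Pre, F1, MCC) use the standard
confusion-count formulas at a configurable threshold, default 0.5, with
the tie `p = t` counted as a positive call; reported values are always
tied to the stated threshold since different operating points move Sn/Sp
against each other. Zero-denominator metrics return 0 with a warning
rather than NaN so imbalanced toy runs still produce reports. AUROC is the
trapezoidal ROC area (equivalently the tie-aware concordance probability);
AUPRC is the step-wise average-precision sum `Σ (Rᵢ − Rᵢ₋₁) Pᵢ`, which
differs from trapezoidal PR interpolation and is stated explicitly for
that reason.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of curated methylation-site
corpora: fixed odd window length centered on an adenosine, positive:
negative ratios of 1:1 (m⁶A-like) or 1:10 (m¹A-like), and a fraction of
windows from sources shorter than the window, produced by truncating the
source and re-extracting so padding exercises the ordinary extraction
path. Background is i.i.d. uniform A/C/G/T; positives carry the planted
motif (default `GGACT`, an m⁶A-consensus-like fixture with no biological
claim) overwritten across the center with probability `motif_insert_prob`.
It deliberately does not model real nucleotide composition, positional
conservation profiles, transcript context, or secondary structure, so
passing tests demonstrate that the pipeline can recover a planted,
position-locked signal and stays at chance on null data — not that any
particular benchmark performance would be attained on biological corpora.

## Desk-scale experiment sizes

The held-out experiments in the test suite and acceptance script use
51-nt windows, 500 windows (400 train / 100 test) for the planted-motif
runs and 1000 windows (400 train / 600 test) for the null calibration —
the larger null test split narrows the chance band of the AUROC estimate —
with a scaled-down network (8 filters, 8 BiLSTM units, dense 32/16) and
16-dimensional embeddings. These sizes keep a full three-encoder run
around twenty seconds while leaving the planted-motif signal comfortably
learnable.

At this scale the three encoders are not equally strong: the one-hot and
trainable-embedding variants recover the planted motif essentially
perfectly (held-out AUROC ≳ 0.93), while the frozen-RGloVe variant is the
weak member (AUROC ≈ 0.5–0.75 depending on the seed). The planted signal
enters the frozen features only as small differences between highly
correlated token vectors, and at 8 filters with the full dropout stack the
optimizer rarely locks onto it within 10 epochs, although the same data
are linearly separable in those features and the same network without
dropout reaches AUROC ≈ 0.98. This is an artifact of freezing a global
embedding at desk scale, not of the embedding objective; the soft vote is
robust to one weak member, which is precisely its purpose here.

## Numerical and degenerate-input choices

Sigmoid is computed in the numerically stable split form; cross-entropy
clips probabilities at 1e−12. Max-pool discards a trailing remainder
shorter than the pool window and routes gradients to the argmax (first
maximum on ties, the numpy convention). Training requires both classes
present and at least two samples; an all-zero co-occurrence matrix,
an empty corpus, even window lengths, and misaligned prediction files are
rejected with specific errors. Seeds are plain integers; every stochastic
component (generator, splits, initialization, shuffling, dropout) is
driven by an explicitly seeded generator and nothing reads global RNG
state.

## Known limitations

Training is single-threaded numpy: the full-size architecture (64 filters,
BiLSTM 64, 300-dim embeddings, 101/1001-nt windows) trains at roughly
seconds per batch and is practical only for small corpora; the scaled-down
configuration is the intended desk-scale operating point. No GPU path, no
gradient clipping, and no learning-rate schedules are provided. The CLI
covers the linear workflow; cross-validation loops are left to the caller.
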