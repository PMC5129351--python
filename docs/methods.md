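# Methods

This note records the modelling choices behind `gepqsar`: what is
implemented, which knobs matter, what the synthetic data does and does
not emulate, and where the published description was ambiguous and a
decision had to be made.

## Genotype, decoding, and protected arithmetic

A chromosome is a fixed-length token string over a function/terminal
alphabet, head length *h* (default 7) followed by a tail of
*t = h(n−1)+1* terminals, where *n* is the maximum function arity. The
tail formula guarantees that level-order decoding always closes every
open argument slot inside the string, so *every* random string satisfying
the head/tail typing is a syntactically valid model. Decoding is
breadth-first: token 1 is the root, and each subsequent tree level is
filled left-to-right, one token per pending child slot; trailing unused
tokens are inert (they are genetic material that recombination may later
expose). The test suite checks this decoder against an independently
written oracle that locates each node's children by cumulative-arity
index arithmetic rather than a queue.

Two function sets are provided: `arithmetic` {+, −, ×, ÷, Q} (Q = square
root), the default for evolution, and `extended` {+, −, ×, ÷, mod, exp,
log, sin, tan}, the alphabet of the published evolved rule. Numeric
constant terminals are supported but disabled by default.

Protected arithmetic keeps every genotype evaluable on every finite
input: x/0 → 1; log(y≤0) → 0; Q(y<0) → Q(|y|); exp exponent clamped to
±700; mod(a,0) → 0 with mod as the floating remainder; tan clamped to
±10⁶ near singularities; and every node result is clamped into
±10³⁰⁰ with NaN → 0 so chained products cannot overflow to infinity.
These are the standard protected-operator conventions of genetic
programming; the specific constants are implementation choices with no
effect on well-conditioned inputs.

## Fitness

Two modes:

* `hits_based` (default): the number of correctly classified training
  compounds under the `rule value > 0` convention. Simple, bounded by
  the training size, and what the search actually optimises.
* `as_printed`: the published composition
  `0 if consig < 0 else consig · ln(compl − 1)`. Since completeness
  `compl = p/P` never exceeds 1, the log argument is never positive and
  the protected log sends the whole expression to 0 identically. The
  composition is almost certainly a typographic corruption of its cited
  source; it is kept verbatim, behind the flag, as a fidelity reference,
  and its well-defined components `consig` and `compl` are tested by
  exhaustive brute force over all coverage grids with P, N ≤ 12.

`consig` of a rule covering nothing is defined as 0 (the limit of the
precision/base-rate comparison). The useful bound
`consig ≤ b(1−b)` with `b = P/(P+N)`, attained exactly by rules covering
only positives, is verified exhaustively.

## The evolutionary loop

Per generation: score all chromosomes; carry the top `elitism` (default
1) unchanged; refill by roulette (fitness-proportionate) selection with a
uniform fallback when all fitnesses are zero; then apply, in order,
per-position point mutation (rate 0.05), IS transposition (0.1/individual;
a random 1–3-symbol segment copied to a random non-root head position,
head truncated at its boundary), RIS transposition (0.1; segment must
start with a function token, inserted at the head root), gene
transposition (a recorded no-op for single-gene genotypes), and
one-point (0.3), two-point (0.3) and whole-genotype (0.1) recombination
on consecutive pairs. Cut indices are shared between parents, so tail
positions only ever receive tail material and closure is structural, not
checked-and-repaired. The run is bit-reproducible from the seed.

The published study gives no run parameters (only a desk-time remark);
the defaults — population 100, 500 generations — are canonical GEP
settings scaled so a full study fits in seconds, and `stop_at_fitness`
allows terminating once training is perfectly classified. Defaults for
head length (7) and operator rates follow common GEP practice.

## Classification and the published rule

`GEPClassifier(table, config).fit()` returns a results object holding the
winning chromosome, decoded rule, history, and provenance (seed + config
hash), serializable to JSON and reloadable into an equivalent predictor.
A rule value of exactly 0 maps to the negative class — the printed rule
uses a strict inequality, and for a carcinogen screen the conservative
default is to not call a borderline compound safe *positive*.

The published evolved rule ships as a frozen expression tree
(`reference_rule`). Two printed fragments are typographically ambiguous:
a tangent term adjacent to a binary-mod bracket, and the grouping of
`x5 mod(x3, x1)` inside a log. Both adjacencies are read as
multiplication by default (`interpretation="product"`), with an alternate
`"modulo"` reading that binds them as an outer binary mod; both are
documented, finite everywhere, and genuinely different parses. Neither
reading can be validated against the original compounds, because the
descriptor values were never published.

## Screening metrics

The 2×2 layout is A=TP, B=FP, C=FN, D=TN, making the printed formulas
the textbook sensitivity A/(A+C) and specificity D/(B+D); the source's
prose description of B and C contradicts its own formulas and is
overridden. Youden's index is computed from unrounded sensitivity and
specificity; note the published summary differences already-rounded
values (0.947 + 0.905 − 1 = 0.852, where the unrounded counts give
0.853). Report rounding is 3 decimals, round-half-even. A brute-force
search over all 93-compound tables shows exactly one count vector,
(A, B, C, D) = (18, 7, 1, 67), reproduces the published GEP training row
to 3 decimals.

The published per-compound prediction columns are internally
inconsistent with the published summary for GEP (recomputed accuracy
0.656 training / 0.686 test vs 0.914 / 0.829); the MLP columns reproduce
their summary accuracies to within printed rounding but not the
sensitivity/specificity pairs. The summary table is treated as metric
ground truth; the columns ship verbatim, and a regression test asserts
the discrepancy so it cannot be silently "fixed". The same applies to
the positive counts (25 + 9 labelled carcinogens in the tables vs the
24 + 11 implied by the text).

## Perceptron baseline

One hidden layer of ⌊(attributes+classes)/2⌋ sigmoid units (8 descriptors,
2 classes → 5), softmax output with cross-entropy, online (per-pattern)
gradient descent with momentum, inputs z-scored on the training table.
Learning rate 0.3, momentum 0.2, and a 20 % validation split are the
conventional workbench defaults the study implicitly used; 500 epochs and
patience 20 are as published. Early stopping restores the best-validation
weights. With `epochs=0` the output layer is set to the log class priors,
so the untrained model predicts the majority class. Margins are
`p(actual) − p(best wrong)`, equal to `2p(actual) − 1` in the binary
case, and are exported as (compound index, margin) tables with an
optional matplotlib plot.

## Synthetic data

The generator emulates the statistical shape the study assumes, not its
chemistry: eight jointly Gaussian descriptors with the published
correlation matrix as target (via its Cholesky factor; if a rounded
target ever leaves the PSD cone it is repaired by eigenvalue clipping
and diagonal renormalisation, and the repair is flagged on the spec —
the published matrix itself is positive definite, smallest eigenvalue
0.114), labels planted by a known rule with independent flip noise in
[0, 0.5), and the 128 → 93/35 encoding-based allocation. The default
planted rule is `ncos + nnos > 0`, balanced under centred marginals.

What passing recovery tests show: the search, decoder, metrics and
splitter interoperate and can find a plantable signal under the study's
correlation structure and sample sizes. What they do not show: anything
about real aromatic-amine chemistry — real descriptors are non-negative,
partly integer-valued, and skewed, and the real class balance is 35/93,
none of which the Gaussian generator reproduces (an optional post-step
rounds the two count columns for workflows that care).

## Problem sizes and numerical conventions

Tests and the acceptance script use the study's own sizes (128 compounds,
93/35 split, population 100 × ≤500 generations) plus n = 5000 draws for
correlation-fidelity checks and 10⁴ trials for operator closure; these
run in seconds. Delimited tables are written with shortest-exact float
representation and read with round-trip parsing, so write∘read is
identity. Ties in the collinearity filter drop the later column; the
filter removes, per offending pair (worst first), the member with the
larger mean absolute correlation to the remaining columns.

## Known limitations

* Single-gene chromosomes only; multi-gene genotypes with linking
  functions are out of scope (gene-level operators degenerate to no-ops
  or whole-genotype swaps).
* The `as_printed` fitness is degenerate by construction (see above).
* The published rule's predictions on the original 128 compounds are
  unrecoverable; fixtures can exercise the evaluator but not validate it
  against the source tables.
* No probability calibration, ROC analysis, parsimony pressure, or
  multi-objective fitness.
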