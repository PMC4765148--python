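# Methods

## Problem setting

A protein may reside in one or several of M subcellular locations. Its
feature vector is a length-T vector of GO term frequencies: the annotation
of its best annotated BLAST homolog is transferred to it, and entry j
counts the occurrences of the j-th vocabulary term. The vocabulary is the
set of distinct GO terms observed in the training proteins, ordered
lexicographically by GO id so that feature vectors are bit-reproducible.
Homolog transfer uses a successive search: homologs are ranked by
ascending E-value (ties: descending bit score, then subject id) and the
first one with any annotation supplies its whole multiset. Whether the
multisets of several homologs should instead be merged is not determined
by the procedure's description, so the first-annotated-homolog reading is
the default and `merge_top_k` exposes the merging dialect. The search
examines at most `max_homologs` (default 5) candidates before signalling
`NullGoTerms`. In leave-one-out evaluation the query's own accession is
excluded from its homolog list (`exclude_self`, default on) to avoid label
leakage.

## Penalized regressions and the homotopy solver

The per-location binary problems minimize the *un-halved, un-averaged*
squared error plus penalties:

    l(β) = Σ_i (y_i − βᵀx_i)² + λ Σ_j |β_j|            (+ γ Σ_j β_j² for the elastic net)

Conversions to other conventions: scikit-learn's `alpha` is λ/(2N);
formulations using ½‖r‖² use λ/2. The constraint form Σ|β_j| ≤ t is
supported by locating the equivalent λ on the coefficient path.

Columns are centered and scaled to unit variance and the response centered
before fitting (a `standardize=False` escape hatch exists); the penalty
acts on the standardized scale, weights are mapped back, and the intercept
— omitted from the objective by centering — is recovered from the
standardization record. Constant columns are flagged, excluded from the
active-set machinery and always get weight zero.

The solver is a LARS homotopy with the LASSO modification: it tracks the
active set and signs while λ decreases, solving G_A d = s_A for the
segment direction and advancing to the next event — a variable joining
when its correlation meets the shrinking boundary |2x_jᵀr| = λ, or leaving
when its coefficient crosses zero. Zero-length join events are
legitimate (a variable exactly on the boundary whose correlation decays
slower than the boundary must enter immediately); the single degenerate
case excluded is the instantaneous re-entry of a variable at the moment it
drops, which is the drop itself. A dropped variable may rejoin later in
the same segment. Singular Gram systems (exactly collinear active
columns) fall back to the minimum-norm direction, which yields a valid
(non-unique) solution that splits weight equally across duplicates. Ties
between simultaneous join events admit the lowest column index;
simultaneous drop and join events process the drop first. Numerical
guards: coefficients below 1e-12 are zeros, knots closer than 1e-12 in λ
are merged, and KKT residuals of returned fits are ~1e-14 (tests assert
< 1e-7).

The elastic net is solved exactly as a LASSO on the augmented design
[X; √γ·I] with the response padded by T zeros. The objective is the
"naive" elastic net — no post-hoc (1+γ) rescaling of coefficients — so the
augmented solution *is* the minimizer. γ = 0 short-circuits the
augmentation, making the elastic-net call bit-identical to the LASSO call.

## Two-stage multi-label training

Stage 1 fits M independent one-vs-rest regressions on ±1 transformed
labels over the full T-space; the union of nonzero supports, in vocabulary
order, is the essential term set S. Stage 2 refits the M regressions over
the S projected columns; refit penalties default to the stage-1 penalties.
Scores are s_m = ε_m + β̃_mᵀx^s with the intercept included (a flag can
zero it). The decision rule thresholds at zero: predict {m : s_m > 0},
else the single argmax (lowest index on exact ties), so predictions are
never empty.

How the per-class penalties λ_m (γ_m) should be chosen is genuinely open;
the default is per-class 5-fold cross-validation of the squared error over
a 20-point logarithmic grid from the path's λ_max down to λ_max·10⁻³,
with γ tuned over {0.01, 0.1, 1} for mEN (or fixed via the `gamma`
argument). All chosen penalties are recorded in the serialized model. This
is a reproducible stand-in, not a claim about how any particular benchmark
was tuned.

Leave-one-out evaluation redoes vocabulary construction, selection and
penalty tuning inside every fold by default; the `global_selection` flag
instead selects once on all proteins and only refits per fold — the
benchmark-style protocol, kept separate because it leaks the held-out
protein into feature selection.

## Hierarchical (HIB) mapping

Queries annotated only with non-essential terms would project to a null
vector. Since each GO taxonomy is a DAG, a non-essential term G still
carries information about a nearby essential term E. The effective count
of E is Σ_G f_G·w(d(G,E)) over annotated terms with d ≤ D, where d is the
shortest-path distance in the undirected view of the is_a/part_of edges
(terms in different taxonomies are at infinite distance). The cited
contribution formula for this mapping lives in an external reference; this
package defines w as a configurable non-increasing family with w(0) = 1,
defaulting to w(d) = 2^(−d) with D = 5, which preserves the stated
contracts (depth-distance based, contributions summed over all essential
terms within reach, non-null whenever any annotated term is within D of
any essential term). Dialect switches: `nearest_only` credits only the
nearest essential term per annotated term; `distance_mode="ancestor"`
restricts paths to the child→parent direction; `edge_types` restricts the
edge set. With D = 0 the mapping reduces exactly to plain projection.
Terms absent from the DAG are skipped with a warning (strict mode errors).

## Metrics

Per-protein set metrics: exact match (OAA), locative accuracy
(Σ|Y∩Y*| / Σ|Y|, counting a k-location protein k times), Jaccard accuracy,
precision |∩|/|Y*|, recall |∩|/|Y|, per-instance harmonic F1, pooled
micro F1, unweighted macro F1, and Hamming loss |YΔY*|/M. For macro F1 a
class absent from both truth and prediction contributes F1 = 0 and is
included in the average (conservative; `include_empty_classes=False`
drops such classes). The invariants OAA ≤ Accuracy ≤ F1 and OAA ≤ OLA are
property-tested.

## Synthetic data

The planted generator draws features as zero-inflated Poisson counts
(zero with probability 0.7, else Poisson(1.5)), matching the sparsity and
small-count character of GO term-frequency vectors. Each class has
exactly k true nonzero weights with magnitudes uniform in (0.5, 1.5) and
random signs; labels are the sign of the latent score β*_mᵀx + b_m + ε
with ε ~ N(0, σ²) and b_m centering the score at the population feature
mean, so classes are roughly balanced and the planted model is the
Bayes-optimal linear scorer (noise enters before the sign; a separate
`flip_rate` adds label noise after it). Five blocks of four strongly
correlated columns (copies of a leader with a 20 % entrywise redraw) are
placed on columns outside every planted support, so they exercise the
elastic net's grouping without making "support recovery" ambiguous. Every
row keeps at least one nonzero count, mirroring the guarantee of
homolog-transferred annotation. The default experiment scale for the
recovery study is N = 500, T = 200, M = 4, k = 10, σ = 0.5 over 20 seeded
replicates; in the containment comparison the elastic net reuses the
CV-chosen LASSO λ_m with fixed γ = 0.1, the small-γ regime in which its
selection is expected to nest the LASSO's.

What the generator does *not* emulate: real GO co-occurrence statistics,
the annotation-depth bias of real GOA releases, sequence-similarity
structure among proteins, and the extreme class imbalance of real
compartment data (the benchmark-composition generator reproduces only the
label-side marginals). Passing the planted-recovery tests therefore
demonstrates correctness of the selection machinery under the model's own
assumptions, not field performance on curated proteomes.

The toy DAG generator builds one rooted complete tree per taxonomy
(child→parent is_a edges) plus a fraction of extra part_of edges to
strictly shallower nodes, which keeps the graph acyclic by construction.

## Known limitations

* The homotopy solves systems from scratch at each knot (O(|A|³) per
  event); it is intended for the ~10⁴-feature scale, not 10⁶.
* LASSO solutions are non-unique under exact collinearity; the solver
  returns the minimum-norm representative, which can differ from other
  solvers' choices while attaining the same objective.
* HIB fidelity to the originally cited contribution formula requires
  consulting that reference; the implemented decay family is a documented
  superset controlled by `HibParams`.
* The CLI consumes pre-computed BLAST tabular output; it never runs BLAST.
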