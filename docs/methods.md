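# Methods

This note documents the models, the synthetic data generator, the
numerical choices, and the limitations of this package, in the order a
user meets them.

## 1. The Simple Configuration Model (SCM)

The SCM is the maximum-entropy ensemble of simple undirected graphs
whose expected degrees match the observed ones. It is parameterized by
one Lagrange multiplier λᵢ per protein; the probability of a link
between proteins *i* and *j* is

    p_ij = 1 / (exp(λᵢ + λⱼ) + 1),

and the λ solve the degree constraints Σ_{j≠i} p_ij = kᵢ.

**Solver.** We work in x_i = exp(−λᵢ), for which
p_ij = xᵢxⱼ/(1 + xᵢxⱼ), and iterate the damped fixed point
xᵢ ← kᵢ / Σ_{j≠i} xⱼ/(1 + xᵢxⱼ) with damping 0.5 and initialization
xᵢ = kᵢ/√(2m). Nodes with equal degree provably share x, so the
iteration runs over distinct degree classes (cost O(D²) per sweep,
D = number of distinct degrees, instead of O(n²)). If the fixed point
stalls, a quasi-Newton root solve on log x takes over. Default
tolerance is a maximum absolute degree residual of 1e-10; a typical
500-node sparse graph converges in a few dozen iterations.

**Degenerate degrees.** Degree-0 nodes are the exact λ → +∞ limit:
their link probabilities are 0, they are excluded from the solve, and
they remain eligible (indeed, top-ranked) negative candidates. A node
of degree n−1 forces p → 1 and an unbounded multiplier; λ is capped at
±50 and the fit reports `converged=False` whenever the capped solution
cannot meet the tolerance.

**Ranking.** Candidate negatives are all unordered non-self pairs that
are *not* observed edges (an observed interaction cannot be a
negative), sorted ascending by p with ties broken by lexicographic pair
order so rankings are reproducible.

## 2. L3 counting and CL3 filtering

For a pair (i, j) the number of simple paths of length 3 (four distinct
nodes) is

    L3(i, j) = (A³)_ij − A_ij (kᵢ + kⱼ − 1),

where A has zero diagonal; the subtraction removes the non-simple
3-walks that revisit i or j, and no other revisit is possible in three
steps. For candidate lists the count is evaluated sparsely — one
(rowᵢA)·A product per distinct left endpoint — so memory stays
proportional to |pairs| + |edges| and the all-pairs A³ is never
materialized. An exhaustive DFS enumerator over i→a→b→j serves as an
independent oracle and is tested against the matrix route on hundreds
of random graphs.

The TPPNI sampler composes: fit SCM → keep the bottom-N non-edges
(default N = 10·|edges|, capped at the candidate count; full-scale runs
would raise this) → count L3 for those pairs → keep the pairs with
L3 = 0, preserving ascending-p order. The output records provenance
(N used, a digest of the source edge set) and is fully deterministic.

## 3. Sequence embedding

Proteins are embedded by mean-pooling the vectors of their overlapping
amino-acid trigrams (windows at 1-based positions 1..L−2). Unknown
trigrams — including any containing nonstandard residues — map to the
out-of-vocabulary (OOV) vector, defined as the element-wise mean of
all table entries. Mean pooling (rather than sum) keeps the embedding
length-invariant; the representation is by construction insensitive to
anything beyond the trigram multiset, which is an acknowledged
information limit. Positional overrides of single window vectors before
pooling implement in-silico ablation.

## 4. The pair decoder

A 3-hidden-layer perceptron (default widths 256/64/16, ReLU, Adam at
1e-3, batch 512, L2 penalty 1e-4) maps the concatenation of two pooled
protein embeddings to an interaction probability. Undirected semantics
are enforced by symmetrization: both concatenation orders are used in
training, and inference averages the two orders, so predict(a,b) ==
predict(b,a) exactly.

Three standard preprocessing/postprocessing stages matter in practice
and are all configurable in `ClassifierSpec`:

- **Standardization.** Pooled embeddings sit on a large compositional
  offset with small variance; features are z-scored with statistics
  fitted on the training pairs only.
- **PCA projection (default 10 components).** Per-protein embeddings
  are projected onto the principal subspace of the *training* proteins.
  Directions the training population never occupies carry no signal but
  are amplified by standardization, where they both invite memorization
  and make single-window ablations jump off the training manifold and
  produce spurious probability dips. Truncating them fixes both.
- **Calibration.** A positive-slope Platt map sigmoid(a·logit + b) is
  fitted on the validation split. It is monotone (rankings and AUROC
  unchanged) and restores dynamic range to overconfident outputs, which
  ablation profiling depends on.

**Inductive split.** Proteins are partitioned into train/val/test
groups (floor(fraction·n) for val and test, remainder to train);
a pair is kept only if both endpoints share a group, so no test protein
ever influences training. Proteins with externally validated labels can
be pinned to the evaluation groups. **Early stopping** monitors the
inductive validation loss with patience 5 (patience 0 stops at the
first non-improving epoch) and restores the best-validation
checkpoint. Cross-validation re-draws the protein split per fold, and
fold results are reported as mean ± std.

Note on regularization: the decoder uses an L2 penalty rather than
dropout; the sklearn MLP backend has no dropout layer, and at the data
sizes involved the L2 path is equally effective and simpler to reason
about.

## 5. Evaluation

AUROC is the tie-corrected Mann–Whitney statistic and AUPRC the
step-wise average precision (both via scikit-learn). PPIHits@TopK /
PPNIHits@BottomK are the fraction of true interactions among the K
highest-scored pairs and of true noninteractions among the K lowest;
at K = n they equal the class prevalences identically. Ranking ties are
broken by canonical pair order, making Hits@K deterministic. The
optimal classification threshold scans (0, 1) in steps of 0.001 (finer
than the cross-fold spread of the optimum) with the "score ≥ threshold"
convention and ties resolved to the smallest threshold. The
L3–prediction association is Spearman's rank correlation with
average-rank ties; a constant input returns 0 with a warning.

## 6. The synthetic fixture

The generator plants a complementarity rule so that every pipeline
stage has checkable ground truth.

**Network.** Each protein carries a 4-bit key and a 4-bit lock. By
default a pair is *compatible* when key·lock ≥ 3 in either direction —
partial key/lock matching; an exact-complement variant
(`rule="exact_complement"`) gives the strict bipartite-like limit.
Compatible pairs become edges with probability `density = 0.3`
(interactome incompleteness: most true interactions are unobserved) and
incompatible pairs with probability `noise = 0.0` (false positives are
not emulated at the defaults). Code values are assigned near-uniformly
(each 4-bit value about equally popular) rather than i.i.d.: with
i.i.d. codes, code popularity drives degree, and degree becomes a
sequence-decodable shortcut that contaminates the embedding-dependence
control. Defaults: 300 proteins, ~1200–1700 edges.

The key/lock structure produces the even-length-cycle signature of
complementarity-driven networks: under degree-preserved rewiring the
exact-complement variant loses most of its 4-cycles (median ratio
~2.7×), the partial-matching default a milder excess (~1.1×, because
its compatibility correlates with degree, which rewiring preserves).

**Sequences (length 120).** Each (role, bit-index) owns one reserved
amino-acid letter and one slot inside a contiguous 22-residue motif
written at a random recorded position; a slot holds its letter when the
bit is 1 and a shared null letter when 0. Slots are separated by two
random spacer residues; all non-motif residues are a balanced multiset
of the 11 non-reserved letters in random order, with fixed 2-residue
terminal pads. These choices are deliberate:

- *Random spacer contexts* make the trigram identity around each bit
  letter protein-specific. Only a compositionally smooth table (where
  trigrams sharing letters are close) transmits the bit through mean
  pooling; an i.i.d.-randomized table sees unrelated vectors and loses
  the signal — this is what makes the embedding-randomization control
  fall to chance, as it does for real models on real data. An unbroken
  motif block would defeat that control in principle, because its
  interior trigrams are deterministic functions of the bits and stay
  informative under any fixed table.
- *Balanced background composition* removes per-protein compositional
  fingerprints whose only possible use is memorization.
- *Fixed terminal pads* keep every informative letter covered by
  exactly three windows for all proteins alike.

**Embedding table.** Complete over all 8000 trigrams,
v(abc) = (e(a)+e(b)+e(c))/√3 + 0.05·ξ_abc with seeded Gaussian letter
vectors e and per-trigram residual ξ. Reserved (motif) letters get
full-scale vectors while background letters are shrunk to 0.1 of that
scale — distinctive binding-site chemistry versus bland scaffold — so
that single-window ablations of background windows are near-neutral
while ablations of bit-letter windows are not.

**What the fixture does not emulate.** Real degree heavy tails, false
positive edges (at the defaults), homologous sequence families,
position-dependent residue usage, and real trigram semantics. Passing
the fixture studies therefore demonstrates that the machinery —
sampling, training, evaluation, ablation — behaves as designed when its
assumptions hold, not that any particular biological accuracy is
attained on real interactomes.

## 7. Study protocols

All studies live in `upna_ppi.experiments` and are what both the test
suite and `scripts/acceptance.py` execute.

- **TPPNI precision** (per seed): precision of the TPPNI set for
  planted incompatible pairs versus a size-matched uniform complement
  sample; training sets for the classifier studies draw negatives
  uniformly from the TPPNI set (the lowest-p prefix would concentrate
  on a handful of lowest-degree proteins).
- **Embedding dependence**: 5 inductive fold re-draws; each fold is
  trained once with the fixture's compositional table and once with a
  freshly drawn i.i.d. U[0,1] table (a fresh draw per fold keeps the
  control from hinging on one unlucky table); statistic = fold-mean
  test AUROC.
- **Robustness**: paired baseline/perturbed runs over 3 seeded
  re-draws; rewiring applies degree-preserved swaps to 25% of the
  train- and val-group positive pairs (within group, so within-group
  degrees are preserved; full rewiring would destroy the label signal
  itself rather than test robustness); scarcity deletes 50% of training
  pairs. Test pairs are never touched.
- **Ablation recovery**: 50 query proteins with at least one observed
  edge; each is profiled against up to 3 of its partners; per-partner
  profiles are pooled as the fold-mean of log-odds (log-opinion
  pooling, insensitive to per-fold saturation), averaged over partners,
  smoothed by a width-3 moving average, and reduced to the position of
  their minimum. A recovery means that minimum falls in a trigram
  window overlapping the planted motif. Multi-partner pooling mirrors
  how a practitioner would corroborate a putative site across binding
  partners.

## 8. Interpretability

`ablation_profile` replaces one trigram window at a time with the OOV
vector on the query side (partner fixed), re-scores with every fold
model, and records per-fold probabilities, their mean/std, and the
unablated baseline. A position whose window vector already equals the
OOV vector reproduces the baseline bit-exactly. `detect_valleys`
formalizes "valleys": smooth the cross-fold mean with a centered moving
average (default width 5), flag maximal runs below
(profile mean − depth·profile std) with depth 1.0, optionally require
cross-fold std below the profile median (consensus, default on), and
report runs as 1-based inclusive residue ranges (window p covers
residues p..p+2). The thresholds are package conventions — valley
detection is intrinsically a judgment call — and all three knobs are
exposed.

## 9. Biophysical and geometric diagnostics

GRAVY is the mean Kyte–Doolittle hydropathy (values taken from
Biopython's table); nonstandard residues are skipped with a warning.
Net charge at pH 7 is a Henderson–Hasselbalch sum over ionizable side
chains with the EMBOSS pKa set (C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1); termini are excluded by default (negligible for whole
proteins) and can be included with the EMBOSS terminal pKas (8.6/3.6).
Pair products of per-protein scores express the
complementarity-versus-mismatch reading: same-sign charges (repulsion)
give positive products.

Hyperbolic utilities operate on externally produced native-disc polar
coordinates: the geodesic distance uses
cosh d = cosh r_p cosh r_q − sinh r_p sinh r_q cos Δθ with Δθ folded to
[0, π] and the acosh argument clamped at 1 for numerical safety; the
pair ("edge") coordinate averages radii arithmetically and angles by
the circular mean (shorter-arc midpoint; exactly antipodal inputs
tie-break to θ_p + π/2). Distances are comparable only within one
embedding run of whatever external embedder produced the coordinates.

## 10. Problem sizes

The shipped defaults (300-protein fixtures, 120-residue sequences,
16-D tables, 5 folds, 50 ablation queries, 100–200 oracle graphs) were
chosen so the whole test suite and the reproduction script each finish
in about a minute on a single CPU while leaving every measured property
far from its decision boundary. All of them scale up through plain
parameters.

## 11. Known limitations

- The word2vec reader handles the text format only (no binary tables).
- `degree_preserved_swap` targets a number of *accepted* swaps with a
  capped number of attempts; on swap-saturated graphs (e.g. complete
  graphs) it returns the original graph with the rejection count rather
  than failing.
- The SCM is the soft (canonical) degree model only; no microcanonical
  stick-together sampling is provided.
- Evidence counts from repeated edge-list rows are combined by maximum,
  which is idempotent under file concatenation but cannot accumulate
  evidence across sources.
- Ablation profiles quantify what the *decoder* relies on; agreement
  with planted motifs on the fixture does not certify binding-site
  accuracy on real proteins.
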