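# Methods

`rbfqsar` builds quantitative structure–activity relationship (QSAR)
regression models from compound × descriptor tables. The archetypal
application is acute aquatic toxicity: a few hundred to a thousand organic
compounds, each described by hundreds of 0–2D molecular descriptors, with a
−log LC50 (mol/L) endpoint spanning roughly 0–9. The pipeline couples a
radial basis function (RBF) network regressor with a quantum-behaved
particle swarm that selects descriptors and network hyperparameters
jointly, averages repeated runs into a consensus model, and delimits the
region of descriptor space in which the consensus is trustworthy.

## The RBF network

The regressor is a single-hidden-layer network of Gaussian units centred on
training compounds,

    ŷ(x) = Σᵢ ωᵢ φ(‖x − cᵢ‖; δ) + b,

trained by greedy orthogonal least squares: at each step the training input
whose inclusion most reduces the residual sum of squares becomes a new
centre, and the output weights (and bias b) are re-solved exactly. Training
stops when the training MSE reaches the goal ε or the neuron cap is hit.
Two parameters therefore govern the bias/variance trade-off: ε (fitting
strength; smaller ε = closer fit, higher over-fit risk) and the shared
spread δ (smoothness of the basis).

Basis convention. The default unit is φ(d) = exp(−(0.8326·d/δ)²), so that
φ(δ) = 0.5 — δ is the *half-width* of the unit, the convention of the
classic neural-network toolboxes this model family was developed with, and
the convention under which the package's default (ε, δ) ranges are
meaningful. A `basis="plain"` switch selects φ(d) = exp(−(d/δ)²) for
users who prefer the textbook form.

Bias term. The textbook network output has no constant term; toolbox
implementations include one. The package fits a bias by default
(`fit_bias=False` restores the bare form). A consequence worth knowing: a
single training point is then reproduced by the bias alone (zero centres) —
the prediction contract is unchanged.

Degenerate inputs (identical rows with conflicting targets) stall the
greedy loop; the model returns the best least-squares fit and emits
`TrainingStallWarning`. The warning is suppressed inside the swarm and the
screening loop, which explore such corners by design.

Cost. Candidate scoring is exact greedy (incremental orthogonalisation),
O(n²) per added centre. This is the reference behaviour and is practical
through a few thousand compounds.

## Data splitting: cluster first, then classify

`som_split` divides compounds into at most 9 structural clusters with a
batch self-organizing map (3×3 hexagonal grid, 300 epochs by default,
z-scored descriptors, neighbourhood radius decaying linearly 3 → 1), then,
within each cluster, sorts by ascending endpoint and sends the **3rd** member
of every complete block of five to the validation set. Incomplete trailing
blocks stay in training. Consequences, asserted as invariants: the
validation fraction is at most 20%; validation endpoints interleave
training endpoints (4 training compounds between consecutive picks); both
endpoint extremes remain in training; every validation compound has
structural neighbours in training. Picking the middle of each block (rather
than an extreme) is a deliberate choice that keeps the endpoint range of
training as wide as possible. Ties in the endpoint are broken by compound
id so the split is deterministic given the SOM seed.

`diversity_diagnostics` emits PCA scores and the min–max-normalised
pairwise distance matrix (train block first) as plot-ready numbers; the
package renders no figures.

## Descriptor screening by permutation importance

The screen estimates each descriptor's importance as the drop in held-out
R² when its column alone is shuffled. One iteration: draw RBF
hyperparameters at random (ε log-uniform on [10⁻³, 10⁻¹] — the range spans
two decades and a log draw weights them equally; δ uniform on [1, 5]),
split the data 90/10, fit on the 90% block, score R₀² on the 10% block,
then for each descriptor i shuffle only column i of the held-out block and
record Ir(i) = R₀² − R₁²(i). The model is never refitted per descriptor.
The grand mean over `n_param_draws × n_repeats` iterations ranks
descriptors; those with mean importance strictly above 0.01 are retained.
An irrelevant descriptor's expected Ir is 0, so the 0.01 threshold on an
R²-difference scale is a weak-signal cut-off, not a significance test.

Full-budget defaults are 100 draws × 50 repeats; the test suite and the
acceptance script use 4 × 5 with a neuron cap of 200, which recovers all
informative descriptors of the reference scenario reliably.

## Joint optimization of descriptors and hyperparameters

Selecting descriptors (discrete) and (ε, δ) (continuous) together is a
mixed search problem. The package encodes a candidate as a real vector of
length 2 + B, B = ⌈p/10⌉: two hyperparameter dimensions clipped to
[10⁻⁴, 5], and one dimension per block of ten descriptors, clipped to
[0, 1023], rounded half-away-from-zero and expanded to ten bits —
bit b (least-significant first) selects descriptor (block−1)·10 + b. The
encoding is bijective on block values (round-trip checked exhaustively).

Fitness balances fit and robustness: with R² the training determination
coefficient and R²cv10 its 10-fold cross-validated counterpart (one fold
partition fixed per run so candidates are comparable),

    fitness = 1 / (R² · R²cv10),   minimised,

with non-positive metrics floored at 10⁻⁴ and an additive penalty of 10⁶
whenever the over-fit constraint 0 < R² − R²cv10 < 0.3 is violated. A
`fitness_form="sum"` hook provides 1/R² + 1/R²cv10 as an alternative.

The shipped optimizer is quantum-behaved particle swarm optimization
(QPSO) with a contraction–expansion coefficient decaying 1.0 → 0.5 and a
Lévy-flight perturbation (Mantegna steps, stability index 1.5) applied with
probability 1/L per particle per iteration and scaled by λ; λ = 1 and
L = 10 by default, population 30, 1000 iterations at full budget.
Out-of-bounds positions are clipped. The optimizer is a plain
bound-constrained minimiser over an objective callable, so any swarm
honouring that contract can be substituted. The best *feasible* candidate
ever evaluated wins and its model is refitted on the selected descriptors.

## Validation metrics

All determination-coefficient metrics share the form 1 − Σ(y−ŷ)²/Σ(y−c)²
and differ only in data and centering constant c:

* R² — training fit, c = ȳ_train;
* R²cv10 — out-of-fold predictions from 10-fold CV (folds dealt
  round-robin after a seeded shuffle), every compound predicted exactly
  once by a model fitted without it;
* R²ext — validation set, c = ȳ_valid;
* Q²ext — validation set, c = ȳ_train.

Since Σ(y−c)² is minimised at c = ȳ_valid, Q²ext ≥ R²ext always, with
equality when the two means coincide. R²adj = 1 − (1−R²)(n−1)/(n−p−1) with
p the number of selected descriptors. Golbraikh–Tropsha external checks:
through-origin slopes k = Σyŷ/Σŷ², k′ = Σyŷ/Σy², through-origin
determination coefficients, acceptance for 0.85 < k, k′ < 1.15 and
(R₀² − R′₀²)/R₀² < 0.1. The Topliss ratio n_train/p guards against chance
correlation (rule of thumb ≥ 5).

Y-randomization refits the network on shuffled endpoints with unchanged
(ε, δ, descriptors). Note a structural property of goal-driven training:
a network permitted enough neurons will meet the same MSE goal on shuffled
labels too, so the training-R² collapse this control looks for is only
observable with a capacity-limited network (neurons ≪ n). The package's
reference demonstration uses 10 neurons at n = 400; the cross-validated
metric collapses (goes negative) regardless of capacity and is the more
robust indicator.

## Consensus modeling

The consensus prediction is the unweighted mean of sub-model predictions,
each sub-model evaluated on its own descriptor subset. Sub-model selection:
methods A/B/C search the subset maximizing consensus R²cv10, R², or
R²·R²cv10 — computed on training data only; the validation set is never
consulted — and method D takes the whole pool, the most stable choice.
Subset search is exhaustive for pools of ≤ 15 models (all non-empty
subsets scored via cached prediction vectors) and falls back to the swarm
above for larger pools. Consensus R²cv10 averages the sub-models'
out-of-fold prediction vectors under one shared fold partition; the
alternative (re-running CV on the averaged model) is not implemented
because sub-models are fitted independently. `stability_sweep` scores
random N-subsets per ensemble size and returns min/quartile/max per metric,
boxplot-ready; spread shrinks as N grows.

## Applicability domain

Leverage AD: h(x) = xᵀ(XᵀX)⁻¹x over the consensus union descriptor set,
warning threshold h* = 3(p+1)/n. The p used in the threshold is
configurable because published thresholds sometimes correspond to one less
than the nominal descriptor count. Singular designs fall back to the
pseudo-inverse with a warning.

Frequency-weighted distance (FWD) AD: each union descriptor j gets weight
f_j = n_j/N — the fraction of sub-models using it — so descriptors the
ensemble actually relies on dominate. Descriptor columns are z-scored with
training statistics (raw scales would otherwise swamp the weighting; this
standardisation is a package decision and changes the distances, so it is
stated prominently and is switchable), multiplied by f_j, and each
compound's distance d_i to the weighted training centroid is computed;
the threshold is mean(d) + 3·sd(d) over training (sd with ddof = 1).
Scaling all f_j by a common constant changes no inside/outside decision.

Outliers are compounds whose residual exceeds 3 training-residual standard
deviations in magnitude. The Williams-plot export carries one row per
compound: leverage, FWD distance, standardized residual, set membership
and inside/outside flags.

## Synthetic reference scenario

The generator emulates the shape of a descriptor/toxicity modeling table:
400 compounds × 40 descriptors (plus 2 constant and 1 all-missing column
appended), of which 5 drive the endpoint; two 4-descriptor blocks with
intra-block correlation 0.7 (one-factor construction); endpoint = a fixed
mixture of saturating (tanh) and quadratic terms of the informative
descriptors, min–max scaled into [0, 9], plus Gaussian noise with standard
deviation one quarter of the noiseless signal's (signal-to-noise ≈ 4).
The quadratic terms are symmetric in centred descriptors and carry no
linear correlation with the endpoint, so a linear model cannot represent
the signal: on the reference scenario an oracle RBF fit on the true
descriptors reaches R²cv10 ≈ 0.82 while 10-fold-CV linear regression stays
near 0.47 — the discriminating gap the test suite leans on.

What the generator does *not* emulate: real descriptor distributions
(heavy tails, integer counts, block-diagonal correlation of descriptor
families), endpoint heteroscedasticity, or activity cliffs. Passing tests
demonstrate that the machinery recovers known structure under controlled
conditions, not that any particular real dataset will yield a valid model.

## Problem sizes and numerical choices

The paper-scale defaults (population 30 × 1000 iterations, 100 × 50
screening budget, 500-neuron cap, 20 models) are the package defaults but
are expensive; the test suite and `scripts/acceptance.py` run the same
code at desk scale: swarm 10 × 100 on 120-compound tables, screening 4 × 5,
5-model pools on a 200-compound scenario. These sizes were chosen once as
the smallest at which the recovery properties are stable across seeds.

Other numerical choices: correlation pruning processes pairs in descending
|r|, drops the member with the smaller |corr(·, y)|, and breaks exact ties
toward the lexicographically later name, making the survivor set
independent of column order; CV folds are dealt round-robin after a seeded
shuffle; all stage seeds derive deterministically from one global seed;
equal seeds give bit-identical artifacts.

## Known limitations

* Exact greedy centre selection is quadratic in n; beyond a few thousand
  compounds a stochastic candidate subsample would be needed.
* The SOM partition is a means to a diverse split, not a clustering claim;
  different topologies give different (equally valid) partitions.
* Consensus R²cv10 is defined via shared-fold out-of-fold averaging; other
  definitions exist and give slightly different numbers.
* The FWD distances depend on the standardisation choice; comparisons
  across models are only meaningful under the same convention.
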