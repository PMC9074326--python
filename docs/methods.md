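# Methods

`rsnet` infers a directed gene regulatory network (GRN) from a gene
expression matrix by combining a Gaussian mutual-information (MI) screen, a
penalised least-absolute-deviation regression solved exactly by linear
programming, and a recursive *redundancy silencing* loop with *network
enhancement* protection for highly dependent regulators. This note records
the model, its assumptions, the numerical choices, and what the bundled
simulator does and does not emulate.

## The model

For every gene in turn as the target `y`, all other genes (or a supplied
transcription-factor list) are candidate regulators.

**1. MI screen.** Dependence between profiles is measured with the Gaussian
MI estimator

    MI(A, B) = 1/2 · ln( |M(A)|·|M(B)| / |M(A,B)| ) = −1/2 · ln(1 − r²),

with `M` covariance matrices and `r` the sample Pearson correlation. MI is
in nats, clamped at 0 below and at `mi_cap` (default 50) for near-collinear
pairs; covariance uses the unbiased (n−1) denominator, which cancels in the
ratio but is fixed for reproducibility. Candidates are split into three
classes by thresholds `theta_low` (default 0.05) and `theta_high` (default
0.2), with half-open intervals `[0, θ_low)`, `[θ_low, θ_high)`,
`[θ_high, ∞)`: **low**-dependence candidates are discarded,
**mid**-dependence candidates enter the regression, **high**-dependence
candidates enter as protected *enhancement* candidates. The defaults are the
thresholds used on the small benchmark networks; the screen operates on the
raw MI scale (not a p-value scale). Constant genes get MI 0 with a warning
so a dead probe cannot abort a run.

**2. Constrained L1 regression.** With candidate matrix `X` (samples × k)
the regulatory strengths β minimise

    (1/n)·‖y − Xβ‖₁ + λ·‖β‖₁ + γ·‖β̂ ∘ β‖₁,

where `∘` is the elementwise product and the enhancement vector `β̂` is 1
for ordinary candidates and 0 for protected ones. Enhancement candidates
therefore pay only the base sparsity penalty λ while all others pay λ+γ — a
differential (adaptive-lasso-like) penalty that gives the highly dependent
regulators priority to stay in the model. A literal positive penalty *on*
the flagged entries would suppress rather than keep them, and a negative γ
can unbound the objective, so the differential reading is the one
implemented. The residual is the **mean** absolute error so that the same λ
has comparable leverage at 5 and at 50 samples (with a raw sum, λ = 0.1 is
numerically inert at n = 50 and nothing is ever silenced). The objective is
piecewise linear and is minimised exactly as a linear program (split
β = β⁺ − β⁻ and the residual into e⁺, e⁻ ≥ 0; HiGHS backend); `‖y − Xβ‖`
is read as the L1 norm precisely because that makes the problem an LP
rather than a QP. λ and γ default to 0.1; no reference values exist for
them, so they are exposed in configuration and logged with every run.

**3. Recursive silencing.** Starting from the mid+high candidates with the
high class protected, each round:

1. solves the LP;
2. silences *weak* connections: candidates with |β| ≤ `silence_threshold`
   (default 0.05 on standardized expression, i.e. a per-standard-deviation
   effect size — a numerical-zero cutoff such as 1e−6 never fires, because
   the LP optimum genuinely keeps ~0.03-magnitude coefficients on
   mediator-collinear candidates);
3. silences *redundant* regulators: if two survivors are more dependent on
   each other than either is on the target (MI(i,j) > max(MI(i,y),
   MI(j,y))), at most one of them can be direct by data-processing-inequality
   logic, and the one with the smaller current |β| is dropped (ties to the
   lexicographically earlier id). This is the mechanism that removes
   indirect regulators, which are near-collinear with their mediator;
4. updates the enhancement protection from the optimization result: a
   protected candidate whose |β| falls below `enhance_fraction` (default
   0.2, mirroring the high-dependence threshold on the max-normalised
   strength scale) of the target's largest |β| is demoted to the full λ+γ
   penalty. Demotion is one-way, so the loop state can only shrink.

The loop stops when neither the surviving set nor the protected set changes
(or at `max_iterations`, default 50, returning the last iterate with a
warning — non-convergence is not treated as failure). Because every
continuation strictly shrinks the state, termination is guaranteed; on
random problems it empirically stays within k+1 solves.

**4. Strength combination.** Final edge strengths blend linear and
nonlinear evidence: for survivor j,

    s_j = α · |β_j|/max|β| + (1 − α) · MI_j/max MI,

max taken within the target's survivor set (all-equal vectors normalise to
1, so a lone survivor scores 1 for any α). α defaults to 0.5 — an
uncommitted 50/50 blend, as no reference value exists. Combination happens
once, after the recursion has stabilised. Output edges are ordered by
strength descending, then regulator id, then target id, making every output
byte-reproducible. β's sign is reported but not interpreted as
activation/repression.

Expression is z-scored per gene before MI and regression (switchable via
`standardize=False`); this makes λ and the silencing threshold comparable
across genes. The per-target loop treats failures as skipped targets with a
logged warning and fails only if every target fails.

## The simulator

`rsnet.simulate` generates gold-standard networks and matched expression so
the whole pipeline is testable offline:

- **Topology.** Genes receive a random topological order; every
  (lower-rank regulator, higher-rank target) pair is an edge independently
  with probability `avg_degree · n_genes / n_candidate_pairs`, so the edge
  count is binomial with mean `avg_degree · n_genes`. Defaults:
  `avg_degree = 2` (the edges-per-gene density of the curated *E. coli*
  benchmark network), acyclic by construction. The inference engine itself
  does not assume acyclicity.
- **Expression.** Linear Gaussian: root genes are standard normal; each
  regulated gene is the weighted sum of its parents' *standardized*
  profiles plus Gaussian noise with sd = `noise_fraction` (default 10%) of
  the noiseless signal sd. Parents are standardized before weighting
  because raw sums let sub-unit weights compound down cascades until a deep
  edge contributes a negligible variance share, defeating the point of the
  0.3 weight-magnitude floor. Weights are uniform on [−1, −0.3] ∪ [0.3, 1].
- **Canonical planted case.** One target with 3 direct regulators, 3
  indirect regulators (each the sole parent of one direct regulator, hence
  acting on the target only through it), and 4 isolated noise regulators.
  This fixture is a designed schematic, not a random draw: all weights have
  magnitude 1 so the three direct effects are equally detectable.
- **Evaluation universe.** Which ordered pairs count as possible edges (all
  pairs vs regulator-restricted) is always an explicit argument, never
  inferred from a prediction.

What the simulator does **not** emulate: kinetic/ODE dynamics, saturation
and combinatorial regulation, cyclic steady states, time series,
measurement-platform noise. Passing the planted-recovery tests therefore
shows that the machinery removes weak/indirect/noise candidates in the
linear-Gaussian regime the model assumes — not that it does so on real
transcriptomes.

## Known statistical limits (measured, not hidden)

- **Mediator collinearity.** With per-gene noise at 10% of signal sd, a
  single-parent gene correlates with its parent at r ≈ 0.995. Substituting
  the indirect parent for the direct one then inflates the residual sd by
  only ~15%, a ~1.5σ margin at n = 50, so *any* fit-based discriminator
  picks the wrong member of the pair in roughly 5–8% of runs. The planted
  fixture has three such pairs; exact recovery of the full direct set
  plateaus near 80–85% of seeds.
- **Direction.** Linear-Gaussian data is Markov-equivalent under edge
  reversal, so reversed edges of true edges score highly; in an
  all-ordered-pairs universe with edges-per-gene 2, even a perfect
  undirected-skeleton oracle caps at ROC AUC ≈ 0.875. Regulator-restricted
  universes mitigate this when a transcription-factor list is available.
- **Small samples.** At the benchmark-matched sample counts (5–25), the MI
  screen is noisy and multi-parent masking hides weak edges; ranking
  quality degrades accordingly. The acceptance script reports the honest
  numbers at scales 10/50/100 (larger scales add runtime, not information,
  for these checks).

## Numerical conventions

- MI: natural log; determinant computed explicitly for the 2×2 case
  (avoids LU round-off that 1/(1−r²) would amplify near collinearity);
  determinant floored at 1e−300.
- Degenerate metrics: PPV = 0 when nothing is predicted positive, MCC = 0
  when a marginal factor of its denominator is 0 — logged, never raised —
  so batch evaluation cannot abort. A gold standard without both classes is
  an error.
- ROC AUC uses the rank/Mann–Whitney form with ties at ½ (identical to the
  trapezoidal area); pairs in the universe missing from the prediction
  score 0. Per-gene AUC excludes (and counts) genes whose slice lacks a
  positive or a negative.
- Parsers reject rather than coerce: duplicate gene ids, non-numeric cells,
  ragged rows, duplicate edge pairs all fail with the offending location;
  self-edges in edge lists are dropped with a warning.
- All randomness flows through explicit integer seeds; fixed seed + fixed
  configuration gives byte-identical outputs end to end.
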