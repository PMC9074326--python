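# rsnet

Gene regulatory network (GRN) inference by **redundancy silencing and
network enhancement** — a method for recovering *direct*
regulator→target interactions from a gene expression matrix while
filtering out the weak, noisy, and indirect associations that plague
dependence-based network inference.

It is aimed at systems-biology practitioners who have a genes × samples
expression table (optionally with a transcription-factor list and a
gold-standard edge list for benchmarking) and want a ranked, directed edge
list plus the standard evaluation battery, with everything — including a
planted-network simulator — runnable offline.

## The method

For each target gene *y* with candidate-regulator matrix *X*:

1. **MI screen.** Gaussian mutual information,
   MI(A,B) = ½·ln(|M(A)|·|M(B)|/|M(A,B)|) = −½·ln(1−r²), splits candidates
   into low (discarded), mid, and high dependence classes at thresholds
   θ_low = 0.05 and θ_high = 0.2 nats.
2. **Constrained L1 regression.** The strengths β minimise

       (1/n)·‖y − Xβ‖₁ + λ‖β‖₁ + γ‖β̂ ∘ β‖₁,

   solved exactly as a linear program. The enhancement vector β̂ is 0 for
   high-dependence candidates and 1 otherwise, so protected candidates pay
   only λ while the rest pay λ+γ — highly dependent regulators get
   priority to stay in the model.
3. **Recursive silencing.** Candidates with |β| below a weak-connection
   threshold are silenced; of any two survivors more dependent on each
   other than on the target (the indirect-regulator signature), the weaker
   is silenced; protection is re-derived from the optimization result; the
   loop repeats until the network structure stops changing.
4. **Strength combination.** Final edge scores blend the evidence:
   s = α·norm(|β|) + (1−α)·norm(MI), α = 0.5 by default.

Evaluation implements TPR, FPR, ACC, PPV, MCC, ROC AUC over an explicit
candidate-pair universe, plus per-target-gene / per-regulator AUC
summaries. See `docs/methods.md` for assumptions, numerical conventions,
and measured statistical limits.

## Worked example

Simulate a 10-gene planted network (edges-per-gene 2, 10% noise), infer,
and score the prediction against the known edges:

```console
$ rsnet simulate --n-genes 10 --n-samples 20 --seed 1
rsnet: wrote expression.tsv (10 genes x 20 samples) and gold.tsv (16 edges)

$ rsnet infer --expr expression.tsv -o edges.tsv
rsnet: wrote 17 edges to edges.tsv

$ head -3 edges.tsv
G01	G05	1.000000
G01	G07	1.000000
G05	G01	1.000000

$ rsnet eval --pred edges.tsv --gold gold.tsv -o report.tsv && cat report.tsv
FPR	TPR	ACC	PPV	MCC	AUC
0.1216	0.5000	0.8111	0.4706	0.3696	0.7002
```

Reading the output: the inferred edge list is ranked by combined strength
(ties broken lexicographically — note G01→G05 and its reversal G05→G01
both score 1.0: direction is genuinely ambiguous for a linear-Gaussian
pair). The report row says the binarised network recovers 50% of the 16
true edges at a 12% false-positive rate over the 90 ordered candidate
pairs (MCC 0.37), and the continuous ranking has ROC AUC 0.70 — typical
for 20 samples of a dense 10-gene network where every true edge's reversal
counts as a negative.

The same pipeline is available as a scikit-learn style estimator:

```python
from rsnet import RSNet
from rsnet.simulate import planted_regulator_case

net, expr = planted_regulator_case()        # 3 direct, 3 indirect, 4 noise
model = RSNet().fit(expr.T)                 # samples x genes
print(model.score_edges().query("target == 'T'")[["regulator", "strength"]])
#   regulator  strength
# 2        D2  1.000000
# 7        D1  0.814823      (only the three direct regulators survive;
# 8        D3  0.720223       the indirect and noise regulators are silenced)
```

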