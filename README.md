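# riccinet

Ollivier–Ricci curvature analysis of weighted gene networks.

Cellular interaction networks can be modeled as weighted graphs whose
functional robustness — the ability to absorb perturbations and return to
a working state — is hard to quantify directly. Network entropy has been
used as a nodal proxy, but it cannot say *which interaction* makes a
network robust. Coarse (Ollivier) Ricci curvature fills that gap: it is
defined per node **pair**, it is positively associated with entropy and
hence with robustness, and it is computable exactly as a small linear
program. `riccinet` is for computational biologists who want to compare
two phenotypes (e.g. tumor vs. adjacent normal tissue) over a fixed
gene–gene interaction topology and rank the interactions whose robustness
changes most.

## The model

A weighted undirected network defines a one-step random walk

```
mu_x(y) = w_xy / d_x,      d_x = sum_{y ~ x} w_xy,
```

and the Ollivier–Ricci curvature of a node pair compares the transport
cost between the two walk neighborhoods with the distance between the
nodes themselves:

```
kappa(x, y) = 1 - W1(mu_x, mu_y) / d(x, y),
```

where `W1` is the earth mover's distance (solved as an exact LP over
couplings) and `d` is the unweighted hop distance. `kappa <= 1` always;
positive values mean overlapping, redundant pathways (robustness),
negative values tree-like fragility. Nodal contractions (the
`mu_x`-weighted mean, the plain sum, the min and the max over the
adjacent neighborhood) make curvature comparable to local network
entropy `-sum_y mu_x(y) log mu_x(y)`.

For a two-phenotype study the topology is fixed from prior interaction
data (SIF pathway files or a stoichiometric reconstruction), each edge is
weighted by `w = (1 + rho)/2` with `rho` the phenotype's Spearman
correlation, and pairs are ranked by `Delta kappa = kappa_tumor -
kappa_normal` with a Fisher-z differential co-expression companion
statistic, distribution-shift summaries (mean and tail differences), and
a paired one-tailed Wilcoxon signed-rank test.

The link between curvature and robustness is made concrete by the
Ornstein–Uhlenbeck process `dx = -alpha x dt + sigma dW`: its time-t
transition laws are equal-variance Gaussians, giving the closed form
`kappa = 1 - exp(-alpha t)` — stronger mean reversion, larger curvature.

## Worked example

```
$ riccinet simulate --n-genes 20 --n-samples 100 --edges 40 --seed 18 \
      --perturb G0000 G0001 0.6 --out fixture
$ riccinet differential --expression fixture/expression.csv \
      --phenotype fixture/phenotype.csv --topology fixture/topology.tsv \
      --top-k 3 --out report
$ head -4 report/delta_curvature.tsv
rank	delta_kappa	diff_coexpression	gene_x	gene_y
1	0.184247	7.213514	G0000	G0001
2	0.079171	1.227781	G0008	G0016
3	0.059200	0.264777	G0003	G0016
```

The fixture plants a +0.6 correlation shift on edge G0000–G0001 in the
"tumor" phenotype only; the pipeline recovers it as the top-ranked
curvature change (`Delta kappa = 0.184`) with by far the largest
differential co-expression (7.21 standard errors). `report/summary.json` holds the
distribution summary (mean and 0.1%–5% tail differences) and the Wilcoxon
p-values; `report/delta_nodal.tsv` the per-gene scalar-curvature and
entropy changes.

The closed-form diffusion demonstration:

```
$ riccinet ou-demo --seed 1 --out ou
alpha = 1: kappa = 0.6321
alpha = 0.1: kappa = 0.0952
```

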