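# rmtnet

Random-matrix level-spacing analysis of gene interaction networks.

Inferred gene interaction networks (e.g. Bayesian-network output with a
per-edge likelihood, the "edge frequency", in [0.2, 1.0]) can be probed
with spectral statistics: form the symmetric 0/1 interaction (adjacency)
matrix *M* (zero diagonal), diagonalize it, and ask whether the
nearest-neighbor spacings *s* of its unfolded eigenvalues follow

* the **Wigner distribution** P(s) = (πs/2)·exp(−πs²/4) — the GOE
  universal law, indicating eigenvalue correlation/repulsion, typical of
  dense, highly connected networks; or
* the **Poisson law of RMT** P(s) = exp(−s) — uncorrelated eigenvalues,
  typical of sparse networks that decompose into weakly coupled modules.

Because *N* is finite, eigenvalues are *unfolded* locally: the sorted
spectrum is trimmed to its central 95% and cut into L segments of n
eigenvalues; within a segment spanning ΔE the local mean spacing is
D̂ = ΔE/n and λ = n(x − x₁)/ΔE. For N ≈ 8000 this gives
L = 76, 38, 25, 19 segments at n = 100, 200, 300, 400. Each segment's
n − 1 spacings are tested against both laws with a one-sample
Kolmogorov–Smirnov test at α = 0.05, and P(s) is the segment-averaged
spacing histogram (bin width 0.2).

The package also subdivides a network into edge-frequency quartiles
M1 (lowest) … M4 (highest) plus ALL, and reports degree-distribution
diagnostics per group: empirical p(k), the random-graph binomial law and
its Poisson limit p(k) = e^(−λ)λ^k/k! with λ = mean(k), and a
least-squares power-law fit p(k) ∝ k^(−γ).

A seeded synthetic-data module generates GOE matrices, uncorrelated
level sequences, Erdős–Rényi and preferential-attachment graphs, and
composite "TCNG-like" gene networks (~8000 nodes, 13k–64k edges, a
scale-free high-frequency backbone over an Erdős–Rényi low-frequency
noise layer), so the whole pipeline runs without any downloads.

## Worked example

```python
import rmtnet

# a dense synthetic gene network: 8000 genes, 51,702 edges
net = rmtnet.generate_tcng_like(8000, 51702, density="dense", seed=3)
mat = rmtnet.build_interaction_matrix(net)
spec = rmtnet.eigenvalues(mat)
segments, plan = rmtnet.trim_and_segment(spec, n=200, coverage=0.95)
_, wig = rmtnet.classify_segments(segments, rmtnet.WIGNER, alpha=0.05)
_, poi = rmtnet.classify_segments(segments, rmtnet.POISSON, alpha=0.05)
print(plan.L, wig.n_passing, poi.n_passing)
```

prints

```
38 38 0
```

i.e. the trimmed spectrum yields 38 segments of 200 eigenvalues, and in
all 38 the KS test accepts the Wigner distribution (p > 0.05) while the
exponential law is rejected everywhere — the dense network's spectrum is
GOE-correlated. A sparse network's high-frequency quartile instead shows
the exponential law (run the same on
`generate_tcng_like(8000, 32124, "sparse", seed=4)` group M4).

The same analysis is available from the shell:

```sh
rmtnet generate --n-nodes 8000 --n-edges 32124 --density sparse \
    --seed 4 -o net.tsv
rmtnet analyze -i net.tsv --groups ALL -o results/
rmtnet report results/report.json
```

`analyze` writes per-segment KS tables, the averaged P(s), a Table-1
style degree summary, and a JSON report classifying each group as
wigner-consistent, poisson-consistent, or neither.

## Acceptance script

`scripts/acceptance.py` recomputes the package's acceptance-target
quantity at run time — the β = 1 (GOE) spacing density evaluated at
s = 0, the level-repulsion boundary value of the Wigner law — and writes
it as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
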