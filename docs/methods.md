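# Methods

## Model and procedure

The object of analysis is the interaction matrix of an undirected gene
network: M_ij = 1 if genes i and j interact, 0 otherwise, with M_ii = 0
and M symmetric. Edge directions from the upstream inference are
discarded; antiparallel duplicates collapse to one undirected edge
keeping the **maximum** of the two edge frequencies (the merge rule is
an open choice upstream — max preserves the strongest evidence; mean or
sum would change only the quartile assignment of merged edges, not the
spectrum). Self-loops are dropped. Nodes are ordered lexicographically
so matrices are deterministic.

The full pipeline is: read/generate the edge list → subdivide into
edge-frequency quartiles M1..M4 (+ ALL) → diagonalize each requested
group's matrix → trim and segment the spectrum → unfold per segment →
KS-test each segment's spacings against the Wigner and exponential laws
→ report pass counts, averaged P(s), and degree diagnostics.

### Spacing laws

The β-family surmise P(s) = a_β s^β exp(−b_β s²) with

    a_β = 2Γ((2+β)/2)^(β+1) / Γ((1+β)/2)^(β+2),
    b_β = (Γ((2+β)/2) / Γ((1+β)/2))²

is implemented for β ∈ {1, 2, 4}; β = 1 reduces to the Wigner
distribution (a₁ = π/2, b₁ = π/4). The uncorrelated-spectrum law is
exp(−s). Both are unit-norm and unit-mean, matching unfolded spacings.
CDFs are closed-form via the regularized lower incomplete gamma
function. Only β = 1 and the exponential are used by the pipeline; GUE
and GSE densities are provided for completeness.

### Unfolding and segmentation

The sorted spectrum is trimmed to ⌊coverage·N⌋ eigenvalues
(coverage = 0.95 by default). The tail loss is split **symmetrically**,
the lower tail taking the ceiling half — the protocol states only that
95% is covered and tails are eliminated, so the apportioning is this
package's choice. The kept run is cut into L = ⌊kept/n⌋ contiguous
segments of exactly n eigenvalues; the kept mod n leftovers are
discarded evenly from the two ends of the kept run (extra one from the
upper end), keeping segments centered on the retained bulk. Within a
segment, λ_i = n(x_i − x₁)/ΔE, so unfolding is exactly invariant under
affine maps of the spectrum and each segment's n − 1 spacings have mean
n/(n − 1) identically.

Degenerate eigenvalues are **kept**: exact multiplicities (common in
sparse adjacency matrices — isolated dyads, duplicate rows) produce zero
spacings that flow into P(s). A segment whose n eigenvalues are all
identical (ΔE = 0) carries no spacing information; it is flagged
degenerate and excluded from both histogram averaging and testing, with
a logged count.

### Hypothesis testing

Each non-degenerate segment's spacings are tested with the one-sample
two-sided Kolmogorov–Smirnov test against the fully specified law (no
fitted parameters). The p-value is exact for samples of at most 500
points and uses the asymptotic Kolmogorov series beyond — the crossover
is this package's choice; at the protocol's segment sizes (n ≤ 400, so
m = n − 1 ≤ 399) the exact branch is always taken. Segments with fewer
than 5 spacings are skipped. A group is labelled wigner-consistent or
poisson-consistent when that law's pass fraction (p > α over all tested
segments) exceeds a threshold (default 0.5) and the other law's
fraction; otherwise "neither" — a real outcome for very sparse networks.

P(s) is the **pointwise mean of per-segment normalized histograms**
(bin width 0.2, left-closed bins from 0), not a pooled histogram; the
two differ only when segments are excluded, and segment averaging
matches the stated protocol.

### Degree diagnostics

Degrees are matrix row sums. The random-graph reference is the binomial
law C(n−1, k) q^k (1−q)^(n−1−k); its n → ∞, nq → λ limit is the Poisson
law, fitted by method of moments (λ = mean k). Distance is total
variation over k = 0..max k plus the reference law's tail mass. The
power-law exponent γ is fitted by least squares on log p(k) vs log k
over k ≥ 1 (maximum-likelihood tail fitting is out of scope), normalized
over 1..max k.

## Synthetic data: what it emulates and what it does not

`generate_tcng_like` emulates the published scale of inferred
cancer-cell gene networks: ~8000 nodes, 13k–64k edges, per-edge
frequencies in [0.2, 1.0]. It overlays a preferential-attachment
backbone (m = 1 attachment, giving quartile mean degrees near 2, the
band reported for real subnetworks) carrying frequencies uniform on
[0.5, 1.0] on an Erdős–Rényi noise layer with frequencies uniform on
[0.2, 0.5). The backbone holds 25% of edges in "sparse" mode — its top
frequency quartile is then essentially the scale-free backbone — and 5%
in "dense" mode, where every quartile is an Erdős–Rényi-like hairball.
The resulting quartile frequency boundaries (~0.28/0.35/0.50) roughly
reproduce those reported for a real sparse network (0.25/0.30/0.53).
Collisions between layers are topped up so the requested edge count is
met exactly.

What the generator does **not** emulate: Bayesian-inference noise
structure, correlated false positives, gene-identifier redundancy, or
the empirical frequency histogram of any real network. A green
endpoint test therefore establishes that the pipeline recovers the two
theoretical spacing laws (GOE → Wigner, uncorrelated levels →
exponential) and that the dense/sparse phenomenology is reproduced on
this stated world — not that any particular real network would classify
the same way.

GOE matrices use (A + Aᵀ)/√2 with A iid standard normal (off-diagonal
variance 1, diagonal 2); the scaling convention is irrelevant after
unfolding and a test asserts this. Uncorrelated spectra are sorted iid
uniforms on [0, 1].

## Numerical choices

- Full dense symmetric eigendecomposition (`scipy.linalg.eigvalsh`);
  N ≈ 8000 takes ~1 minute on one CPU. No partial/Lanczos spectra.
- Quartile split ties are broken by the lexicographic node pair, making
  the partition deterministic when frequencies tie at a boundary.
- Remainders: edge count mod 4 gives one extra edge to each of the
  first (lowest-frequency) groups; kept mod n handled as above.
- Symmetry check on input matrices at tolerance 1e-12; spectrum trace of
  an interaction matrix is ~0 within 1e-8·N.
- All generators are deterministic given (parameters, seed); pipeline
  runs with the same config and seed produce identical reports up to
  recorded wall-clock provenance.

## Defaults

| parameter | default | meaning |
|---|---|---|
| segment sizes n | 100, 200, 300, 400 | eigenvalues per segment (protocol) |
| coverage | 0.95 | central spectrum fraction retained |
| α | 0.05 | KS significance level |
| bin width | 0.2 | P(s) histogram resolution |
| groups | ALL | groups to diagonalize (quartile degree summaries always computed) |
| classify threshold | 0.5 | pass fraction needed for a law label |

Only ALL is diagonalized by default because each group costs a full
eigendecomposition; quartile spectral analysis is opt-in
(`--groups M4,ALL`).

## Known limitations

- Directed networks (GUE statistics) and higher-order eigenvalue
  correlations (number variance, spectral rigidity) are out of scope.
- Whether a sparse adjacency ensemble at mean degree ≈ 2 yields exactly
  exponential spacings (vs intermediate statistics with localization
  effects) is not settled theory; the strict endpoint tests use GOE and
  uniform-level ensembles, and TCNG-like expectations are qualitative.
- The power-law fit is a log-log least-squares slope, adequate for
  diagnostics but not a rigorous tail estimator.
- No quantitative criterion separates "random-graph" from "scale-free"
  subnetworks; the package reports distances and fits and leaves the
  call to the user.
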