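# Methods

This note records the models implemented in `msabias`, the default
parameter values, the numerical choices, and the limitations.  Everything
here is the package's own specification of its simulation study; the
defaults were chosen once, up front, and the statistical tests in
`tests/test_acceptance.py` are run against them as-is.

## Substitution models

Time-reversible models are parameterized by symmetric exchangeabilities
`r_xy` and stationary frequencies `π`:

```
Q_xy = r_xy · π_y   (x ≠ y),   Q_xx = −Σ_{y≠x} Q_xy,
```

rescaled so the expected substitution rate at stationarity,
`−Σ_x π_x Q_xx`, is one; branch lengths are then expected substitutions per
site.

* **Nucleotides** — GTR with the study parameterization
  `(r_AC, r_AG, r_AT, r_CG, r_CT, r_GT) = (0.30, 1.0, 0.20, 0.25, 1.39, 0.22)`
  (the `r_AG = 1` convention) and `π = (0.25, 0.26, 0.27, 0.22)`, values in
  the range typical of mammalian nuclear genes.
* **Amino acids** — the published WAG exchangeability matrix with its
  published frequencies (`data/wag.dat`, PAML layout and state order
  `ARNDCQEGHILKMFPSTWYV`); observed-frequency (+F) variants are available
  via `SubstitutionModel.with_frequencies`.

Transition matrices use the symmetric eigendecomposition of
`B = Π^{1/2} Q Π^{−1/2}` (real spectrum for reversible `Q`), so
`P(t) = Π^{−1/2} V e^{Λt} V^T Π^{1/2}`; rows are clipped to `[0, 1]` and
renormalized to absorb rounding at extreme branch lengths.

## Among-site rate variation

Discrete-Γ with equal-probability categories; category rates are the exact
conditional means of a mean-one Γ(α, α) over its quantile intervals,
computed in closed form from the incomplete-gamma identity
`∫ x f_α = F_{α+1}(b) − F_{α+1}(a)` (no numerical quadrature).  Default
shape α = 1.8 with 4 categories.  A site keeps its category for all time
(rates are inherited through indels for surviving sites; inserted sites
draw a fresh category).

## Sequence simulation with indels

Along each branch the simulator runs a Gillespie walk over insertion and
deletion events; between events, substitutions are applied *exactly* via
the matrix exponential for the elapsed time (no time discretization
error).  Defaults:

* insertion rate = deletion rate = `0.05 × L` relative to the substitution
  rate, where `L` is the current sequence length;
* indel lengths are truncated-Zipf with shape 1.7, maximum 20 residues
  (amino acids) or 60 nt (the nucleotide equivalent of 20 codons);
* insertions choose a uniform position (including the ends); deletions a
  uniform start, truncated at the sequence end;
* the root sequence is drawn from the stationary distribution
  (default root length 408 aa / 1,224 nt).

Every site carries a persistent homology id; a global doubly-linked column
order threads inserted columns between their neighbors, so the simulator
can emit the exact *true alignment* (columns restricted to those present in
at least one leaf).  This is the ground truth for all error metrics.

The generator emulates a neutral indel + substitution process on a fixed
tree.  It does **not** model selection, rate variation of the indel process
itself, context-dependent substitution, or alignment-column
autocorrelation beyond what indel blocks induce.

## The builtin aligner

A deliberately transparent progressive aligner, used as the
"alignment-uncertainty" arm:

* pairwise distances: shared k-mer multiset counts,
  `d = 1 − common/(min len − k + 1)`, with k = 6 (nt) / 3 (aa);
* guide tree: neighbor joining (scikit-bio) by default, or UPGMA;
* profile–profile merges leaf-to-root with affine-gap Gotoh DP
  (numba kernel), "once a gap, always a gap";
* scores: integer log-odds `round(10 · log(P_xy(1)/π_y))` from the same
  substitution model family at reference distance 1.0; gap open −11,
  extend −1.

It is not a replica of any published tool; its purpose is to produce
realistic, reproducible alignment errors whose downstream effects can be
studied without external binaries.  An adapter (`external_align`) can run
command-line aligners when available.

## Alignment error metrics

An alignment is decomposed into pairwise homology statements: aligned
residue pairs, and gap events labeled by the last preceding residue of the
gapped sequence (making the label invariant to padding columns).  The
symmetric difference over the union of two alignments' statement sets gives
a distance in [0, 1] that is zero iff the alignments assert identical
homologies — a pseudo-metric over alignments of the same sequences.
Aligned-pair statements alone give the sum-of-pairs SPFN/SPFP rates against
the true alignment.

## Likelihood machinery

Felsenstein pruning over unique site patterns with gaps treated as missing
data (partial likelihood of all ones).  Degree-two roots are collapsed
first, since only the sum of the two root edges is identifiable under a
reversible model.  Labeled internal nodes (taxa that sit at internal nodes
after unrooting two-taxon trees) are supported via indicator
multiplication.

Branch lengths are optimized **jointly by L-BFGS-B with analytic
gradients**, computed from inside/outside partial vectors
(`∂ℓ/∂t_e = Σ_sites w · Fᵀ Q (P U) / L_site` per rate category), rather
than one-dimensional per-branch sweeps: at the study's largest problem
sizes (10^5 sites) the joint quasi-Newton approach converges roughly an
order of magnitude faster while optimizing the same objective.  The Γ
shape and the five free GTR exchangeabilities (log-parameterized, `r_AG`
fixed at 1) can be estimated jointly; their gradient components use central
differences (h = 10⁻⁴) with per-iterate caching.  Bounds: branch lengths
`[10⁻⁹, 20]`, shape `[0.02, 100]`, exchangeabilities `[10⁻⁴, 10⁴]`.

No likelihood rescaling is applied during pruning: with ≤ 32 taxa and
double precision the smallest site likelihoods are bounded far above the
underflow threshold (a site's partial product shrinks by at most ~10⁻⁸ per
edge, giving ~10⁻²⁵⁰ in the worst case over ~31 edges, within the 10⁻³⁰⁸
range); a hard floor of 10⁻³⁰⁰ guards degenerate cases.  This keeps the
inner loops pure BLAS.  The experiment designs here never exceed 512 taxa
for simulation and 8 taxa for fitting.

Topology selection fits every candidate and splits the win equally among
candidates within `1e-2` log-likelihood units of the maximum (ties are
counted fractionally).  Parsimony uses Fitch counting on bitmasks with gaps
as missing; multifurcating roots are binarized with zero-length edges
(score-invariant).

## SH test (RELL)

For candidates `k` with per-site log-likelihood vectors at their ML branch
lengths: `δ_k = lnL_max − lnL_k`; `B = 1,000` bootstrap index resamples of
sites; per-candidate centering of the resampled totals; the null
distribution of `max − centered` gives
`p_k = #(null δ ≥ δ_k)/B` (≥, conservative).  The ML tree always has
`p = 1`.  Default α = 0.05.

## Study designs

* **Balanced (divergence)** — 8 taxa, 13 equal branches, total tree length
  0.5–6; the root splits the central branch.  Branch classes: external (8),
  middle (4), root (2).
* **Polytomy** — a degree-4 root joining two short (0.06) and two long
  (0.7) cherries; all branches within a subtree share its length.  The
  three resolutions insert a zero-length internal branch; the one pairing
  the two long subtrees is the LBA candidate.
* **Felsenstein grids** — four subtrees (two shallow depth α, two deep
  depth β) around an internal branch (default α), arranged in the three
  possible pairings; grids α ∈ {0.025…0.25}, β ∈ {0.25…1.375}.
* **Supertree embedding** — the 8-taxon balanced core embedded exactly
  (path lengths preserved) in 64/512-leaf supertrees by splitting core
  branches at uniform positions; pendant edges uniform(0.05, 0.5·branch).

Default replicate count 200; per-replicate seeds derive from the master
seed via `SeedSequence(master, spawn_key=...)` reduced mod 2³¹, so arms are
paired and every run is reproducible.  Failed replicates are logged and
counted, never silently dropped.

## Problem sizes and defaults

The desk-scale checks use: 50 replicates at 1,224 nt for tree-length
calibration; 100 replicates at 408 aa for polytomy neutrality and SH
conservatism; single 10⁵-site (nt) and 5·10⁴-site (aa) no-indel
simulations for parameter recovery.  These sizes put Monte-Carlo error
comfortably inside the stated tolerances (3–7%) while keeping a full run
around ten minutes on one CPU.  In the 5·10⁴-site amino-acid fit the Γ
shape is fixed at its generating value and only branch lengths are
estimated (a WAG+Γ fit), which matches the quantity being checked and
halves the runtime.

## Limitations

* The builtin aligner is intentionally simple; absolute alignment-error
  levels are not comparable to modern consistency- or phylogeny-aware
  aligners, only the *direction* of downstream effects is meaningful.
* Likelihood fitting assumes the candidate topology set is given; there is
  no tree search.
* No codon models, no +I class, no partitioned models.
* The indel process is homogeneous across the tree and across sites.
* Heat-map rendering of the grid experiments is left to the caller
  (the drivers emit tidy TSV tables; the package has no plotting
  dependency).
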