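# Methods

## Shape abstraction

A structure snapshot becomes an ordered set of k landmarks, one per
residue, at the unweighted mean of the residue's heavy side-chain atoms
plus the Cα; backbone N, C, O and OXT are excluded, and the glycine
landmark is exactly the Cα.  By default *every* non-hydrogen side-chain
atom contributes, including sulfur and selenium: excluding S would
silently displace Cys and Met centroids by an arbitrary amount.  A
`strict_con` option restricts side chains to C/N/O for users who want
the narrower convention.  Alternate locations are resolved by highest
occupancy; insertion codes are part of the residue identity; waters,
hetero groups and hydrogens are discarded.  A residue that lacks a Cα
in any model is dropped from every model of that ensemble (with a
warning) so all snapshots of one homolog share an identical landmark
set.

Homology across structures is *not* inferred here: a tab-separated
homology map (typically derived from a multiple structure alignment
such as MATT) is authoritative, and only fully homologous columns —
sites present in every structure — enter the phenotype matrix.  Columns
are 0-based internally and 1-based in every output.

## Superposition

Pairwise superposition is the closed-form Kabsch solution (SVD of the
cross-covariance with a determinant correction); reflections are never
allowed, because protein chirality is physical.  Generalized Procrustes
Superimposition iterates align-to-consensus until the summed squared
distance to the consensus changes by less than 1e-10 Å² (at most 100
iterations; non-convergence is a warning, not an error).  The protocol
is two-stage, mirroring how ensemble data arrive: GPS within each
ensemble first, then GPS over the pooled set of all pre-aligned shapes.

Scaling is **off by default**: coordinates are in Å, absolute size is
physically meaningful, and the energetic fitness proxy is
size-dependent.  Full similarity-mode GPA (with the total sum of
squares held fixed so the consensus cannot collapse) is available for
strict shape analysis.  Turning scaling on changes the absolute
magnitudes of gradients but not angles.

## Covariance decomposition

With group labels s = 1..S over n snapshots, W is the pooled
within-group covariance: deviations from each group's own mean,
cross-products summed over all observations, divided by n − S.  V_P is
the ordinary sample covariance (divisor n − 1), and B = V_P − W,
symmetrized to kill round-off asymmetry.  The decomposition is additive
by construction.  B is *not* projected to the nearest PSD matrix by
default — the raw difference is the estimator — but an eigenvalue-
clipping repair (`nearest_psd`) is provided.  The estimator cannot
separate an independent error term from the within-group signal: W
absorbs within-group error, B absorbs its between-group residue.  All
computation is double precision with means subtracted before
cross-products.  Group mean-centering happens after the global GPS, not
before; the implemented order is GPS first, then covariance.

## Selection machinery

The breeder's-equation algebra works on whichever matrix is supplied —
B as the genetic proxy G, W as the dynamic matrix M, or V_P for the
directional gradient — with no separate code paths.  Because G has rank
at most S − 1 ≪ l, β_λ = G⁺Δz̄ uses the Moore–Penrose pseudo-inverse
with singular values below `1e-10 × l` (relative to the largest)
treated as zero; components of Δz̄ outside the retained range are
annihilated.  An optional ridge solve (G + εI)β = Δz̄ with user-chosen ε
is offered as the alternative regularization.

Angles are reported in degrees and computed with the atan2 form
(2·atan2(‖û−v̂‖, ‖û+v̂‖)), which is exact near 0° and 180° where the
arccos of a cosine loses half its digits.  The subspace angle measures
v against its projection onto the span of the leading eigenvectors of
the matrix whose cumulative (positive-spectrum) eigenvalue share first
reaches the requested fraction (default 0.99); both the response and
the gradient versions are exposed, since either can be the quantity of
interest.

Per-residue maps sum |β| over each residue's three components and
min-max scale to [0, 1]; a uniform vector maps to all zeros by
convention.  The ranking tables implement two complementary rules:
residues with at least one positive gradient component ranked by
descending Σ|β| ("directional"), and residues with at least one
negative component ranked by ascending Σβ ("purifying").  Residue
numbers in tables come from the homology map's author numbering of a
chosen reference structure (the source structure by default).

## Fitness

The default proxy is stability: per-residue unfolding energy
ΔĜ° = ΔG°/r (kcal/mol/residue), with r the residue count, so proteins
of different size are comparable.  The loader never flips signs; an
explicit `negate_energy` flag covers energy conventions where smaller
totals mean more stable.  Where kcat and KM toward one common substrate
are available, F = ΔG°·kcat/KM combines stability with catalytic
efficiency; the loader enforces a single substrate per analysis.  The
framework is otherwise fitness-agnostic — any per-model scalar column
works, and target/source snapshots may be chosen as the fitness
extremes or named explicitly (there is no requirement to use the
extremes).  The fitness surface view pairs the first two principal
components of the shapes with fitness as the vertical axis; eigenvector
signs are fixed by making the largest-magnitude loading positive.

## Random skewers

n random selection vectors are drawn uniformly on the unit sphere
(normalized Gaussians); ρ is the mean cosine similarity of the paired
responses Av and Bv.  The default correlation is the cosine of the
*uncentered* responses (the response-direction question); Pearson after
centering is available.  The p-value is the fraction of a null
distribution — cosines between pairs of independent random unit vectors
of the same dimension, with the same draw count — that exceeds ρ.
Skewer count defaults to 1000.

## The synthetic-data generator

The generator emulates the layout of an ensemble study: S taxon mean
shapes drawn from N(0, B); R replicate snapshots per taxon from
N(mean, W); iid isotropic noise N(0, σ²ₑI) on top, standing in for
measurement/registration error that no estimator of this design can
separate.  Default study scale is S = 100 taxa and R = 500 replicates.
Default B and W are independent random PSD matrices QΛQᵀ with
log-uniform eigenvalues spanning two decades and random orthogonal Q —
anisotropic enough that skewer correlations are informative (a flat
spectrum makes every comparison trivially 1).  σ²ₑ defaults to 5% of
the mean within-matrix eigenvalue: a modest error term.  An optional
mode draws taxon means by Brownian motion along a user-supplied Newick
tree (shared-path-length covariance); the default generator uses no
phylogeny, matching the estimator, which never uses one either.

Two notions of "truth" are recorded, and they are deliberately
distinct.  The *population* parameters are the MVN covariances above.
The *realized* generating matrices are the sample covariance of the
taxon means actually drawn and the pooled covariance of the replicate
deviations actually drawn (before error) — exactly known in a
simulation.  The feasibility benchmark scores the estimator against the
realized matrices, because that isolates what the estimator is
responsible for (splitting V_P into its components) from Wishart
sampling noise of the finite taxon draw, which is a property of the
draw, not of the estimator: with 100 taxa and ≥ 256 traits no estimator
can track the population parameter direction-for-direction, and a
benchmark against it would measure sample size rather than method.
Convergence toward the population parameters is tested separately (the
within matrix to < 5% relative Frobenius error at ≥ 10⁴ within-group
degrees of freedom; the between matrix's skewer correlation rising with
taxon count).

What the generator does *not* emulate: GPA-induced correlations from
removing rigid-body freedom, non-Gaussian conformational jumps,
autocorrelation between consecutive MD frames, and landmark-level
geometry (traits are abstract coordinates).  Passing benchmarks
therefore demonstrate the estimator's statistical behaviour on grouped
Gaussian data of matched size, not the fidelity of any MD force field.

## Numerical choices and degenerate inputs

Ties in ambassador selection (the snapshot closest to the ensemble
mean) and in fitness extremes break toward the lowest model id /
lexicographically smallest key, making every pipeline bit-reproducible.
Degenerate landmark configurations (k < 3 or collinear) are rejected
before superposition.  Zero vectors make angles undefined and raise.
An all-zero covariance matrix cannot be inverted and raises.  Benchmark
sub-runs derive child seeds from a single seed via NumPy's seed
sequences, so one integer reproduces the entire table.

## Problem sizes

The feasibility benchmark runs 8–1024 traits at the full 100 × 500
study scale; the largest cell (1024 traits, 50 000 snapshots) completes
in about a minute on one CPU core within ~2 GB.  Unit and property
tests use reduced sizes (tens of taxa, tens of replicates) chosen to
keep the statistical assertions sharp while the whole suite stays fast.

## Known limitations

- B inherits both between-group error and, at low replicate counts, a
  W/R inflation from group-mean estimation; neither is subtracted.
- The pooled-within proxy has no explicit phylogeny; B conflates
  divergence with phylogenetic structure.
- Realized responses taken from single snapshots (rather than ensemble
  means) carry that snapshot's dynamic noise into Δz̄.
- Gradient magnitudes depend on the GPS scaling convention; angles do
  not.
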