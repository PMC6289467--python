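# Methods

## Model

Both elastic models in this package are Gaussian network models: an
isotropic, single-parameter harmonic description of residue fluctuations
in which all spatial detail is reduced to a contact topology.  For a
network with Kirchhoff (graph Laplacian) matrix Γ, the mean-square
fluctuation of residue *i* is the *i*-th diagonal element of the
Moore–Penrose pseudo-inverse of Γ, and B-factors are 8π²/3 times that.
The model assumes fluctuations are Gaussian, isotropic and fully
determined by contact topology — no side chains, no anisotropy, no
solvent.

**Structure-based reference.** Γ_ij = −1 when Cα atoms *i* and *j* are
within a cutoff (default 10 Å, a conventional choice for Cα-level GNMs),
0 otherwise, diagonal = minus the row sum.  Cross-chain pairs count, so
feeding a multi-chain trace models an oligomeric biological unit.

**Sequence-based model.** The Kirchhoff splits into two parts:

* *Chain term* (Rouse chain): unit springs between residues i and i±1…3
  within each chain.  This encodes backbone connectivity, which is known
  from the sequence itself.
* *Non-bonded term*: for each residue pair whose evolutionary-coupling
  percentile rank exceeds the threshold τ, a spring of strength equal to
  that rank.  Using the rank rather than the raw score (a) normalizes
  across inference pipelines and protein lengths and (b) lets contact
  strength attenuate smoothly with coupling confidence.  There is no
  global force constant; fluctuation magnitudes are therefore in
  arbitrary units and all comparisons are made with Pearson correlation
  or within-protein percentile ranks, where any constant cancels.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| τ (rank threshold) | 0.98 | keep the top 2 % of scored pairs; lower values admit noisy contacts, higher values starve the network.  The `sweep` command scans 0.92–0.99. |
| min_separation | 4 | non-bonded contacts require \|i−j\| ≥ 4 so they never duplicate the i±1…3 chain term (prevents double-counting; configurable). |
| rank_universe | `file` | ranks are computed over the pairs present in the score file.  `all_pairs` instead ranks over all N(N−1)/2 pairs with missing pairs below every present one — useful when servers truncate their lists very differently. |
| cutoff | 10 Å | structure-model contact distance (Cα–Cα). |
| zero-mode rtol | 1e-8 | eigenvalues with \|λ\| ≤ rtol·λ_max are treated as rigid-body modes; robust in double precision for chains up to several hundred residues. |

Percentile ranks use the maximum-tie convention, rank(s) = #(scores ≤ s)/n,
so tied scores are kept or dropped by a threshold together and the top
rank is exactly 1.

## Degenerate inputs and numerical choices

* The pseudo-inverse is computed by symmetric eigendecomposition; the
  number of numerically zero modes must equal the number of connected
  components of the contact graph, otherwise a degeneracy error is raised
  rather than returning a corrupted profile.
* A coupling table that is empty (or empties under τ) degrades to the
  pure chain model with a warning — the chain term keeps each chain
  connected, so the computation stays well-posed.
* Multi-chain inputs without inter-chain contacts produce one zero mode
  per chain; fluctuations are then per-component pseudo-inverses and a
  warning is emitted.
* PDB alternate locations: the first-listed Cα wins (deterministic).
  Residue identity is (chain, residue number, insertion code); profile
  indices are 1-based file-order positions, and `ProteinChain.mapping_table`
  translates author numbering so variant positions can be placed on a
  profile.  How external coupling-table numbering is reconciled with PDB
  author numbering is this package's own mechanism, exposed explicitly
  rather than assumed.
* Profile TSVs are written with 17 significant digits, so write/read
  round trips are exact and identical configurations give byte-identical
  outputs.

## Variant analysis

Variant sites are placed on percentile profiles and binned into five
bins of width 0.2 ([lo, hi), the last closed at 1.0 so the top-ranked
residue lands in the top bin).  Expected counts come from the pooled
background of all residue percentiles across all proteins; the
observed/expected ratio per bin is the enrichment.  Two null tests are
reported, because a bin-level departure statistic does not dictate a
unique test: a chi-square goodness-of-fit over the populated bins (4 df
when all five are populated) and a seeded permutation test that draws
10,000 variant-sized multinomial samples from the background bin
distribution.  On well-populated fixtures the two agree in order of
magnitude; the permutation p is floored at 1/(1+draws).  Bins with zero
expectation get an undefined ratio and are excluded from the chi-square.

The classifier is a plain logistic regression (intercept + features; the
only regularization is a tiny ridge for conditioning, C = 1e6) evaluated
over repeated stratified 80/20 train/test splits — stratification rules
out degenerate single-class splits at small n; split seeds are recorded
in the report so any evaluation reproduces exactly.  Metrics: per-split
ROC AUC (mean and max), and accuracy, sensitivity (disease true-positive
rate) and selectivity (neutral true-negative rate) at the 0.5 probability
threshold.  "Selectivity" here is specificity; the term is kept because
it is the one used in this analysis tradition.

## Synthetic data: what it emulates, and what it does not

The generator provides every input with known ground truth:

* **Chains.**  `helix` uses ideal α-helix geometry (rise 1.5 Å, radius
  2.3 Å, 100°/residue), chosen because its 10 Å contact pattern
  (i, i±4…6) is analytic and testable.  `compact_walk` grows a seeded
  self-avoiding walk on a 3.8 Å cubic lattice biased toward its own
  centroid, giving globule-like traces with genuine long-range contacts
  (trapped walks restart deterministically from the seed stream).  The
  experimental-B column is the chain's own structure-model B-factors plus
  seeded Gaussian noise (default σ = 0.1 of their spread).
* **Couplings.**  All true long-range contacts score ~N(1, σ); to set the
  top-tier precision to p_true, T·(1−p_true)/p_true false pairs are
  promoted into the same tier, and decoy pairs (default twice the top
  tier, capped by availability) score ~N(0, σ).  σ = 0 gives an exact
  indicator table whose top tier is one rank-1 tie.  This emulates the
  key failure mode of real coupling inference — a contaminated top of the
  ranking — but not its spatial error structure (real false positives
  cluster near true contacts and along secondary-structure patterns).
* **Variants.**  Disease positions sampled ∝ (1 − percentile)^γ, neutral
  ∝ percentile^γ; γ = 0 is the uniform null, γ = 2 the default biased
  condition with 400 variants per class on a 100-residue chain.

Passing tests on these fixtures therefore demonstrates that the
machinery is correct — thresholding, matrix construction, inversion,
binning, testing, classification — and that signal present in the inputs
is recovered.  It does not demonstrate accuracy on real proteins, where
coupling quality varies with alignment depth, percentile bias in variants
is much weaker, and crystallographic B-factors carry lattice-contact and
refinement artifacts that no additive noise model reproduces.

## Problem sizes used by the verification suite

100-residue compact-walk chains; 20 seeds per condition for
recovery/sweep statistics; coupling fidelities p_true ∈ {1.0, 0.7, 0.4}
at σ = 0.01; 400 variants per class for enrichment (γ = 2) and 1000
replicates of the uniform-null calibration; n = 2000 variants for
logistic parameter recovery (generator β0 = −1.5, β1 = 3 on
1 − percentile, chosen to balance the classes).  These sizes make every
check exercise the same code paths as full-scale runs while each
completes in seconds.

## Known limitations

* Isotropic GNM only: no anisotropic network model, mode animation or
  cross-correlation maps.
* Coupling inference itself (alignments, Potts/DCA fitting, deep-learning
  contact prediction) is out of scope; the package starts from a score
  table.  Likewise external predictor scores and evolutionary-rate
  features are consumed as precomputed columns only.
* The percentile-rank universe of a score file matters when comparing
  servers that emit very different list lengths; both conventions are
  implemented, but mixing them across proteins is the caller's
  responsibility.
* mmCIF is not parsed; convert to PDB first.
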