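# Methods

## Overview

`argsel` infers positive selection at a focal genomic site from the
*local genealogies* of an ancestral recombination graph (ARG).  The core
idea: a selective sweep distorts the timing of coalescences around the
selected site, and that distortion is captured compactly by counting
genealogical lineages through time.  A recurrent network trained on
coalescent simulations then maps these lineage-count curves to a sweep
probability, a selection-coefficient estimate, or a full
allele-frequency (AF) trajectory.

## Genealogy encoding

All genealogies are overlaid on one fixed grid of K = 100 timepoints
(generations before present).  The grid is *log1p-uniform*:

    t_j = (exp((j/(K-1)) · log(1 + c·t_max)) − 1) / c ,   j = 0..K−1

with defaults t_max = 1e5 generations and curvature c = 1.  Spacing is
non-decreasing in j, so recent history — where sweep signal lives — is
resolved most finely.  Any approximately log-uniform grid would serve;
this closed form makes the construction reproducible and configurable.

At the focal site, lineages active at each grid time are split into
*derived* (the mutation branch and its descendants) and *ancestral*
classes.  The mutation branch is the unique branch whose descendant
leaves are exactly the observed derived carriers (infinite-sites
assumption, biallelic sites only).  Two flanking trees on each side
contribute total lineage counts, capturing linkage disequilibrium.  The
result is a K × 6 channel matrix — 600 values with the defaults.

Numerical conventions, chosen once and fixed:

* **Branch activity** is half-open: a branch is active at t iff
  child_time ≤ t < parent_time, so each coalescence reduces the count
  exactly once.
* **Root clamp**: for t at or above the root, the total count is 1 (the
  persisting ancestral lineage), never 0; this avoids uninformative
  all-zero tails and keeps normalized features in (0, 1] for the total
  channels.  The derived channel is 0 above the mutation branch.
* **Flank selection** is topological: the nearest *distinct* trees by
  genomic interval, not fixed-distance windows.  At contig edges the
  outermost available tree is repeated.
* **Normalization**: counts are divided by sample size n by default, so
  a model transfers across data sets of the same design; raw counts are
  available by flag.
* **Channel order** (fixed): left-2, left-1 totals; focal ancestral;
  focal derived; right-1, right-2 totals.  Time is fed present → past.
* For inferred (real-data) genealogies that conflict with the observed
  carrier set, an optional maximal-Jaccard branch assignment exists
  behind an explicit flag; it is off by default and unused in
  simulation studies.

## Simulation

### Allele-frequency trajectories

The trajectory of the selected allele is simulated backward from its
present-day frequency f to its single-copy origin as a per-generation
Wright–Fisher binomial process around the conditioned-on-loss drift of
the genic-selection diffusion,

    E[Δx] = − s·x(1−x) · coth(2N(t)·s·(1−x)) ,

obtained by Doob h-transforming the forward diffusion (drift s·x(1−x),
variance x(1−x)/2N) with its loss probability
ℓ(x) = (e^{−4Nsx} − e^{−4Ns})/(1 − e^{−4Ns}).  Limits behave correctly:
for s → 0 the drift degenerates to the neutral conditioned value
−x/2N; for 2Ns ≫ 1 and x away from 1 it reduces to logistic decay at
rate s.  Each backward generation draws Binomial(2N(t), x + Δx); the
path is absorbed when ≤ 1 copy remains (fixation is excluded — a
loss-conditioned path cannot fix).  Soft sweeps are neutral below the
standing frequency f_init; the generation of that crossing is recorded
as the selection onset.  Paths exceeding a length cap are rejected and
redrawn (cap 2e6 generations, 1,000 attempts).

Two calibration checks anchor this machinery: the mean 0.95 → 0.05
sojourn at s = 0.05, N = 10,000 matches the deterministic logistic
duration 2·ln(19)/s ≈ 117.8 generations within Monte-Carlo error plus
an O(s) discretization allowance, and pooled neutral increments vanish
at the O(1/2N) scale of the conditioning drift (martingale check).

### Structured coalescent with recombination

Sweep genealogies are sampled backward in time by a structured
coalescent in which lineages carry ancestral genomic segments and an
allelic class.  Coalescence occurs only within a class, at
per-generation rate C(k,2)/(2N(t)·x(t)) in the derived background and
C(k,2)/(2N(t)·(1−x(t))) in the ancestral background, with x(t) read
from the pre-simulated trajectory.  Recombination detaches material at
rate r per bp per lineage span; the fragment on the focal side of the
breakpoint keeps its class, the other rejoins the derived background
with probability x(t).  The derived lineage count is capped by the
number of derived copies in the population, forcing the class to
collapse to a single lineage by the allele's origin; the focal mutation
is recorded there and the lineage rejoins the ancestral background.
Beyond the origin (and throughout neutral simulations) the process is
the ordinary coalescent with recombination under a piecewise-exponential
size history, with waiting times drawn in closed form inside constant
epochs and by per-generation hazard accumulation inside growth epochs.
Events are resolved at generation resolution with fractional jitter to
keep node times strictly increasing.

The sampler emits tskit tables (binary, fully coalesced local trees);
neutral mutations are then placed by msprime under the infinite-sites
binary model, and the focal site travels with the tree sequence as a
real site/mutation record.  Neutral regions use msprime's standard
coalescent-with-recombination directly.  Both backends satisfy the same
`SimulatedRegion` schema, so an external simulator can be substituted.

In its neutral limit the structured engine reproduces E[TMRCA] =
4N(1 − 1/n) and E[π] = 4Nμ; sweep mode shortens derived-carrier
coalescence times by an order of magnitude at s = 0.01 (both checked in
the test suite).

### Priors and named designs

Default priors mirror the European-panel design: s ~ U(0.0001, 0.02),
f ~ U(0.01, 0.99), μ, ρ ~ U(1.25e−8, 2.5e−8) per bp per generation,
sample size 198 haplotypes over 100-kb regions with the selected site
at the midpoint; the soft-sweep standing frequency is U(0.01, 0.05)
with a 56-haplotype songbird-style design available.  The CEU-like size
history ships as an epoch table following the published composite
European model (ancestral size 7,310; African expansion to 14,474 at
5,920 generations; out-of-Africa bottleneck 1,861; European bottleneck
1,032; two growth phases reaching ≈512,000 at present).  Those numbers
come from the cited demographic literature, not from first principles;
every entry is configurable.  The capuchino-like history is modeled as
a piecewise-constant single-population path (130,000 diploids to
44,000 generations ago; 14,380,000 to 1.85 M generations; 1,450,000
beyond), a deliberate single-deme simplification of a two-population
divergence model.

Neutral training regions receive a *DAF-matched* focal site: a target
frequency drawn from the sweep f prior, then a uniformly chosen
segregating site within ±0.02 of it (regions without one are
resimulated).  This prevents the classifier from keying on allele
frequency alone.

Seed management: one master seed fans out per-region child seeds via
`numpy.random.SeedSequence`; child seeds are recorded in dataset
metadata, and identical configurations reproduce label arrays
bit-identically.

## Network

The model is a stack of two LSTM layers (default 100 tanh units each)
unrolled over the K timepoints, implemented in NumPy with hand-derived
backpropagation-through-time, and read by a dense head: a 2-unit
softmax with cross-entropy for sweep classification, a linear unit with
MSE for selection-coefficient or onset regression (s predictions are
clipped at 0), and a per-timestep linear unit with MSE for the
many-to-many AF-trajectory task (trajectory labels are the
grid-discretized truth, 0 before the allele's origin; outputs are
clipped to [0, 1]).  Optimization is Adam at its conventional defaults
(lr 1e−3, β₁ 0.9, β₂ 0.999) with global-norm gradient clipping at 5;
the forget-gate bias starts at 1.  BPTT gradients are verified against
numerical differentiation in the test suite.

Choices the architecture leaves open were fixed as follows: inverted
dropout (default rate 0.2) after each stack with one mask per sequence
shared across timesteps; batch size 64; up to 40 epochs with early
stopping on a 10% validation split (patience 5, best weights restored).

**Uncertainty** comes from Monte-Carlo dropout: dropout masks stay
active at inference, each thinned network yields one prediction, and a
95% interval is formed from the empirical 2.5/97.5 percentiles of
(default) 100 samples, widened if necessary to contain the
deterministic point estimate.  Rate 0 collapses the interval to zero
width; width grows with the rate.

## Baseline statistics

The classical sweep scans used for benchmarking are implemented from
their standard definitions (π, Watterson's θ_W = S/a₁, Fay–Wu's
θ_H = Σ 2d²/(n(n−1)), Tajima's D with its usual variance
normalization, distinct-haplotype count, Garud's H1/H12/H2-H1, ZnS as
mean pairwise r², the ω LD-ratio maximum, and iHS).  Decisions the
standard descriptions leave open:

* **iHS**: EHH integrated by the trapezoid rule over bp distance,
  truncated where EHH < 0.05 (or at the block edge); unstandardized
  iHS = ln(iHH_ancestral/iHH_derived) at sites with minor AF > 5%;
  standardization in 50 equal-width derived-AF bins, bins with < 2
  scored sites falling back to the global moments; the region score is
  the mean over scored sites.
* **ω**: every split with at least one segregating site per side is
  evaluated (so 3 sites yield 2 candidate splits); within-flank means
  use the exact pair counts of each flank.
* **Windowed features**: 11 statistics over five equal-bp windows,
  each statistic row normalized by its across-window sum;
  zero-sum or undefined entries propagate as missing rather than being
  silently dropped.
* **Haplotype sorting** (genotype-image encoder): Manhattan-distance
  centrality with ties broken by original row index, for determinism.

The genotype-image encoder reproduces the fixed-width (n × 360,
focal variant at column 180) zero-padded matrix used by
alignment-based CNN baselines.  A CNN itself is not included — the
LSTM is this package's model; the encoders exist so such a baseline
can be assembled externally.

## Scaled experimental design

The full-scale study behind this method trains on 10⁶ regions of
100 kb with 198 haplotypes (~150 CPU-hours of simulation plus GPU
training); its headline error figures are not reproducible on a
workstation.  The package therefore fixes a scaled design, used by both
the test suite and `scripts/acceptance.py`:

* constant N = 10,000 diploids, n = 32 haplotypes, L = 50 kb, true
  genealogies, s ~ U(0, 0.02), focal-site f ~ U(0.05, 0.95);
* 800 sweep + 400 DAF-matched neutral training regions; 300 held-out
  sweeps, 150 held-out neutrals; stratified test sets of 80 regions per
  class at s ∈ {0.001, 0.005, 0.01} and a strong stratum
  (s ~ U(0.0075, 0.02)) at focal DAF ≥ 0.7;
* LSTM width reduced to 2 × 32 units, ≤ 30 epochs.

Under this design the regressor reaches Spearman ρ ≥ 0.6 between true
and predicted s with median predicted s ≤ 0.002 on neutral regions, the
classifier exceeds AUROC 0.9 on strong high-frequency sweeps with power
increasing in s, and the trajectory model's present-day AF output
correlates strongly with the true focal DAF.  These thresholds are the
package's acceptance properties; the exact numbers for a given seed are
whatever `scripts/acceptance.py` prints.

## What the simulations do and do not show

The generator produces phased, fully polarized, error-free haplotypes
with *true* genealogies and a single selected site per region.  Passing
tests therefore demonstrate the statistical machinery — encoding,
training, calibration — not robustness to ARG-inference error,
phasing/polarization error, background selection, or multiple linked
sweeps.  Real-data use should train on genealogies inferred by the same
tool that will be applied to the data (the Newick/VCF input path exists
for exactly this), and the `robustness_grid` harness quantifies
sensitivity to demographic mis-specification without retraining.

## Known limitations

* Single panmictic population with piecewise-exponential size history;
  no migration, no background selection, one selected site per region.
* The structured coalescent resolves events at generation resolution;
  sub-generation rate variation is ignored (negligible at coalescent
  time scales).
* Class assignment of recombinant fragments not spanning the focal site
  follows the standard background-frequency rule, an approximation
  shared with discrete structured-coalescent sweep simulators.
* Onset-time regression shares the architecture but has no dedicated
  calibration study here.
* Recurrent mutation and multiallelic sites are out of scope; sites
  whose carriers conflict with the genealogy are rejected unless the
  Jaccard fallback is explicitly enabled.
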