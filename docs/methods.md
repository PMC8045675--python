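# Methods

## The model

`mbwsim` studies how an RNAi knockdown of the anthocyanin-activating R2R3
MYB (*MYB5a*/*NEGAN*) propagates through the MBW regulatory network of
*Mimulus luteus var. variegatus*, using the smallest model that captures
the network's logic: a two-species activator–inhibitor system.

The activator `a` stands for the active MBW complex (MYB5a together with
its bHLH and WD40 partners); the inhibitor `i` stands for the single-repeat
R3 MYB repressor (RTO), which is transcriptionally activated by the MBW
complex and represses it by sequestering bHLH proteins. On an arbitrary
concentration scale:

    da/dt = f (σ_a + ρ_a a² / ((1 + κ a²) i)) − μ_a a + D_a ∇²a
    di/dt = σ_i + ρ_i a^n − μ_i i + D_i ∇²i

This is a Gierer–Meinhardt-type system with basal production (σ), a
saturating autocatalytic loop (κ), cooperativity of inhibitor induction
(n ≥ 1), and linear decay. RNAi is the factor `f ∈ (0, 1]` multiplying
*total* activator production — basal and autocatalytic — because transcript
destruction acts upstream of both production routes.

### Knockdown fold changes

With σ = 0 and κ = 0 the positive steady state is

    a* = (f ρ_a μ_i / (μ_a ρ_i))^(1/(n−1)),   i* = ρ_i a*^n / μ_i

so a knockdown to factor `f` folds the activator down by
`FC_a = (1/f)^(1/(n−1))` and the inhibitor by `FC_i = FC_a^n`. Because
n ≥ 1, **the repressor always falls at least as hard as the activator** —
this is the model's explanation for the central experimental observation:
a modest (threefold) MYB5a knockdown collapsing the RTO repressor 19- and
29-fold. A 19-fold collapse at a threefold activator fold-down corresponds
to n = ln 19 / ln 3 ≈ 2.68. Away from the σ = κ = 0 limit the
amplification ratio varies with parameters (basal inhibitor production
floors `i*`, so `FC_i` saturates while `FC_a` can diverge); the package
computes both branches numerically and the property suite checks the
monotonicity claim — every knockdown lowers both steady-state levels —
across hundreds of random parameterizations.

Steady states are found by slaving `i` to its nullcline, bracketing sign
changes of the reduced 1-D equation on a log grid spanning `1e-12`–`1e12`
(6000 points), refining with Brent's method, and classifying stability
from the analytic Jacobian. `steady_state` returns the largest positive
stable root — the pigmented branch. When no positive root exists (possible
only with σ_a = 0) a flagged trivial result `(0, σ_i/μ_i)` is returned
rather than an exception; a knockdown that lands there is reported as an
infinite fold-down, i.e. complete pigment loss.

Numerical settings: Brent tolerance `xtol = 1e-14`; ODE integration with
LSODA at `rtol = 1e-8`, `atol = 1e-12`. The inhibitor in the autocatalytic
denominator is floored at `1e-12` so `i = 0` cannot divide by zero;
concentrations above the floor are used exactly.

## Petal patterning

The petal is a rectangular grid (default 96×64, spacing h = 1) whose
proximal third is the nectar guide and the rest the lobe. Zones share all
kinetics except the basal drive σ_a; genotypes are presets of per-zone σ_a
plus a global `f`. Integration is explicit forward Euler with a 5-point
Laplacian and reflecting (no-flux) edges; the step is checked against the
diffusion stability bound `h²/(4 max(D_a, D_i))` and defaults to half of
it. The initial condition is the per-zone homogeneous ground state — the
lowest stable branch, since pigment develops from an unpigmented field —
plus seeded uniform noise (1% of the mean by default).

The shipped kinetics (σ_i = 0.2, ρ = 1, μ_a = 1, μ_i = 1.5, κ = 0.2,
n = 2, D_a = 0.25, D_i = 12.5) were chosen so that sweeping lobe σ_a
traverses three regimes:

* **σ_a ≲ 0.01** — a stable low branch coexists with the high branch; the
  field stays unpigmented (*uniform_low*: the yellow luteus lobe). The
  strong lateral inhibition (D_i/D_a = 50) pins spot fronts at the zone
  boundary, so a spotted guide does not invade a low lobe.
* **σ_a ≈ 0.05–0.1** — only the high branch exists and it is Turing
  unstable (tr J < 0, det J > 0, growing modes at k > 0); noise breaks the
  field into spots (*spotted*: the F1 lobe, the nectar guide).
* **σ_a ≳ 0.2** — saturation weakens activator self-enhancement enough to
  stabilize the homogeneous high state; pigment fills the zone
  (*uniform_high*: the solid variegatus lobe).

Decreasing `f` on the variegatus background walks the same path backwards
(solid → spotted → unpigmented), matching the partial- and strong-RNAi
phenotypes. The F1 genotype is modelled simply as intermediate lobe σ_a;
the package deliberately does not commit to a cis- vs trans-dosage
mechanism.

Phenotype calls: the pigmentation threshold is the midpoint of the field's
(min, max), floored at an absolute level threshold (default 0.5) so a field
that is low everywhere is not split at its own noise scale; a zone with
spatial CV < 0.05 is uniform (low/high by its mean against the level
threshold), otherwise spotted, with spots counted as 4-connected
components. All cut-offs are configurable; they are reporting conventions,
not model content.

The 1D dispersion check compares the dominant FFT wavenumber of a simulated
profile against `k_max` of the linear growth rate
`max Re eig(J − k² diag(D_a, D_i))`; agreement within a factor of 2 is the
pass criterion, and the shipped fixture lands within ~2%.

## Synthetic transcriptome

The generator emulates the downstream product of the sequencing design —
three wild-type and three RNAi petal libraries — as a genes × samples
integer matrix. Counts are negative binomial with mean
`μ_gs = depth_s · baseline_g · FC_g^[s ∈ RNAi]` and variance
`μ + α μ²` (α = 0.05 by default; α = 0 degenerates to Poisson). Depth
factors are log-normal around 1 (σ = 0.1). Everything is deterministic
given the configuration and seed.

The `fig5c` effect preset plants the study's regulator fold-downs: MYB5a 3;
bHLH1, bHLH2, WD40a 2.5 (midpoint of the observed two- to threefold
range); RTO1 19 and RTO2 29 (the assignment of 19 vs 29 to the two
homeologs is an arbitrary labelling). The enzyme panel holds 30 genes —
CHS 7, CHI 6, F3H 5, DFR 4, ANS 4, UF3GT 4 — with the early classes
homeolog-enriched (> 2 copies each); only the total of 30 and the
enrichment are constrained, the per-class split is a choice. LBG copies
share a fourfold knockdown and EBG copies cycle up/down/no-change
(1.5×, 1/1.5×, 1×): these reproduce the qualitative early/late dichotomy
and are not measured values. 2,000 null background genes (log-uniform
baselines 5–2000, uniform lengths 500–5000 b) give the multiple-testing
burden a desk-scale analysis needs.

What the generator does *not* emulate: read-level artefacts (mapping
ambiguity between homeologs, GC/length biases), correlated genes,
outlier samples, and indirect knockdown targets beyond the panel (the
count of indirectly affected genes in real data depends on the genome
annotation and is deliberately left at zero). Passing recovery tests
therefore show the DE stage is calibrated for NB sampling noise at n = 3,
not that it is robust to real-data artefacts.

## Differential expression

A deliberately simple, fully documented small-replicate pipeline (the
original study used an established DE package; cloning its numerics is out
of scope and unnecessary for the questions here):

1. **Size factors** — median-of-ratios against the per-gene geometric-mean
   reference, computed over genes expressed in every sample; total-count
   fallback with a logged warning if no such gene exists. Factors are
   defined relative to the common reference, so equivariance under
   rescaling a sample holds for between-sample factor ratios.
2. **Dispersion** — per-gene method of moments on normalized counts,
   pooled within groups by degrees of freedom, clipped at zero, then
   shrunk toward the panel mean with fixed weight w = 0.3. The weight is a
   simple documented stabilizer for n = 3; parameter-recovery simulations
   (truth α = 0.2, 50/group) confirm the shrunken median stays within
   [0.1, 0.3].
3. **Wald test** — log2 ratio of normalized group means with a
   delta-method SE from `Var(count/sf) = m/sf + α m²`. A 0.5 pseudocount
   is added to both means only when either is zero: conditional
   application keeps the fold change of expressed genes an exact ratio,
   hence exactly invariant to rescaling any sample's column, while still
   handling zeros. Degenerate SEs yield null p-values and are excluded
   from testing.
4. **BH-FDR and significance** — step-up adjusted p-values (validated
   against a brute-force implementation and statsmodels), with the study's
   rule: |log2FC| ≥ 1 and adjusted p < 0.05. Null simulations at the
   default settings keep the significant fraction well below 5%.

Study-specific summaries: RPKM (`count · 10⁹ / (length · library size)`),
the EBG/LBG dichotomy call (a class is "LBG-like coordinate-down" iff all
its copies are significantly down), the regulator fold-down table, and the
exact two-sided binomial test (minimum-likelihood convention) for the 3:1
transgene segregation ratio — for the observed 6 of 8 white-flowered
offspring, 6 is the modal outcome and the two-sided p is exactly 1.

## Problem sizes and reproducibility

Default sizes are chosen for a desk-scale workflow: 96×64 spatial grids,
2,036-gene panels, 3-vs-3 designs, 50-replicate recovery medians, and
20-seed null calibrations. Every stochastic step takes an explicit seed;
pipeline runs write their full configuration and a SHA-256 manifest next
to their outputs, and identical configuration plus seeds reproduce
identical files.

## Known limitations

* The activator–inhibitor form is a minimal stand-in for the MBW complex's
  three-protein assembly; WD40 and bHLH are not dynamic variables (they
  enter only through the transcriptome presets).
* Amplification `FC_i ≥ FC_a` is a theorem only in the σ = κ = 0 limit;
  with basal inhibitor production the inhibitor fold saturates.
* The symmetric parameterization with μ_a = μ_i is marginally stable
  (trace J = 0); stability statements use μ_i > μ_a.
* Pattern classifications depend on reporting thresholds (CV 0.05, level
  0.5); they are calibrated to the shipped fixture, not to photographs.
* No parameter fitting to real transcriptomes or petal images is
  attempted anywhere.
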