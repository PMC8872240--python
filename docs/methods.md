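# Methods

`paleometh` studies a practical question in paleoepigenomics: **how much
sequencing coverage does an ancient genome need before per-CpG
methylation estimates inferred from post-mortem deamination stop
improving?**  It answers it with a fully synthetic, ground-truth-known
pipeline: a generative model of damaged ancient-DNA (aDNA) reads, a
windowed maximum-likelihood methylation estimator, and a coverage
down-sampling titration with a 2×SD stopping rule.

## 1. Generative model

### Reference and methylome

A synthetic chromosome of length *L* (default 0.5 Mb) is drawn with a
CG-free background into which *n* CpG dinucleotides (default 5,000) are
planted at uniform, non-adjacent positions.  Because the background
contains no CG, the planted list enumerates every CpG — the simulator's
coordinate ground truth is exact.

True methylation levels *m<sub>s</sub>* ∈ [0,1] are assigned per CpG in
consecutive blocks of `block_len` sites (default 50).  Each block draws
one level from a two-component Beta mixture: with probability `p_high`
(default 0.75) from Beta(8, 2) (the methylated compartment that
dominates vertebrate genomes), otherwise from Beta(1, 9)
(hypomethylated, CpG-island-like).  The defaults emulate the strongly
bimodal marginal distribution and the regional, kb-scale coherence of
vertebrate methylomes.  The block length matters: the estimator pools a
26-CpG window, so block lengths well below that make the "true value at
the focal site" a poorly defined target for any windowed method.

### Fragments and damage

Fragment lengths are lognormal (log-mean 4.0 ≈ 55 bp, log-sd 0.35)
truncated to [20, 150] bp, matching typical aDNA size distributions.
Fragment count is Poisson so the realized coverage matches the request;
starts and strands are uniform.

Deamination acts on each cytosine of the fragment's own strand at
distance *i* from its 5′ end:

    δ_u(i) = δ_bg + (δ_max − δ_bg)·λ^i        (unmethylated)
    δ_m(i) = min(1, ρ·δ_u(i))                 (methylated, ρ ≥ 1)

with defaults δ_max = 0.30, λ = 0.30, δ_bg = 0.01, ρ = 2.  A CpG
cytosine with methylation *m* converts C→T with probability
*m*·δ_m(i) + (1−*m*)·δ_u(i) (non-UDG libraries).  In UDG mode,
deaminated unmethylated cytosines are excised (the base becomes a gap
in the read) while 5mC-derived thymines survive.  Sequencing error ε
(default 0.001) then hits every emitted base uniformly over the three
alternatives.  Damage is applied symmetrically on both strands
(double-stranded library convention); reverse-strand damage appears as
G→A in the forward frame.  The read-position index is capped at
I<sub>max</sub> = 25, beyond which the interior rate applies — damage is
terminal, and the cap bounds all tables.

The default δ_max of 0.30 represents a typically preserved sample; the
"preserved" preset uses 0.15, the terminal rate of an exceptionally
well-preserved ~38× genome, which is deliberately the *lowest* of the
three archetypes.  ρ = 2 is a conventional choice: ρ > 1 is what makes
methylation identifiable at all in non-UDG data, but the ratio itself
is not estimated from the data (no procedure for it exists here), so it
is a shared configuration constant and f estimates scale accordingly.
Sensitivity: overstating ρ compresses f̂ downward, understating it
inflates f̂; coverage-titration conclusions are insensitive because
Δf compares the same estimator against itself.

Not modelled: alignment/mapping error, indels, single-stranded-library
3′ G→A asymmetry, bisulfite chemistry, contamination.  Passing tests
therefore demonstrate correctness of the estimator and the titration
logic under idealized alignment, not robustness to mapping artifacts.

## 2. Pileup and damage-profile estimation

Pileups count C/T observations per cytosine site, stratified by read
position *i*, and are strand-matched: forward reads count at forward-C
sites, reverse reads at reference-G sites (complemented, so G→n_C,
A→n_T), and the G of a CpG folds into its C site.  Opposite-strand
reads carry no deamination signal about a site and are excluded —
including them would dilute every damage estimate twofold.

δ_u(i) is estimated as the pooled T fraction at **non-CpG** cytosine
sites per read position (vertebrate non-CpG methylation is negligible,
so these sites are treated as fully unmethylated).  The estimate
absorbs a small ε/3 sequencing-error component, which is consistent
between profile and likelihood.

Sites carrying C>T (or complemented A>G) germline variants would mimic
full methylation, so CpG sites are masked when their interior
(*i* ≥ 10) T fraction reaches 0.9 with at least 5 supporting
observations.  Interior positions are used because damage is near
background there; the thresholds are conventional allele-frequency
choices, and the synthetic genome contains no true variants, so in
simulation this is a guard rather than a workload.

## 3. Windowed maximum-likelihood methylation estimator

For focal CpG *s*, observations are pooled from *s* and the NCPG CpG
sites downstream (default 25; truncated at the chromosome end; masked
sites are skipped).  The estimator maximizes over *f* ∈ [0,1]

    ℓ(f) = Σ_i [ t_i · log P_T(f, i) + c_i · log(1 − P_T(f, i)) ]

with, in non-UDG mode,

    P_T(f, i) = D + (ε/3)(1 − D),   D = f·δ̂_m(i) + (1 − f)·δ̂_u(i)

where δ̂_u(i) is the estimated profile and δ̂_m(i) = min(1, ρ·δ̂_u(i));
in UDG mode P_T(f, i) = f·δ̂_m(i) + ε/3.  The maximizer is found on a
dense grid (step 10⁻³) and refined by golden-section search to 10⁻⁶.

Numerical conventions: flat stretches and ties resolve to the smallest
maximizing *f* (deterministic output, and boundary cases return exact
0 or 1); a site is *missing* exactly when the focal CpG has zero
observations; read positions with an undefined profile are dropped; if
δ̂_m ≡ δ̂_u at every supported position the likelihood is flat in *f*
and the estimator raises a non-identifiability error (the ρ = 1 trap)
rather than returning an arbitrary interior value; T observations at
positions where the model puts zero T probability raise a degenerate-
profile error.

With all observations at a single read position and ε = 0 the MLE has
the closed form clip((t − δ_u)/(δ_m − δ_u), 0, 1), t = n_T/(n_C+n_T);
this and a brute-force 10⁻⁴ likelihood grid serve as independent test
oracles.

## 4. Coverage titration

One full-coverage read set is simulated per seed; every down-sampled
level (grid ⊆ {1,3,5,10,15,20,25,30}×, capped strictly below the full
coverage) is an independent Bernoulli thinning of that **same** read
set, mirroring down-sampling of a single sequencing run.  Per level the
pipeline re-runs end to end (pileup → profile → mask → f), then

* Δf_s = f_level(s) − f_full(s) over sites defined in both tracks,
* SD(Δf) per level (sample SD, n−1),
* non-covered CpGs (zero focal observations) per level,
* a trendline fit of SD versus coverage,
* the recommendation: smallest grid level whose SD does not exceed
  2 × the SD at the reference level — the highest down-sampled level
  below full coverage.  (Δf at the full coverage itself is identically
  zero, so "the value calculated from the maximum coverage" can only
  mean its nearest down-sampled neighbour.)

### Trendline form

For a linear statistic, nested thinning gives Var(Δf) ∝ 1/c − 1/full
exactly, i.e. SD(c) = a·√(1/c − 1/full) + d.  This sqrt-law is
implemented and exactly recovers synthetic inputs, but it does **not**
describe the measured decay: at realistic damage levels the windowed
MLE has standard errors of ~0.3 and clips heavily at 0 and 1, so the
decay is flatter than √(1/c) and the sqrt-law leaves R² anywhere
between 0.83 and 0.95 across seeds.  The exponential family
a·e^(−b·c) + d describes the measured decay well (R² 0.97–0.99) and is
the default; the power law a·c^(−b) is also available.  R² is always
computed on the original scale, and a constant SD series returns
R² = 0 with a degenerate flag rather than an error.

The recommendation uses the *empirical* per-level SDs, not the fitted
curve: smoothing was evaluated and rejected because the global fit
distorts exactly the high-coverage tail where the threshold decision is
made.

### Sample archetypes

| preset          | full cov | δ_max | grid cap | typical outcome |
|-----------------|----------|-------|----------|-----------------|
| ans017-like     | 24×      | 0.30  | 20×      | 15× recommended |
| SF12-like       | 38×      | 0.15  | 30×      | 20× recommended |
| stuttgart-like  | 19×      | 0.30  | 15×      | 10× recommended |

The better-preserved (lower-deamination) archetype needs *more*
coverage: each read carries less methylation signal, so the SD(Δf)
curve is shifted up and crosses the threshold later.  At the default
problem size (0.5 Mb / 5,000 CpGs, chosen to keep a full three-seed
titration under two minutes on one core) the 38× decision is within a
few percent of its threshold, so individual seeds occasionally return
15×; the reported value is the median over three seeds.

## 5. Degenerate inputs and edge behavior

* zero requested coverage → empty read set, valid empty outputs;
* empty down-sampling grid → error (nothing to titrate);
* up-sampling (target above current coverage) → error;
* fewer than 2 compared sites at a level → error;
* fewer than 3 trend points → error;
* constant truth in recovery reports → Pearson r reported as missing.

## 6. Known limitations

* ρ is assumed known and position-independent; real 5mC/C deamination
  ratios vary with context and age.
* The windowed estimator reports a window-average f; sharp methylation
  boundaries inside a window are smoothed over (the same trade-off any
  NCPG-style pooling makes).
* Non-covered-CpG counts use the focal-site rule (zero observations at
  the focal CpG); window-based alternatives would count differently.
* The simulation knows nothing of mappability, GC bias or clonality,
  all of which shape real coverage distributions; its
  coverage-sufficiency numbers are therefore statements about estimator
  statistics, not about library economics.
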