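# Methods

## Scope and data model

`qsippy` analyzes amplicon data from CsCl density-gradient SIP
experiments in which each sequenced "sample" is one density fraction —
or, in the pooled design the package defaults to, one of three density
groups (light [1.65, 1.69), medium [1.69, 1.75), heavy [1.75, 1.80]
g/mL) — of one replicate soil core. The pipeline starts at the
ASV-by-sample count table; read processing is out of scope. Buoyant
density is either supplied directly or derived from refractive index
through a linear calibration (default ρ = 10.9276·RI − 13.593, the
standard CsCl relation at 20 °C; instruments differ, so both constants
are user-set). The published group bounds leave small gaps
(1.689–1.69, 1.749–1.75); the scheme closes them with half-open bins so
every in-range density is assignable to exactly one group, and the
volume unit is taken as g/mL (DNA in CsCl bands near 1.7 g/mL; "g/µL"
in some descriptions is a typographical slip).

## Preprocessing

Fixed order: (1) depth filter — samples retained when sequencing depth
lies within mean ± k·SD (k = 2), mean and sample SD computed once over
all input samples, not re-iterated; (2) rare-taxon filter — a taxon is
kept when its per-sample count reaches `min_count` (3) in at least
⌈`min_prevalence`·N⌉ samples (2% of N). The "three times in 2% of
samples" idiom is ambiguous between per-sample and total counts; the
per-sample reading is implemented, and both thresholds are
configurable so the other reading can be approximated; (3) relative
abundance per sample; (4) QSEQ normalization — each column is scaled by
that sample's total 16S copies per ng DNA from qPCR, so column sums
equal the qPCR totals and values are gene copies per ng DNA. Samples
without a qPCR record are dropped and reported. No rarefaction is
performed. Every removal is logged in a `FilterReport` whose counts
reconcile the dimension change exactly.

## Enrichment chain

Per replicate core, a taxon's WAD is the abundance-weighted mean of the
sample densities, computed over whatever density groups (or fractions)
that core has; missing groups are tolerated and the groups actually
used are recorded, because losing the light group biases WADs upward
(the simulator reproduces this artifact and tests assert the logging).

Uncertainty comes from a core-level bootstrap: replicate cores are the
exchangeable unit (n = 2–3 in the motivating design), resampled with
replacement within isotope treatment, labeled and unlabeled resampled
within the same draw and differenced per draw; 1,000 draws, percentile
2.5/97.5 CIs. An exhaustive-enumeration mode (all nⁿ resamples) exists
for validation at small n. CI choice is percentile because nothing in
the motivating description constrains it further; with n = 3 cores
percentile intervals are known to under-cover somewhat, which shows up
as a false-call rate above the nominal one-sided 2.5% (measured ≈2–7%
across simulation seeds at default noise).

The per-draw chain is: GC from the unlabeled WAD (G clamped into [0, 1]
for the mass formulas, raw value retained and reported), M_LIGHT,
M_HEAVYMAX with the first-principles carbon count N_C(G) = 10 − G/2
(dAMP/dTMP/dGMP carry 10 carbons, dCMP 9), M_LAB by the proportional
mass–density relation, then atom fraction excess A against the natural
¹³C background 0.01111233. A is never clipped; negative estimates are
reported as such. The forward model (`forward_density_shift`) is the
exact algebraic inverse of this chain, and round trips recover the
excess to machine precision — this also fixes the simulator's physics.

Activity: the CI rule (mean APE > 0 and lower CI > 0) for taxa with
both treatments; the label-only rule (taxon WAD lower CI above the ¹³C
community WAD upper CI) for taxa never seen in ¹²C cores. Each result
row records the route taken, the bootstrap seed and draw count.

## Community summaries

Activity is called at ASV level, then member-ASV absolute abundances
are summed to genus (falling back to the finest resolved rank) per
labeled core over the heavy + medium groups — the groups sitting above
the labeled treatment's community WAD — and averaged across cores per
treatment group, with both SD and SE reported (dispersion is marked
missing, not zero, for n = 1). Background abundance repeats the
aggregation over all three groups and both isotopes. Shannon diversity
is H = −Σ p ln p (nats) on each core's active-community abundances.
Overlap of active sets across treatment groups is an exact disjoint
partition of the union into the 2ᵏ − 1 Venn regions (k ≤ 5).

## Simulator

The generator draws taxon GC from a truncated normal (mean 0.60,
SD 0.08, bounds 0.25–0.78 — soil communities are GC-rich on average and
span roughly this range), converts GC to the unlabeled density through
the same linear relation the analysis inverts, assigns each taxon a true
atom-fraction excess (an inactive fraction at exactly zero, active taxa
uniform on 1–10%), and shifts labeled band centers with the forward
model. DNA mass is banded as a Gaussian in density (default SD
0.005 g/mL; gradients are near-Gaussian and this width keeps bands
narrower than the groups, as in well-formed gradients) and integrated
over the bins — the three pooled groups by default (`collapse=True`),
or a uniform grid of fractions (`collapse=False`, 30 fractions). Read
counts are multinomial at the configured depth (default 50,000 per
sample, 3 + 3 cores per treatment); qPCR totals are proportional to a
group's share of the core's 16S pool with mean-one lognormal noise
(CV 20%; qPCR replicate variability is of this order), emulating the
QSEQ assumption that copies/ng track total copies. Density groups drop
out independently at 5% per core-group, mimicking failed fraction
pools. Mean relative abundances are lognormal (σ = 1). Truth (GC,
densities, excess, active flags) is always returned/written alongside
the data so recovery tests never reverse-engineer the generator.

What the simulator does **not** model: per-fraction density measurement
error, tube-to-tube gradient deformation, compositional coupling between
taxa beyond the multinomial, chimeras/sequencing error, or abundance
differences between cores. Passing recovery tests therefore demonstrate
the estimator's behavior under clean gradient physics with realistic
counting and qPCR noise, not robustness to instrument drift.

## Numerical and design choices

- **Group densities.** Pooled samples carry the design density of their
  bin (the bin midpoint); real experiments would use the
  temperature-corrected mean fraction density of the pool.
- **Three-group discretization bias.** With bands (SD 0.005) narrower
  than the groups (0.04–0.06 g/mL wide), a WAD computed from three
  fixed densities responds to a band-center shift only through the mass
  crossing a bin boundary: taxa mid-bin are insensitive (APE attenuated
  toward zero), taxa near a boundary are amplified (observed APE up to
  ~4× the truth at the default geometry). This is intrinsic to the
  pooled design, not to the implementation: at fraction-level
  resolution (bin width ≤ banding SD) the midpoint-rule WAD equals the
  band center to ~1e-9 and recovered APE is unbiased to within
  Monte-Carlo error (asserted over 20 seeds at zero qPCR noise).
  Detection (active/inactive) is much less affected than the APE
  magnitude, because amplification inflates signal and bootstrap spread
  together; sensitivity for true APE ≥ 3% measured ≈0.84–0.93 across
  seeds at default conditions. Users wanting calibrated APE magnitudes
  should analyze fraction-level data (the model accepts it unchanged).
- **Zero-abundance taxa.** A WAD over all-zero abundances is undefined
  and returned as NaN, then excluded from core averaging; taxa with no
  unlabeled data route to the label-only rule.
- **Ties/boundaries.** Density bins are half-open with the top bin
  closed; boundary densities therefore assign deterministically.
- **Determinism.** One `numpy` Generator seeded per fit drives every
  bootstrap; seed and draw count are stamped on each output row, and
  the CLI manifest records config, input digests and seeds so
  deterministic stages re-run byte-identically.
- **Problem sizes.** Validation simulations use 200 taxa, 3 + 3 cores,
  50k reads/sample and 1,000 bootstrap draws — enough for binomial
  tolerances of a few percent on sensitivity/false-call rates while a
  full suite run stays in seconds.

## Known limitations

- Only ¹³C chemistry is implemented (no ¹⁸O/¹⁵N variants, no growth
  rates).
- The label-only rule compares against the community WAD of labeled
  cores; in communities dominated by heavily labeled taxa it becomes
  conservative.
- Percentile CIs from 2–3 cores are approximate; treat borderline
  active calls accordingly.
- Routine downstream statistics (ANOVA, NMDS/PERMANOVA, rank tests) are
  deliberately left to standard tools operating on the exported CSVs.
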