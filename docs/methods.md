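# Methods

`metaqtl` implements a complete meta-QTL analysis for barley yield traits:
it integrates quantitative-trait-locus (QTL) reports curated from many
independent linkage-mapping studies into a small number of consensus loci
(meta-QTL, MQTL), validates them against genome-wide association results,
and mines candidate genes inside the best-supported regions.  This note
documents the statistical model, the numerical choices, and what the
synthetic data generator does and does not emulate.

## 1. Input harmonization

**Trait classes.** Raw trait names are normalized (lower-case, collapsed
whitespace) and mapped onto 11 canonical yield-trait classes (GMT, GN, SRT,
GW, GY, GFRT, GPT, BY, PH, TN, HI) through a packaged, editable synonym
table (`metaqtl/data/trait_vocabulary.tsv`).  Unmapped names are never
silently dropped: they are excluded with a per-line report, or fatally in
strict mode.

**Imputation.** Reports lacking a LOD score receive LOD = 3; reports
lacking PVE (percentage of phenotypic variance explained, R²) receive
PVE = 10%.  Both imputations are flagged on the record.

**CI recalibration.** Reported confidence intervals are not comparable
across studies, so each 95% CI width is recomputed from population size
*n* and PVE:

    CI = c / (n × PVE),   c = 287 (DH), 163 (RIL), 530 (F2 and BC)

**PVE is on the percent scale** (10 means 10%); treating it as a proportion
would make every interval 100× wider.  The recomputed interval is centred
on the reported peak.  Two switches control the policy:

* `use_reported_ci = True` disables recalculation entirely (sensitivity
  analysis);
* by default, records whose PVE was **imputed keep their reported CI**.
  Recomputing an interval from an imputed PVE would replace a measured
  interval with one derived from a made-up value; when the true
  (unreported) PVE is smaller than the 10% default the formula fabricates
  precision, and in clustering such records detach as spurious
  single-member MQTL.  `recalc_imputed_ci = True` restores unconditional
  recalculation.

## 2. Consensus map construction

Component linkage maps are merged per chromosome by linear programming.
Each map contributes order-and-distance constraints between consecutive
shared markers (`max_interval` controls how many neighbours; default 1).
Consensus coordinates `x` minimize

    Σ |(x_b − x_a) − d_ab|   subject to   x_b ≥ x_a  for retained pairs,

the average-absolute-error objective, solved with HiGHS
(`scipy.optimize.linprog`) after splitting absolute values into slack
pairs.  Positions are shifted so each chromosome starts at 0.

**Order conflicts.** Opposite orderings between maps create cycles in the
constraint graph.  Minimal feedback-arc removal is NP-hard, so the package
removes greedily: the edge on the most currently-enumerated simple cycles
goes first (ties: fewest supporting maps, then lexicographic — fully
deterministic).  On small instances this matches an exhaustive minimal
search, which the test suite verifies by brute force; on large instances
minimality is heuristic.  Every removal is logged with its source map.

**Flat optima.** The L1 objective often has flat directions (e.g. a marker
present in one map only).  A tie-break term with weight 10⁻⁶ pulls each
marker toward the centroid of its per-map positions, making the optimum
unique and runs reproducible.  Markers placed on different chromosomes by
different maps are excluded from the merge and reported.

## 3. QTL projection

Each QTL is transferred from its study's map to the consensus by homothetic
(proportional) interpolation between *anchor markers* — the closest markers
bracketing the QTL present on both maps.  The position and both CI
endpoints use the same anchor pair, so the CI width scales with the local
consensus/source length ratio.  A QTL outside the shared-marker span is
extrapolated with the terminal interval's scale factor and clamped to the
chromosome bounds.  A chromosome sharing fewer than two markers with the
consensus makes the QTL unprojectable; it is carried through with an
explicit reason and excluded from clustering.  Studies without a published
map are anchored directly through their flanking markers, which are assumed
to delimit the reported CI.

## 4. Mixture meta-analysis

Projected QTL positions on one chromosome follow a 1-D Gaussian mixture
with **known, observation-specific variances**:

    p(x_i) = Σ_k π_k N(x_i; μ_k, s_i²),     s_i = (projected CI width)/3.92

(the 95%-normal-interval convention; the division by 2×1.96 is the standard
assumption of the two-step clustering method, which the source analyses do
not state explicitly).  Only the K component means and K−1 free weights are
estimated, so the parameter count is p = 2K − 1.

**EM.** The E-step computes responsibilities; the M-step updates
μ_k = Σ_i r_ik x_i/s_i² / Σ_i r_ik/s_i² and π_k = mean_i r_ik.  Iteration
stops when the relative log-likelihood gain falls below `tol` (default
1e-8) or at `max_iter` (500).  Ten restarts are run batched: the first from
quantile-spaced means (deterministic), the rest from K data points sampled
at random; the best log-likelihood wins.  On instances small enough to
enumerate, this matches an oracle that seeds EM from every partition of the
points.  Observation sds are floored at 1e-3 cM to keep zero-width CIs
finite.

**Choosing K.** For K = 1..min(K_max, n) (K_max default 20) five criteria
are evaluated:

    AIC  = −2lnL + 2p
    AICc = AIC + 2p(p+1)/(n−p−1)        (undefined when n ≤ p+1; abstains)
    AIC3 = −2lnL + 3p
    BIC  = −2lnL + p ln n
    AWE  = −2lnL_c + 2p(3/2 + ln n)

where lnL_c is the classification log-likelihood under hard assignments
z_i = argmax_k r_ik (the AWE definition of the original clustering software
is undocumented; this classification-likelihood form is the standard one).
Each criterion votes its minimizer; the **modal vote** wins, ties broken
toward the smallest K (parsimony).

**MQTL summaries.** Members are assigned by hard assignment.  The MQTL
position is μ_k; its 95% CI comes from the pooled precision
Var(μ_k) = 1/Σ_i w_ik/s_i², with w_ik the responsibilities (`membership =
"soft"`, default) or 0/1 hard assignments (`"hard"`); with hard weights the
MQTL CI can never exceed its narrowest member's CI.  LOD and PVE are
arithmetic means over members.  Components left empty by hard assignment
trigger a refit at K−1 (flagged).  A member whose projected CI does not
overlap its MQTL's CI is removed and reported as *unintegrated* — the
analogue of initial QTL that real analyses fail to integrate.  Names follow
`MQTL{chromosome}-{rank}` by position.

## 5. Physical anchoring, GWAS validation, screening

The markers flanking the MQTL's genetic CI with known physical positions
define its physical interval ([min bp, max bp], 1-based inclusive); the
*peak* is the linear cM→bp interpolation of the MQTL position between those
anchors (a proxy — the original peak formula is not published in the
emulated analysis).  An MQTL overlapping at least one GWAS marker-trait
association (MTA) — same chromosome, start ≤ bp ≤ end, boundaries
inclusive — is GWAS-validated; hits and distinct GWAS studies are counted.
Overlap is position-only by default; `require_trait_match = True` restricts
hits to MTAs sharing a trait class with the MQTL.

Two screens, all inequalities strict exactly as written:

* **breeder's MQTL**: validated, CI < 2 cM, mean PVE > 10%, ≥ 4 member QTL
  from ≥ 4 distinct studies.  "PVE > 10%" applies to the MQTL's mean PVE.
* **hcMQTL** (high confidence): CI < 1 cM, physical span < 20 Mb, ≥ 5
  member QTL.  The gene-mining region is the whole interval when it spans
  < 2 Mb, else peak ± 1 Mb.

Candidate genes are annotation features overlapping a mining region by any
amount, inner-joined with the ortholog table; one row per (region, barley
gene, source gene), species concatenated when the same source gene is
listed under several species.  BED exports convert to 0-based half-open
coordinates.

## 6. Synthetic data generator

The generator emulates the curated inputs of a barley yield meta-QTL study
so that the whole pipeline can be exercised and scored offline:

* 5 chromosomes of 150 cM / 600 Mb with 120 markers each; the cM↔bp
  correspondence is monotone with a configurable pericentromeric plateau
  (`recomb_suppression`), so loci cluster sub-telomerically in physical
  space;
* population types in proportion 10 BC : 27 DH : 43 RIL with sizes uniform
  in the published ranges (BC 28–301, DH 72–312, RIL 35–300);
* PVE ~ lognormal(median 9%, σ 1.1) and LOD ~ lognormal(median 3, σ 0.35),
  clipped to the observed extremes (0.26–91.32% and 1.02–70.47) — fitted so
  ~46% of PVE mass falls in 3–12% and ~65% of LOD mass in 2–4, the reported
  frequency bins; LOD/PVE are withheld at rate 0.02 (`missing_rate`);
* each QTL picks a true MQTL; its coordinate is expressed **in its own
  study map's frame** (the true position is transferred through the study's
  bracketing markers, as a real QTL coordinate is tied to the study's own
  markers) and scattered by N(0, τ²) with τ = formula-CI/3.92 from the
  record's own n and PVE — so the reported precision matches the actual
  dispersion; the reported CI is the formula width times a lognormal
  distortion (σ 0.15), giving the recalibration stage real work;
* study maps are 50% marker subsamples with iid positional jitter.  The
  default jitter (0.005 cM) keeps inter-map disagreement an order of
  magnitude below the median CI-implied sd (~0.07 cM), the regime of a
  study whose component maps are themselves high-quality consensus maps.
  Because the percent-scale CI formula makes this synthetic world a
  *miniature* (sub-cM CIs instead of tens of cM), all map noise must scale
  down with it for the generated data to remain consistent with its own
  reported CIs;
* MTAs are placed within ±1 Mb of true MQTL (false positives uniform, rate
  0.3); a configurable fraction of true MQTL receive a causal gene within
  ±1 Mb plus an ortholog entry, the rest of the ortholog table is decoys.

Everything derives from one seed; identical (seed, config) gives
byte-identical output files.

**What passing tests show — and don't.**  The generator draws positions
from exactly the heteroscedastic mixture the analysis fits, so recovery
results certify the correctness and calibration of the machinery, not its
robustness to real-data pathologies: correlated QTL from shared parents,
systematic per-study map biases, non-normal position errors, trait-specific
clustering, or mis-specified population sizes.  Two realistic impurities
*are* included — CI distortion and LOD/PVE missingness with the standard
imputation — and the latter measurably degrades K selection (imputed-PVE
records with understated CIs detach as singletons), which motivated the
default CI-recalculation policy in §1.

## 7. Problem sizes and determinism

Default analyses (400 QTL, 5 chromosomes, 20 study maps, 120
markers/chromosome) run in a few seconds; the repeated-dataset recovery
study in `scripts/acceptance.py` uses 50 such datasets, a size chosen to
give ~250 chromosome fits for stable rates while remaining a desk-scale
computation.  All randomness — generator, EM restarts — flows from explicit
seeds; pipeline reruns and stage reruns from persisted intermediates are
byte-identical (tables are written with round-trip float formatting).

## 8. Known limitations

* The feedback-arc heuristic is not guaranteed minimal on large conflict
  sets.
* The AWE formula and the hcMQTL peak are standard-form reconstructions of
  quantities whose exact definitions are not published.
* Position-only GWAS overlap can validate an MQTL with an MTA of an
  unrelated trait; use `require_trait_match` where trait classes for MTAs
  are trustworthy.
* The 530-constant is shared by F2 and BC populations; other designs
  (e.g. F2:3) are not distinguished.
* Extrapolated projections beyond terminal shared markers inherit the
  terminal interval's scale factor, which can distort long extrapolations.
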