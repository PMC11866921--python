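# Methods

This note documents the models, procedures, defaults and known
limitations behind `tpscreen`, in the order the workflow runs them.

## Problem setting

Advanced oxidation of drinking water (UV photolysis, optionally with
H₂O₂ and in the presence of natural organic matter, NOM) removes organic
micropollutants but creates transformation products (TPs) that are
usually unknown, unstandardised, and present at trace level.  The
package implements the data-analysis half of a designed degradation
study: mixtures of parent pharmaceuticals (flecainide, metoprolol,
sulfamethoxazole, phenazone by default) are exposed for 2 h under three
photolytic conditions (U, UH, UHN) at three initial concentrations
(25/75/150 µg/L, 3 replicates), together with single-parent runs
(150 µg/L, n = 2), dark controls and 0 h-exposure counterparts.  The
input to the software is the aligned LC-HRMS feature-group table
produced by upstream feature detection (which is out of scope), plus
MS² spectra, suspect lists and optional reference standards.

## Formula and isotope engine

Molecular formulas are element-count maps over a configured alphabet
(default C/H/N/O/S/F — the elements of the four parents plus oxidation
chemistry; Cl/Br/Si/P remain parseable for candidate filtering but are
excluded from formula generation).  Monoisotopic masses come from an
embedded CIAAW/IUPAC-2021-style table; `[M+H]+` m/z adds 1.007276 Da
(proton mass, electron-corrected).  Positive-mode electrospray is the
only ionisation assumed; the adduct table is the extension point.

Isotopologue patterns are computed per nominal-mass offset by
convolving per-element isotope distributions (exponentiation by
squaring, truncated at the requested offset) and normalising to the
monoisotopic peak — the "agglomerated" form a Q-TOF reports.  The M+2
abundance of all four parents is below 6%, which is what makes the M+2
channel usable for quantifying parents that would otherwise saturate
the detector.  The test suite checks the convolution against an
independent multinomial-enumeration oracle to 1e-6 relative.

## Structure metrics

* **Similarity** (`sim_suspects`): Tanimoto over circular (Morgan)
  fingerprints, radius 2, 2048 bits — the de-facto standard; radius and
  width are arguments.
* **Parent fit** (`fit_compound`): maximum common substructure via
  RDKit's FMCS (connected, element- and bond-order-matched, default 2 s
  timeout; a timeout returns the best-so-far size flagged as a lower
  bound, never silently).  The fit is |MCS| divided by the heavy-atom
  count, taken in both directions; the reported value is the maximum
  (configurable to either single direction).  For small molecules the
  MCS size is verified against a brute-force connected-subgraph
  enumeration oracle.
* **log P**: the Crippen atom-contribution estimator.  It is used only
  ordinally (reversed-phase elution order), which matters because
  estimators disagree in absolute value: Crippen puts flecainide at
  ~3.4 while fragment methods used elsewhere give ~4.5.  Both agree it
  is >1.5 log units above the other parents, and that ordering is the
  only property the workflow relies on.

## Synthetic experiments

The generator (`tpscreen.simulate`) is first-class, tested code.  It
emulates the study design exactly (sample arms as listed above) with:

* parent removal fractions per condition (defaults roughly follow the
  observed magnitudes: high removal ~0.8 for sulfamethoxazole and
  phenazone, low ~0.1–0.3 for flecainide and metoprolol; config values,
  not claims);
* planted TPs with condition-specific molar yields: TP formation (µM)
  = parent removal (µM) × yield, so TP intensity is linear in the
  initial parent concentration — the statistical signature the
  prioritization stage exploits;
* intensities = response factor × mass concentration × multiplicative
  lognormal noise (default σ = 0.1), optionally truncated at a
  saturation cap to exercise the tolerant regression branch;
* background ("noise") features present in *all* samples, 0 h included,
  with concentration-independent intensities (exchangeable across arms;
  a permutation test in the suite confirms it);
* MS² spectra for planted structure TPs generated from the package's
  own bond-breaking fragmenter plus 0.8 mDa jitter, two co-isolated
  background peaks, and a flanking (off-peak) spectrum carrying the
  same background so the background-removal step has real work;
* a ~140-structure drug-like decoy library (scaffold × substituent
  combinations) standing in for database candidate retrieval, and
  exactly linear calibration series encoding the planted response
  factors.

A fixed seed makes every output byte-identical.  What the generator
does **not** emulate: kinetic time courses, matrix/ion-suppression
effects beyond multiplicative noise, RT drift, isotopologue features,
and chimeric MS² beyond the planted background — so green tests show
the algorithms implement their definitions and recover planted truth
under the stated statistical conditions, not that real LC-HRMS data
will be as clean.

## Prioritization

Three composed filters with per-step provenance counts:

1. **Blank subtraction**: a feature survives when its maximum 2 h
   intensity is ≥ k × the mean across matching 0 h samples (default
   k = 5); features absent at 0 h always survive (the rule is ordered
   to avoid division).  Features matching a dosed parent's [M+H]+ are
   exempted and tracked separately — they are quantitation targets, not
   TP candidates.
2. **Replicate filter**: detected in ≥ 2 replicates of at least one
   photolytic 2 h mixture arm.
3. **Concentration regression**: OLS of replicate-mean intensity on
   initial concentration over the photolytic mixture arms (dark
   controls are presence/absence controls and are excluded from the
   series).  Kept iff slope > 0 AND (one-sided p ≤ 0.05 OR R² ≥ 0.7).
   The relaxed-R² branch deliberately tolerates saturation-flattened
   profiles.  Features detected in fewer than two concentration arms
   are excluded outright, which prevents two-point artifacts;
   non-detections inside an included feature count as zero.

Worth noting: with only three concentration levels the one-sided test
has a single degree of freedom, so the blank subtraction — background
chemistry is present at 0 h, planted TPs are not — carries most of the
specificity, and the regression mostly orders/annotates what remains.

## Suspect screening and linking

Suspects are deduplicated across sources on the first (connectivity)
block of the InChI key, merging stereoisomers and unioning source tags;
formula suspects merge on (parent, formula).  "Metabolic logic" formula
suspects apply the configured delta set (+O, +O2, −H2+O, +H2O, −H2,
+H2, +H2O2, −CH2, −C2HF3 by default) to each parent, skipping
infeasible subtractions with a logged reason.  Matching is by accurate
[M+H]+ m/z within ±5 mDa (absolute mDa tolerance throughout, per
Q-TOF practice); structure suspects claim features before formula
suspects, and the remainder are "unknowns" — the three classes
partition the prioritized set, which the reporting layer re-checks.

Suspect-matched features link to their suspect's parent; unknown
features provisionally link to every parent in the mixtures.  The
single-parent experiments then prune: a link (P, F) is removed when F
appears in another parent's single run, unless the mixture intensity
(max across replicates, top concentration arm) is ≥ 5× that single-run
intensity, or F also appears in P's own single run.  Maxima rather
than means are the conservative choice where the rule's operand is not
pinned down.  Pruning decisions are verified against an exhaustive
enumeration oracle.

## MS² handling and annotation

Background removal subtracts flanking-window spectra: a peak is dropped
when a flanking spectrum contains a matching m/z at ≥ 1/2 of its
intensity (factor b = 2), then a 1% base-peak floor applies.  This is a
documented stand-in with the natural interface (precomputed clean
spectra are also accepted).

Formula annotation is exhaustive generate-and-filter over the element
bounds (default C≤20 H≤40 N≤5 O≤8 S≤2 F≤6): ring-double-bond
equivalents ≥ 0 and total-valence parity, sorted by |mass error|; the
suite pins it to a nested-loop oracle.  Fragment peaks are assigned the
precursor subformula whose cation mass (formula mass minus one
electron) is closest within 5 mDa — so a protonated neutral fragment F
is reported as F+H, at identical ion mass.

The fragmenter breaks up to `depth` (default 2) bonds: acyclic bonds
singly, ring bonds pairwise (one depth unit per pair), tracking
fragments as atom subsets so hydrogens stay attached; fragment budgets
overflow to a flagged partial result.  Matching tolerates ±1 H
(rearrangement), the common in-silico compromise.  The compound
annotation score is the intensity-weighted fraction of peaks matched by
the candidate's fragment masses; annotation similarity is the Jaccard
index of assigned-formula sets.  A missing spectrum yields a
distinguished *absent* score, never zero — features without MS² remain
rankable on the remaining metrics.

## Unknown-candidate ranking

Per unknown feature: an element filter (drop Cl/Br/Si/P candidates), an
elution-order filter (drop candidates whose log P difference from the
parent contradicts the observed RT order by more than 2.0 log units;
prediction failures are retained fail-open), then scoring: formula fit
(Σ element-wise minima / candidate atom count), parent MCS fit, maximum
suspect similarity, and annotation score.  The TP score is the mean of
the components that are present (absent components renormalised away;
a weighted combiner is exposed in config).  Thresholds per metric come
from the same metrics evaluated on suspect-matched features —
leave-one-out for the similarity metric, so calibration reflects what
a genuinely novel candidate can attain.  The threshold is the 5th
percentile of the calibration values using the *attained* (lower)
order statistic by default, which guarantees ≥95% calibration retention
for any calibration size; linear interpolation is available by config.
Survivors are cut to the top 25 by TP score with deterministic
tie-breaks (formula fit, then candidate id).  Proposed structures for
formula-annotated features are verified to share the assigned formula
and scored through the same path; note that fragment-mass-only
annotation cannot always separate isomers, so ties are possible and
the guarantee is only that no decoy strictly outscores the truth.

## Identification and quantitation

Confidence levels follow the standard five-level HRMS communication
scheme: 1 standard-confirmed unique structure; 3a standard-confirmed
but isomer-ambiguous (≥2 connectivity-distinct suspects on the
feature); 2 MS² library match (boolean input); 3 (tentative) structure
candidate with annotation support ≥ 0.2 (or prioritized without MS²);
4 single surviving formula; 5 exact mass only.  Sub-levels 3b–d are
collapsed into one tentative class.  Standard confirmation requires
|ΔRT| ≤ 0.1 min, |Δm/z| ≤ 5 mDa, and an isotope-fit score < 100.  The
isotope-fit score is 1000 × the RMS deviation of unit-normalised
abundance fractions over offsets 0–2 — a deliberately simple,
documented stand-in for proprietary pattern-fit scores, scaled so the
conventional <100 acceptance corresponds to ≲10% per-peak deviations.

Calibration lines (unweighted OLS; 1/x weighting by config) are
accepted only with ≥5 points, R² ≥ 0.99 and every |residual| ≤ 30% of
the fitted response; rejected curves cannot quantify and extrapolation
is flagged.  Parents quantify on the M+2 channel; TPs use their own
standard curve when available (provenance "standard") or a predicted
response factor (provenance "predicted", default predictor: the
parent's response factor; per-analyte predictions can be supplied by
CSV).  Predicted concentrations carry a documented factor-5 uncertainty
band.  Removal per condition is 100 × (1 − mean 2 h / mean 0 h) with a
pooled-variance two-sample t-test (two-sided, α = 0.05); single
replicates report removal with significance marked unavailable.

Molar mass balance = 100 × Σ TP µM / parent removal µM.  TPs linked to
several parents cannot be attributed exactly: by default they count
fully toward each parent with an explicit note (an upper bound), or
split equally by config; individual TPs can be excluded from the sum
while staying itemised.  Non-positive or non-significant removal leaves
the balance undefined rather than quoting a misleading ratio.

## Reporting and CLI

Each kept parent/TP link gets an identifier
`<Class>-<PARENT>-M<nominal [M+H]+>-<index>` with class SuS/SuF (matched
structure/formula suspect) or UnC/UnF (unknown, compound/formula
annotation workflow).  The summary tables re-derive every count and
hard-fail on any inconsistency with stage provenance — an accounting
bug detector, not a warning.  The HTML report is self-contained
(base64 PNG abundance plots, disable with `report.plots: false`); the
JSON report carries the same content machine-readably.  The run log
echoes the fully resolved configuration for provenance, and contains no
timestamps so that fixed-seed runs are byte-identical.

## Problem sizes and numerical choices

The bundled demo (`tpscreen run-all --seed N`) uses 4 parents, 13–14
planted TPs and 300 noise features and runs in well under a minute; the
acceptance script scales the prioritization check to 10,000 noise
features and ~50 planted TPs and verifies ranking over ~145 candidates
per feature for 11 features — sizes chosen so that the statistical
claims are meaningful while the whole reproduction stays interactive.
Ties everywhere break on deterministic keys; degenerate inputs (empty
tables, zero-variance responses, features absent from all 0 h samples,
empty flanking sets, zero removal) are all defined cases with tests.

## Known limitations

* Only `[M+H]+` positive-mode ionisation by default; acidic TPs that
  ionise negatively are invisible to the default configuration.
* Linear intensity–concentration prioritization will miss TPs governed
  by strongly nonlinear kinetics; the relaxed-R² branch only cushions
  mild saturation.
* The fragmenter ignores rearrangements beyond ±1 H and scores by mass
  only, so isomer discrimination is weak by construction.
* No matrix-effect correction; semi-quantitative balances inherit the
  factor-5 response-factor band and should be read as indicative.
* The isotope-fit score is not bit-compatible with any vendor
  implementation; only its acceptance behaviour is comparable.
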