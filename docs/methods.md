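# Methods

## Experimental design assumed by the pipeline

The pipeline models a multiplexed TMT experiment with three omics layers
measured from the same biological samples: protein abundance (proteome),
cysteine oxidation via sequential iodoTMT labeling (redoxome) and
phosphorylation (phosphoproteome). The default design is 3 LC-MS runs ×
4 biological replicates = 12 replicates and two exposure time points
(4 h, 24 h), with the treated and control sample of each replicate
multiplexed into the same TMT mix. Redoxome mixes are assembled per time
point and carry each sample twice: once labeled at the TMT1 stage (free
thiols, labeled first) and once at the TMT2 stage (reversibly oxidized
thiols, labeled after reduction). Consequently the TMT1 channels report
the *reduced* cysteine pool — their fold changes are sign-inverted
downstream so that "up" means "more oxidized" — and the TMT2 channels
report the reversibly oxidized pool directly. Irreversible oxidation is
signal absent from both labeled pools and is not quantified.

Input is the peptide-isoform level export of a search engine (one row per
peptide isoform per mix, one intensity column per channel). PSM scoring,
protein inference and shared-peptide (razor/unique) resolution are
upstream concerns: each row carries exactly one protein accession.
Missing intensities are encoded as empty cells and are never zero; a
measured zero is excluded from ratio computation instead of being
imputed.

## Statistical chain

Per analysis layer (proteome, ox_all, ox_rev, phospho) and time point:

1. **Impurity correction.** Observed channel vectors are corrected by
   solving *M x = o* with the reagent impurity matrix *M* (entry (i, j) =
   fraction of channel j's signal read in channel i). The solve is
   restricted to the observed channels' submatrix — bleed-through from an
   unobserved channel is not modeled rather than imputed — and negative
   solutions are clipped to 0 and counted in the log. The correction
   refuses ill-conditioned matrices (condition number > 1e12).
2. **Site rollup.** A site's intensity is the sum of all peptide isoforms
   containing it; a peptide carrying k sites contributes its full
   intensity to each of the k sites. No stoichiometric splitting is
   attempted: the data do not resolve which cysteine of a two-cysteine
   peptide changed, and any apportioning rule would invent information.
   Site intensities are therefore not additive across sites of a protein.
3. **Fold changes.** log2(treated/control) within each replicate's mix,
   per time point. A replicate's value is missing if either side is
   missing or zero.
4. **Filter.** Entities quantified in ≥ 3 replicates are kept (the
   "reliably quantified" subset). The threshold is a parameter
   (`min_replicates`), floor 1.
5. **Median normalization.** Each replicate column is centered at zero
   median over the layer's entities. The alternative reading (centering
   per entity) would remove the effect under test and is not offered.
6. **PTM-to-protein normalization.** Site log2 FC minus the parent
   protein's log2 FC in the same replicate, preserving replicate-level
   variance for the t-test. Sites whose parent protein is not quantified
   in the proteome are dropped and counted.
7. **Inversion of ox_all.** The TMT1-derived fold changes are negated so
   positive means increased overall oxidation. The operation is guarded
   by a provenance flag so it cannot run twice in one pipeline.

   *Order of 6 and 7.* Protein normalization is applied **before**
   inversion. The free-thiol signal scales with protein abundance exactly
   as the proteome does, so the abundance component must be subtracted on
   the un-inverted scale: for a pure abundance change d, site FC = d and
   normalized FC = d − d = 0, after which inversion changes nothing.
   Inverting first and then subtracting would turn a pure abundance
   change into a spurious −2d. The two orders are indistinguishable for
   the non-inverted layers.
8. **Testing.** Two-sided one-sample Student t-test of the replicate
   log2 FCs against 0 (df = n − 1), Benjamini–Hochberg step-up across all
   tested entities of the layer × time point, significance at FDR ≤ 0.05
   (`alpha` parameter). Entities with zero variance across replicates
   have no defined t statistic; they are reported with p = NaN, excluded
   from the BH family and never flagged significant. No moderated or
   shrinkage variance estimation is used — the plain t-test is the method
   under study. BH and the t statistic are implemented in-package;
   scipy provides only the t distribution's survival function.

## Enrichment, dynamics, overlap, annotation

**Over-representation.** Significant entities are collapsed to gene
symbols via a user-supplied accession→symbol map (sites through their
parent accession). Each gene set of a GMT collection intersecting the
universe is tested with the one-sided hypergeometric upper tail
P(X ≥ k); the universe is the set of reliably quantified genes of the
analyzed scope (one layer, the combined oxidation scope, or the union of
all layers for the integrative analysis) — not the whole genome, which
would inflate enrichment through detection bias. BH runs across all sets
tested in a collection per scope and time point. Direction of regulation
is the sign of the median log2 FC of the significant members assigned to
the set, pooling protein- and site-level values in integrative scopes so
PTM effects can dominate direction. GO cellular-component collections
are used for membership mapping only (no test).

**Dynamics.** Mean log2 FCs of entities present at both time points are
correlated (Pearson; two-sided p from t = r √((n−2)/(1−r²)), df = n−2),
separately for entities significant at ≥ 1 time point ("significant";
switchable to "both") and at neither ("not_affected"), with the
least-squares trendline reported. Fewer than 3 pairs yields a flagged,
non-computable result.

**Overlap.** Proteins are classified by which layers carry significant
changes (protein level; any oxidation site in ox_all ∪ ox_rev; any
phosphorylation site). The seven non-empty Venn classes partition the
union of significant proteins; "multiply modified" means significant
oxidation and phosphorylation.

**Annotation.** Significant-site tables are left-joined against a flat,
user-exported table of known modified cysteines and disulfide partners;
no live database access, so results are reproducible offline. Sites
without a row are reported as not previously described.

## Synthetic-data generator

The generator emulates the assumed design at desk scale. Per biological
sample, noise-free signals are

| layer | peptide signal |
|---|---|
| proteome | A · e |
| redox TMT1 | A · e · Σ_sites (1 − f) |
| redox TMT2 | A · e · Σ_sites f |
| phospho | A · e · occ |

with A the protein's abundance (log2-normal, mean 20, sd 2 — arbitrary
reporter units), e a per-peptide ionization efficiency (log2-normal,
sd 1), f the cysteine's reversibly oxidized fraction and occ the
phospho-site occupancy. Treatment multiplies A by 2^δ_protein and f (or
occ) by 2^δ_site for affected entities. Baseline f is drawn uniformly
from (0.05, 0.6), occupancy from (0.05, 0.5); for positively affected
sites the baseline is drawn so that f·2^δ < 0.95, which keeps the model
exactly invertible (no clipping). Defaults: 500 proteins, ~Poisson(3)
peptides per protein, ~Poisson(1.2) cysteines and ~Poisson(1) phospho
sites per protein, 10 % of entities affected per effect class with
|δ| = 1 log2 and random sign (the same entities and signs at both time
points, so planted effects persist across time), multiplicative
log-normal noise of sd 0.2 log2 units per (peptide, channel), 5 % of
peptide rows deleted per mix completely at random, and nearest-neighbour
channel bleed of 2 % mixed in forward so the correction step has real
work. A configurable fraction of cysteine peptides carries a second
cysteine of the same protein (default 15 %), exercising the rollup
ambiguity.

Ground truth records every planted effect and, per rolled-up entity, the
**model-implied** noise-free log2 FC on the pipeline's reporting scale —
for multi-cysteine peptides the rollup mixes sites, so the implied value,
not the planted δ, is what a perfect measurement would report. Recovery
metrics (bias, RMSE, sensitivity at FDR ≤ 0.05, realized false discovery
proportion) are computed against these implied values. Note that the
TMT1 readout intrinsically compresses effects: a δ on the oxidized
fraction appears in ox_all as −log2((1 − f·2^δ)/(1 − f)), which is well
below δ for typical f. Detection power for ox_all is accordingly lower
than for ox_rev at the same planted δ; this is a property of the
free-thiol measurement, not of the statistics.

When a planted pathway is configured, one gene set's members receive
elevated effect probability and the remaining sets are drawn from
non-planted genes, so they are true null pathways for the
false-discovery accounting.

What the generator does **not** emulate: intensity-dependent
missingness (missingness is completely at random; the pipeline's only
missingness handling is the replicate filter), shared peptides across
proteins, isotope-envelope structure beyond the linear impurity matrix,
retention-time or acquisition effects, and correlated biological
covariance between layers beyond the shared abundance factor. Passing
tests therefore demonstrate correctness of the computation under the
stated model, not robustness to those real-data phenomena.

## Validation studies and problem sizes

The acceptance studies (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use these sizes, chosen to keep Monte-Carlo
error well below the margins being checked: 10 000 random p-vectors of
length ≤ 12 for the BH oracle (tolerance 1e-12, against an O(m²)
definitional implementation), 400 t-tests for n = 3..12 against a
numerically integrated t density (1e-9), 2000 hypergeometric instances
with N ≤ 12 against exhaustive enumeration (1e-12); 200 global-null runs
of 2000 proteins × 12 replicates for FDR calibration (realized FDP vs
0.05 + 2·MC-SE, pooled Kolmogorov–Smirnov uniformity); 5 runs of 400
proteins with |δ| = 1, σ = 0.2 for effect recovery (|bias| < 0.05,
sensitivity ≥ 0.9 on the layers whose reporting scale carries δ
directly — see the compression note above); 100 runs for planted-pathway
detection (≥ 95 % at FDR ≤ 0.05, null-set FDP ≤ 0.05 + 2·MC-SE); and a
double pipeline run checked for byte-identical outputs.

## Numerical and encoding choices

UTF-8 TSV without quoting; floats written at 9 significant digits, so
write/read round-trips are exact to that precision. Site positions are
1-based on the canonical protein sequence (UniProt convention), rendered
as residue letter + position (C105, S536). Ties in BH are handled by the
standard step-up (stable mergesort); the median of an even member count
can be exactly 0, which the direction call reports as "mixed-zero"
rather than forcing a side. Degenerate inputs (empty design, empty gene
sets, all-missing columns, zero-variance entities, n < 3 correlation
subsets) fail loudly or are flagged, never silently defaulted.
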