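# Methods

## The stepwise duplex-formation model

A miRNA represses a transcript by binding its 3′UTR. `mirthermo`
scores candidate binding sites by the free-energy balance of a
two-step process: the mRNA first opens its local secondary structure at
the site (disruption energy ΔG_open), then the miRNA hybridizes to the
exposed bases (hybridization energy ΔG_H). The total change

    ΔΔG = ΔG_H − ΔG_open        (kcal/mol; lower = better target)

is the primary site score. Because ΔG_open ≤ 0 by construction
(it is RT·ln of a probability), subtracting it penalizes sites buried
in stable structure.

### Candidate sites

Any UTR position with a perfect Watson–Crick 4-mer complement (the
duplex *nucleus*) to the miRNA seed region (positions 2–8, 1-based from
the 5′ end) is a candidate; the nucleus may start at positions 2–5.
G-U wobbles are mismatches both here and in seed typing — wobble-rich
matches are handled by the energy model, not the match definition.
UTR coordinates are 0-based half-open; miRNA positions are 1-based so
"positions 2–8" reads as in the miRNA literature.

### Hybridization energy

For each nucleus the UTR context is the 4-mer plus flanks of up to
twice the length of the corresponding remaining miRNA arm on each side
(the miRNA 5′ arm faces the downstream flank, antisense). The flank may
extend into the upstream CDS when the site sits near the stop codon.
Longer context would only accumulate intramolecular structure that does
not describe the binding event. The miRNA and context are cofolded with
the four nucleus pairs constrained. If the returned structure leaves a
nucleus base unpaired or contains any intramolecular pair, the
structure is *repaired* — nucleus pairs enforced, all intramolecular
pairs removed, other intermolecular pairs kept — and re-evaluated; the
repair is idempotent. "Intramolecular" is read as any within-molecule
pair, in either molecule.

### Disruption energy

ΔG_open uses local folding with window size W = 80 nt, maximum pair
span L = 40 nt and open-region length u = 20 nt, at T = 310.15 K
(RT = 0.6163 kcal/mol). Temperature is exposed in
`ThermoEngineConfig`; 37 °C is the folding default and the intended
organism is human. For every placement of the u-length open region that
fully contains the 4-mer nucleus (17 placements for an interior site),
a window of exactly W nt centered on the open region is extracted —
shifted inward at sequence ends, shrunk only when the whole sequence is
shorter than W — so the engine reports the exact single-window
unpaired probability. Each probability is converted by RT·ln(P) *before*
averaging: the expectation of a log is not the log of an expectation.
Probabilities are floored at 1e-12 before the log; an exact zero is an
engine artifact, not physics. A config switch (`windows_over="span"`)
instead slides the open region over the whole extracted duplex span;
the nucleus reading is the default because the match site is defined by
its 4-mer. A second switch (`flank_rule="symmetric"`) is reserved for
sensitivity analysis of the arm-specific flank rule.

### Seed taxonomy and filters

Each site's seed type is the highest-priority label its maximal
complement to positions 1–8 supports, in the fixed order
8mer > 7mer-A > 7mer > 6mer > 7in8 > 6in8 > 5mer > 5in8 > 4mer.
Consecutive classes (k-mer) require unbroken WC runs within positions
2–8 (the 8mer adds position 1); 7mer-A is the full 2–8 run plus an
adenine across position 1; gapped classes (k-in-8) count pairs anywhere
in 1–8, with an A across position 1 counting as a pair. UTR positions
that fall off either end score as mismatches rather than raising.
Filters: `6mer` keeps {8mer, 7mer-A, 7mer, 6mer}; `6in8` adds
{7in8, 6in8}; `4mer` keeps everything — nested by construction.

Overlapping nuclei of one miRNA–UTR pair (transitive closure of 4-mer
interval overlap) are represented by their minimum-ΔΔG member; ties
break by position so output is reproducible. Sites shared verbatim
between isoforms of one gene (same nucleus, same energies) are counted
once; context differences that change the energies keep both.

## Thermodynamics engines

The engine contract has three primitives: constrained bimolecular
folding, fixed-structure evaluation, and single-window unpaired
probability. Two implementations ship:

- **ViennaEngine** — the ViennaRNA bindings. Cofolding constrains the
  nucleus with hard base-pair constraints; unpaired probability is the
  partition-function ratio exp(−(F_open − F_free)/kT) of the
  constrained (region forced unpaired) and free folds of the W-window
  with pair span capped at L.
- **ToyEngine** — deterministic pair counting (WC −1.0, G-U −0.5
  kcal/mol, no intramolecular pairs) with either a constant unpaired
  probability or, in `"au"` mode, a logistic function of the open
  region's AU fraction plus a GC-context modulation (±15 %) of pair
  energies. The AU mode exists because a constant P makes every
  accessibility feature constant — degenerate for model fitting — and
  because coarse quantized pair energies make the ΔΔG and ΔG_H site
  rankings coincide exactly, which would duplicate feature columns.
  Both effects have real counterparts (AU-rich regions are more open;
  nearest-neighbor stacking varies continuously), but the toy values
  are not thermodynamic: they make the pipeline testable in
  milliseconds, nothing more.

## Shuffled-miRNA controls

Negatives for site-level evaluation come from shuffled miRNAs: the
start base is drawn from the miRNA's mononucleotide frequencies and the
sequence is extended by consuming the miRNA's own dinucleotide multiset
(uniform among remaining instances whose second base is still in the
mononucleotide budget, which makes composition conservation exact). If
the walk strands fewer than 15 % of the bases, the leftovers are
inserted at uniform random positions (including the seed region — the
conflict filter re-checks afterwards); otherwise the attempt is
retried. Shuffles whose positions 2–8 equal any known miRNA seed
heptamer, or whose first 8 bases contain a poly-A motif (AAAAAA,
AAUAAA), are rejected; "overlap" with known seeds is read as exact
heptamer identity, with an optional stricter 6-mer (positions 2–7)
mode. Each accepted shuffle is paired with 10 UTRs drawn without
replacement (10 shuffles per miRNA), and one match site per control
pair is sampled uniformly as the control site. All randomness flows
from one seeded generator.

## Per-UTR features and the linear model

The 14 features are: best and second-best ΔΔG and ΔG_H (minimum = most
favorable), best and second-best ΔG_open (*maximum* = most accessible —
true sites sit in open regions, so accessibility closer to zero is
"best"), ΔG_H and ΔG_open read off at the best and second-best ΔΔG
sites, the three per-type sums over all sites, and UTR length (longer
UTRs accumulate chance matches). Genes with fewer than two sites get
zeros for the affected features so every gene stays scorable; sums use
compensated summation so feature vectors are exactly invariant to site
order.

Three exact linear identities hold by construction:
`sum_ΔΔG = sum_ΔG_H − sum_ΔG_open`, and the per-site identity
ΔΔG = ΔG_H − ΔG_open read off at the best and at the second-best ΔΔG
site. The design matrix therefore has a three-dimensional null space;
OLS (statsmodels) fits through the pseudoinverse with a warning, and
only coefficient vectors orthogonal to the null directions are
identifiable. All 14 features are always fitted — excluding redundant
ones is a modeling decision left to the fitter, not the feature
builder.

Training keeps pairs with observed log2FC ≤ 0 (positive changes are
dominated by indirect effects); a −0.1 cutoff re-training sheds
near-zero noise. Evaluation is 5-fold cross-validation with folds
split at the *gene* level (each test fold contains rows from all
miRNAs but no gene seen in training), scored by Spearman rank
correlation of held-out predictions. De novo scores are the median of
the five fold models, applied to all genes including up-regulated
ones; lower score = stronger predicted down-regulation. No
regularization — plain linear regression is the point; models
serialize losslessly to JSON.

## Evaluation machinery

Site level: ROC over all distinct score cutoffs; AUC equals the
Mann–Whitney U statistic normalized by n_pos·n_neg with ties counted ½
(tested against a brute-force pairwise oracle), so it is invariant
under monotone transforms. Group differences use the Wilcoxon rank-sum
test (normal approximation, tie-corrected; the all-tied degenerate case
returns p = 1). Paired empirical CDFs export on the merged value grid.

Gene level: genes rank ascending by score (ties break by gene id);
enrichment at top-N (N = 50, 100, …, truncated at the gene count, final
point = full set where enrichment is exactly 1) is the bona fide
fraction in the top N divided by the overall bona fide fraction, with
bona fide = observed log2FC ≤ cutoff. The canonical 6-mer baseline is
the same ratio among genes carrying ≥ 1 canonical-6mer-or-better site;
on a set restricted to such genes it is exactly 1. The machinery
consumes any labelled score table — dataset construction is the
caller's concern.

## The synthetic cohort

`fixtures.synthetic_cohort` emulates a single-miRNA transfection study:
UTRs with log-normal lengths (median ≈ 245 nt, clipped to 60–800 nt —
shorter than the human median, chosen to keep full-cohort studies fast
while leaving multiple sites per UTR), base composition A/C/G/U =
0.3/0.2/0.2/0.3, a planted 8mer in 10 % and a planted 6in8 in 10 % of
genes (each planted window is verified through the seed classifier,
with mismatch bases chosen so no accidental upgrade is possible), and
responses

    log2FC = intercept + Σ βᵢ·featureᵢ + N(0, 0.2).

The transfected miRNA is fixed (a let-7a-like 22-mer) rather than
drawn per cohort: a random miRNA's seed composition shifts every
gene's response together, a batch-like effect that array normalization
removes in real data. The ground-truth β (favorable energies →
down-regulation; small negative length effect) lies in the identifiable
subspace — each (ΔΔG, ΔG_H, ΔG_open) triple satisfies
β_ΔΔG − β_ΔG_H + β_ΔG_open = 0 — and the intercept (1.75) centers the
cohort's log2FC near zero so that conventional bona fide cutoffs
(−0.3, −0.4) select a down-regulated tail instead of the bulk.

What the cohort does *not* emulate: real nearest-neighbor
thermodynamics (toy engine), 3′-supplementary pairing, expression-level
heterogeneity between transcripts, indirect regulatory effects, and
isoform structure. One visible artifact: planted strong-seed windows
are GC-rich for a GC-containing seed, so under the toy AU-accessibility
rule they are *less* accessible than background — the accessibility
direction on synthetic data is an engine artifact. The accessibility
claim itself (identical duplex, worse total energy inside a hairpin
stem) is tested directly against the ViennaRNA backend instead.
Passing tests on the cohort therefore demonstrate the correctness of
the machinery — energies, bookkeeping, fitting, calibration — not
biological accuracy on real UTRs.

## Numerical and design notes

- Energies are computed at full precision and serialized at 2 decimals.
- Overlap grouping is transitive over chains of overlapping 4-mers;
  per-chain best-ΔΔG selection with positional tie-breaks.
- `resolve_overlaps` runs before seed filtering, so a filtered scan
  still scores overlaps among all candidates first.
- P_unpaired = 0 floors at 1e-12; unpaired probability of an empty
  region is 1 by contract.
- OLS rank deficiency warns and falls back to the minimum-norm
  pseudoinverse solution; a ridge flag exists for degenerate fixtures
  only.
- The acceptance study (`scripts/acceptance.py`) uses 1,000 genes, 25
  miRNAs × 200 shuffles for conservation statistics, and the toy AU
  engine — sizes chosen so the whole study reruns in seconds while
  every statistic is stable to the reported precision across seeds.

## Known limitations

- No 3′-supplementary pairing (positions 13–16) and no centered-site
  class; such sites appear only insofar as they contain a seed-region
  4-mer nucleus.
- The exact set of sliding windows the disruption average should cover
  is ambiguous in principle; both readings are implemented, defaulting
  to windows over the nucleus.
- Tarbase/PAR-CLIP/microarray dataset construction is out of scope; the
  evaluation operations consume any labelled score tables.
- The Vienna adapter cofolds through the concatenated-sequence
  interface; pseudoknots and temperature series are unsupported.
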