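# Methods

## Model and procedure

`succmap` analyzes two-group (case/control) succinylome experiments
given two label-free quantification tables: succinyl-lysine site
intensities `x_is` (site *i*, sample *s*) and host-protein intensities
`a_ps` (protein *p*). The analysis assumes intensities are already
normalized between runs (no between-sample normalization is applied)
and that measurement noise is log-normal, the standard LFQ error model.

**Pseudo site occupancy.** The corrected value `occ_is = x_is / a_p(i),s`
divides the site by its host protein *within the same sample*. This
makes the statistic invariant to per-sample global scaling applied
jointly to both tables and removes protein-abundance changes from
site-level fold changes. Zero intensities are coerced to missing on
input (log-undefined); a zero protein denominator likewise yields a
missing corrected value. Sites whose protein was not quantified are
dropped by default, or passed through uncorrected (flagged
`corrected=False`) under the `passthrough` policy.

**Differential testing.** Per site, `log2FC` is the difference of group
means of `log2 occ`. Sites need at least two observed values per group
to be testable; untestable sites are reported with empty p/q, never
silently removed. The default test moderates the per-site pooled
variance with an empirical-Bayes scaled inverse-chi-square prior fitted
across all testable sites by the method of moments on `log s²`
(trigamma inversion by Newton iteration); the t statistic then carries
`d0 + df` degrees of freedom, and an infinite prior df collapses to a
common-variance z-test. At the n = 2–3 per group typical of these
experiments, per-site variance estimates are far too unstable to test
against directly: Welch's test in particular loses its Satterthwaite
degrees of freedom to sampling noise and tops out near 83% sensitivity
under the recovery conditions used in the acceptance checks, whereas
moderation reaches ~94% at the same empirical FDR. Plain pooled
(`test="pooled"`) and Welch (`test="welch"`) engines remain available;
the scalar `welch_test` implements the textbook Welch/Satterthwaite
formulas with explicit degenerate policies (both variances zero: p = 1
when means agree, p = 0 flagged degenerate otherwise).

Benjamini–Hochberg adjustment is applied once across all testable sites
of an experiment (separate experiments — e.g. fibroblasts and myotubes
— are analyzed separately). A site is called hyper-succinylated when
`log2FC > 1` **and** `q < 0.05`, both strict inequalities, both
thresholds configurable.

**Site statistics.** Sites-per-protein counts feed a histogram and a
top-N list; the abundance-corrected density `n_sites / abundance` uses
the mean protein intensity over *control* samples as the abundance
(user-overridable), with ties broken lexicographically by accession so
ranking is deterministic and scale-invariant. The set-level rank test
is the two-sided Wilcoxon rank-sum of a target protein set against its
complement: exact enumeration when the smaller group has ≤ 8 members
and values are tie-free, otherwise the normal approximation with tie
and continuity correction (one-sided available via flag). The
fold-change ANOVA is one-way across proteins with ≥ 3 sites each
(`min_sites` configurable), with Tukey HSD — Tukey–Kramer for unequal
group sizes — for all pairwise comparisons; groups with zero total
variance return the degenerate p = 1.

**Enrichment.** For each annotation term, the one-sided Fisher exact
p is the hypergeometric upper tail P(X ≥ k) of the 2×2 table
(k, n−k; K−k, N−K−n+k). The background defaults to all proteins
detected in the experiment's protein table — not the whole annotation —
to avoid silent background drift. Annotations are used as given (direct
terms only; no ontology propagation). BH is applied across terms.

**Cross-species transfer.** Orthologue pairs are aligned once with an
in-package global Needleman–Wunsch–Gotoh aligner: BLOSUM62, affine gaps
costing `10 + 0.5·(L−1)` for a gap of length L, end gaps penalized
(EMBOSS-needle defaults; the original studies specify no parameters, so
the conventional deterministic choice is fixed here). The dynamic
program is row-vectorized (match and gap-in-B states from the previous
row; the in-row gap-in-A state via a running prefix maximum), and the
traceback is deterministic with tie order residue-pair, then gap in B,
then gap in A. Residues outside the matrix alphabet score as 'X'. A
site transfers to the B position aligned to it; it is unmapped when it
faces a gap or (by default) when the aligned residue is not lysine. A
*matched* site additionally requires study B to report that exact
position — no ±window tolerance. Protein pairing uses an explicit
two-column ortholog map, or case-insensitive identifier equality
without one; many-to-many rows resolve to the highest alignment score
with a logged warning. Overlap reporting counts proteins with at least
one site in both studies, matched sites, the Pearson r² of per-protein
site counts over common proteins (raw counts by default; log10 via
flag), and per-protein median fold changes over matched sites only.

## Synthetic data

The generator emulates the statistical structure of an SCL-deficiency
succinylome: on the log2 scale, protein abundance ~ N(20, 2), site
offset ~ N(−3, 1) (sites sit well below their host protein), a group
effect of `effect_log2` (default 2) added to case samples of affected
sites (default 95% of sites), `protein_effect_log2` (default 0 — a flat
proteome) added to case protein intensities and inherited by their
sites, and i.i.d. Gaussian noise. Site-level noise defaults to
`noise_sd_log2 = 0.4` (~30% CV, typical of single-peptide PTM
quantification; the studies report no variance estimates, so this is a
generator choice). Protein-level noise defaults to
`protein_noise_sd_log2 = 0.15` (~10% CV): protein quantities aggregate
many peptides and are substantially more precise than site-level
values, and this asymmetry is what makes dividing by the protein a
net win rather than a noise amplifier. Sites-per-protein follow a
geometric distribution (mean 2.5, capped at 27); the default design is
2 control vs 3 case samples. Cells are masked missing completely at
random at rate 0.05 — intensity-dependent (MNAR) missingness is
deliberately not modeled, so passing tests say nothing about
left-censored missingness in real data. Random protein sequences
(length 150–450) carry planted lysines at the site positions. A single
RNG per call is consumed in fixed order (per-protein draws, per-site
draws, noise matrices row-major, missing masks), so a seed fully
determines the output.

`simulate_ortholog` mutates a sequence with per-residue substitutions
(uniform over the 19 alternatives) and geometric(0.5) indels capped at
length 3 — short enough that optimal alignments are essentially
unambiguous at these rates — never touching a declared set of preserved
positions, and returns the exact residue correspondence as ground truth
for the transfer machinery. The pipeline's synthetic "second study"
derives an orthologue per protein (site lysines preserved), detects 80%
of affected sites at their true mapped positions, and scales their fold
changes by 0.6 (noise sd 0.3), emulating a weaker perturbation measured
in another organism.

What the generator does not emulate: peptide-level identification,
shared peptides, MNAR missingness, between-run drift, or correlated
noise within proteins. Recovery results on synthetic data therefore
bound what the statistics can do under their own assumptions, not
performance on raw mass-spectrometry output.

## Numerical choices and scales

Alignment scores are multiples of 0.5; traceback compares with a 1e-9
tolerance. BH is statsmodels' step-up implementation, checked against
the closed-form `min_{j≥i} p_(j)·m/j` in the tests. The acceptance
script runs the study-scale pipeline at 366 proteins (~930 sites, 2+3
samples), calibration at ~2,000 sites × 20 replicates (null, 4+4) and
~400 sites × 20 replicates (recovery, 3+3), 50 random alignment pairs
(length ≤ 40) against an independent optimal aligner, and 20 orthologue
pairs (length 300, substitution rate 0.05, indel rate 0.01, 10
preserved lysines each) — sizes chosen so the whole run completes in
well under a minute while Monte-Carlo error stays a few percent.

## Known limitations

* The moderated test assumes exchangeable variances across sites; with
  strongly heteroscedastic real data the `welch` engine is the
  conservative fallback.
* Orthology is taken as given (map file or identifier equality); no
  orthology inference, and paralogs are disambiguated only by alignment
  score.
* The Fisher enrichment reproduces the test, not any specific web
  tool's background or term universe; enrichment p-values are only as
  meaningful as the supplied annotation and background.
* `corrected_site_density` requires positive abundance; proteins
  lacking it are excluded with a flag rather than imputed.
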