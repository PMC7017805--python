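# Methods

## Scope and data model

`kynet` analyzes small plasma-marker cohorts: per sample, seven
kynurenine-pathway (KP) metabolite concentrations (TRP and KYN in µM,
KYNA, 3-HK, 3HAA, AA, XA in nM) and a panel of immune proteins on the
NPX log2 scale, with group labels (HC = healthy control, PRE = patient
before treatment, TRM = same patient during MAPK-inhibitor treatment)
and optional PRE↔TRM patient pairing. All concentrations are converted
to nM at load (µM → ×1000, exact and invertible); NPX columns are
unitless and untouched. Marker classes (metabolite vs protein) come from
the input schema, never from name guessing.

## Group statistics

Per-marker two-sample t-tests compare groups. The default is Welch's
unequal-variance t — at n = 5 per group with visibly unequal spread a
pooled variance is hard to defend — with Student's pooled t available by
flag. Correction is Bonferroni, `p_corr = min(1, m·p)`, where `m`
defaults to the number of markers tested in that comparison (7 for the
metabolite panel) and is overridable. Per-group 95% CIs are t-intervals
(`mean ± t(0.975, n−1)·sd/√n`). Markers constant in both groups have no
defined t; they are reported NaN and flagged rather than dropped, except
that two *equal* constants are reported as t = 0, p = 1 (no evidence of
difference). 

Ratio indices — KYN:TRP (IDO activity), 3-HK/KYN (KMO branch flux),
XA/3-HK (transamination toward xanthurenic acid) — are computed
per sample on the canonical nM scale. A sample with denominator ≤ 0 is
flagged undefined and excluded from that ratio's group mean with a
warning and a count; nothing is imputed.

PCA (for confounder screening) pools the groups, centers and by default
autoscales markers to unit variance (the panels mix nM and NPX scales),
and decomposes by SVD. Constant markers cannot be autoscaled and are
dropped with a warning.

## Network inference

For one group, the Spearman matrix is the Pearson correlation of
average-ranked columns (tie-safe; a constant marker's correlations are
stored as 0 and the marker flagged, never NaN-propagated). The network
at cutoff τ has an edge for every pair with `|ρ| ≥ τ`, carrying the
signed ρ as weight; markers with no retained edge are excluded.

τ is chosen by the fragmentation rule: scan a descending grid (default
0.95 … 0.05, step 0.05) and return the highest cutoff at which the graph
restricted to non-isolated markers has exactly one connected component.
Dropping isolated markers first is the default because observed node
counts in this kind of panel analysis sit below the full panel size
(81–82 nodes from 99 markers); a strict mode requiring *every* marker in
the single component is available by flag. If no grid value qualifies
the smallest is returned with a fragmentation warning. Note the regime
matters: with n = 5 samples Spearman ρ is highly discrete and many pairs
tie at high |ρ|, so the scan typically terminates at a high cutoff with
a dense single component; with larger n and continuous data the
non-strict rule can terminate as soon as a single strong pair appears.
The edge rule is thresholding on |ρ|, not a significance filter: at
n = 5, p < 0.05 would already force |ρ| ≳ 0.9, which is incompatible
with cutoffs near 0.5 that this style of analysis reports; a
significance filter is therefore an optional flag, off by default.

Summaries follow fixed conventions, stated here because tools differ:
median degree uses the midpoint convention; average clustering is the
mean over nodes of local clustering with degree-<2 nodes contributing 0
(Cytoscape-compatible); hubs are nodes whose degree **strictly** exceeds
the q-th percentile (default q = 80) of the degree distribution, with
the percentile computed by linear interpolation; hub lists sort by
degree descending, ties alphabetical.

## Network comparison

The edge-count permutation test reassigns pooled samples to the two
groups at random (preserving group sizes) and rebuilds both networks per
permutation — the permutation unit is the sample, the data-generating
unit. τ stays fixed at the value selected on the observed data (the
analysis applies one cutoff to both networks); per-permutation
re-selection is not performed. The statistic is `edges(B) − edges(A)`;
`p = (b+1)/(B+1)` with `b` the number of permuted statistics at least as
extreme in the direction of the `alternative` ("greater" by default,
"less"/"two-sided" available), so p is never 0. The default is a fixed
upper tail, not "the direction of the observed sign": a sign picked by
the data doubles the type-I error and would break the 5% calibration
this test is required to have. An exact mode enumerates all label
assignments for small cohorts.

Degree distributions are compared with the two-sample Kolmogorov–Smirnov
test, asymptotic p by default (degree samples here have tens of points),
exact by flag. Hub overlap partitions the two hub sets (shared, A-only,
B-only) and intersects each part with a differential-marker list, which
the pipeline takes from the between-group comparison at corrected
p ≤ 0.05.

## Synthetic cohorts

The generator states a world and sticks to it:

- **Groups**: HC, PRE, TRM; n = 5 per group by default. PRE and TRM
  share patient ids; HC is unpaired.
- **Metabolite marginals**: zero-truncated normals with per-group means
  taken from the published group table, and sds derived from its 95% CIs
  by inverting the t-interval: `sd = half_width·√5 / t(0.975, 4)`
  (the only dispersion information available; asymmetric intervals use
  `(hi−lo)/2`). Truncation is implemented as the inverse-CDF transform
  of the truncated normal — equivalent in distribution to
  redraw-until-nonnegative, but rank-preserving. For these parameters
  the truncation mass is negligible, so means are preserved to well
  within Monte-Carlo error.
- **Protein marginals**: normal on the NPX scale, default mean 6, sd 1
  for every marker and group — mid-range for log2 immunoassay panels,
  where single-condition plasma NPX values commonly sit between roughly
  2 and 10 with near-unit spread. Per-group mean shifts are available
  (`protein_group_shift`) but default to none: the default world encodes
  *no* protein-level treatment effect.
- **Dependence**: Gaussian copula with a block-structured latent
  correlation matrix — `r_within` inside each block, `r_between` across
  (defaults 0.5/0.1, blocks = {metabolites}, {proteins}: one
  co-regulated pathway block and one co-regulated immune block). The
  matrix is eigenvalue-clipped and renormalized if indefinite. A latent
  Pearson r implies Spearman `(6/π)·arcsin(r/2)` (e.g. r = 0.9 → 0.891),
  which is what rank-based downstream stages see.
- **Pairing**: an optional shared per-patient latent offset
  (`patient_effect_sd`, default 0 — no published magnitude exists) adds
  within-patient PRE↔TRM coupling; latent variables are rescaled by
  `1/√(1+s²)` so margins stay exact.
- **Reproducibility**: one `numpy` Generator seeded from the spec drives
  the whole call; identical spec + seed ⇒ bit-identical cohorts.

What a green synthetic test does and does not establish: it validates
the machinery (rank correlation, thresholding, topology, calibration of
the permutation test, marginal/copula calibration of the generator) on
data with the stated structure. It does not reproduce the study's
patient-level results — the patient matrices exist only as article
supplementary material — and it does not emulate LC-MS/MS or PEA
measurement error structure, detection limits, batch effects, or
real biological covariance beyond the block model.

## Numerical choices and edge cases

- Spearman via `rankdata` (average ranks) + `corrcoef`; matrices
  symmetrized and clipped to [−1, 1]; diagonal forced to 1.
- Threshold grid values validated to (0, 1], strictly descending;
  τ is reported at grid resolution.
- Tables are TSV (CSV accepted), decimal point only; floats written via
  `repr` and parsed with Python's exact `float()`, so write→read
  round-trips are bit-identical.
- Empty networks summarize to zeroed fields; exporting an empty network
  is an error.
- Pipeline bundles are byte-identical across reruns at fixed seed: no
  timestamps in outputs, stage wall-times go to the log stream only, and
  the provenance/config records exclude the output path.

## Known limitations

- The fragmentation rule's non-strict default can return a high cutoff
  with a tiny network on large-n continuous data (see above); use
  `strict=True` or inspect the summary when n is not small.
- The permutation test ignores PRE↔TRM pairing (labels are reshuffled
  freely); with strong patient effects a paired scheme would be more
  powerful.
- Bonferroni is the only correction offered, matching the analysis this
  package reimplements; no FDR option is exposed.
- The hub *membership* rule is implemented; normalized "degree
  centrality" values attached to published hub lists follow no standard
  convention we could identify and are not reproduced.
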