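# Methods

## Model and procedure

The unit of analysis is a two-generation nuclear family genotyped at
per-gene SNP panels of one to six markers.  Multi-generation pedigrees are
out of scope: every covariate the cohort statistics use is a
nuclear-family quantity, and restricting to nuclear units keeps the phase
enumeration contract exact.  Affected founders are rejected by validation
rather than modelled — pseudo-dominant segregation is outside the
recessive model.

**Phase enumeration.**  A gene panel spans one locus and its flanks, so no
recombination is modelled within a panel: each child inherits exactly one
unrecombined haplotype per parent per gene.  Per parent, only heterozygous
markers contribute phase choices (at most 2^6 ordered diplotypes);
homozygous markers are forced and missing parental genotypes leave the
corresponding haplotype entries missing.  Missing entries act as wildcards
when matched against child genotypes and are never imputed: two haplotypes
differing only at missing positions are distinct assignments, avoiding
invented certainty.  Copy labels 1/2 are identity-by-descent labels by
construction; when a parent's two haplotypes are identical in content the
copies remain distinct labels, and downstream questions are resolved by
existential quantification over assignments.  Assignments are
canonicalised under independent swaps of each parent's labels.  Because a
swap always flips a child's copy label, the swap group acts freely on the
raw consistent set whenever the family has at least one child, so the
canonical count is exactly the raw count divided by four; the production
call path uses this identity while the reference implementation
materialises and deduplicates, and the two are tested against each other
and against a brute-force oracle.

**Exclusion call.**  A phase assignment is recessive-compatible when some
disease pair (maternal copy, paternal copy) is carried by every affected
child and by no unaffected child; children of unknown affection constrain
phase but not compatibility.  A gene is EXCLUDED only when consistent
assignments exist and none is compatible; INCONSISTENT (no consistent
assignment) is surfaced to the paternity screen and never counted as
excluded.  UNINFORMATIVE_INCLUDED is operationalised as: the gene is
included *and* every transmission vector over the children typed at the
panel is realised by some consistent assignment — the genotypes place no
restriction on transmission, so no data of this shape could ever exclude.
This reduces to the intuitive cases (all genotypes missing, or all
relevant markers homozygous).  Children untyped at a panel are
marginalised inside the call: their transmissions are unconstrained, which
provably cannot change the verdict, and the reported assignment count is
rescaled accordingly.  Full penetrance and no phenocopies are assumed, so
an unaffected sib carrying both disease haplotypes falsifies the gene; a
switch (`unaffecteds_constrain=False`) drops the unaffected constraint for
sensitivity analysis under incomplete penetrance.

The per-family exclusion proportion divides the EXCLUDED count by the
number of genes *analyzed* for that family — genes with no non-missing
call in any family member leave the denominator; INCONSISTENT genes count
as analyzed but not excluded.

**Shared-haplotype scan.**  An affected child is reported for a query
haplotype when at least one consistent assignment of its family places a
matching haplotype on one of the child's transmitted copies; missing
positions on either side are wildcards.  This is a screening operation —
it asserts possibility under some phase, not certainty.

**Paternity screen.**  Per gene, single-marker checks classify each
inconsistency by the parent who cannot supply a required allele; when
either parent could equally be blamed, or neither can supply, the marker
is indeterminate.  A gene is paternal-inconsistent when some child has
paternal-specific marker evidence and none maternal; whole-gene haplotype
contradictions without single-marker attribution are reported as
indeterminate (both kinds of evidence are computed; parent-of-origin is
attributed only from single-marker evidence).  A family is flagged when
the paternal-inconsistent fraction of analyzed genes reaches the
threshold, default 0.5 — deliberately permissive, since the phenomenon of
interest is gross multi-gene inconsistency, while an isolated single-gene
inconsistency (possible genotyping error) sits far below any sane
threshold.  Maternal misattribution is screened symmetrically and
reported; cohort filtering removes families flagged on either side, with
every removal logged.  No likelihood-ratio paternity index is computed.

**Cohort statistics.**  The exclusion proportion is regressed on
treatment-coded categorical covariates by ordinary least squares (no
logistic/beta refinement), with reference levels affected "≥3",
unaffected "0", maternal/paternal DNA "No", sibship "≥5", so each
coefficient equals its level mean minus the reference mean exactly.
Counts are of genotyped individuals; the unaffected top bin is "2" with
larger counts folded in; sibship size counts all sibs.  Backwards
elimination starts from the full multivariate model and repeatedly
removes the variable with the largest multi-degree-of-freedom F-test
p-value above alpha (default 0.05), breaking ties toward the variable
later in the input order; a per-dummy criterion is available behind a
flag.  Degenerate inputs (zero residual variance) yield zero standard
errors without faults.  The cost model assumes sequencing cost
proportional to transcript size: fold savings = total transcript size of
analyzed genes over that of non-EXCLUDED genes (INCONSISTENT and
uninformative genes are retained); all genes excluded is reported as an
explicitly marked infinite fold.

## Synthetic cohorts

The simulator gene-drops founder haplotypes through nuclear families:
each founder haplotype is sampled marker-by-marker from population allele
frequencies (linkage equilibrium within a panel — panel SNPs are chosen
from different haplotype blocks, making independence the neutral
default); one maternal and one paternal founder copy at a designated
causal gene are risk copies; children draw one copy per parent per gene
independently; affection = both risk copies (penetrance 1.0 by default)
or phenocopy (rate 0.0).  Families are rejection-sampled on the sibship's
affection pattern until the configured numbers of affected and unaffected
genotyped sibs are available (ascertainment conditions on observed
structure); sibs beyond the genotyped ones are emitted untyped with
affection recorded as unknown.  False paternity re-draws a latent
biological father whose haplotypes the children inherit while the
recorded father keeps his own genotypes.  Genotype error (symmetric
substitution to a uniformly chosen other allele) and per-genotype
missingness are applied last, to observed calls only.  One master seed
drives deterministic per-family substreams.

The default panel models 28 arRP/LCA candidate genes with six biallelic
SNPs each (five for the four genes whose assays dropped out), minor
allele frequencies uniform on [0.2, 0.5] fixed by an internal seed, and
plausible stand-in transcript sizes; it is a synthetic stand-in, not any
historical assay, though the USH2A panel carries its six published rsIDs
with allele codings able to express the reported shared haplotype
CCTGCA.  The default 31-family cohort structure samples the published
cohort's marginals (affected counts 9/13/7 for 1/2/≥3, unaffected
12/11/6 for 0/1/2, sibship 4/12/8/5 for 2/3/4/≥5, maternal DNA 24/29,
paternal 21/29).  `reference_cohort_config` additionally injects false
paternity into two families given the cohort's modal detectable structure
(two affected + one unaffected genotyped sibs, both parents sampled) — a
family whose false paternity was observable necessarily had paternal DNA.
`informative_panel` plus `SimulationConfig.informative_genes` assigns the
four alleles of a four-allele marker deterministically to the four
founder copies, yielding always-fully-informative loci for analytic
checks.

What the simulator does *not* emulate: linkage disequilibrium among a
panel's SNPs (an optional haplotype-frequency path is not implemented;
frequencies enter marker-wise), population stratification, assay-specific
error structure, relatives beyond the nuclear family, and mutation-level
detail (disease status attaches to haplotype copies, not alleles).
Passing tests therefore demonstrate the correctness and calibration of
the inference given the recessive transmission model, not the real-world
informativity of any particular SNP panel — exclusion *rates* depend
strongly on panel informativeness in the study population, so simulated
cohort means (e.g. genes excluded per family) are expected to differ from
any published cohort's values, while orderings and exact guarantees
(causal-gene protection, monotonicity, closed forms) transfer.

## Numerical and design choices

- Alleles are opaque symbols; no strand or ref/alt orientation handling.
  Markers may be multi-allelic so fully informative loci exist for tests.
- Half-called genotypes are demoted to missing with a logged warning (no
  half-call rule exists for this assay model).
- Enumeration is exact with no heuristic pruning beyond per-marker early
  rejection; at ≤6 markers and nuclear-family sibships the worst case is
  small.
- Closed-form validation sizes: 10,000 Monte-Carlo replicates per (k, u)
  setting, 3-binomial-SE bands; 500 brute-force oracle instances (≤3
  markers, ≤4 children); 1,000 families for causal-gene protection; 500
  augmentations for monotonicity; a 100-family cohort for the
  affected-count gradient.  Unit tests use smaller spot-check sizes; the
  acceptance suite and script use these full sizes.
- Rejection sampling of family affection patterns is capped (default
  100,000 attempts per family) and fails with guidance rather than
  hanging when the requested structure is improbable.
- Tie-breaks: backwards elimination removes the later variable in input
  order on exact p-value ties; canonical assignment selection uses
  lexicographic order on haplotype tuples.

## Known limitations

- Only nuclear families; cross-family founder information is not pooled.
- Exclusion is all-or-nothing: no posterior probability or LOD score
  accompanies a retained gene, and no recombination-fraction estimation
  is attempted.
- The paternity screen reports evidence counts, not a likelihood ratio;
  it cannot distinguish clustered genotyping failure from true
  non-paternity beyond the threshold heuristic.
- The published fold-savings figures depend on exactly which genes a real
  cohort excludes; this package reproduces the estimator (formula and
  invariants), not those cohort-specific values.
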