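# Methods

This note documents the models, parameter choices and numerical decisions
behind `mimoscan`, and what the synthetic-data generators do and do not
emulate.

## Recognition-motif model

A class I HLA-presented nonamer is indexed P1–P9.  The motif assigns each
position one of three constraint kinds — `fixed` (one residue), `allowed`
(a residue set) or `free` — plus optional per-position forbidden sets and
a functional annotation (HLA anchor at P2/P9, auxiliary anchor at P7, TCR
contact at P5/P8, neutral elsewhere).  A peptide matches iff every
constrained position it covers holds an admitted residue and no forbidden
residue occurs; the verdict lists every failing position, not just the
first.  Octamers are handled in nonamer register: their NH2-terminal
residue occupies P2 (octamer index i ↔ P(i+1)), so P1 is simply not
evaluated for them.  The canonical Vα3S1/Vβ13S1 motif shipped as a
convenience is `P2=R, P5∈{R,N,Q}, P7∈{R,L}, P8=R, P9∈{L,M,V,F,I}`; the P9
set is the wild-type leucine plus the four tolerated anchor exchanges
(Phe, Ile, Met, Val).

### Critical-position inference

`infer_critical_positions` thresholds an alanine-scan profile: a position
is critical when its residual activation (fraction of the CD3-normalised
wild-type response) falls below the **abolition threshold, default 0.2**.
The published description of abolished stimulation is qualitative
("completely abolished"); 0.2 cleanly separates near-zero substitution
responses from tolerated ones while being robust to assay noise.
Untested positions are reported with a warning and never silently counted
as critical.  When a position was probed with several substitutions
(anchor-exchange sets), the table reader uses the alanine row if present,
else the minimum residual activation.

### Frequency model and logo numerics

`build_frequency_model` counts residues of stimulatory ligands per
nonamer column; octamers contribute to P2–P9 only.  Frequencies add a
**pseudocount (default 0)** to every cell before column normalisation.
The default is zero because the ligand families involved are small and
any smoothing constant would be a guess; the knob is exposed instead.  A
column with neither observations nor pseudocount (P1 under an all-octamer
family) is reported as uniform — maximum entropy, zero information —
rather than undefined.  Per-column information content is
`IC_j = log2(20) − H_j` bits, in [0, log2 20 ≈ 4.32]; **no small-sample
correction is applied**, so values are comparable to standard sequence
logos drawn without one.

### Motif derivation and pattern compilation

`derive_recognition_motif` makes each critical position `fixed` or
`allowed`.  The **allowed-set rule defaults to the observation union**
(any residue seen at least once among stimulatory ligands); a frequency
threshold can tighten this for larger ligand collections.  Non-critical
positions stay free.

`compile_search_patterns` renders the motif as octamer pattern strings
(residue letters plus `X`; PROSITE import/export is provided as an I/O
dialect).  Two policies exist because the published eight-pattern search
set is a subset of the 30-combination cartesian product with no stated
selection rule: `cartesian` enumerates the full product of allowed
residues at variable positions; `explicit` emits exactly a configured
list after validating every symbol against the motif.  A wildcard at a
constrained position is rejected — except at P7, where the classic
pattern set itself uses one; such patterns are flagged `wildcard_p7`
since their match set exceeds the motif language at that position.

## Proteome scanning

The scanner tests every octamer window of every protein (overlapping
matches all reported, deterministic order: protein, then offset), using
compiled regular expressions with lookahead.  Windows containing
non-standard residues (X, B, Z, J, U, O) are skipped and counted rather
than expanded — a conservative choice that cannot create false positives.
Coordinates are 0-based half-open internally and 1-based inclusive in the
TSV output.

P1 completion takes the single upstream residue from the protein
sequence; hits at offset 0 stay octamer-only and are flagged `no_P1` but
kept, since octamers lacking P1 can still stimulate.  Curation applies
forbidden-residue rules (default: **Arg at P6**, which abolishes TCR
activation despite an intact motif); removal reasons are recorded
verbatim (`P6:R forbidden`) and kept + removed always partition the
input.  Ranking uses a per-position log-odds score against a background
composition (default uniform 1/20; a Swiss-Prot-average composition is
shipped as YAML).  A residue unseen by a zero-pseudocount model scores
−∞ and sorts last; ties break by (protein id, offset).

The analytic false-positive control multiplies, over constrained
positions, the background mass of the allowed residues.  For the
canonical motif under uniform composition this is
(1·3·2·1·5)/20⁵ = 9.375 × 10⁻⁶ per window, and the empirical match count
on 10⁷ random windows is checked against the 99% binomial interval around
it.

HLA binding is a pluggable hook: a user-supplied scorer (e.g. a wrapper
around an external peptide-MHC predictor) annotates hits; without one,
the built-in surrogate checks the anchors directly (P2 = R,
P9 ∈ {L,M,V,F,I}).  Hook failures annotate `binding_unscored` and never
drop hits.

## Assay statistics

The stimulation index is the central stimulated readout over the mean
unstimulated control: **median for cpm triplicates, mean for CD137
duplicates** (and for sGFP reporter fractions).  SI is scale-invariant
and undefined for a non-positive control mean (an error, not a NaN).
Records from subjects whose CD3 positive control failed can be excluded
by rule (`exclude_failed_positive_controls`, default SI < 2), with every
exclusion logged.

Two-group comparisons use the two-sided Mann-Whitney U test: exact
enumeration when the combined sample size is ≤ 12 with no ties, otherwise
the normal approximation with tie correction.  The **continuity
correction is omitted** in the asymptotic branch: at the sample sizes
typical here (10–40 per group) it is markedly conservative and pulls the
attained level visibly below the nominal α, whereas the uncorrected
approximation attains it (verified by the shipped calibration harness:
2000 null replicates at n = 10+10 give rejection rates within three
binomial standard deviations of 0.05).  Multiple groups use
Kruskal-Wallis with tie correction — constant data degenerate to H = 0,
p = 1 — and Bonferroni-adjusted pairwise tests, `min(1, m·p)`, with the
family size defaulting to the number of peptides tested within a readout
(the family definition is configurable because it is a reporting
convention, not a property of the data).

## Cohort analysis

The shipped case series (`data/gfd_cohort.tsv`) is the only published
patient-level dataset: 13 psoriasis patients on a gluten-free diet,
transcribed field-for-field including original treatment spellings.
Response means PASI75 or better within three months; the printed
improvement class is consumed directly, with
`pasi_percent_improvement` + `classify_pasi_improvement` available for
prospective data (thresholds inclusive: ≥ 90% → PASI90, ≥ 75% → PASI75).
Serology is elevated when **any available quantitative titer is
≥ 10 U/ml** (inclusive); "neg" entries in the quantitative columns are
treated as no usable titer, falling back to the categorical screen, which
yields the identical call.  Patients with neither titers nor screen are
ND and excluded from the 2×2 table.  The association uses the two-sided
Fisher exact test; because the series never states whether the screen or
the quantitative titers anchor the negative predictive claim, the JSON
report computes the table both ways (they coincide on this series:
rows responder/non-responder × columns elevated/not = ((3,4),(5,1)),
p ≈ 0.266).  Degenerate tables return p = 1 with a warning.

## Synthetic-data generators

All generators draw from numpy's PCG64 `default_rng` seeded from their
config; the same seed reproduces outputs byte-for-byte, and every
generator returns a truth table sufficient to score sensitivity and
specificity of the downstream stages.

* **Proteomes** — background residues i.i.d. from a configurable
  composition (default uniform 1/20; Swiss-Prot-like composition
  shipped); default 50 proteins of 200–600 residues.  Planted nonamers
  are sampled uniformly from the motif language (or given verbatim) and
  written over the background at recorded coordinates; overlapping plants
  are an error, and `avoid_forbidden` lets plants steer clear of curation
  rules when full-pipeline sensitivity is the quantity under test.
* **Assays** — each subject draws a log-normal baseline
  (σ_between = 0.6 on the log scale, around a 200-cpm control mean);
  control replicates scatter around the baseline and stimulated
  replicates around baseline × group effect (σ_within = 0.25).  Defaults
  mirror the proliferation arm of the study conditions: 41 patients vs 12
  controls, triplicates, a 3-fold patient-group effect for a wheat-like
  peptide.  The σ values are chosen as realistic for PBMC proliferation
  assays (between-subject spread dominating replicate noise); CD137-style
  percentage readouts are clipped to [0, 100].
* **Cohorts** — Bernoulli response (default 7/13), serology positivity
  optionally response-dependent (default independent at 8/13), relapse
  and PsA rates mirroring the observed series; generated titers straddle
  the 10 U/ml threshold on the side matching the serology label.

What the generators deliberately do **not** emulate: TCR signalling or
binding kinetics, real proteome repeat structure and domain composition,
HLA peptidome biases, assay plate effects, or correlated serology
titers.  Passing the synthetic suites therefore demonstrates the
correctness and calibration of the algorithms under their stated
assumptions — i.i.d. backgrounds, multiplicative log-normal effects —
not performance on real proteomes or patient data.

## Problem sizes and known limitations

The shipped validation uses 10⁷ random windows for the background-rate
check, 2000 replicates for type-I calibration, 200 for power, and
100 random sequences up to 10 kb for scanner/oracle equivalence — sizes
at which the binomial checks are sharp while the whole suite runs in
well under a minute of compute.

Limitations: the per-subject assay values behind the published group
contrasts are unpublished, so group-level significance is validated on
synthetic data only; the scanned nonamer of the original autoantigen is
likewise not printed here and must be supplied by configuration; Fisher's
exact test is conservative at case-series sizes (its null rejection rate
sits below α, as the cohort calibration test documents); and the P3/P4
preference weights for hit ranking have no shipped default because no
quantitative values are published — they are user-configurable.
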