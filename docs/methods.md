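# Methods

This note documents the models, conventions and numerical choices behind
`signalstrap`, and what the test suite does and does not establish.

## Coordinates and cleavage convention

All sequence coordinates are 1-based inclusive. `sp_end` is the index of
the **last** residue of the signal peptide, so cleavage falls between
`sp_end` and `sp_end + 1` and mature position 1 is `sp_end + 1` (the
convention of SP predictors that report "cleavage between k and k+1").
`X` is permitted in sequences; it scores 0 against every residue and is
never counted as coordinating. Annotation precedence when several sources
exist for one protein: user-supplied file > generator truth > built-in
heuristic; the source used is written to the run log per protein.

## Short-query search model

The search stage emulates the configuration public BLAST servers switch to
for short queries, because the original procedure delegated parameter
choice to those servers:

| parameter | default | why |
|---|---|---|
| matrix | PAM30 | short-query standard; BLOSUM62 selectable |
| gap open / extend | 9 / 1 (gap of length L costs 9 + L) | short-query standard |
| E-value cutoff | 1000 | hit selection is triage's job, not the search's |
| max targets | 500 | the procedure raised the server default 100 → 500 |
| exclusion | exact match on the record's taxon tag | "exclude source organism"; untagged records are never excluded (logged) |

Scanning is exhaustive Smith–Waterman over every record — no heuristic
seeding — with a fully specified traceback tie-break (diagonal over up over
left; end cell = lexicographically lowest (row, column) among maxima) so
byte-identical reruns are guaranteed. An optional 2-mer prefilter
(`prefilter=True`) trades sensitivity for speed; its results are provably a
subset of the exhaustive scan and the default keeps it off.

**Statistics.** λ is the unique positive root of
`Σᵢⱼ pᵢ pⱼ exp(λ sᵢⱼ) = 1` (Robinson–Robinson background; bracketed
bisection; residual < 1e−9) and `E = K·m·n·e^(−λS)` with K = 0.13. These
are **ungapped** parameters applied to gapped scores — a documented
approximation; exact gapped statistics would need large-scale simulation.
`synthdata.calibrate_K` fits the Gumbel form to maximal scores against
shuffled background sequences for an empirical check of K. A practical
consequence of the approximation is that E-values for long gapped
alignments are optimistic, which motivates the rescreen default below.

## Triage rules

A hit becomes an **accepted** candidate iff (i) the subject residue aligned
— without a gap — at the query's appended position is a chelator (His by
default), (ii) the subject's mature position 1 after cleavage is in the
chelating set, and (iii) mature position 2 is not in the position-2 rule
set. His1-positive subjects failing only (i) are flagged **review** rather
than dropped, mirroring the manual procedure's human-judgement step;
subjects with no SP annotation from any permitted source are
`rejected_no_annotation`.

Two residue sets are deliberately distinct and independently configurable:

* **coordination inventory** (ranking only): {H, C, D, E, M, N, Q} —
  side chains commonly found ligating first-row transition metals;
* **position-2 rejection**: {H, C, D, M}. E, N and Q are excluded here
  because a worked-example family's mature sequence begins "HE" and was
  retained by the original procedure; a rule set containing E would reject
  the method's own examples. This is the package's reading of an
  under-specified rule and is surfaced prominently in the config.

Ranking: accepted before review; within a class, larger coordination
inventory first, then smaller E-value, then id.

## Rescreen and conservation

Each accepted candidate's **full-length** sequence is re-searched to
collect its homologue set (same exclusion/sort contract as the primary
search). The rescreen uses its own E-cutoff, default 1e−5: with the
ungapped-λ approximation, full-length gapped scores of unrelated proteins
can reach E ≈ 1–10, and the conservation profile should describe likely
family members, not every weak similarity. The number of rescreened
candidates per run is capped (default 3) to bound runtime.

Conservation is **cleavage-anchored**: every member is indexed from its own
mature position 1, with no multiple alignment. This is exact for the
headline statistic (the fraction of members retaining His1) and
increasingly approximate downstream where indels shift register — a known
divergence from HMM/logo pipelines, accepted because position 1 is the
quantity of interest. Members without a usable annotation are dropped and
reported (`n_dropped`), since which homologues an external SP predictor
fails on is itself unknown. Pairwise percent identity uses global
Needleman–Wunsch (BLOSUM62, gaps 10/0.5) with gap columns in the
denominator; because external aligner conventions differ, the convention is
stated in the output and arguments are canonically ordered so
pid(a,b) = pid(b,a) exactly.

## N-terminal enrichment

Cytosolic proteins contribute the residue at position 2 of M-starting
sequences (a proxy for Met excision; no aminopeptidase specificity model;
non-Met starts are skipped and counted), secreted proteins the residue at
mature position 1. Frequencies are normalised per class; the enrichment
ratio f_sec/f_cyt is flagged undefined when f_cyt = 0. Frequencies print
as percent to one decimal; full precision is retained in JSON/counts.

## Metal sites

Ligands are N/O/S atoms within 2.8 Å of a metal (typical first shell for
M–N/O bonds), other metals excluded. Brace motifs depend on **protein**
donors only; waters and exogenous ligands (buffer ions, malonate) are
inventoried but never change the class. Geometry thresholds — T-shaped at
a maximal donor–metal–donor angle ≥ 150°, facial cap when all angles lie in
[70°, 110°] — were chosen to separate a near-linear trans pair with a
perpendicular third donor from three mutually orthogonal donors; the
underlying descriptions are qualitative, so both thresholds are
configurable. Sites with fewer than three protein donors get geometry
`other` with a warning. Residue 1 of a chain is the standard residue with
the lowest residue number; alternate locations keep altloc A or blank
(a B-only residue is kept).

## Synthetic proteomes

The generator plants ground truth for every stage. Defaults: 500 proteins,
50 % secreted, 2 families × 10 members, per-site substitution rate
μ = 0.05, partner-His position drawn from 10–40, mature lengths 80–300,
background = Robinson–Robinson.

* Signal peptides are tripartite: n-region 1–5 aa containing ≥1 K/R (a
  1-residue n-region is a single K/R, since the charge requirement
  precludes a Met start at that length); h-region 7–15 aa drawn from
  {A,I,L,M,F,V,W} with a leucine-rich composition (L 0.32, V 0.16, I 0.14,
  F 0.12, M 0.10, A 0.08, W 0.08) — realistic for h-regions and keeping
  alanine rare enough that the c-region's terminal A-x-A cleavage motif
  stays distinctive; c-region 3–7 aa of polar filler (excluding A) ending
  A-x-A.
* Family members share one consensus (SP + mature). The substitution rate
  μ applies independently per site to the **mature region only** (the SP is
  held fixed within a family), so recall statistics are driven by the
  His1/position-2 rules rather than SP drift; position 1 mutates to a
  uniform non-H residue with rate μ. Consensus position 2 is forced
  non-coordinating so triage verdicts reflect mutations, not construction.
* Decoy secreted proteins draw mature position 1 from the background
  excluding H; cytosolic proteins start with M and carry no SP.

All randomness flows from one numpy PCG64 seed recorded in the truth-table
header; regeneration from (spec, seed) is byte-identical.

The SP model is deliberately crude and pattern-based. Passing tests on
this generator show that the pipeline's rules and statistics behave as
specified under known ground truth; they do **not** show that the built-in
heuristic SP caller approaches real predictor accuracy on biological
sequences (real SPs lack a literal A-x-A guarantee, have variable
composition, and cleavage-site prediction is genuinely hard — which is why
external predictor annotations take precedence whenever available).

## Problem sizes and study conditions

The suite and `scripts/acceptance.py` use: 500 random instances of length
≤ 8 for the alignment-enumeration oracle; a 500-protein proteome
(2 families × 10 members, μ = 0.05) for end-to-end recovery; 500 family
members at μ = 0.2 for His1-fraction parameter recovery (3 binomial SD
band); 200 secreted proteins at μ = 0 for heuristic cleavage recovery; 100
random rigid-body transforms for geometry invariance. These sizes give
stable statistics at interactive runtimes; all scale linearly if larger
checks are wanted.

## Known limitations

* E-values are approximate (ungapped λ, K on gapped scores); they order
  hits well but are not calibrated significance levels.
* No lipoprotein (SPII) or Tat cleavage classes; one generic SP model.
* Conservation beyond mature position 1 ignores indels (no MSA).
* mmCIF structures must be converted to PDB first (e.g. `gemmi convert`).
* The search is exhaustive O(m·n) per subject — intended for proteome-scale
  FASTA files, not nr-scale databases.
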