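# Methods

## Identification rule

A protein is called a complete P450 when it satisfies all of:

* an **ExxR** match (`E-x-x-R`) starting in the C-terminal 60% of the
  sequence (the K-helix salt bridge sits late in the fold);
* a **CxG** match (`C-x-G`) starting within the final 120 residues (the
  heme-binding loop is near the C-terminus);
* ExxR strictly before CxG;
* length ≥ `min_length` (default **300 aa**).

Exactly one in-window motif — or both motifs on a sequence shorter than
`min_length` — gives *fragment*; no in-window motif gives *non-P450*. The
motif patterns live in a 4-letter space, so spurious matches in unrelated
proteins are common; the positional windows suppress them. Both windows and
the length cutoff are configurable (`MotifConfig`, CLI `--min-length`,
`--no-motif-windows`). The ambiguity residue `X` may occupy wildcard
positions but never matches the fixed letters E, R, C, G.

Two deliberate edge-case resolutions:

* The reported `MotifEvidence.has_exxr`/`has_cxg` record **whole-sequence**
  presence (so borderline cases remain inspectable); window compliance is
  applied at classification time. A full-length sequence whose two motifs
  exist but not in a window-compliant ordered configuration is called
  *fragment* — one match is treated as spurious.
* `min_length = 300` is a deliberate operationalization of "too short to be
  a complete P450": it sits below the ~350–400 aa of the shortest complete
  bacterial P450s, so clear truncations are excluded without rejecting
  compact P450s.
* Proteins with zero motifs are *non-P450*, not fragments, and are excluded
  from fragment counts.

An optional precomputed P450-domain hit table (protein_id → 0/1) can
prefilter the input; without one, the motif rule alone governs.

## Percent identity and nomenclature

Identity is computed from a **global** Needleman–Wunsch alignment under
BLOSUM62 with gap open 10 and gap extend 0.5 (all configurable), as

    identity% = 100 · identical aligned pairs / aligned (non-gap) columns.

Global alignment over full-length proteins is the natural reading of
"percent identity" between complete P450 domains; a local (BLAST-style)
identity is not offered because partial-coverage identities would interact
badly with the family thresholds. Each pair is aligned in a canonical
(lexicographic) order internally so identity is exactly symmetric even when
co-optimal alignment paths differ between argument orders.

Thresholds follow the International P450 Nomenclature Committee convention
and are applied as **strict inequalities**: > 55% to the best panel hit →
same subfamily; > 40% and ≤ 55% → same family, new subfamily; ≤ 40% → new
family. The convention's prose leaves exactly-40% and exactly-55%
unspecified; this package resolves both downward (40.0% founds a new
family, 55.0% is a family match) and tests pin that behavior. Ties at the
best identity resolve to the lexicographically smallest reference name, with
a warning.

Placeholder naming is deterministic. Queries founding new families are
clustered among themselves by single-linkage at the 40% threshold, so
mutually similar novel queries share one `CYPNEW-<k>` label (k by first
occurrence in input order); family-matched queries needing a new subfamily
are grouped the same way at 55% and share `!<ordinal>` subfamily
placeholders per family. The single-linkage rule mirrors how a cohesive
novel group would receive one name.

## Profiling

The profile is a genomes × families integer count matrix (all genomes seen
in the calls keep a row; columns are assigned families, so none is
all-zero), plus a per-genome fragment count. The three summary statistics
are closed-form over the profile (see README); rounding happens only at
report time — average and BGC percentage to the nearest integer, diversity
to 2 decimals — and raw reals are always retained.

* **Bloomed** family: ≥ `multi_copy_min` copies (default 3) in ≥
  `genome_frac_min` (default 0.5) of genomes. The literature uses "bloomed"
  informally; these defaults operationalize it so that, for the packaged
  126-strain survey spread uniformly, exactly the two largest families
  (CYP105, CYP107) qualify. Both knobs are exposed.
* **Conserved** family: present in ≥ `presence_frac_min` of genomes
  (default 1.0, i.e. every genome).
* **Heat-map**: counts are binarized to 3 (presence) / −3 (absence) — the
  encoding of MeV-style presence/absence displays — and rows and columns are
  clustered hierarchically with Euclidean distance and **average linkage**
  (the display tool's default; the linkage is configurable in code).
  Clustering is on the binary matrix, matching the published display
  convention rather than the raw counts. Scipy's index-order tie-breaking
  makes the output deterministic for a given input order; an all-equal
  matrix keeps identity ordering with a warning.

## smBGC linkage

Membership is **full containment** of the gene interval (1-based inclusive,
strand-agnostic) in the cluster interval on the same genome and contig.
Cluster callers draw generous boundaries, so genes genuinely in a cluster
lie inside them; any-overlap is available behind a flag for permissive
analyses. A gene inside several overlapping clusters is assigned to each
(multiplicity warned). Composition signatures keep **gene order along the
contig** rather than sorting, because orthologous clusters share order and
the published variety strings are order-sensitive. Fragments never enter
signatures unless `--include-fragments` is set (the packaged variety table
contains a few literal `...-fragment` labels, which the label grammar
tolerates, as it does `/`-variants like `CYP105W2/3` and the package's own
`CYPNEW-<k>` placeholders). The cluster-type vocabulary is an open string
set, not an enum.

## Phylogeny

Distances are d = 1 − identity/100 from all-pairs global alignment, and the
tree is standard Saitou–Nei neighbor joining, implemented in-package with a
deterministic smallest-index tie-break in the Q-criterion minimum and
negative branch lengths clamped to zero (count recorded on the tree).
NJ is exact on additive matrices — the tests verify topology and branch
lengths against randomly generated additive trees (n ≤ 10) and against an
exhaustive enumeration of all unrooted topologies at n ≤ 6, plus a
cross-check against an independent library implementation. On real
identity distances NJ is a heuristic, and this module makes no claim of
reproducing any published tree topology: a web-service alignment/tree
pipeline is not re-run here, so acceptance for this module is
property-based (planted families group into clades on synthetic data).
Leaf coloring marks the k most abundant families (default 8).

## Synthetic data generator

The generator emulates the statistical structure of a multi-strain CYPome
survey; its defaults are the package's reference study conditions:

| parameter | default | rationale |
|---|---|---|
| genomes | 10 | desk-scale stand-in for a 126-strain survey |
| families (archetypes) | 6 | enough for distinct profile/tree structure |
| archetype length | 420 aa | typical complete bacterial P450 |
| P450s per genome | 20 | matches the surveyed per-strain average (~21) |
| identity bands | (57,90) / (42,53) / (15,38) | subfamily / family / new-family, ≥ 2-point margins around the 40/55 thresholds |
| band weights | 0.80 / 0.15 / 0.05 | strains of a few close species are mostly near-identical at subfamily level |
| fragment rate | 0.05 | survey ratio 129 fragments : 2643 P450s |
| decoys per genome | 5 | motif-free non-P450 background |
| clusters per genome | 3 | scaled-down cluster density |
| P450s per cluster | 1–6, weights (.45,.25,.12,.08,.06,.04) | most observed clusters carry 1–2 P450s; 6 is the observed maximum, and one 6-member cluster is always planted |
| cluster types | 18 observed labels, frequency-weighted | matches the surveyed type distribution |

Identity bands are enforced by **measure-and-resample**: alignment identity
is not a simple function of substitution count once gaps enter, so each
plant is mutated (BLOSUM62-weighted substitutions, motif columns frozen),
measured with the same global-identity routine the pipeline uses, and
re-mutated with an adjusted substitution count until its **best identity
over the whole panel** lies strictly inside the band with the source
archetype as best hit — which makes planted-band recovery a sharp test of
the assignment logic rather than of the generator. Fragments are made
either by truncating to the C-terminal 280 residues (both motifs, short) or
by ablating the heme-motif cysteine (one motif, full length); spurious
in-window motif matches created by mutation are disrupted so every plant's
classification is unambiguous, and the generator self-checks each plant
with the classifier. Cluster member groups are laid out as contiguous gene
blocks and cluster intervals are padded by 500 bp, so planned membership and
interval containment coincide exactly. All outputs are deterministic under
the seed (per-genome seed streams), and byte-identical across re-runs.

What the generator does **not** emulate: real P450 sequence composition
(plants are band-calibrated mutants of random archetypes, not homologs of
real families), indels (substitution-only by default), multi-contig
assemblies and assembly gaps, nested or overlapping real cluster calls, and
inter-genome phylogenetic structure beyond shared archetypes. Passing the
end-to-end recovery tests therefore demonstrates the pipeline's logic is
correct under controlled identity structure — not that real-survey
annotations would be error-free.

## Problem sizes and runtimes

The default synthetic study (10 genomes × 20 P450s, 6 families) was chosen
so a complete simulate → classify → assign → link run takes ~10 s on one
CPU, and tree construction is run on a per-family subsample (≤ 8
high-identity plants per family) in the tests; the full test suite completes
in well under a minute. All knobs scale upward if heavier runs are wanted.

## Known limitations

* Atypical P450s lacking ExxR (known in the literature) are outside the
  motif rule and will be called fragments or non-P450s.
* The nomenclature engine matches against the supplied panel only; the
  repository ships no real named-P450 panel (a synthetic demonstration panel
  is generated), so real-data use requires a user-supplied panel FASTA.
* Cluster membership by interval containment is a reproducible surrogate
  for gene-list membership in upstream cluster callers; the two can differ
  for genes at cluster edges.
* Literature-based functional annotation is shipped only as a static
  family → known-function lookup (`known_family_functions()`), with no
  computation behind it.
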