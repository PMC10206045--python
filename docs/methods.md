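# Methods

`wrkykit` re-implements, as a tested library, the desk-scale analysis of a
plant WRKY transcription-factor family: domain detection and subgroup
classification, duplication-mode typing with Ka/Ks selection screening,
and a fold-change intersection screen for candidate anthocyanin
regulators across flower-color varieties of azalea (*Rhododendron*).
This note records the models, the tunables, what the synthetic data do
and do not emulate, and the numerical choices.

## Domain model and scanner

A WRKY domain is taken to be a conserved heptapeptide (canonically
`WRKYGQK`) followed within ~60 residues by a zinc finger, one of two
grammars:

* **C2H2**: `C-X(4,5)-C-X(22,24)-H-X-H`
* **C2HC**: `C-X(7)-C-X(22,24)-H-X-C`

The C-to-H spacer is widened by one residue beyond the tightest published
family descriptions (22–23 for the two-domain group, 23 for the C2HC
group) to absorb annotation wobble; the bound is a module constant, not a
fit parameter.  Zinc fingers are reported non-overlapping, scanning left
to right; at equal start the shortest C-to-C spacer wins, then the
shortest overall span.  This greedy policy is deterministic and matches
exhaustive enumeration of all grammar placements on short sequences (a
property pinned by an oracle test).

Heptapeptide detection has three tiers:

1. every exact `WRKYGQK`, anywhere;
2. for each zinc finger, the best 7-mer starting `WR` with at most 4
   mismatches within the 60 residues upstream (ties resolve to the hit
   closest to the anchor).  The search is *anchor-conditioned* because an
   unanchored 4-mismatch scan floods false positives, while real variants
   (`WRKYGEK`, `WRKYGRK`, `WRQCRRK`) sit directly upstream of an intact
   zinc finger.  The cap of 4 is the smallest admitting `WRQCRRK`;
3. a terminal `WR`/`WRK` prefix with no room for a full 7-mer is reported
   as a truncated (partial) motif.

Assembly pairs each zinc finger with the nearest unconsumed upstream
heptapeptide inside the 60-aa window.  An unpaired near-canonical
heptapeptide (≤1 mismatch, not truncated) is kept as a domain that has
lost its zinc finger — such proteins are genuine family members in the
reference inventory.  A protein with no domain at all is not a WRKY and
is dropped (the retention rule of the original identification step).  A
truncated prefix with no zinc-finger support does not count as a domain,
so proteins merely ending in `WR` are not annotated; this is the one
place the implementation is stricter than a literal reading of the
motif tiers.

## Classification ladder

First match wins:

1. ≥2 domains and any C2H2 → **I** (one intact zinc finger suffices; the
   reference family contains a two-domain member whose second
   heptapeptide is truncated);
2. any C2HC → **III**;
3. no intact zinc finger (or only truncated motifs) → **UC**;
4. single C2H2 with C-X4-C → **IIc**;
5. single C2H2 with C-X5-C: the seven residues after the second cysteine
   are matched against the subgroup signatures
   IIa `PVKKK[LV]Q`, IIb `PVRKQVQ`, IId `PARKHVE`, IIe `PARK[QM]V[ED]`.
   Exact match wins; otherwise minimum Hamming distance within a
   tolerance (default 2, configurable; ties go to the lexically smallest
   subgroup); otherwise UC.

The Hamming fallback exists because real signatures drift; exact-only
matching would inflate UC.  UC members can then be resolved on a
phylogeny supplied as input (trees are never inferred here): each UC
leaf takes the label of its nearest labeled leaf by patristic distance,
ties resolved by majority label then lexical order.  Label transfer
never touches a structurally classified protein.  For the packaged
azalea inventory the four zinc-finger-lost members ship with their
published, phylogeny-derived labels as a curated reassignment map, so
group summaries do not depend on reproducing the original tree.  (The
printed table lists those four under a main-group column that predates
the reassignment; the fixture keeps the printed value verbatim and the
summary applies the map.)

## Duplication modes

Collinear blocks are detected by greedy rank chaining: pairs grouped by
chromosome pair, sorted by rank on one side, extended while both rank
gaps stay ≤ `max_rank_gap` (default 25) with a consistent direction, and
kept at ≥ `min_anchors` (default 5).  The defaults mirror the common
defaults of the standard synteny tool chain.  This is a deliberate
simplification of dynamic-programming synteny detection — adequate for
planted-block genomes, not for dense real genomes with inversions inside
blocks.

Pair rules, first hit wins: block anchor → WGD; same chromosome at rank
gap 1 → tandem (no intervening gene); gap ≤ `proximal_max` (default 10)
→ proximal; exactly one side with block evidence → transposed; else
dispersed.  The transposed rule approximates the ancestral-locus test of
the reference tool, which needs outgroup genomes that are out of scope
here; with planted genomes the approximation recovers ≥95% of modes, and
the limit is intrinsic, not numerical.  Per-gene modes collapse pair
calls under the priority WGD > tandem > proximal > transposed >
dispersed, matching the convention of per-gene "gene type" tables.

## Ka/Ks (NG86)

Sites: per codon and position, the fraction of the three single-
nucleotide neighbors preserving the amino acid; neighbors that are stop
codons count as nonsynonymous, so S + N = 3 × compared codons exactly.
Differences: codons differing at 2–3 positions average step counts over
all orderings of single steps, excluding pathways through stop codons;
a codon whose every pathway is blocked is skipped and excluded from the
site totals (logged).  Proportions are Jukes–Cantor corrected,
`d = -(3/4) ln(1 - (4/3) p)`, undefined at p ≥ 3/4 (saturation is
flagged rather than clamped).  Ks = 0 gives an undefined ratio, never
infinity, and undefined ratios are excluded from category tallies —
this avoids manufacturing "positive selection" from invariant pairs.

The selection trichotomy (purifying < 1, neutral = 1, positive > 1) is
operationalised with a band of half-width ε = 0.05 around 1, because
exact equality is measure-zero on continuous estimates.  NG86 was chosen
over model-averaged or ML estimators because it is fully specifiable and
oracle-checkable; numerical identity with tool-specific model averages is
not claimed.  Back-translation threads CDS codons onto a gapped protein
alignment after verifying the CDS translates exactly to the protein
(standard code only; terminal stops stripped with a log line).

## Expression screen

DEGs are threshold-only, faithful to the published rule: a gene is
differential when |log2 FC| ≥ 1, computed on arithmetic replicate-mean
FPKM with a pseudocount (default 1.0) in both numerator and denominator.
There is no dispersion test or p-value — the method under study defines
DEGs by fold change alone, and adding one would change the screen's set
logic.  The two colored-vs-white contrasts of a stage are intersected:
up in both → candidate positive regulator, down in both → candidate
suppressor.  Boundary values are included (≥), following the printed
inequality.

qPCR validation arithmetic: ΔCt against the arithmetic mean of the
reference-gene Cts (geometric mean on the expression scale, matching a
dual-reference design), ΔΔCt against a calibrator group, fold = 2^−ΔΔCt.

Enrichment is a one-sided hypergeometric upper tail (over-representation
only) with Bonferroni correction by the number of terms actually tested
(terms with ≥1 population gene), not the ontology size.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of parameters and seed; truth tables
score every stage without external data.

* **Proteomes** plant exact subgroup cassettes in random flanks; flanks
  are rejection-sampled against an independent regex check so no
  accidental zinc-finger or near-canonical heptapeptide appears —
  otherwise classifier "errors" could be generator artifacts.  Cassette
  filler positions avoid C/H/W for the same reason.  Real proteins have
  composition bias, paralog-specific drift and domain context that these
  sequences lack, so 100% recovery here demonstrates rule correctness,
  not real-proteome accuracy.
* **Codon pairs** use accept/reject evolution (synonymous proposals
  always accepted, nonsynonymous with probability ω, stops rejected),
  with the branch length as attempted changes per site (default runs use
  0.3 with 500 codons).  It is not a full codon-model process (no
  transition/transversion bias, no rate heterogeneity); recovery
  tolerance (±0.1 around ω = 0.2) is set accordingly.
* **Genomes** space planted structures >25 ranks apart so they cannot
  chain into spurious blocks; real genomes are denser and messier.
* **FPKM tables** use 8-fold planted effects, lognormal σ = 0.25
  replicate noise, 3 replicates, three varieties × two stages — the
  screen's design at a size (default 100 genes) where the suite runs in
  seconds.  Real RNA-seq has count noise, batch effects and correlated
  genes.

## Packaged fixtures

The 57-gene inventory, the per-stage candidate lists, the four-gene
reassignment map and the five-species subgroup reference are transcribed
from the printed tables of the source study and shipped as TSV with
SHA-256 checks and load-time invariants (record counts, closed label
vocabulary, list sizes).  They are inputs, not outputs: the package
treats printed tables as data the way it treats any TSV.

## Limitations

* Genome-wide rediscovery of the 57-member inventory from a real
  proteome is out of scope: identification used profile-HMM searches
  against curated databases, which this motif scanner does not replicate.
  The packaged inventory stands in for that step.
* Per-contrast DEG counts and the enrichment-term inventory of the
  original study depend on the raw sequencing data and annotation
  sources and are not recomputed; only the intersection arithmetic on
  the printed lists is reproduced.
* Cross-species synteny/orthology, tree inference, figure rendering and
  3D structure prediction are out of scope by design.
* The transposed-duplication call is an approximation (see above); on
  real genomes it will disagree with outgroup-based callers for a
  fraction of pairs.
* Scaffold-placed genes are ordered lexically after the numbered
  chromosomes when ranks are assigned; the original naming convention
  for scaffolds is not documented and cannot be checked.
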