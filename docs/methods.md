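# Methods

`chsfam` re-implements, at desk scale, the analysis strategy used by large
genome surveys of the fungal chitin synthase (CHS) gene family: candidate
screening, extraction of the conserved catalytic region, domain-architecture
typing, reference-guided phylogenetic class assignment, repertoire profiling,
and detection of the head-to-head *ChsV*/*ChsVII* gene arrangement.  This
note describes the models and procedures, the parameters that matter, the
synthetic data the tests run on, and the design choices made where the
procedure was genuinely open.

## The CON1 region and motif model

Every chitin synthase carries a conserved catalytic region, CON1, delimited
by three short motifs: QxxEY, EDRxL and QxRRW (`x` = any residue).  The
region is defined operationally: it starts at the start of a QxxEY
occurrence, ends at the end of a QxRRW occurrence, and an EDRxL occurrence
lies strictly between them, none overlapping.  When several ordered triples
exist, the minimal-span triple is chosen, ties broken by leftmost start and
then leftmost internal motif.  Minimal span plus a fixed tie order makes the
extraction deterministic; the minimum region length is 15 residues (three
non-overlapping 5-mers), and no maximum is imposed because surveyed CON1
lengths reach 1,200 aa (observed range 97–1,200 aa, mean 141 aa).

Motif patterns are fixed-length wildcard patterns with optional bracketed
alternatives, configurable as named sets.  The default ("primary") set is
the identification set above; an "alternate" set (QxxEY / [ED]Dx / Q[RQ]xRW)
reflecting looser definitions from the older literature is selectable but
not used for screening.  Probabilistic motif models are deliberately out of
scope — the three anchors are short, nearly invariant, and the operational
definition of CON1 depends on exact coordinates.

## Screening

A candidate is accepted when all three criteria hold:

1. **Characteristic domain** — at least one hit to {PF03142, PF01644} at
   E ≤ 1e-5, with cd04190 (the CDD model of the same catalytic domain)
   treated as an alias of PF03142.  PF01644 is included deliberately:
   Division 1 CHSs carry only the CON1 remnant of PF03142 (its N-terminus
   was lost by recombination, leaving the PF01644–CON1 fusion), so requiring
   an intact PF03142 would discard the whole division.
2. **CON1 present** — the extraction above succeeds.
3. **Not a duplicate** — within a species, proteins with identical
   full-length sequences are collapsed to the lexicographically smallest
   protein id.  Collapse runs after criteria 1–2 and only within species;
   cross-species identity is biologically meaningful and is kept.

The E-value threshold (1e-5) is a conventional domain-presence cutoff; the
original searches ran permissively (E = 10) and filtered by domain presence,
which needs a concrete operational threshold here.

## Domain architectures and structure types

Typing uses six focal accessions — PF08407, PF01644 (CS1), PF00063 (myosin
motor-like), PF00173 (cytochrome b5-like), PF03142 (CS2), PF08766
(DEK_C-like) — plus the CON1 token.  Resolution order: overlapping
same-accession hits are merged (union interval, best score); overlapping
different-accession hits are resolved greedily by higher bit score; a
PF03142 hit contained in (or partially overlapping) the CON1 region is
replaced by the CON1 token, whereas a PF03142 hit that itself contains the
region suppresses the token — an intact CS2 domain subsumes its catalytic
core.  Any other accession is recorded as auxiliary and never affects the
type label (surveys find ~20 domain types on CHSs, but only the focal six
show a class-correlated pattern).

Structure types are functions of the focal-element multiset, with order
checked only where the type definition states it (Group A requires PF01644
immediately followed by CON1; A3 requires PF03142 after CON1):

| Type | Elements |
|------|----------|
| A1 | PF01644–CON1 |
| A2 | PF08407–PF01644–CON1 |
| A3 | PF08407–PF01644–CON1 … PF03142 |
| B1 | PF03142 |
| B2 | PF03142 + PF00173 |
| B3 | PF00063 + PF03142 + PF08766 |
| B4 | PF00063 + PF00173 + PF03142 + PF08766 |

Everything else is `other`.

## Phylogenetics

The built-in tree machinery is intentionally compact: distance-based rather
than full maximum likelihood.  The classification contract — a query joins a
monophyletic labelled clade with bootstrap support above a threshold — is
preserved, and externally computed alignments (aligned FASTA) and trees
(Newick) can be imported wherever the built-in versions would be used.

- **Alignment** — progressive: pairwise global alignments (BLOSUM62, affine
  gaps open −10 / extend −1) give guide distances, a UPGMA guide tree fixes
  the merge order, and profiles are merged with an affine-gap Gotoh DP
  scoring columns as expected BLOSUM62 scores over residue frequencies
  (gaps contribute zero).  Traceback preference (diagonal, then gap-in-B,
  then gap-in-A) is fixed, so output is deterministic.
- **Distances** — p-distance over compared sites, optionally
  Poisson-corrected (d = −ln(1 − p)).  Site rules: `pairwise_deletion`, or
  `partial_deletion` which first drops columns with residue occupancy below
  a coverage threshold (default 95%) and then compares pairwise within the
  retained columns.  Zero comparable sites or a saturated pair under the
  correction is an error naming the pair.
- **Neighbor joining** — standard Saitou–Nei Q-criterion.  Determinism
  rules: ties in Q are broken by the lexicographically smallest
  cluster-label pair (a cluster is labelled by its smallest leaf name);
  negative branch lengths are clamped to zero with the deficit moved to the
  sister branch.  On additive matrices NJ provably recovers the generating
  topology; the tests verify this against brute-force enumeration.
- **Bootstrap** — alignment columns resampled with replacement per
  replicate; an internal edge's support is the percentage of replicate
  trees containing the same unrooted bipartition.  All resampling is driven
  by an explicit seed.

### Query placement

A query is profile-aligned to the labelled reference alignment, the joint
NJ tree rebuilt with bootstrap, and candidate host clades collected: the
bipartition sides containing the query whose reference leaves are non-empty
and all share one class label.  The smallest candidate wins; a size tie
between different labels means no placement (the query sits ambiguously
between class clades).  The support reported is the bootstrap of the *class
clade's* edge — the side holding the query plus every reference leaf of the
host label — because that is the edge the support threshold is meant to
protect; when that exact bipartition is absent from the point tree the
chosen candidate's edge is used instead.

Placements also record whether the query is **proximal** to its host: its
mean p-distance to the host's reference leaves must be less than half its
mean distance to all other reference leaves.  A genuine class member
(within-class divergence ≪ between-class) passes easily; a deeply divergent
sequence that merely attaches to a clade's stem is roughly equidistant to
every clade and fails.  The rule is scale-free (a ratio, no new tunable) and
exists because stem attachment with good clade support is otherwise
indistinguishable from membership by topology alone.

## Classification

Class calls combine structure type and placement.  Compatibility: classes
I, II, III and 23b ↔ A2; IV ↔ B2; V and VII ↔ B4; VI ↔ B1.  A class is
called iff the host label matches, support clears the threshold (default
60%, strict `>` matching the published ">60%" rule; configurable), and the
type is compatible; 23b is called through the same rule because the
reference's basal-to-(II+III) leaves carry their own `23b` label.  All other
cases are unclassified.

The noise-exclusion rule ("randomly scattered through the tree" in survey
language) is operationalised deterministically: Types A1, A3 and B3 are
always excluded; Type B1 is excluded unless placed in the Division 3
(Class VI) clade with support ≥ threshold *and* proximal as defined above;
excluded proteins are reported as unclassified with a `noisy` flag.  This
encodes the observed split of Type B1 proteins into Division 3 residents
versus scattered copies.

Species are processed one at a time against the master reference
("species-by-species" inclusion).  A query whose CON1 exactly equals a
reference leaf's sequence takes that leaf's class directly with support 100
instead of rebuilding a tree that contains a duplicate leaf — this both
mirrors the dedup-before-inclusion step and keeps the partition property
(every screened-in protein gets exactly one label).  Per-protein seeds are
derived from the base seed and the protein id (CRC32), so results are
independent of processing order and reproducible.

The reference must carry all seven classes; a reference missing a class is
rejected outright, since class calls against it would be systematically
impossible.

## Family dynamics

The profile is a species × class count matrix (including `unclassified`);
species known to the taxonomy with no accepted CHSs keep explicit zero
rows.  A taxon summary (taxa are lineage names or free-form tags such as
`early_diverging`, so groupings are data, not code) reports the mean CHS
count per species — rounded half-up to one decimal, the convention used in
survey reporting — and per class the fractions of member species with
multiple, one, or no members, which sum to one by construction.

## Synteny

Two genes are head-to-head when they share a contig, lie on opposite
strands with 5′ ends facing each other across the intergenic interval
(divergent transcription), and have at most `max_intervening` annotated
genes strictly between them.  The default of 1 encodes the observed
pattern for tandem V/VII duplicates: most pairs have no gene between them,
a minority a single predicted hypothetical gene.  No distance cap is
applied by default; one is configurable.  Intron status of a gene model is
`True` iff it has ≥ 2 exons, `False` iff exactly 1, unknown otherwise.
Species with multiple V or VII copies yield one call per V×VII pair,
flagged ambiguous; the arrangement call is symmetric in the two labels.

## Synthetic data: what it emulates and what it does not

The generator plants every signal the pipeline is designed to detect:

- a root CON1 (141 aa, the surveyed mean) carrying the three motifs, evolved
  along a fixed two-level tree (root → 3 divisions → 8 class lineages, with
  23b a sister lineage of II+III inside Division 1);
- substitution-only evolution, uniform over the 19 alternative residues per
  mutated site, with the motifs' fixed letters frozen so every descendant
  keeps extractable anchors;
- per-branch substitution rates calibrated numerically (Brent root-finding)
  so the *expected pairwise p-distance over the whole region* equals the
  configured divergence — within-class between two members (default 0.05
  substitutions/site), between-class between sibling-class consensuses
  (default 0.5).  Under this model the p-distance is an unbiased estimate of
  the configured divergence, which the calibration test checks to within
  three standard errors;
- class-specific architectures (I/II/III/23b → A2, IV → B2, V/VII → B4,
  VI → B1) assembled as flank + domain segments + CON1 + flank, with the
  domain-hit table emitted to match the planted architecture exactly (zero
  annotation noise);
- decoys lacking either a motif (EDRxL destroyed) or any characteristic
  domain hit; phylogenetically incoherent B1 copies drawn from the root at
  between-class divergence;
- gene models on one contig per species: eligible species with both V and
  VII receive a divergent adjacent pair with probability 0.95, with a
  single intervening hypothetical gene with probability 17/95 — both rates
  taken from the surveyed Pezizomycotina counts — and V/VII genes always
  have ≥ 2 exons.

A rejection loop re-draws any protein whose full sequence happens to contain
a spurious motif triple that would change the minimal-span extraction, so
extractor output always equals planted coordinates.

The default species table (12 species) mirrors surveyed taxon structure:
five filamentous Pezizomycotina-like species with full 7-class repertoires
(two also carrying 23b), two contracted Saccharomycotina-like yeasts, three
Basidiomycota-like species without Class VI, and two early-diverging-like
species expanded by eight unclassifiable B1 copies each.

**What it does not emulate:** indels (alignments of synthetic regions are
gap-free, so the aligner and the partial-deletion site filter are exercised
mainly by hand-built cases); rate heterogeneity across sites or lineages;
domain-annotation noise (coordinates are exact); genome rearrangement beyond
the planted arrangements; and realistic sequence composition.  Passing tests
therefore demonstrate the pipeline's logic under its stated assumptions —
they do not demonstrate robustness to alignment error or annotation noise in
real proteomes, where an ML tree and curated alignments (both importable)
are the appropriate instruments.

## Numerical and procedural choices

- All internal sequence coordinates are 0-based half-open; GFF3 stays
  1-based inclusive at its boundary; HMMER envelope coordinates are
  converted on input.  Envelope (not alignment) coordinates are used as the
  domain extent.
- Bootstrap replicates, simulation draws and placement orders all consume
  explicit seeds; per-protein seeds derive from (base seed, CRC32 of id).
- Ties everywhere (Q-matrix, motif triples, cluster joins, duplicate
  collapse) break lexicographically.
- Problem sizes used by the acceptance experiments: 100 placement queries
  per divergence setting, 100 bootstrap replicates, 24-leaf reference
  (3 per class), 50 additive-matrix trials at 6 taxa, 100 random motif
  layouts — sizes at which every stochastic criterion is stable across
  seeds while a full run stays in the tens of seconds.

## Known limitations

- NJ on corrected p-distances is a deliberate substitute for ML under WAG;
  on real, saturated data the two can disagree near the support threshold.
- The unclassified category is a rule surrogate (compatibility + support);
  surveys additionally applied judgement not reducible to a stated rule.
- `partial_deletion` filters columns globally and then compares pairwise
  within retained columns; implementations differ in whether remaining
  pairwise gaps are tolerated, and this choice is documented rather than
  universal.
- The proximal criterion's factor (one half) is a fixed "markedly closer"
  rule; it is scale-free but, like any fixed ratio, can misjudge datasets
  whose within/between divergence ratio approaches one — where
  classification is ill-posed anyway.
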