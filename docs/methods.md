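# Methods

## The model

The package treats superfamily classification as a graph filtration
problem. Every pair of sequences gets the significance of its optimal
local alignment, expressed as `logE = log10(m·n·2^(−bits))` with
`bits = (λS − ln K)/ln 2`; a sequence similarity network keeps the pairs
with `logE` below a stringency threshold, and connected components at
increasing stringency define families, then subfamilies. Function
(substrate head-group specificity) is transferred within clusters from
the sparse characterized members, on the empirical premise that
specificity is homogeneous within subfamilies even where it varies
within a family.

Assumptions worth making explicit:

- **Pairwise E-values, pairwise search space.** `m·n` is the product of
  the two aligned lengths, not a database size. A database-wide search
  space would shift every `logE` by the same constant, which the
  stringency thresholds absorb; the pairwise convention keeps an edge a
  property of its two sequences alone.
- **Threshold semantics.** "Edges shown below the threshold" is
  implemented as `logE ≤ t`. With continuous scores the boundary has
  measure zero; `≤` makes the preset ladders self-consistent.
- **Representative-level edges.** The edge between two representative
  nodes is the alignment of the two representatives, not the best of
  all member pairs — deterministic and cheapest, and the granularity at
  which the published networks are drawn.

## Scoring and numerical choices

- BLOSUM62 with affine gaps, open 11 / extend 1 (a length-k gap costs
  `11 + k`), λ = 0.267 nats, K = 0.041 — the standard published gapped
  protein defaults. All four are configurable through `ScoringScheme`.
- Scores come from exact dynamic programming (Biopython's
  `PairwiseAligner`); there is no heuristic seeding, so no score is ever
  underestimated. This caps practical corpus size at desk scale (a few
  thousand sequences), which is the intended regime.
- Percent identity of an edge uses aligned columns (including gap
  columns) as denominator, the convention of BLAST-style reports. The
  *clustering* identity used by the representative collapse instead
  divides identical columns by the **shorter sequence length** (the
  CD-HIT convention). The distinction matters: over a short
  high-scoring stretch two unrelated proteins can exceed 60% column
  identity, and using the column convention for clustering demonstrably
  merges unrelated background sequences; dividing by the shorter length
  makes 60% mean "near-duplicate over its whole length", which is what
  the collapse is for.
- Greedy collapse order: decreasing length, ties by id. Every tie in
  the pipeline (pair orientation, cluster labels, classification ties,
  NJ joins) is broken lexicographically, so all outputs are
  byte-reproducible.
- The empty local alignment (no positive-scoring pair) is reported as
  score 0, zero columns, identity 0.

## The cytochrome-b5 rule

Some desaturases carry a fused cytochrome-b5 electron-donor domain. A
shared fusion domain inflates pairwise significance for reasons
unrelated to the desaturase fold, so the fusion contributes to a pair's
E-value only when **both** partners carry it; otherwise both sequences
are trimmed to their desaturase portion (residues inside `cytb5` domain
ranges removed) before alignment, and `m`, `n` are the trimmed lengths.
Domain ranges are input metadata, not inferred: domain calling is a
separate, solved problem and out of scope here.

## Annotation transfer

A cluster's consensus substrate is decided by characterized members
only. "Strict majority" means the top substrate must exceed half of the
characterized votes; an exact tie *and* a plurality short of a majority
both report "ambiguous" (a 2-1-1 split is not a mandate), and a cluster
with no characterized member reports "unknown" with support 0.
Confidence attached to a classified query is the assigned cluster's
consensus support — the inherited claim is the cluster's, not the
pair's, so an E-value transform would overstate certainty.

Binding-site comparisons map user-supplied 1-based reference positions
through a global alignment (local alignment could truncate terminal
sites). Residue charge classes: positive {K,R,H}, negative {D,E},
polar-uncharged {S,T,N,Q,Y,C}, hydrophobic {A,V,L,I,M,F,W,G,P}; X and
gaps are "special". Histidine as positive is a stated convention —
desaturase His-box histidines are catalytic, and callers studying them
can supply their own table.

## The synthetic superfamily

The generator plants a star hierarchy: a uniform random root sequence,
family ancestors mutated from it at per-site probability `p_family`,
subfamily ancestors at `p_subfamily`, tips at `p_tip`; each site
substitutes to a uniformly chosen different residue. Defaults — the
study conditions of the recovery experiment — are 4 families × 3
subfamilies × 25 tips of 400 residues with rates 0.7 / 0.35 / 0.1, 50
unrelated background sequences, half of family 1 fused with a 90-aa
accessory segment (one accessory ancestor, tip-rate divergence), one
substrate label per subfamily, and 20% of tips characterized (at least
one per subfamily, so every subfamily has a definable consensus).

Under the lumped two-state recurrence
`P(same) ← P(same)(1−p) + (1−P(same))p/19` these rates give expected
identities of ≈ 81% within subfamilies, ≈ 35% within families and
≈ 9% between families — the separation of tiers the real superfamily
shows, in idealized form. What the generator deliberately does *not*
emulate: indels (alignment length equals sequence length within a
family), compositional bias and rate heterogeneity across sites,
realistic tree shapes, and partial-length sequences. Passing the
planted-recovery tests therefore demonstrates that the pipeline's graph
logic, thresholds and bookkeeping are correct under controlled identity
tiers — not that the thresholds are optimal for any particular real
corpus, where score variance and domain architecture are messier.

Background sequences are mutually unrelated by construction, so the
planted truth treats each one as its own singleton family; the adjusted
Rand index is computed over all retained sequences, components
propagated from representative nodes to their members.

## Frozen experiment parameters

A pilot sweep of the default configuration (three seeds) placed the
edge tiers at roughly −40…−60 for cross-subfamily pairs, down to about
−100…−116 where both representatives carry the shared b5 segment, with
within-subfamily alignments near −170. The recovery experiment
therefore scores **family** recovery at `logE ≤ −13` (the overview
stringency, far looser than any within-family edge) and **subfamily**
recovery and hold-out classification at `logE ≤ −130`, mid-gap between
the fused cross-subfamily tier and the within-subfamily tier. These two
values are frozen constants (`FAMILY_THRESHOLD`, `SUBFAMILY_THRESHOLD`)
alongside the published ladder (−5, −13, −20, −30, −56, −65).

The hold-out experiment withholds 20% of tips (never background) before
the network is built; a held-out tip is "correct" when it is assigned
to the cluster holding the majority of its subfamily's training tips.

Problem sizes throughout (350-sequence corpora, 62 representative
nodes, 60 hold-out queries) are chosen so the full experiment runs in a
few minutes on one CPU while keeping every identity tier populated.

## The companion tree

The `phylo` module is explicitly an approximation, not a reimplementation
of a maximum-likelihood analysis: distances are
`d = −ln(max(p − 0.05, ε)/0.95)` from pairwise local-alignment
fractional identity `p` (0.05 is the 20-letter random-identity floor;
`ε = 0.01` caps pairs at or below random identity at a finite ceiling
of ≈ 4.55), and the tree is neighbor joining with Studier–Keppler
branch lengths, lexicographic tie-breaking, and negative branches
clamped to zero with a warning (none occur on additive inputs, which
the tests verify are reproduced exactly). No multiple alignment is
built, so bootstrap support is undefined and deliberately absent.

## Known limitations

- O(n²) exact alignment: not for proteome-scale inputs.
- The length filter default (250, 550) follows the procedural record;
  the (350, 550) overview range is available as the `"overview"`
  preset. Both are corpus-assembly choices, not biology.
- Query classification is nearest-representative; remote homologues
  below the assignment cutoff are reported "unclassified" rather than
  guessed.
- Consensus transfer is only as good as the curation of the
  "characterized" labels; a single mislabelled member in a small
  cluster shifts the consensus.
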