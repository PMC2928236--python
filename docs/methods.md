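# Methods

This note records the models and procedures `silkphylo` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Characters and missing data

All parsimony operations use unordered (Fitch) characters. Alignment gaps
(`-`), the `?` symbol, and the alphabet placeholders (`X` for protein, `N`
for nucleotide) are normalized to missing at read time; a missing cell
contributes its column's full observed state set and therefore never adds
steps. Coordinates in every report are 1-based inclusive, matching the
usual "position 70 / position 140" style of alignment discussion.
Concatenated matrices number the first block first, so an N block of 168
columns followed by a C block of 109 gives combined positions 1–168 and
169–277, and a taxon absent from one block can be filled with missing data
(this mirrors how a partial sequence — e.g. a spidroin with an unknown
C-terminus — enters a combined analysis).

## Motif grammar

Five structural motif classes of silk repeat biology are coded as 0/1
characters: a poly-alanine run of ≥ 4 contiguous A; ≥ 2 consecutive GA
couplets; ≥ 2 consecutive GS couplets; ≥ 2 contiguous GPGX units (GPG
followed by 1–3 residues from a configurable X set, default {G,Q,Y,S,A},
the residues seen in published GPGXX silk motifs); and ≥ 2 tandem GGX
units with X any standard residue. All thresholds live in `MotifConfig`, so
changing the X set or a minimum run length is a one-line edit. Overlapping
parses resolve left-greedily (the regex engine's leftmost match), which
makes scanning deterministic and independent of input order; missing
symbols break every run. Scanning is monotone under concatenation: a motif
present in a fragment is present in any extension.

## Hydropathy, identity, conservation, terminus pairing

Hydropathy profiles are sliding-window arithmetic means of the published
Kyte–Doolittle residue scale (taken from Biopython); the default window of
11 is a conventional choice for domain-scale profiles and is configurable.
Windows touching a missing symbol emit no value, which appears as a break
over gapped regions when plotted. Pairwise identity between two aligned
sequences counts matches over the columns where *both* are non-missing, so
identical partial sequences score 100%; this denominator choice is
documented because published identity figures rarely state theirs. A
column is universally conserved when every sequence carries the same
non-missing residue, and majority-conserved when one residue reaches the
(inclusive) majority fraction, default 0.5.

N- and C-terminal partial cDNAs are paired when they come from the same
species and their repeat fragments agree at ≥ 95% identity over ≥ 30
aligned residues under a simple ungapped sliding comparison. "Nearly
identical" has no published operational threshold, so both numbers are
configurable; every qualifying candidate is reported and multiple matches
are flagged ambiguous rather than resolved silently (the realistic outcome
for recently duplicated paralogs with near-identical repeats).

## Parsimony engine

Fitch lengths are computed by the two-pass set algorithm over bit-packed
state sets: every character occupies a fixed-width field of one big
integer (one bit per observed state plus a guard bit), so one tree is
scored with a handful of bitwise operations regardless of matrix width.
Exhaustive search enumerates all (2n−5)!! unrooted topologies up to 10
taxa and is the oracle for everything else. Heuristic search does
random-order stepwise addition followed by first-improvement branch
swapping (NNI, SPR, or full tree-bisection-reconnection; TBR is the
default), pooling equally short trees across addition replicates and
closing the set over equal-length neighbours up to a `maxtrees` cap
(default 64). Heuristic MPT sets are therefore lower bounds on the true
set of most parsimonious trees — the usual caveat for any heuristic
search. All randomness flows through one explicit integer seed; searches,
bootstraps and permutation tests are bit-reproducible.

Tree collections are canonically ordered by their sorted split sets so
repeated runs print identical output. Bootstrap pseudo-replicates resample
columns jointly across partitions (standard behaviour for combined
matrices); a replicate contributes once per split, averaged over its tied
shortest trees. Bremer decay of a split is the length difference between
the best trees lacking it and the global optimum — computed by filtered
exhaustive enumeration up to 10 taxa and by reverse-constraint (forbidden
split) heuristic search above that. CI and RI use the standard m/s and
(g−s)/(g−m) definitions with g the star-tree maximum; a matrix with no
steps has CI defined as 1.

## Branch-support decomposition

PBS at a node is the difference between a partition's mean length on the
shortest combined-data trees lacking the node and its mean length on the
combined MPTs; means over ties make fractional values natural. Because
every tied tree shares the same total length, Σ over partitions of PBS
equals the node's Bremer support exactly — the identity the test suite
uses as the primary oracle. Separate-analysis branch support is signed:
positive decay when the partition's own shortest trees contain the node,
and −(extra steps to include it) when they contradict it. PHBS and HBS
follow by subtraction. The partition-homogeneity test removes invariant
characters, permutes the remaining characters among blocks of the original
sizes, and reports the add-one permutation p-value for D = combined length
− Σ separate lengths, with larger D more extreme; D ≥ 0 always because
concatenation cannot shorten trees. Conflict detection between two
support-annotated trees reports pairs of splits that are incompatible by
the four-intersection rule and both meet the support threshold (default
70, intended for bootstrap percentages; posterior-probability thresholds
would need a Bayesian analysis, which this package does not perform).

## Ancestral states: Sankoff DP, ACCTRAN/DELTRAN

Ancestral reconstruction runs a unit-cost Sankoff dynamic programme on the
rooted tree: a downward pass gives per-node-per-state subtree costs, an
upward pass the cost of the rest of the tree, and their sum identifies the
MPR state set at every node (a node with MPR {0,1} is flagged equivocal).
The two classical optimizations are deterministic trace-backs: DELTRAN
keeps the parental state whenever doing so is cost-neutral (delaying
changes), ACCTRAN changes state whenever a change is cost-neutral
(accelerating them); ties among target states break to the smallest
symbol, and the root takes the smallest-symbol state among its optimal
set. Both trace-backs attain the character's Fitch length by construction,
which the tests assert instance by instance. A synapomorphy is listed for
a branch only when both optimizations place a change there with identical
ancestral and derived states; everything else is reported as ambiguous.
Motif characters are treated as unordered and freely reversible (gains and
losses cost the same) by default; because the plausibility of regaining a
lost silk motif is debatable, a Dollo alternative (`dollo_reconstruction`:
a single gain on the stem of the smallest clade containing every presence,
losses counted inside it) is offered alongside.

## Reconciliation and rooting

A rooted binary gene tree is embedded in a rooted binary species tree by
the LCA map; a gene node duplicates when its image equals a child's image,
and losses are counted per gene edge as the species-path length k minus
one for speciations, k for duplications. The weighted score is
c_dup·D + c_loss·L with the Notung-default costs 1.5 and 1.0. The species
tree is pruned to the species present in the gene tree before counting
losses — otherwise never-sampled species inflate L; `prune=False` (CLI
`--no-prune`) restores the stricter behaviour. Root search evaluates all
2n−3 branches of the unrooted gene tree and returns the full ranking with
co-optimal rootings adjacent, never tie-broken silently. Polytomies are
rejected rather than resolved. The bundled species tree
(`data/species_tree_synthetic.nwk`) is a synthetic stand-in assembled from
coarse, text-stated lineage memberships of the 15 study species; it is an
example input, not an authoritative phylogeny.

## Synthetic data generator

The generator reproduces the statistical shape of a terminal-domain study,
with every quantity recorded as ground truth:

- **Species tree**: pure-birth (Yule) topology, ultrametric, depth scaled
  to 1; default 15 species.
- **Gene family**: birth–death of gene lineages along the species tree
  (defaults: duplication 0.5 and loss 0.2 events per unit branch length,
  giving families of roughly 15–25 surviving copies). Internal nodes carry
  duplication/speciation labels; a duplication with no surviving second
  copy is unobservable and is not counted, so with loss rate 0 the
  recorded count is exactly what reconciliation should recover.
- **Domain matrix**: root sequences drawn uniformly over the 20 amino
  acids, N length 151–162 and C length 87–107 (the study's observed
  ranges), evolved by a symmetric jump process (Poisson substitutions per
  site, uniform replacement). Intensities default to 0.95 (N) and 1.5 (C)
  substitutions/site per unit depth, calibrated once so mean N-terminal
  pairwise identity across replicate datasets sits near the mid-30s% with
  the C block consistently lower — the conservation contrast the real
  domains show. No indels are simulated: the real pipeline takes
  alignments as input, so synthetic matrices enter at the same stage.
- **Repeats**: motif presence evolves per motif by a two-state Markov
  gain/loss process (defaults 0.4/0.4, root presence probability 0.5);
  each tip's exemplar is assembled from grammar units and inert spacer
  residues and is verified at construction to scan back to its true state
  vector.
- **Paired transcripts**: each tip's N and C partial transcripts share an
  identical 40-residue repeat flank; other paralogs of the same species
  carry decoy flanks mutated to ~70% identity, below the pairing
  threshold.

What passing recovery tests show — and what they do not: the synthetic
matrices are gap-free, rate-homogeneous across sites, and free of
alignment error, composition bias, and the G/A-rich compositional
peculiarity of real silk domains. Recovery under these conditions
validates the algorithms, not the robustness of the biological
conclusions to real-data violations.

## Problem sizes and numerics

The test suite exercises exact oracles at small sizes chosen so the whole
suite runs in well under a minute of CPU per heavy check: Fitch versus
labeling enumeration on all topologies with ≤ 6 leaves × 1000 characters;
heuristic versus exhaustive search on 100 random 7-taxon matrices;
support-decomposition identities on 50 random 6-taxon two-partition
matrices; reconciliation versus embedding enumeration for every rooted
gene topology on 4–6 leaves; 200-permutation homogeneity tests; 100
single-gain recovery replicates; and a full simulate→search→support→
reconcile→motif pipeline run twice under one seed and compared bit for
bit. Identities (ΣPBS = BS, PHBS arithmetic) are asserted to 1e-9;
integer quantities exactly. Degenerate inputs fail loudly: searches need
≥ 4 taxa, exhaustive search refuses > 10, reconstruction refuses unrooted
trees, reconciliation refuses polytomies and unmapped leaves, and all
readers reject malformed input rather than repairing it.

## Known limitations

Likelihood and Bayesian methods (model-based scoring, posterior supports,
topology tests) are out of scope by design. Heuristic MPT counts are not
guaranteed complete, so support values computed from them are approximate
in the way all reverse-constraint heuristics are. The ILD test's known
sensitivity to rate heterogeneity between partitions is inherited, not
corrected. ACCTRAN/DELTRAN trace-backs use deterministic tie-breaking;
other equally parsimonious event placements exist whenever the two
optimizations disagree, and the event summaries flag exactly those cases.
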