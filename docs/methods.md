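# Methods

## Arrangement model and canonicalization

A mitogenome is an ordered sequence of signed elements over a 38-token
vocabulary (13 PCGs, 2 rRNAs, 22 tRNAs, CR), circular for complete genomes
and linear for chromosomes of multipartite genomes. Two physical facts drive
all comparisons:

1. a circular genome has no origin — any rotation is the same genome;
2. strand labels are a reading convention — reversing the order and flipping
   every strand (full reflection) is the same genome.

`linearize` therefore picks a canonical representative: rotate so `cox1`
(present and unique in every genome analysed; fallbacks `cox2`, `cob`,
`rrnL` for fragments) comes first, reflecting first if needed to put the
anchor on the majority strand. It is idempotent and invariant under
rotation/reflection of the input, so equality of canonical token lists is
equality of genomes.

Duplicated elements get copy indices by order of appearance along the
canonical walk (deterministic labelling for duplicate tRNAs and CRs).
CR2/CR3 are stored as copies 2/3 of `CR`.

## Boundaries

A boundary is the junction between consecutive elements. Its canonical key
renders both readings — `X→Y` and `−Y→−X` — and keeps the lexicographically
smaller string, with copy indices stripped (boundary identity is
gene-identity based: a `trnM.2` junction counts as a `trnM` junction) and CR
strand ignored (CRs are non-coding; no strand is biologically meaningful).
Strand-awareness matters: an in-place inversion must create derived
boundaries, which an unsigned adjacency model would miss. Because published
totals rarely state their convention, two switches are exposed and swept in
the report: `cr_mode` (`exclude` deletes CRs first, so genes flanking a CR
become adjacent — the default for ancestral/derived accounting, matching the
"37 ancestral boundaries" of the CR-free ancestor; `include` keeps CRs, for
reporting CR locations) and `strand_sensitive` (default on; off reduces keys
to unordered gene pairs).

Classification against the fixed ancestral insect arrangement is a set
intersection of canonical keys; the catalogue tallies, per taxon and overall,
ancestral vs derived boundaries and the shared/unique split of distinct
derived keys. Multipartite genomes contribute their chromosomes as separate
linear arrangements whose ends add no wrap-around adjacency; missing genes
are not imputed — absence simply changes the flanking adjacency. The
breakpoint distance requires equal gene content; an option removes
asymmetric genes from both sides first (the standard treatment of undetected
tRNAs in pairwise comparisons).

## Conserved blocks

A block is a maximal circular run of consecutive ancestral boundaries each
retained by **at least one** study taxon (maximality over the union, not per
taxon — so a block can be complete in no single taxon while its pieces
survive in different lineages). Blocks are labelled A, B, … walking the
ancestor from the anchor. Per taxon a block is complete (all member
boundaries present), modified (some), or absent (none); a translocation into
the middle of a block breaks an internal boundary and yields "modified".
Degenerate case: if every ancestral boundary is retained somewhere the
single block is the whole circle and carries #genes boundaries rather than
#genes − 1.

## Parsimony mapping

Each derived boundary is a binary presence/absence character over the tree
tips; the ancestor is attached as an outgroup tip scoring 0 everywhere. The
bottom-up pass is the unit-cost Sankoff recursion (equivalent to Fitch for
two states); the top-down pass enumerates **all** most-parsimonious
reconstructions — feasible at ≤15 tips — and summarises each as its gain and
loss edge sets. The root state is fixed to 0 in classification: the root
ancestor by construction lacks every derived boundary, and with a state-0
outgroup tip at the root this provably never changes the change count — it
only discards reconstructions that posit a bogus loss along the ancestor's
own lineage (e.g. for a character present in every ingroup tip).

Classification: autapomorphy (one tip), synapomorphy (every reconstruction
is exactly one gain, no losses — the gain edge is then unique and names the
supported clade), otherwise homoplastic-or-secondarily-lost. Gain-edge
candidates across reconstructions are reported for the residual ambiguous
cases. Gains and losses cost the same; this matches a screen for
*unambiguous* synapomorphies rather than a Dollo model in which a shared
derived state is never regained.

## Simulator

Four content-preserving operators act on the circular order: transposition
(segment moves), inversion (segment reversed in place, strands flipped),
inverse transposition (both), and TDRL (segment duplicated in tandem, then
one copy of each duplicated gene deleted by an independent fair coin;
all-heads/all-tails regenerate the parent and are permitted). Segment choice:
start uniform on the circle, length 1 + geometric(`segment_length_param`,
default 0.7) truncated at n−2, favouring the short moves that dominate
observed rearrangements; a rejection step accepts tRNA-only segments with
relative weight `trna_mobility_weight` (default 4), reflecting the much
higher mobility of tRNAs than of PCGs/rRNAs. Two logged non-conserving
processes: CR duplication (probability 0.1/branch, uniform position) and
tRNA loss (probability 0.02/branch, uniform victim — the real data show one
lost tRNA in 14 genomes).

Per branch, event counts are Poisson(rate × branch length, default length 1)
per class, applied in uniformly shuffled order (no within-branch order
information exists). One seeded generator consumed in fixed preorder makes
runs bit-reproducible, and the event log (branch, event parameters, result
hash) replays to the exact tip arrangements. The outgroup branch is
event-free by default: that tip stands for the lineage that retained the
ancestral arrangement.

Preset rates for `thrips_like` (transposition 1.8, inversion 0.45, inverse
transposition 0.3, TDRL 0.4 per branch) were calibrated once so tips average
20–30 derived boundaries, the regime of the real 14-genome thrips data
(403/14 ≈ 29 per taxon); measured mean ≈ 25 across seeds. `single_event`
places one "clean" single-gene transposition (moved gene, its neighbours and
the insertion flanks all non-CR and distinct) on the Frankliniella + Thrips
stem, guaranteeing exactly three novel adjacencies whatever the CR mode —
the ground truth for recovery tests. `ancestor_only` applies no events.

## What the synthetic data does and does not show

The simulator emulates the *process* structure of the real data — event
classes, tRNA-biased mobility, CR duplication, rare tRNA loss, a fixed
14-taxon tree — but not: sequence evolution, selection on gene order,
rate variation between branches (all branch lengths default to 1), or the
clustered multi-gene TDRLs that common-interval analyses infer for the
deepest thrips branches. Passing recovery tests therefore shows the
*analysis* is correct and internally consistent, not that the event model is
an adequate fit to thrips history. Reproduction of the published totals
requires the 14 deposited GenBank records (`scripts/fetch_genbank.py`);
the real-data acceptance test sweeps both CR modes and both strand
conventions and reports per-convention discrepancies when no convention
matches.

## Numerical and degenerate-input choices

* Tie-breaks in GenBank feature ordering: start coordinate, then feature
  length descending (stable for overlapping genes like atp8/atp6);
  origin-spanning joins are placed by their first-listed fragment.
* When both a bare `gene` feature and a typed CDS/tRNA/rRNA feature cover a
  span, the typed feature wins (it carries the product qualifiers used for
  name canonicalization); misc_features are CRs only when their notes say so,
  otherwise ignored.
* Arrangements shorter than 2 elements after CR removal are rejected.
* MPR enumeration is capped (10^5) as a safety net; the cap is unreachable
  on ≤15-tip trees.
* Problem sizes in tests and the acceptance script (200 random arrangements,
  200 random characters on 8 tips, 100 replay runs, 5–10 preset replicates)
  were chosen to make brute-force oracle comparison exact and exhaustive
  while keeping the whole suite under a few seconds.

## Known limitations

* The synapomorphy screen is topology-conditional: it takes the tree as
  fixed truth and does not propagate phylogenetic uncertainty.
* Boundary characters are not independent (one event changes up to three),
  so synapomorphy counts are descriptive, not a likelihood-based test.
* Copy-index stripping means a duplicated gene's two junction sets can
  collapse to one key; this matches gene-identity-based boundary accounting
  but discards paralogue-specific signal.
* Event-scenario inference between genome pairs (common-interval methods)
  and ancestral whole-genome reconstruction are out of scope by design.
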