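"""Conserved ancestral gene blocks and per-taxon retention scoring.

A *gene block* is a maximal run of consecutive ancestral adjacencies each of
which is retained by at least one taxon in the study set (maximality over the
union of taxa, so a block may be complete in no single taxon).  Per taxon a
block is *complete* when all its member boundaries are present, *modified*
when some but not all are (e.g. another gene translocated into the block),
and *absent* when none are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .boundary_analysis import BoundaryCatalogue, adjacency_pairs
from .errors import UnknownTaxon
from .genome_model import Arrangement, SignedGene, linearize

Retention = Literal["complete", "modified", "absent"]


def _letters(i: int) -> str:
    """0 -> A, 1 -> B, ..., 26 -> AA (blocks beyond Z are unlikely but legal)."""
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


@dataclass
class GeneBlock:
    """A maximal conserved run of ancestral adjacencies."""

    block_id: str
    genes: tuple[SignedGene, ...]
    member_boundaries: tuple[str, ...]
    retention: dict[str, Retention]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _status(member: tuple[str, ...], present: set[str]) -> Retention:
    hits = sum(1 for k in member if k in present)
    if hits == len(member):
        return "complete"
    return "modified" if hits else "absent"


def detect_conserved_blocks(
    catalogue: BoundaryCatalogue, ancestor: Arrangement
) -> list[GeneBlock]:
    """Find all conserved blocks and score retention for every taxon.

    Blocks are labelled A, B, ... walking the ancestor from the linearization
    anchor.  When every ancestral boundary is retained somewhere the single
    block covers the whole circle (its boundary count then equals its gene
    count rather than gene count - 1).
    """
    anc = linearize(ancestor)
    pairs = adjacency_pairs(
        Arrangement(anc.taxon_id, anc.elements, "circular", anc.source),
        catalogue.cr_mode,
    )
    keys = [
        b.canonical_key if catalogue.strand_sensitive else b.strand_insensitive_key
        for b in pairs
    ]
    elems = [b.left for b in pairs]  # elems[i] -| keys[i] |- elems[i+1 mod n]
    retained = catalogue.ancestral_retained_keys()
    n = len(keys)
    marked = [k in retained for k in keys]

    blocks: list[GeneBlock] = []
    if all(marked):
        member = tuple(keys)
        genes = tuple(elems)
        blocks.append(GeneBlock("A", genes, member, _retention(catalogue, member)))
        return blocks

    runs: list[list[int]] = []
    i = 0
    while i < n:
        if marked[i] and not marked[(i - 1) % n]:
            run = []
            j = i
            while marked[j % n]:
                run.append(j % n)
                j += 1
            runs.append(run)
            i = j
        else:
            i += 1
    runs.sort(key=lambda r: r[0])
    for idx, run in enumerate(runs):
        member = tuple(keys[i] for i in run)
        genes = tuple(elems[i] for i in run) + (elems[(run[-1] + 1) % n],)
        blocks.append(GeneBlock(_letters(idx), genes, member, _retention(catalogue, member)))
    return blocks


def _retention(catalogue: BoundaryCatalogue, member: tuple[str, ...]) -> dict[str, Retention]:
    return {
        taxon: _status(member, tb.ancestral)
        for taxon, tb in catalogue.per_taxon.items()
    }


def block_status(block: GeneBlock, taxon_id: str, catalogue: BoundaryCatalogue) -> Retention:
    """Retention status of one block in one taxon."""
    if taxon_id not in catalogue.per_taxon:
        raise UnknownTaxon(taxon_id)
    return _status(block.member_boundaries, catalogue.per_taxon[taxon_id].ancestral)
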