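"""Strand-aware gene adjacencies (boundaries) and ancestral/derived accounting.

A *boundary* is the junction between two elements immediately consecutive on
the genome.  Because a circular genome can be read from either strand, the
adjacency ``X -> Y`` is the same physical junction as ``-Y -> -X``; the
canonical key of a boundary is the lexicographically smaller of the two
renderings, with copy indices stripped (boundary identity is gene-identity
based) and CR strand ignored (CRs are non-coding).

Boundaries present in the fixed ancestral arrangement are *ancestral*; all
others are *derived*.  Derived boundaries found in two or more taxa are
*shared*; those found in exactly one taxon are *unique*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import ArrangementTooShort, DuplicateTaxonId, GeneContentMismatch
from .genome_model import Arrangement, SignedGene

CrMode = Literal["exclude", "include"]


def _signed_name(sg: SignedGene) -> str:
    # copy_index stripped; CR strand recorded but never compared
    strand = "+" if sg.label.is_cr else sg.strand
    return ("-" + sg.name) if strand == "-" else sg.name


def _neg(signed: str) -> str:
    return signed[1:] if signed.startswith("-") else "-" + signed


@dataclass(frozen=True)
class Boundary:
    """A strand-aware adjacency between two signed elements."""

    left: SignedGene
    right: SignedGene

    @property
    def canonical_key(self) -> str:
        a, b = _signed_name(self.left), _signed_name(self.right)
        fwd = f"{a}|{b}"
        rev = f"{_neg(b)}|{_neg(a)}"
        return min(fwd, rev)

    @property
    def strand_insensitive_key(self) -> str:
        return "|".join(sorted((self.left.name, self.right.name)))


def boundary_key(left: SignedGene, right: SignedGene, strand_sensitive: bool = True) -> str:
    b = Boundary(left, right)
    return b.canonical_key if strand_sensitive else b.strand_insensitive_key


def adjacency_pairs(a: Arrangement, cr_mode: CrMode = "exclude") -> list[Boundary]:
    """All boundaries of an arrangement, in genome order.

    In ``exclude`` mode CR elements are deleted first, so the genes flanking a
    CR become adjacent.  A circular arrangement with *n* surviving elements
    yields *n* boundaries; a linear one yields *n* - 1 (chromosome ends
    contribute no wrap-around boundary).
    """
    elems: Sequence[SignedGene] = (
        [sg for sg in a.elements if not sg.label.is_cr]
        if cr_mode == "exclude"
        else list(a.elements)
    )
    if len(elems) < 2:
        raise ArrangementTooShort(
            f"{a.taxon_id}: {len(elems)} element(s) after CR handling"
        )
    pairs = [Boundary(elems[i], elems[i + 1]) for i in range(len(elems) - 1)]
    if a.topology == "circular":
        pairs.append(Boundary(elems[-1], elems[0]))
    return pairs


def adjacency_set(
    a: Arrangement, cr_mode: CrMode = "exclude", strand_sensitive: bool = True
) -> set[str]:
    """The set of canonical boundary keys of an arrangement."""
    return {
        b.canonical_key if strand_sensitive else b.strand_insensitive_key
        for b in adjacency_pairs(a, cr_mode)
    }


@dataclass
class TaxonBoundaries:
    """Classified boundaries of one taxon relative to the ancestor."""

    taxon_id: str
    ancestral: set[str] = field(default_factory=set)
    derived: set[str] = field(default_factory=set)

    @property
    def n_boundaries(self) -> int:
        return len(self.ancestral) + len(self.derived)


def classify_vs_ancestor(
    a: Arrangement,
    ancestor: Arrangement,
    cr_mode: CrMode = "exclude",
    strand_sensitive: bool = True,
) -> TaxonBoundaries:
    """Split a taxon's boundaries into ancestral vs derived.

    A boundary is ancestral iff its canonical key occurs in the ancestor's
    adjacency set; classification is invariant under rotation and reflection
    of either arrangement.
    """
    anc_keys = adjacency_set(ancestor, cr_mode, strand_sensitive)
    keys = adjacency_set(a, cr_mode, strand_sensitive)
    return TaxonBoundaries(
        taxon_id=a.taxon_id,
        ancestral=keys & anc_keys,
        derived=keys - anc_keys,
    )


@dataclass
class BoundaryCatalogue:
    """Merged boundary classification across a taxon set.

    ``derived_taxa`` maps each distinct derived key to the set of taxa
    carrying it; the unique/shared split follows from the taxon-set size.
    """

    ancestor_id: str
    cr_mode: CrMode
    strand_sensitive: bool
    ancestor_keys: set[str]
    per_taxon: dict[str, TaxonBoundaries]

    @property
    def taxa(self) -> list[str]:
        return list(self.per_taxon)

    @property
    def derived_taxa(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for tb in self.per_taxon.values():
            for key in tb.derived:
                out.setdefault(key, set()).add(tb.taxon_id)
        return out

    @property
    def shared_derived_keys(self) -> set[str]:
        return {k for k, t in self.derived_taxa.items() if len(t) >= 2}

    @property
    def unique_derived_keys(self) -> set[str]:
        return {k for k, t in self.derived_taxa.items() if len(t) == 1}

    @property
    def total_derived_boundaries(self) -> int:
        """Sum over taxa of per-taxon derived boundary counts."""
        return sum(len(tb.derived) for tb in self.per_taxon.values())

    def ancestral_retained_keys(self) -> set[str]:
        """Ancestral boundaries retained by at least one taxon."""
        out: set[str] = set()
        for tb in self.per_taxon.values():
            out |= tb.ancestral
        return out

    def summary(self) -> dict[str, int]:
        return {
            "n_taxa": len(self.per_taxon),
            "total_derived_boundaries": self.total_derived_boundaries,
            "distinct_shared_derived": len(self.shared_derived_keys),
            "distinct_unique_derived": len(self.unique_derived_keys),
            "ancestral_boundaries": len(self.ancestor_keys),
            "ancestral_retained_somewhere": len(self.ancestral_retained_keys()),
        }


def build_catalogue(
    arrangements: Iterable[Arrangement],
    ancestor: Arrangement,
    cr_mode: CrMode = "exclude",
    strand_sensitive: bool = True,
) -> BoundaryCatalogue:
    """Classify every taxon against the ancestor and merge the results.

    A taxon id may appear on several *linear* arrangements (the chromosomes
    of a multipartite genome); their boundary sets are unioned, and chromosome
    ends contribute no artificial adjacency.  Duplicate circular arrangements
    for one taxon raise :class:`DuplicateTaxonId`.
    """
    anc_keys = adjacency_set(ancestor, cr_mode, strand_sensitive)
    per_taxon: dict[str, TaxonBoundaries] = {}
    seen_circular: set[str] = set()
    for a in arrangements:
        tb = classify_vs_ancestor(a, ancestor, cr_mode, strand_sensitive)
        if a.taxon_id in per_taxon:
            if a.topology != "linear" or a.taxon_id in seen_circular:
                raise DuplicateTaxonId(a.taxon_id)
            merged = per_taxon[a.taxon_id]
            merged.ancestral |= tb.ancestral
            merged.derived |= tb.derived
        else:
            per_taxon[a.taxon_id] = tb
            if a.topology == "circular":
                seen_circular.add(a.taxon_id)
    if not per_taxon:
        raise ValueError("need at least one arrangement")
    return BoundaryCatalogue(
        ancestor_id=ancestor.taxon_id,
        cr_mode=cr_mode,
        strand_sensitive=strand_sensitive,
        ancestor_keys=anc_keys,
        per_taxon=per_taxon,
    )


def pairwise_shared_derived(
    a: Arrangement,
    b: Arrangement,
    ancestor: Arrangement,
    cr_mode: CrMode = "exclude",
    strand_sensitive: bool = True,
) -> int:
    """Number of derived boundary keys present in both taxa (symmetric)."""
    ta = classify_vs_ancestor(a, ancestor, cr_mode, strand_sensitive)
    tb = classify_vs_ancestor(b, ancestor, cr_mode, strand_sensitive)
    return len(ta.derived & tb.derived)


def breakpoint_distance(
    a: Arrangement,
    b: Arrangement,
    cr_mode: CrMode = "exclude",
    strand_sensitive: bool = True,
    restrict_to_shared: bool = False,
) -> int:
    """Breakpoint distance: adjacencies of ``a`` absent from ``b``.

    Requires equal gene content after CR handling and copy-index stripping
    (symmetric in that case).  With ``restrict_to_shared`` genes absent from
    either arrangement are removed from both before comparison, mirroring the
    treatment of undetected tRNAs in pairwise analyses.
    """
    def content(x: Arrangement) -> set[str]:
        return {
            sg.name for sg in x.elements
            if not (cr_mode == "exclude" and sg.label.is_cr)
        }

    ca, cb = content(a), content(b)
    if ca != cb:
        if not restrict_to_shared:
            raise GeneContentMismatch(ca - cb, cb - ca)
        shared = ca & cb
        a = _restrict(a, shared)
        b = _restrict(b, shared)
    ka = adjacency_set(a, cr_mode, strand_sensitive)
    kb = adjacency_set(b, cr_mode, strand_sensitive)
    return len(ka - kb)


def _restrict(a: Arrangement, names: set[str]) -> Arrangement:
    from dataclasses import replace

    kept = tuple(sg for sg in a.elements if sg.name in names or sg.label.is_cr)
    return replace(a, elements=kept)
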