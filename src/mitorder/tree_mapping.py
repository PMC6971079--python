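"""Parsimony mapping of derived-boundary characters onto a fixed rooted tree.

Each derived boundary becomes a binary presence/absence character over the
tips.  Unit-cost (Fitch) parsimony gives the minimum number of state changes;
enumerating *all* most-parsimonious reconstructions (MPRs) lets us apply a
strict synapomorphy screen: a boundary is an unambiguous synapomorphy for
clade N only when every MPR consists of exactly one 0->1 gain (on the branch
to N) and no 1->0 losses.  Characters failing that screen are homoplastic or
secondarily lost; characters present in a single tip are autapomorphies.

The ancestor is represented by an outgroup tip carrying state 0 for every
derived character (the outgroup lineage retained the ancestral arrangement).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

from .block_detection import GeneBlock
from .boundary_analysis import BoundaryCatalogue
from .errors import UnknownTaxon

INF = float("inf")


def clade_name(node: dendropy.Node) -> str:
    """Stable node id: the tip label, or mrca(sorted tip labels) for clades."""
    if node.is_leaf():
        return node.taxon.label
    tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return "mrca(" + ",".join(tips) + ")"


@dataclass
class FitchResult:
    min_changes: int
    n_mpr: int
    #: per MPR: (frozenset of gain-edge clade ids, frozenset of loss-edge clade ids)
    mpr_profiles: list[tuple[frozenset[str], frozenset[str]]]

    @property
    def all_single_gain_no_loss(self) -> bool:
        return all(len(g) == 1 and not l for g, l in self.mpr_profiles)

    @property
    def gain_nodes(self) -> set[str]:
        return {g for gains, _ in self.mpr_profiles for g in gains}


def fitch_reconstruct(
    tree: dendropy.Tree,
    states: Mapping[str, int],
    root_state: int | None = None,
    max_mpr: int = 100_000,
) -> FitchResult:
    """Unit-cost parsimony with full MPR enumeration (feasible for <=~20 tips).

    ``states`` maps every tip label to 0/1.  The bottom-up pass is the Sankoff
    dynamic programme with unit substitution cost (equivalent to Fitch for two
    states); the top-down pass enumerates every optimal internal labelling and
    summarises each as its sets of gain and loss edges.

    ``root_state`` fixes the state at the root (used when the root ancestor
    is known to lack every derived boundary); with a state-0 outgroup tip
    attached at the root this never increases the change count, it only
    discards reconstructions that contradict the known ancestral state.
    """
    cost: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in states:
                raise UnknownTaxon(f"tip {label!r} has no state")
            s = states[label]
            cost[node] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            c = [0.0, 0.0]
            for s in (0, 1):
                c[s] = sum(
                    min(cost[ch][t] + (1 if t != s else 0) for t in (0, 1))
                    for ch in node.child_nodes()
                )
            cost[node] = c
    root = tree.seed_node
    if root_state is None:
        min_changes = int(min(cost[root]))
    else:
        min_changes = int(cost[root][root_state])

    # top-down enumeration of all optimal labellings
    profiles: list[tuple[frozenset[str], frozenset[str]]] = []

    def collect(node: dendropy.Node, state: int) -> list[tuple[frozenset, frozenset]]:
        children = node.child_nodes()
        if not children:
            return [(frozenset(), frozenset())]
        per_child: list[list[tuple[frozenset, frozenset]]] = []
        for ch in children:
            best = min(cost[ch][t] + (1 if t != state else 0) for t in (0, 1))
            variants: list[tuple[frozenset, frozenset]] = []
            for t in (0, 1):
                if cost[ch][t] + (1 if t != state else 0) != best:
                    continue
                for g, l in collect(ch, t):
                    if t != state:
                        if t == 1:
                            g = g | {clade_name(ch)}
                        else:
                            l = l | {clade_name(ch)}
                    variants.append((g, l))
            per_child.append(variants)
        out: list[tuple[frozenset, frozenset]] = []
        for combo in itertools.product(*per_child):
            g: frozenset = frozenset()
            l: frozenset = frozenset()
            for cg, cl in combo:
                g |= cg
                l |= cl
            out.append((g, l))
            if len(out) > max_mpr:
                raise RuntimeError("MPR enumeration exceeded max_mpr")
        return out

    if root_state is None:
        root_states = [s for s in (0, 1) if cost[root][s] == min(cost[root])]
    else:
        root_states = [root_state]
    for s in root_states:
        profiles.extend(collect(root, s))
    return FitchResult(
        min_changes=min_changes,
        n_mpr=len(profiles),
        mpr_profiles=profiles,
    )


@dataclass
class BoundaryCharacter:
    """One derived boundary scored and classified on the tree."""

    canonical_key: str
    presence: dict[str, int]
    min_changes: int
    n_mpr: int
    classification: str  # synapomorphy | homoplastic_or_lost | autapomorphy
    synapomorphy_node: str | None = None
    autapomorphy_tip: str | None = None
    #: candidate gain nodes across MPRs (reported for root-ambiguous cases)
    gain_candidates: tuple[str, ...] = ()


def classify_characters(
    catalogue: BoundaryCatalogue,
    tree: dendropy.Tree,
    keys: Iterable[str] | None = None,
) -> list[BoundaryCharacter]:
    """Classify derived boundary keys (default: all of them) on the tree.

    Tips absent from the catalogue (the ancestor/outgroup tip) score 0 for
    every derived character.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = sorted(set(catalogue.per_taxon) - set(tips))
    if missing:
        raise UnknownTaxon(f"catalogue taxa absent from tree: {missing}")
    derived_taxa = catalogue.derived_taxa
    if keys is None:
        keys = sorted(derived_taxa)
    out: list[BoundaryCharacter] = []
    for key in keys:
        taxa = derived_taxa.get(key, set())
        presence = {tip: (1 if tip in taxa else 0) for tip in tips}
        if len(taxa) == 1:
            tip = next(iter(taxa))
            out.append(
                BoundaryCharacter(
                    canonical_key=key,
                    presence=presence,
                    min_changes=1,
                    n_mpr=1,
                    classification="autapomorphy",
                    autapomorphy_tip=tip,
                )
            )
            continue
        res = fitch_reconstruct(tree, presence, root_state=0)
        if res.all_single_gain_no_loss and len(res.gain_nodes) == 1:
            node = next(iter(res.gain_nodes))
            cls, syn = "synapomorphy", node
        else:
            cls, syn = "homoplastic_or_lost", None
        out.append(
            BoundaryCharacter(
                canonical_key=key,
                presence=presence,
                min_changes=res.min_changes,
                n_mpr=res.n_mpr,
                classification=cls,
                synapomorphy_node=syn,
                gain_candidates=tuple(sorted(res.gain_nodes)),
            )
        )
    return out


def synapomorphies_by_node(characters: Iterable[BoundaryCharacter]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for ch in characters:
        if ch.classification == "synapomorphy":
            out.setdefault(ch.synapomorphy_node, []).append(ch.canonical_key)
    return {node: sorted(keys) for node, keys in sorted(out.items())}


def map_blocks_on_tree(
    blocks: Iterable[GeneBlock],
    tree: dendropy.Tree,
    characters: Iterable[BoundaryCharacter] = (),
) -> str:
    """Text report: per-tip block retention tags plus per-node synapomorphies.

    A complete block is tagged with its letter, a modified one with a trailing
    ``*`` (partial retention); absent blocks are not shown.
    """
    blocks = list(blocks)
    lines = ["# per-tip ancestral block retention (X = complete, X* = modified)"]
    for leaf in tree.leaf_node_iter():
        tip = leaf.taxon.label
        tags = []
        for blk in blocks:
            status = blk.retention.get(tip)
            if status == "complete":
                tags.append(blk.block_id)
            elif status == "modified":
                tags.append(blk.block_id + "*")
        lines.append(f"{tip}\t" + (" ".join(tags) if tags else "-"))
    per_node = synapomorphies_by_node(characters)
    if per_node:
        lines.append("# per-node synapomorphic derived boundaries")
        for node, keys in per_node.items():
            lines.append(f"{node}\t" + " ".join(keys))
    return "\n".join(lines) + "\n"
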