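"""Independent naive reference implementations used as test oracles.

These work directly on token strings and dendropy primitives with brute-force
loops, independently of the package's own data structures and algorithms.
"""

from __future__ import annotations

import itertools

import dendropy


def _base(token: str) -> str:
    """Token -> gene name: strip strand sign and copy suffix; CR2/CR3 -> CR."""
    t = token.lstrip("-")
    if "." in t:
        t = t.split(".", 1)[0]
    if t in ("CR2", "CR3"):
        t = "CR"
    return t


def _signed(token: str) -> str:
    sign = "-" if token.startswith("-") else ""
    base = _base(token)
    if base == "CR":
        return "CR"  # CR strand ignored
    return sign + base


def _neg(s: str) -> str:
    return s[1:] if s.startswith("-") else "-" + s


def naive_adjacency_keys(
    tokens: list[str],
    circular: bool = True,
    exclude_cr: bool = True,
    strand_sensitive: bool = True,
) -> set[str]:
    toks = [t for t in tokens if not (exclude_cr and _base(t) == "CR")]
    keys = set()
    m = len(toks)
    last = m if circular else m - 1
    for i in range(last):
        a, b = _signed(toks[i]), _signed(toks[(i + 1) % m])
        if strand_sensitive:
            keys.add(min(f"{a}|{b}", f"{_neg(b)}|{_neg(a)}"))
        else:
            x, y = sorted((_base(toks[i]), _base(toks[(i + 1) % m])))
            keys.add(f"{x}|{y}")
    return keys


def naive_catalogue_totals(
    taxa_tokens: dict[str, list[str]],
    ancestor_tokens: list[str],
    exclude_cr: bool = True,
    strand_sensitive: bool = True,
) -> dict[str, int]:
    """Brute-force derived/shared/unique totals via nested loops."""
    anc = naive_adjacency_keys(ancestor_tokens, True, exclude_cr, strand_sensitive)
    per_taxon_derived = {}
    for taxon, tokens in taxa_tokens.items():
        keys = naive_adjacency_keys(tokens, True, exclude_cr, strand_sensitive)
        per_taxon_derived[taxon] = {k for k in keys if k not in anc}
    all_derived = set()
    for d in per_taxon_derived.values():
        all_derived |= d
    shared, unique = set(), set()
    for key in all_derived:
        count = 0
        for taxon in taxa_tokens:
            if key in per_taxon_derived[taxon]:
                count += 1
        (shared if count >= 2 else unique).add(key)
    return {
        "total_derived": sum(len(d) for d in per_taxon_derived.values()),
        "distinct_shared": len(shared),
        "distinct_unique": len(unique),
    }


def naive_pairwise_shared(
    tokens_a: list[str],
    tokens_b: list[str],
    ancestor_tokens: list[str],
    strand_sensitive: bool = True,
) -> int:
    anc = naive_adjacency_keys(ancestor_tokens, True, True, strand_sensitive)
    da = naive_adjacency_keys(tokens_a, True, True, strand_sensitive) - anc
    db = naive_adjacency_keys(tokens_b, True, True, strand_sensitive) - anc
    n = 0
    for k in da:
        if k in db:
            n += 1
    return n


def naive_breakpoints(tokens_a: list[str], tokens_b: list[str]) -> int:
    ka = naive_adjacency_keys(tokens_a)
    kb = naive_adjacency_keys(tokens_b)
    return len([k for k in ka if k not in kb])


def naive_fitch_min_changes(tree: dendropy.Tree, states: dict[str, int]) -> int:
    """Minimum changes by exhaustive enumeration of internal labelings."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), combo))
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = states[leaf.taxon.label]
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                if assign[id(node)] != assign[id(node.parent_node)]:
                    changes += 1
        if best is None or changes < best:
            best = changes
    return best
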