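"""Readers and writers: GenBank flat files, gene-order tables, trees, TSVs.

The plain-text gene-order table format is one taxon per line::

    # comment
    <taxon_id> <tok> <tok> ...

where a token is a canonical gene name, ``-`` prefix for the minority strand
and a ``.n`` suffix (or ``CR2``/``CR3``) for the n-th copy of a duplicated
element, e.g. ``cox1 -nad5 trnM.2 CR``.
"""

from __future__ import annotations

import io
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.SeqFeature import SeqFeature

from .errors import EmptyFeatureTable, OrderTableParseError, UnknownGeneName
from .genome_model import (
    Arrangement,
    GeneLabel,
    SignedGene,
    linearize,
    normalize_gene_name,
)

# ---------------------------------------------------------------------------
# Gene-order tables
# ---------------------------------------------------------------------------


def read_order_table(path_or_text, topology: str = "circular") -> list[Arrangement]:
    """Parse a gene-order table into arrangements (circular by default)."""
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        path = Path(path_or_text)
        lines = path.read_text().splitlines()
        origin = str(path)
    else:
        lines = str(path_or_text).splitlines()
        origin = "<text>"
    out: list[Arrangement] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise OrderTableParseError(origin, lineno, "need a taxon id and >=2 tokens")
        taxon, tokens = fields[0], fields[1:]
        try:
            elements = tuple(SignedGene.from_token(t) for t in tokens)
            out.append(Arrangement(taxon, elements, topology, source=origin))
        except (UnknownGeneName, ValueError) as exc:
            raise OrderTableParseError(origin, lineno, str(exc)) from exc
    return out


def write_order_table(arrangements: Iterable[Arrangement], path) -> None:
    with open(path, "w") as fh:
        for a in arrangements:
            fh.write(f"{a.taxon_id}\t" + " ".join(a.tokens()) + "\n")


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_TYPED_FEATURES = ("CDS", "tRNA", "rRNA", "D-loop")
_CR_NOTE_HINTS = ("control region", "d-loop", "a+t", "at-rich", "at rich")


def _feature_label(feat: SeqFeature) -> GeneLabel | None:
    """Canonical label for a feature, or None for an ignorable misc_feature."""
    quals = feat.qualifiers
    name = (quals.get("gene") or quals.get("standard_name") or [""])[0]
    product = (quals.get("product") or quals.get("note") or [""])[0]
    if feat.type == "D-loop":
        return GeneLabel("CR")
    if feat.type == "misc_feature":
        text = " ".join(quals.get("note", []) + quals.get("standard_name", [])).lower()
        if any(h in text for h in _CR_NOTE_HINTS):
            return GeneLabel("CR")
        return None
    return normalize_gene_name(name, product)


def _sort_key(feat: SeqFeature) -> tuple[int, int]:
    # origin-spanning joins are placed by their first-listed (5'-most) fragment;
    # overlaps ordered by start, ties broken by length descending
    parts = feat.location.parts
    start = int(parts[0].start)
    length = sum(len(p) for p in parts)
    return (start, -length)


def read_genbank_arrangement(source) -> Arrangement:
    """Extract the circular gene arrangement from a GenBank flat file.

    ``source`` may be a path, an open handle, or record text.  Typed features
    (CDS/tRNA/rRNA/D-loop, plus CR-describing misc_features) win over bare
    ``gene`` features covering the same span; complement-strand features map
    to the minority strand; duplicated genes get copy indices by order of
    appearance in the linearized order.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    record = SeqIO.read(source, "genbank")
    typed: list[SeqFeature] = []
    bare_genes: list[SeqFeature] = []
    for feat in record.features:
        if feat.type in _TYPED_FEATURES or feat.type == "misc_feature":
            typed.append(feat)
        elif feat.type == "gene":
            bare_genes.append(feat)
    # a bare gene feature is kept only when no typed feature overlaps it
    def _span(f: SeqFeature) -> tuple[int, int]:
        return (min(int(p.start) for p in f.location.parts),
                max(int(p.end) for p in f.location.parts))

    kept: list[SeqFeature] = [f for f in typed]
    for g in bare_genes:
        gs, ge = _span(g)
        if not any(s < ge and gs < e for s, e in map(_span, typed)):
            kept.append(g)

    entries: list[tuple[tuple[int, int], str, str]] = []
    for feat in sorted(kept, key=_sort_key):
        label = _feature_label(feat)
        if label is None:
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        entries.append((_sort_key(feat), label.name, strand))
    if not entries:
        raise EmptyFeatureTable(f"{record.id}: no usable gene features")
    raw = [(name, strand) for _, name, strand in entries]
    return _assemble_circular(record.id, raw, source=record.id)


def _assemble_circular(
    taxon_id: str, raw: list[tuple[str, str]], source: str = ""
) -> Arrangement:
    """Build a circular arrangement, assigning copy indices deterministically
    (by order of appearance in the linearized walk)."""
    counts: dict[str, int] = {}
    provisional = []
    for name, strand in raw:
        counts[name] = counts.get(name, 0) + 1
        provisional.append(SignedGene(GeneLabel(name, counts[name]), strand))
    arr = Arrangement(taxon_id, tuple(provisional), "circular", source)
    walk = linearize(arr)
    walk_counts: dict[str, int] = {}
    remap: dict[tuple[str, int], int] = {}
    for sg in walk.elements:
        walk_counts[sg.name] = walk_counts.get(sg.name, 0) + 1
        remap[(sg.name, sg.label.copy_index)] = walk_counts[sg.name]
    final = tuple(
        SignedGene(GeneLabel(sg.name, remap[(sg.name, sg.label.copy_index)]), sg.strand)
        for sg in provisional
    )
    return Arrangement(taxon_id, final, "circular", source)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(newick: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree (text or path); polytomies allowed."""
    if isinstance(newick, Path) or (isinstance(newick, str) and newick.strip().endswith(".nwk")):
        data = Path(newick).read_text()
    else:
        data = str(newick)
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    return tree


def validate_tree_taxa(tree: dendropy.Tree, taxon_ids: Iterable[str]) -> None:
    """Check that every taxon id has a tip; report unmatched names."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(taxon_ids) - tips)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")


# ---------------------------------------------------------------------------
# Result tables & packaged fixtures
# ---------------------------------------------------------------------------


def write_tables(tables: Mapping[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write each result DataFrame as a TSV with stable column/row order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    return written


def _data_text(filename: str) -> str:
    return (resources.files("mitorder") / "data" / filename).read_text()


def load_ancestral_arrangement() -> Arrangement:
    """The inferred ancestral insect mitochondrial arrangement (circular)."""
    return read_order_table(_data_text("ancestral_insect.order"))[0]


def load_bi1_tree() -> dendropy.Tree:
    """The fixed study phylogeny: 14 thrips tips plus an outgroup tip."""
    return read_tree(_data_text("bi1.nwk"))


BI1_TIPS: tuple[str, ...] = (
    "G_uzeli", "H_aculeatus", "F_vespiformis", "H_indicus", "R_cruentatus",
    "D_minowai", "A_obscurus", "N_samayunkur", "S_dorsalis_EA", "S_dorsalis_SA",
    "F_intonsa", "F_occidentalis", "T_imaginis", "T_palmi",
)
OUTGROUP_TIP = "outgroup"
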