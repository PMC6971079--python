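"""One-command orchestration: ingest -> boundaries -> blocks -> tree mapping.

Because published boundary totals rarely state their counting convention,
the summary reports the headline totals under all four conventions
(cr_mode x strand sensitivity) side by side; the configured convention drives
the detailed tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .block_detection import GeneBlock, detect_conserved_blocks
from .boundary_analysis import BoundaryCatalogue, build_catalogue
from .genome_model import Arrangement
from .order_io import (
    load_ancestral_arrangement,
    load_bi1_tree,
    read_genbank_arrangement,
    read_order_table,
    read_tree,
    validate_tree_taxa,
    write_tables,
)
from .tree_mapping import (
    BoundaryCharacter,
    classify_characters,
    map_blocks_on_tree,
    synapomorphies_by_node,
)

log = logging.getLogger("mitorder")


@dataclass
class PipelineConfig:
    orders: str | None = None
    genbank_dir: str | None = None
    ancestor: str | None = None  # None -> packaged ancestral insect fixture
    tree: str | None = None      # None -> packaged study tree fixture
    cr_mode: str = "exclude"
    strand_sensitive: bool = True
    outdir: str = "mitorder_out"
    log_level: str = "INFO"
    seed: int = 0


@dataclass
class ReportBundle:
    catalogue: BoundaryCatalogue
    blocks: list[GeneBlock]
    characters: list[BoundaryCharacter]
    summary: dict
    paths: dict[str, Path] = field(default_factory=dict)


def ingest(config: PipelineConfig) -> list[Arrangement]:
    arrangements: list[Arrangement] = []
    if config.orders:
        arrangements.extend(read_order_table(Path(config.orders)))
    if config.genbank_dir:
        gb_dir = Path(config.genbank_dir)
        if not gb_dir.is_dir():
            raise FileNotFoundError(f"GenBank directory not found: {gb_dir}")
        for path in sorted(gb_dir.glob("*.gb")) + sorted(gb_dir.glob("*.gbk")):
            arrangements.append(read_genbank_arrangement(str(path)))
    if not arrangements:
        raise ValueError("no input arrangements (need --orders and/or --genbank)")
    return arrangements


def boundary_table(catalogue: BoundaryCatalogue) -> pd.DataFrame:
    shared = catalogue.shared_derived_keys
    rows = []
    for taxon in sorted(catalogue.per_taxon):
        tb = catalogue.per_taxon[taxon]
        for key in sorted(tb.ancestral):
            rows.append((taxon, key, "ancestral", ""))
        for key in sorted(tb.derived):
            rows.append((taxon, key, "derived", "shared" if key in shared else "unique"))
    return pd.DataFrame(rows, columns=["taxon", "boundary", "status", "sharing"])


def block_table(blocks: list[GeneBlock], catalogue: BoundaryCatalogue) -> pd.DataFrame:
    taxa = sorted(catalogue.per_taxon)
    rows = []
    for blk in blocks:
        row = {
            "block_id": blk.block_id,
            "genes": " ".join(sg.token() for sg in blk.genes),
            "n_genes": blk.n_genes,
            "n_boundaries": len(blk.member_boundaries),
        }
        for taxon in taxa:
            row[taxon] = blk.retention[taxon]
        rows.append(row)
    return pd.DataFrame(rows)


def character_table(characters: list[BoundaryCharacter]) -> pd.DataFrame:
    rows = [
        {
            "boundary": ch.canonical_key,
            "n_taxa": sum(ch.presence.values()),
            "min_changes": ch.min_changes,
            "n_mpr": ch.n_mpr,
            "classification": ch.classification,
            "node": ch.synapomorphy_node or ch.autapomorphy_tip or "",
            "gain_candidates": ";".join(ch.gain_candidates),
        }
        for ch in sorted(characters, key=lambda c: c.canonical_key)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "boundary", "n_taxa", "min_changes", "n_mpr",
            "classification", "node", "gain_candidates",
        ],
    )


def convention_sweep(arrangements: list[Arrangement], ancestor: Arrangement) -> pd.DataFrame:
    """Headline totals under each cr_mode x strand-sensitivity convention."""
    rows = []
    for cr_mode in ("exclude", "include"):
        for strand in (True, False):
            cat = build_catalogue(arrangements, ancestor, cr_mode, strand)
            s = cat.summary()
            rows.append({"cr_mode": cr_mode, "strand_sensitive": strand, **s})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        log.info("mitorder %s pipeline start", __version__)
        (outdir / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2) + "\n"
        )
        for label, p in (("orders", config.orders), ("ancestor", config.ancestor),
                         ("tree", config.tree)):
            if p and not Path(p).exists():
                raise RuntimeError(f"{label} path does not exist: {p}")
        arrangements = _stage("ingest", ingest, config)
        ancestor = (
            read_order_table(Path(config.ancestor))[0]
            if config.ancestor
            else load_ancestral_arrangement()
        )
        tree = read_tree(Path(config.tree)) if config.tree else load_bi1_tree()
        validate_tree_taxa(tree, [a.taxon_id for a in arrangements])

        catalogue = _stage(
            "boundaries",
            build_catalogue,
            arrangements, ancestor, config.cr_mode, config.strand_sensitive,
        )
        blocks = _stage("blocks", detect_conserved_blocks, catalogue, ancestor)
        characters = _stage("map", classify_characters, catalogue, tree)

        n_syn = sum(1 for c in characters if c.classification == "synapomorphy")
        n_homo = sum(
            1 for c in characters
            if c.classification == "homoplastic_or_lost"
        )
        summary = {
            **catalogue.summary(),
            "conserved_blocks": len(blocks),
            "synapomorphies": n_syn,
            "homoplastic_or_lost": n_homo,
            "cr_mode": config.cr_mode,
            "strand_sensitive": config.strand_sensitive,
        }
        tables = {
            "boundaries": boundary_table(catalogue),
            "blocks": block_table(blocks, catalogue),
            "characters": character_table(characters),
            "convention_sweep": convention_sweep(arrangements, ancestor),
            "summary": pd.DataFrame([summary]),
        }
        paths = write_tables(tables, outdir)
        tree_report = map_blocks_on_tree(blocks, tree, characters)
        (outdir / "tree_report.txt").write_text(tree_report)
        paths["tree_report"] = outdir / "tree_report.txt"
        maps = "".join(
            render_linear_map(a) + "\n" for a in arrangements
        )
        (outdir / "linear_maps.txt").write_text(maps)
        paths["linear_maps"] = outdir / "linear_maps.txt"
        log.info("summary: %s", summary)
        return ReportBundle(catalogue, blocks, characters, summary, paths)
    finally:
        log.removeHandler(fh)
        fh.close()


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        log.error("stage %s failed: %s", name, exc)
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def render_linear_map(
    a: Arrangement,
    blocks: list[GeneBlock] | None = None,
    catalogue: BoundaryCatalogue | None = None,
) -> str:
    """One-line textual gene-order map, minority-strand genes prefixed '-'.

    With annotations, a legend row lists the taxon's block retention tags
    (letter = complete, letter* = modified) and its boundary tallies.
    """
    from .genome_model import linearize

    ordered = linearize(a) if a.topology == "circular" else a
    lines = [f"{a.taxon_id}\t" + " ".join(ordered.tokens())]
    legend = []
    if blocks:
        tags = []
        for blk in blocks:
            status = blk.retention.get(a.taxon_id)
            if status == "complete":
                tags.append(blk.block_id)
            elif status == "modified":
                tags.append(blk.block_id + "*")
        legend.append("blocks: " + (" ".join(tags) if tags else "-"))
    if catalogue and a.taxon_id in catalogue.per_taxon:
        tb = catalogue.per_taxon[a.taxon_id]
        legend.append(f"ancestral: {len(tb.ancestral)} derived: {len(tb.derived)}")
    if legend:
        lines.append("# " + "; ".join(legend))
    return "\n".join(lines)
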