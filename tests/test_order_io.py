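"""IO tests; GenBank fixtures are generated in-memory with Biopython.

The synthetic flat files emulate the annotation styles seen in deposited
mitogenomes (typed CDS/tRNA/rRNA features with product qualifiers, D-loop or
misc_feature control regions, complement locations for the minority strand,
bare `gene` features duplicating typed ones).
"""

import io

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mitorder.errors import EmptyFeatureTable, OrderTableParseError
from mitorder.genome_model import SignedGene, arrangement_from_tokens
from mitorder.order_io import (
    load_bi1_tree,
    read_genbank_arrangement,
    read_order_table,
    read_tree,
    validate_tree_taxa,
    write_order_table,
    write_tables,
)

# GenBank-style naming for each canonical gene, exercising the synonym table
_GB_NAMES = {
    "cox1": ("COX1", "cytochrome c oxidase subunit I", "CDS"),
    "cox2": ("COII", "cytochrome c oxidase subunit II", "CDS"),
    "cox3": ("COX3", "cytochrome c oxidase subunit III", "CDS"),
    "cob": ("CYTB", "cytochrome b", "CDS"),
    "nad4L": ("ND4L", "NADH dehydrogenase subunit 4L", "CDS"),
    "rrnS": ("rrnS", "12S ribosomal RNA", "rRNA"),
    "rrnL": ("rrnL", "16S ribosomal RNA", "rRNA"),
    "trnL1": ("trnL1", "tRNA-Leu(CUN)", "tRNA"),
    "trnL2": ("trnL2", "tRNA-Leu(UUR)", "tRNA"),
    "trnS1": ("trnS1", "tRNA-Ser(AGN)", "tRNA"),
    "trnS2": ("trnS2", "tRNA-Ser(UCN)", "tRNA"),
}

_AA = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "M": "Met", "N": "Asn", "P": "Pro",
    "Q": "Gln", "R": "Arg", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}


def _feature_fields(name: str):
    if name in _GB_NAMES:
        return _GB_NAMES[name]
    if name == "CR":
        return (None, None, "D-loop")
    if name.startswith("trn"):
        return (name, f"tRNA-{_AA[name[3]]}", "tRNA")
    return (name.upper(), name, "CDS")


def genbank_text(arrangement, record_id="SYN000001", bare_gene_shadow=True) -> str:
    """Render an arrangement as a synthetic GenBank flat file (100 bp/gene)."""
    step = 100
    n = len(arrangement.elements)
    record = SeqRecord(
        Seq("A" * (step * n)),
        id=record_id,
        name=record_id,
        description="synthetic mitogenome fixture",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for i, sg in enumerate(arrangement.elements):
        gene, product, ftype = _feature_fields(sg.name)
        loc = SimpleLocation(i * step, (i + 1) * step, strand=-1 if sg.strand == "-" else 1)
        quals = {}
        if gene:
            quals["gene"] = [gene]
        if product:
            quals["product"] = [product]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
        if bare_gene_shadow and ftype in ("CDS", "tRNA", "rRNA"):
            record.features.append(
                SeqFeature(loc, type="gene", qualifiers={"gene": [gene or product]})
            )
    handle = io.StringIO()
    from Bio import SeqIO

    SeqIO.write(record, handle, "genbank")
    return handle.getvalue()


class TestOrderTable:
    def test_round_trip(self, tmp_path, ancestor):
        path = tmp_path / "orders.tsv"
        write_order_table([ancestor], path)
        (back,) = read_order_table(path)
        assert back.tokens() == ancestor.tokens()
        assert back.topology == "circular"

    def test_sign_and_copy_tokens(self):
        arrs = read_order_table("t1 cox1 -nad5 trnM.2 CR2 nad2\n")
        sg = arrs[0].elements[1]
        assert (sg.name, sg.strand) == ("nad5", "-")
        assert arrs[0].elements[2].label.copy_index == 2
        assert arrs[0].elements[3].label == SignedGene.from_token("CR2").label

    def test_comments_and_blank_lines_ignored(self):
        text = "# header\n\nt1 cox1 nad2 nad3\n"
        assert len(read_order_table(text)) == 1

    def test_parse_error_reports_line_number(self):
        with pytest.raises(OrderTableParseError, match=":2:"):
            read_order_table("t1 cox1 nad2\nt2 cox1 notagene\n")


class TestGenBankReader:
    def test_ancestral_round_trip(self, ancestor):
        """GenBank reader and order-table reader agree on the same genome."""
        text = genbank_text(ancestor)
        arr = read_genbank_arrangement(text)
        assert arr.topology == "circular"
        assert arr.tokens() == ancestor.tokens()

    def test_trna_absence_and_single_cr(self, ancestor):
        tokens = [t for t in ancestor.tokens() if t != "trnI"]
        a = arrangement_from_tokens("no_trnI", tokens)
        arr = read_genbank_arrangement(genbank_text(a))
        names = arr.gene_names()
        assert "trnI" not in names
        assert names.count("CR") == 1
        assert len(arr.elements) == 37

    def test_duplicated_trna_gets_copy_indices(self, ancestor):
        tokens = ancestor.tokens()
        tokens.insert(5, "trnM.2")  # second trnM copy elsewhere in the genome
        a = arrangement_from_tokens("dup", tokens)
        arr = read_genbank_arrangement(genbank_text(a))
        copies = sorted(
            sg.label.copy_index for sg in arr.elements if sg.name == "trnM"
        )
        assert copies == [1, 2]

    def test_empty_feature_table_raises(self):
        record = SeqRecord(
            Seq("A" * 200),
            id="EMPTY01",
            name="EMPTY01",
            annotations={"molecule_type": "DNA"},
        )
        handle = io.StringIO()
        from Bio import SeqIO

        SeqIO.write(record, handle, "genbank")
        with pytest.raises(EmptyFeatureTable):
            read_genbank_arrangement(handle.getvalue())

    def test_origin_spanning_feature_placed_by_first_fragment(self):
        # cox1 spans the origin: join(901..1000,1..100); it must sort last,
        # not first, preserving the circular order nad2, nad3, cox1
        record = SeqRecord(
            Seq("A" * 1000),
            id="WRAP01",
            name="WRAP01",
            annotations={"molecule_type": "DNA", "topology": "circular"},
        )
        loc_cox1 = CompoundLocation(
            [SimpleLocation(900, 1000, strand=1), SimpleLocation(0, 100, strand=1)]
        )
        record.features.append(
            SeqFeature(loc_cox1, type="CDS", qualifiers={"gene": ["COX1"]})
        )
        record.features.append(
            SeqFeature(SimpleLocation(200, 400, strand=1), type="CDS",
                       qualifiers={"gene": ["ND2"]})
        )
        record.features.append(
            SeqFeature(SimpleLocation(500, 700, strand=1), type="CDS",
                       qualifiers={"gene": ["ND3"]})
        )
        handle = io.StringIO()
        from Bio import SeqIO

        SeqIO.write(record, handle, "genbank")
        arr = read_genbank_arrangement(handle.getvalue())
        assert arr.gene_names() == ["nad2", "nad3", "cox1"]


class TestTrees:
    def test_two_tip_tree(self):
        tree = read_tree("(A,B);")
        assert len(tree.leaf_nodes()) == 2

    def test_packaged_tree_has_15_tips(self):
        tree = load_bi1_tree()
        tips = {l.taxon.label for l in tree.leaf_node_iter()}
        assert len(tips) == 15
        assert "outgroup" in tips and "H_indicus" in tips

    def test_unmatched_tip_reported_by_name(self):
        tree = read_tree("(A,(B,C));")
        with pytest.raises(ValueError, match="D"):
            validate_tree_taxa(tree, ["A", "B", "D"])


def test_write_tables_empty_frame_gives_header_only(tmp_path):
    import pandas as pd

    paths = write_tables({"empty": pd.DataFrame(columns=["a", "b"])}, tmp_path)
    assert paths["empty"].read_text() == "a\tb\n"
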