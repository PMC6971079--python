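"""Canonical gene vocabulary and arrangement model for circular mitogenomes.

A metazoan mitochondrial genome is modelled as an ordered sequence of signed
elements: 13 protein-coding genes, 2 rRNAs, 22 tRNAs and one or more control
regions (CRs), each on the majority (+) or minority (-) strand.  Circular
arrangements are compared up to rotation and full reflection (reverse the
order and flip every strand); :func:`linearize` picks the canonical
representative of that equivalence class, anchored on ``cox1``.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from .errors import MissingAnchor, UnknownGeneName

# ---------------------------------------------------------------------------
# Controlled vocabulary
# ---------------------------------------------------------------------------

PCGS: tuple[str, ...] = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNAS: tuple[str, ...] = ("rrnS", "rrnL")
TRNAS: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
CR_NAME = "CR"

VOCABULARY: frozenset[str] = frozenset(PCGS + RRNAS + TRNAS + (CR_NAME,))

#: Major genes: the slow-rearranging classes kept by reduce_to_major_genes.
MAJOR_GENES: frozenset[str] = frozenset(PCGS + RRNAS)

# one-letter amino-acid code -> tRNA name, for products like "tRNA-Ala"
_AA3_TO_TRNA = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD",
    "cys": "trnC", "gln": "trnQ", "glu": "trnE", "gly": "trnG",
    "his": "trnH", "ile": "trnI", "lys": "trnK", "met": "trnM",
    "phe": "trnF", "pro": "trnP", "thr": "trnT", "trp": "trnW",
    "tyr": "trnY", "val": "trnV",
}

# Synonym table reconciling MITOS / GenBank / literature spellings.
_SYNONYMS: dict[str, str] = {
    # protein-coding genes
    "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytb": "cob", "cytochrome b": "cob", "cob": "cob", "cyt b": "cob",
    "atpase6": "atp6", "atpase8": "atp8", "atp 6": "atp6", "atp 8": "atp8",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    # rRNAs
    "rrns": "rrnS", "rrnl": "rrnL",
    "12s": "rrnS", "16s": "rrnL",
    "12s rrna": "rrnS", "16s rrna": "rrnL",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
    "small subunit ribosomal rna": "rrnS",
    "large subunit ribosomal rna": "rrnL",
    "12s ribosomal rna": "rrnS", "16s ribosomal rna": "rrnL",
    # control region
    "d-loop": CR_NAME, "control region": CR_NAME, "cr": CR_NAME,
    "a+t rich region": CR_NAME, "at-rich region": CR_NAME,
    "putative control region": CR_NAME, "non-coding region": CR_NAME,
    "cr2": "CR2", "cr3": "CR3",
    # serine / leucine tRNA paralogue spellings
    "trnl(uur)": "trnL2", "trnl(cun)": "trnL1",
    "trns(ucn)": "trnS2", "trns(agn)": "trnS1",
    "trnl1": "trnL1", "trnl2": "trnL2", "trns1": "trnS1", "trns2": "trnS2",
}
# every canonical token maps to itself (case-insensitively)
_SYNONYMS.update({name.lower(): name for name in VOCABULARY})
_SYNONYMS.update({"cr2": "CR2", "cr3": "CR3"})

_TRNA_PRODUCT_RE = re.compile(
    r"trna[-_ ]?(?P<aa>[a-z]{3})\s*(?:\((?P<codon>[acgtun]{3})\))?", re.I
)


def _trna_from_product(product: str) -> str | None:
    m = _TRNA_PRODUCT_RE.search(product)
    if not m:
        return None
    aa = m.group("aa").lower()
    codon = (m.group("codon") or "").lower()
    if aa == "leu":
        # UUR family = trnL2, CUN family = trnL1 (insect mitogenome convention)
        if codon:
            return "trnL2" if codon.startswith("uu") or codon.startswith("tt") else "trnL1"
        return None
    if aa == "ser":
        if codon:
            return "trnS2" if codon.startswith("uc") or codon.startswith("tc") else "trnS1"
        return None
    return _AA3_TO_TRNA.get(aa)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GeneLabel:
    """A canonical gene name plus copy index (1 for the first/only copy)."""

    name: str
    copy_index: int = 1

    def __post_init__(self):
        if self.name not in VOCABULARY:
            raise UnknownGeneName(self.name)
        if self.copy_index < 1:
            raise ValueError(f"copy_index must be >= 1, got {self.copy_index}")

    @property
    def is_trna(self) -> bool:
        return self.name.startswith("trn")

    @property
    def is_cr(self) -> bool:
        return self.name == CR_NAME

    @property
    def is_major(self) -> bool:
        return self.name in MAJOR_GENES


@dataclass(frozen=True, order=True)
class SignedGene:
    """A gene label with strand orientation ('+' majority, '-' minority)."""

    label: GeneLabel
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def name(self) -> str:
        return self.label.name

    def flipped(self) -> "SignedGene":
        return SignedGene(self.label, "-" if self.strand == "+" else "+")

    def token(self) -> str:
        """Render as an order-table token, e.g. ``-nad5``, ``trnM.2``, ``CR2``."""
        if self.label.is_cr:
            base = CR_NAME if self.label.copy_index == 1 else f"CR{self.label.copy_index}"
        else:
            base = self.label.name
            if self.label.copy_index > 1:
                base += f".{self.label.copy_index}"
        return ("-" + base) if self.strand == "-" else base

    @classmethod
    def from_token(cls, token: str) -> "SignedGene":
        """Parse an order-table token ('-' = minority strand, '.n' = copy n)."""
        strand = "+"
        body = token.strip()
        if body.startswith(("-", "−")):  # accept ASCII or unicode minus
            strand = "-"
            body = body[1:]
        copy_index = 1
        m = re.fullmatch(r"(?P<base>.+)\.(?P<idx>\d+)", body)
        if m:
            body = m.group("base")
            copy_index = int(m.group("idx"))
        m = re.fullmatch(r"CR(?P<idx>[23])", body)
        if m:
            body, copy_index = CR_NAME, int(m.group("idx"))
        if body not in VOCABULARY:
            raise UnknownGeneName(body, _nearest(body))
        return cls(GeneLabel(body, copy_index), strand)


@dataclass(frozen=True)
class Arrangement:
    """An ordered sequence of signed genes + CRs for one taxon.

    ``topology`` is ``"circular"`` for a complete mitogenome or ``"linear"``
    for a linearized representative or a chromosome fragment of a multipartite
    genome.  Circular arrangements are considered equal to any rotation of
    themselves and to their full reflection.
    """

    taxon_id: str
    elements: tuple[SignedGene, ...]
    topology: str = "circular"
    source: str = ""

    def __post_init__(self):
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")
        if len(self.elements) < 2:
            raise ValueError("arrangement needs at least 2 elements")
        seen: set[tuple[str, int]] = set()
        for sg in self.elements:
            key = (sg.label.name, sg.label.copy_index)
            if key in seen:
                raise ValueError(f"duplicate element without distinct copy_index: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[SignedGene]:
        return iter(self.elements)

    def tokens(self) -> list[str]:
        return [sg.token() for sg in self.elements]

    def gene_names(self) -> list[str]:
        return [sg.name for sg in self.elements]

    def rotated(self, k: int) -> "Arrangement":
        """Rotate a circular arrangement so element ``k`` comes first."""
        if self.topology != "circular":
            raise ValueError("cannot rotate a linear arrangement")
        k %= len(self.elements)
        return replace(self, elements=self.elements[k:] + self.elements[:k])

    def reflected(self) -> "Arrangement":
        """Reverse the order and flip every strand (read the other strand)."""
        return replace(self, elements=tuple(sg.flipped() for sg in reversed(self.elements)))

    def equivalent(self, other: "Arrangement") -> bool:
        """Equality up to rotation/reflection (circular) or exact order (linear)."""
        if self.topology != other.topology:
            return False
        if self.topology == "linear":
            return self.elements == other.elements
        return _canonical_tokens(self) == _canonical_tokens(other)


# linearization anchor preference; cox1 is present and unique in every
# mitogenome analysed, the rest are fallbacks for degenerate fragments
ANCHOR_PREFERENCE: tuple[str, ...] = ("cox1", "cox2", "cob", "rrnL")


def _find_anchor(a: Arrangement) -> int:
    for anchor in ANCHOR_PREFERENCE:
        for i, sg in enumerate(a.elements):
            if sg.name == anchor and sg.label.copy_index == 1:
                return i
    raise MissingAnchor(
        f"{a.taxon_id}: none of {ANCHOR_PREFERENCE} present; cannot linearize"
    )


def linearize(a: Arrangement) -> Arrangement:
    """Canonical linear representative of a circular arrangement.

    Rotates so the anchor gene (``cox1``, falling back to cox2/cob/rrnL) comes
    first and reflects the whole genome if needed to put the anchor on the
    majority strand.  Idempotent; invariant under rotation and reflection of
    the input.  A linear input is returned unchanged.
    """
    if a.topology == "linear":
        return a
    i = _find_anchor(a)
    if a.elements[i].strand == "-":
        a = a.reflected()
        i = _find_anchor(a)
    rotated = a.rotated(i)
    return replace(rotated, topology="linear")


def _canonical_tokens(a: Arrangement) -> tuple[str, ...]:
    return tuple(linearize(a).tokens())


def reduce_to_major_genes(a: Arrangement) -> Arrangement:
    """Drop all tRNAs and all CR copies except the primary CR.

    Analyses of deep rearrangement history use only the relative order of the
    major genes (PCGs, rRNAs, primary CR) because tRNAs relocate far too often
    to carry signal.  The primary CR is the first CR encountered after the
    anchor when walking the linearized order (a deterministic stand-in for the
    biologically "original" copy, which annotation alone cannot identify).
    """
    ordered = linearize(a) if a.topology == "circular" else a
    primary_cr: GeneLabel | None = next(
        (sg.label for sg in ordered.elements if sg.label.is_cr), None
    )
    kept = tuple(
        sg for sg in a.elements if sg.label.is_major or sg.label == primary_cr
    )
    return replace(a, elements=kept)


def normalize_gene_name(raw_name: str, raw_product: str = "") -> GeneLabel:
    """Map a raw annotation name/product to the canonical vocabulary.

    Handles the common MITOS/GenBank spellings (COI, ND4L, CYTB, D-loop, ...)
    and tRNA products like ``tRNA-Leu(UUR)``.  Raises :class:`UnknownGeneName`
    with nearest-synonym suggestions otherwise.  Copy indices are not assigned
    here; duplicate handling happens at arrangement-assembly time.
    """
    for raw in (raw_name, raw_product):
        if not raw:
            continue
        key = raw.strip().lower()
        if key in _SYNONYMS:
            canonical = _SYNONYMS[key]
            if canonical in ("CR2", "CR3"):
                return GeneLabel(CR_NAME, int(canonical[-1]))
            return GeneLabel(canonical)
        trna = _trna_from_product(raw)
        if trna is not None:
            return GeneLabel(trna)
    token = raw_name or raw_product
    raise UnknownGeneName(token, _nearest(token))


def _nearest(token: str) -> list[str]:
    return difflib.get_close_matches(token.lower(), sorted(_SYNONYMS), n=3)


def arrangement_from_tokens(
    taxon_id: str,
    tokens: Iterable[str],
    topology: str = "circular",
    source: str = "",
) -> Arrangement:
    return Arrangement(
        taxon_id=taxon_id,
        elements=tuple(SignedGene.from_token(t) for t in tokens),
        topology=topology,
        source=source,
    )
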