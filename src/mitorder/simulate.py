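"""Rearrangement simulator: evolve an arrangement along a rooted tree.

Four event classes act on a circular arrangement, mirroring the operator set
of common-interval rearrangement analysis:

* **transposition** — a contiguous segment moves to a new position;
* **inversion** — a segment is reversed in place, flipping strands;
* **inverse transposition** — the segment both moves and is reversed/flipped;
* **TDRL** (tandem duplication / random loss) — a segment is duplicated in
  tandem, then exactly one copy of each duplicated gene is deleted
  (an independent fair coin per gene), yielding a shuffled order.

All four conserve gene content.  Two further logged processes do not:
control-region duplication (inserts an extra CR copy) and tRNA loss.

Every random draw comes from one seeded generator consumed in a fixed
traversal order, so identical seed + config + tree reproduce every tip and
the event log exactly, and replaying the log regenerates the tips bit-exactly
(verified by per-event arrangement hashes).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import InvalidSegment
from .genome_model import Arrangement, GeneLabel, SignedGene
from .tree_mapping import clade_name

# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


def _rotated(elems: tuple[SignedGene, ...], k: int) -> tuple[SignedGene, ...]:
    k %= len(elems)
    return elems[k:] + elems[:k]


def _revflip(seg: Sequence[SignedGene]) -> tuple[SignedGene, ...]:
    return tuple(sg.flipped() for sg in reversed(seg))


@dataclass(frozen=True)
class Transposition:
    start: int
    length: int
    dest: int  # insertion index into the remainder, 1..m-1 (0/m = identity)

    def apply(self, elems: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
        seg, rest = _split(elems, self.start, self.length)
        m = len(rest)
        if not 1 <= self.dest <= m - 1:
            raise InvalidSegment(f"dest {self.dest} outside 1..{m - 1}")
        return rest[: self.dest] + seg + rest[self.dest:]


@dataclass(frozen=True)
class Inversion:
    start: int
    length: int

    def apply(self, elems: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
        seg, rest = _split(elems, self.start, self.length, max_len=len(elems) - 1)
        return _revflip(seg) + rest


@dataclass(frozen=True)
class InverseTransposition:
    start: int
    length: int
    dest: int

    def apply(self, elems: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
        seg, rest = _split(elems, self.start, self.length)
        m = len(rest)
        if not 1 <= self.dest <= m - 1:
            raise InvalidSegment(f"dest {self.dest} outside 1..{m - 1}")
        return rest[: self.dest] + _revflip(seg) + rest[self.dest:]


@dataclass(frozen=True)
class Tdrl:
    start: int
    length: int
    keep_first: tuple[bool, ...]  # per duplicated gene: keep the first copy?

    def apply(self, elems: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
        seg, rest = _split(elems, self.start, self.length)
        if len(self.keep_first) != len(seg):
            raise InvalidSegment("keep_first length != segment length")
        first = tuple(sg for sg, k in zip(seg, self.keep_first) if k)
        second = tuple(sg for sg, k in zip(seg, self.keep_first) if not k)
        return first + second + rest


@dataclass(frozen=True)
class CrDuplication:
    position: int
    copy_index: int

    def apply(self, elems: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
        new = SignedGene(GeneLabel("CR", self.copy_index), "+")
        return elems[: self.position] + (new,) + elems[self.position:]


@dataclass(frozen=True)
class TrnaLoss:
    name: str
    copy_index: int

    def apply(self, elems: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
        kept = tuple(
            sg for sg in elems
            if not (sg.name == self.name and sg.label.copy_index == self.copy_index)
        )
        if len(kept) == len(elems):
            raise InvalidSegment(f"{self.name}.{self.copy_index} not present")
        return kept


Event = Transposition | Inversion | InverseTransposition | Tdrl | CrDuplication | TrnaLoss

EVENT_CLASSES = ("transposition", "inversion", "inverse_transposition", "tdrl")


def _split(
    elems: tuple[SignedGene, ...], start: int, length: int, max_len: int | None = None
) -> tuple[tuple[SignedGene, ...], tuple[SignedGene, ...]]:
    n = len(elems)
    limit = max_len if max_len is not None else n - 2
    if not 0 <= start < n:
        raise InvalidSegment(f"start {start} outside 0..{n - 1}")
    if not 1 <= length <= limit:
        raise InvalidSegment(f"length {length} outside 1..{limit} (n={n})")
    rot = _rotated(elems, start)
    return rot[:length], rot[length:]


def apply_event(a: Arrangement, event: Event) -> Arrangement:
    """Apply one rearrangement event to a circular arrangement."""
    if a.topology != "circular":
        raise InvalidSegment("events are defined on circular arrangements")
    return replace(a, elements=event.apply(a.elements))


def arrangement_hash(a: Arrangement) -> str:
    payload = a.topology + ":" + " ".join(a.tokens())
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Configuration and log
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Per-branch event intensities and segment-choice parameters.

    Rates are expected events per branch (multiplied by branch length,
    defaulting to 1).  ``trna_mobility_weight`` >= 1 biases segment choice
    toward tRNA-only segments, reflecting the much higher translocation rate
    of tRNAs; ``segment_length_param`` is the geometric parameter for segment
    length (larger -> shorter segments).
    """

    transposition_rate: float = 1.8
    inversion_rate: float = 0.45
    inverse_transposition_rate: float = 0.3
    tdrl_rate: float = 0.4
    trna_mobility_weight: float = 4.0
    segment_length_param: float = 0.7
    cr_duplication_prob: float = 0.1
    gene_loss_prob: float = 0.02
    seed: int = 0
    #: branches (child clade/tip names) on which no events occur; the
    #: outgroup tip stands for the ancestral lineage and stays event-free
    event_free_branches: tuple[str, ...] = ("outgroup",)

    def __post_init__(self):
        for cls in EVENT_CLASSES:
            if getattr(self, f"{cls}_rate") < 0:
                raise ValueError(f"{cls}_rate must be >= 0")
        for p in (self.cr_duplication_prob, self.gene_loss_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 < self.segment_length_param <= 1:
            raise ValueError("segment_length_param must be in (0, 1]")


@dataclass(frozen=True)
class EventRecord:
    branch: str
    event: Event
    result_hash: str


@dataclass
class EventLog:
    records: list[EventRecord] = field(default_factory=list)

    def for_branch(self, branch: str) -> list[EventRecord]:
        return [r for r in self.records if r.branch == branch]


@dataclass
class SimulationResult:
    root: Arrangement
    tree: dendropy.Tree
    config: SimulationConfig
    tips: dict[str, Arrangement]
    log: EventLog
    node_arrangements: dict[str, Arrangement]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _sample_segment(
    rng: np.random.Generator,
    elems: tuple[SignedGene, ...],
    cfg: SimulationConfig,
    max_tries: int = 200,
) -> tuple[int, int]:
    """Segment start/length; tRNA-only segments accepted preferentially."""
    n = len(elems)
    w = max(cfg.trna_mobility_weight, 1.0)
    start = length = None
    for _ in range(max_tries):
        start = int(rng.integers(0, n))
        length = int(min(rng.geometric(cfg.segment_length_param), n - 2))
        seg = _rotated(elems, start)[:length]
        weight = cfg.trna_mobility_weight if all(sg.label.is_trna for sg in seg) else 1.0
        if rng.random() < weight / w:
            return start, length
    return start, length


def _sample_event(
    rng: np.random.Generator,
    cls: str,
    elems: tuple[SignedGene, ...],
    cfg: SimulationConfig,
) -> Event:
    start, length = _sample_segment(rng, elems, cfg)
    if cls == "inversion":
        return Inversion(start, length)
    if cls == "tdrl":
        keep = tuple(bool(b) for b in rng.integers(0, 2, size=length))
        return Tdrl(start, length, keep)
    m = len(elems) - length
    dest = int(rng.integers(1, m))  # 1..m-1, excludes identity placements
    if cls == "transposition":
        return Transposition(start, length, dest)
    return InverseTransposition(start, length, dest)


def _branch_events(
    rng: np.random.Generator,
    arr: Arrangement,
    branch: str,
    edge_length: float,
    cfg: SimulationConfig,
    log: EventLog,
) -> Arrangement:
    classes: list[str] = []
    for cls in EVENT_CLASSES:
        k = int(rng.poisson(getattr(cfg, f"{cls}_rate") * edge_length))
        classes.extend([cls] * k)
    rng.shuffle(classes)
    for cls in classes:
        event = _sample_event(rng, cls, arr.elements, cfg)
        arr = apply_event(arr, event)
        log.records.append(EventRecord(branch, event, arrangement_hash(arr)))
    if rng.random() < cfg.cr_duplication_prob:
        idx = 1 + max(
            (sg.label.copy_index for sg in arr.elements if sg.label.is_cr), default=0
        )
        event = CrDuplication(int(rng.integers(0, len(arr.elements) + 1)), idx)
        arr = replace(arr, elements=event.apply(arr.elements))
        log.records.append(EventRecord(branch, event, arrangement_hash(arr)))
    if rng.random() < cfg.gene_loss_prob:
        trnas = [sg for sg in arr.elements if sg.label.is_trna]
        if trnas:
            victim = trnas[int(rng.integers(0, len(trnas)))]
            event = TrnaLoss(victim.name, victim.label.copy_index)
            arr = replace(arr, elements=event.apply(arr.elements))
            log.records.append(EventRecord(branch, event, arrangement_hash(arr)))
    return arr


def simulate_along_tree(
    root: Arrangement, tree: dendropy.Tree, config: SimulationConfig
) -> SimulationResult:
    """Evolve ``root`` down every branch of a rooted tree.

    Event counts per branch are Poisson(rate x branch length) per class,
    applied in a uniformly shuffled order.  Branches named in
    ``config.event_free_branches`` (by child tip/clade name) receive no
    events.
    """
    rng = np.random.default_rng(config.seed)
    log = EventLog()
    node_arr: dict[int, Arrangement] = {id(tree.seed_node): replace(root)}
    tips: dict[str, Arrangement] = {}
    named: dict[str, Arrangement] = {clade_name(tree.seed_node): root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_arr = node_arr[id(node.parent_node)]
        branch = clade_name(node)
        edge_len = node.edge.length if node.edge.length is not None else 1.0
        arr = replace(parent_arr, taxon_id=branch if node.is_leaf() else parent_arr.taxon_id)
        if branch not in config.event_free_branches and edge_len > 0:
            arr = _branch_events(rng, arr, branch, edge_len, config, log)
        node_arr[id(node)] = arr
        named[branch] = arr
        if node.is_leaf():
            tips[node.taxon.label] = replace(arr, taxon_id=node.taxon.label, source="simulated")
    return SimulationResult(
        root=root, tree=tree, config=config, tips=tips, log=log, node_arrangements=named
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: internal branch carrying the event in the single_event preset: the stem of
#: the Frankliniella + Thrips clade on the fixed study tree
SINGLE_EVENT_BRANCH = "mrca(F_intonsa,F_occidentalis,T_imaginis,T_palmi)"
SINGLE_EVENT_CLADE = ("F_intonsa", "F_occidentalis", "T_imaginis", "T_palmi")

PRESETS = ("thrips_like", "ancestor_only", "single_event")


@dataclass
class Dataset:
    """A generated dataset plus its ground truth."""

    preset: str
    result: SimulationResult
    ancestor: Arrangement
    ground_truth: dict


def _no_event_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        transposition_rate=0.0,
        inversion_rate=0.0,
        inverse_transposition_rate=0.0,
        tdrl_rate=0.0,
        cr_duplication_prob=0.0,
        gene_loss_prob=0.0,
        seed=seed,
    )


def _sample_clean_single_gene_transposition(
    rng: np.random.Generator, elems: tuple[SignedGene, ...]
) -> Transposition:
    """A single-gene move whose CR-excluded projection is a genuine move.

    The moved gene, its two original neighbours and the two insertion flanks
    must all be non-CR and mutually distinct, so the move creates exactly
    three novel gene adjacencies regardless of CR handling.
    """
    n = len(elems)
    while True:
        start = int(rng.integers(0, n))
        x = elems[start]
        left, right = elems[(start - 1) % n], elems[(start + 1) % n]
        if any(sg.label.is_cr for sg in (x, left, right)):
            continue
        rot = _rotated(elems, start)
        rest = rot[1:]
        dest = int(rng.integers(1, n - 1))
        p, q = rest[dest - 1], rest[dest]
        if any(sg.label.is_cr for sg in (p, q)):
            continue
        if {p, q} & {left, right, x}:
            continue
        return Transposition(start, 1, dest)


def generate_dataset(preset: str, seed: int = 0) -> Dataset:
    """Generate a synthetic dataset with known ground truth.

    Presets:

    * ``ancestor_only`` — every tip keeps the root arrangement (no events);
    * ``single_event`` — one clean single-gene transposition on the
      Frankliniella + Thrips stem branch, all other branches event-free;
    * ``thrips_like`` — all four event classes at rates calibrated so tips
      carry on average 20-30 derived boundaries, the regime observed in the
      real 14-genome thrips data (403 derived boundaries over 14 taxa).
    """
    from .order_io import OUTGROUP_TIP, load_ancestral_arrangement, load_bi1_tree

    root = replace(load_ancestral_arrangement(), taxon_id="root")
    tree = load_bi1_tree()
    if preset == "ancestor_only":
        result = simulate_along_tree(root, tree, _no_event_config(seed))
        result.tips.pop(OUTGROUP_TIP, None)
        return Dataset(preset, result, root, {"events": 0})
    if preset == "single_event":
        rng = np.random.default_rng(seed)
        event = _sample_clean_single_gene_transposition(rng, root.elements)
        result = simulate_along_tree(root, tree, _no_event_config(seed))
        result.tips.pop(OUTGROUP_TIP, None)
        # graft the event onto the chosen internal branch and propagate
        branch_arr = apply_event(root, event)
        result.log.records.append(
            EventRecord(SINGLE_EVENT_BRANCH, event, arrangement_hash(branch_arr))
        )
        for tip in SINGLE_EVENT_CLADE:
            result.tips[tip] = replace(
                branch_arr, taxon_id=tip, source="simulated"
            )
        result.node_arrangements[SINGLE_EVENT_BRANCH] = branch_arr
        return Dataset(
            preset,
            result,
            root,
            {"event": event, "branch": SINGLE_EVENT_BRANCH, "clade": SINGLE_EVENT_CLADE},
        )
    if preset == "thrips_like":
        config = SimulationConfig(seed=seed)
        result = simulate_along_tree(root, tree, config)
        result.tips.pop(OUTGROUP_TIP, None)
        return Dataset(preset, result, root, {"config": config})
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def replay_log(root: Arrangement, tree: dendropy.Tree, log: EventLog) -> dict[str, Arrangement]:
    """Re-apply a recorded event log from the root; verifies every hash."""
    node_arr: dict[int, Arrangement] = {id(tree.seed_node): replace(root)}
    tips: dict[str, Arrangement] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        arr = node_arr[id(node.parent_node)]
        branch = clade_name(node)
        for rec in log.for_branch(branch):
            arr = replace(arr, elements=rec.event.apply(arr.elements))
            if arrangement_hash(arr) != rec.result_hash:
                raise RuntimeError(f"replay hash mismatch on branch {branch}")
        node_arr[id(node)] = arr
        if node.is_leaf():
            tips[node.taxon.label] = replace(arr, taxon_id=node.taxon.label, source="simulated")
    return tips
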