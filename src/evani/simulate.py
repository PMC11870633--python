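"""Birth–death genome evolution with substitutions, indels, duplication, LGT.

A species tree is drawn from a birth–death process and rescaled so that
the root-to-leaf path length equals the configured mutation rate in PAM
units (100 PAM = one accepted substitution per site on average).  A root
genome of ``n_genes`` concatenated random genes then evolves down the
tree:

* substitutions arrive as a Poisson process with mean b/100 events per
  site on a branch of b PAM; each event replaces the current base with a
  uniformly chosen different base (Jukes–Cantor style), so repeated hits
  at one site can revert it;
* insertions and deletions arrive at ``indel_rate`` per site per PAM with
  Zipf-distributed lengths truncated at ``max_indel_len``; insertion
  content is random;
* gene duplications copy a uniformly chosen gene of the same lineage into
  a random inter-gene position;
* lateral gene transfers (LGT) copy a uniformly chosen gene from a
  contemporaneous donor lineage into a random inter-gene position of the
  recipient.

Lineages are advanced through a global, chronologically ordered event
queue so that an LGT donor's sequence is its state at the moment of
transfer.  Gene intervals, family ids, and per-gene provenance are
maintained through every event, yielding a truth layer (HomologyMap) for
ortholog-restricted comparisons downstream.
"""

from __future__ import annotations

import heapq
import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .errors import ConfigError, DataError
from .kmers import decode
from .matrix import DistanceMatrix

__all__ = [
    "SimConfig",
    "SimGenome",
    "GeneRecord",
    "HomologyMap",
    "sample_species_tree",
    "evolve",
    "patristic_matrix",
]


@dataclass
class SimConfig:
    """All simulation knobs; rates follow the conventions in the module doc.

    ``mutation_rate`` is the expected root-to-leaf divergence in PAM.
    ``dup_rate`` and ``lgt_rate`` are per gene per PAM; ``indel_rate`` is
    per site per PAM.  ``gc_drift`` (default off) is the standard
    deviation, per 100 PAM, of a Brownian walk in each lineage's target
    GC fraction: substitution targets are then drawn with that bias, so
    base composition itself drifts along the tree — a second,
    composition-borne distance signal on top of sequence homology.
    """

    n_leaves: int = 15
    birth_rate: float = 0.01
    death_rate: float = 0.001
    mutation_rate: float = 50.0
    n_genes: int = 100
    gene_len: int = 1000
    indel_rate: float = 1e-4
    zipf_exponent: float = 1.8
    max_indel_len: int = 50
    dup_rate: float = 0.0
    lgt_rate: float = 0.0
    gc_drift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_leaves < 2:
            raise ConfigError(f"n_leaves must be >= 2, got {self.n_leaves}")
        if self.birth_rate <= 0:
            raise ConfigError(f"birth_rate must be > 0, got {self.birth_rate}")
        for name in (
            "death_rate",
            "mutation_rate",
            "indel_rate",
            "dup_rate",
            "lgt_rate",
            "gc_drift",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_genes < 1 or self.gene_len < 1:
            raise ConfigError("n_genes and gene_len must be >= 1")
        if self.zipf_exponent <= 1.0:
            raise ConfigError(
                f"zipf_exponent must be > 1, got {self.zipf_exponent}"
            )
        if self.max_indel_len < 1:
            raise ConfigError("max_indel_len must be >= 1")


@dataclass
class SimGenome:
    """One leaf genome with its gene annotation and provenance."""

    leaf_id: str
    sequence: str
    genes: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    family_ids: list[int]
    origin: list[str]  # per gene: vertical | duplication | lgt
    n_substitutions: int = 0  # accepted substitution events on the path from root

    def __post_init__(self) -> None:
        if not (len(self.genes) == len(self.family_ids) == len(self.origin)):
            raise DataError("genes, family_ids and origin must have equal length")

    def gene_intervals(self, origins: set[str] | None = None) -> list[tuple[int, int]]:
        """Gene intervals, optionally restricted to the given origins."""
        if origins is None:
            return list(self.genes)
        return [g for g, o in zip(self.genes, self.origin) if o in origins]


@dataclass
class GeneRecord:
    """Provenance of a single leaf gene back to the root."""

    leaf_id: str
    gene_index: int
    family_id: int
    origin: str
    path: tuple  # events ('dup', time) / ('lgt', time, donor, recipient)


class HomologyMap:
    """Truth layer: every leaf gene's root family and event path."""

    def __init__(self, records: list[GeneRecord], n_root_families: int):
        self.records = records
        self.n_root_families = n_root_families
        self._by_leaf: dict[str, list[GeneRecord]] = {}
        for rec in records:
            self._by_leaf.setdefault(rec.leaf_id, []).append(rec)

    def genes_of(self, leaf_id: str) -> list[GeneRecord]:
        return self._by_leaf[leaf_id]

    def vertical_families(self, leaf_id: str) -> set[int]:
        """Families represented by a vertically inherited copy in this leaf."""
        return {r.family_id for r in self._by_leaf[leaf_id] if r.origin == "vertical"}

    def shared_vertical(self, leaf_a: str, leaf_b: str) -> set[int]:
        """Families vertically co-inherited by both leaves."""
        return self.vertical_families(leaf_a) & self.vertical_families(leaf_b)


def sample_species_tree(config: SimConfig) -> dendropy.Tree:
    """Sample a rooted binary ultrametric tree and scale it to PAM units.

    The birth–death process is run until ``n_leaves`` extant tips exist;
    pendant edges are then extended by one exponential waiting time (rate
    n·(birth+death)) so the youngest cherry has positive depth, and all
    branch lengths are rescaled so that the root-to-leaf path length
    equals ``mutation_rate`` PAM.  Leaves are labelled g01, g02, ... and
    internal nodes n0, n1, ... in preorder.
    """
    config.validate()
    rng = random.Random(config.seed)
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_leaves,
        rng=rng,
        repeat_until_success=True,
    )
    tree.seed_node.edge.length = 0.0
    extra = rng.expovariate(
        config.n_leaves * (config.birth_rate + config.death_rate)
    )
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = tree.max_distance_from_root()
    scale = config.mutation_rate / depth if depth > 0 else 0.0
    width = max(2, len(str(config.n_leaves)))
    leaf_counter = 0
    internal_counter = 0
    for node in tree.preorder_node_iter():
        node.edge.length = (node.edge.length or 0.0) * scale
        if node.is_leaf():
            leaf_counter += 1
            node.taxon.label = f"g{leaf_counter:0{width}d}"
            node.label = node.taxon.label
        else:
            node.label = f"n{internal_counter}"
            internal_counter += 1
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    assert n_leaves == config.n_leaves
    return tree


# ---------------------------------------------------------------------------
# lineage state and branch-segment evolution


class _Lineage:
    """Mutable genome state of one lineage at a point in time."""

    __slots__ = ("codes", "starts", "ends", "families", "origins", "paths",
                 "time", "n_sub", "gc_bias")

    def __init__(self, codes, starts, ends, families, origins, paths, time,
                 n_sub=0, gc_bias=0.0):
        self.codes = codes          # np.uint8 array of 2-bit base codes
        self.starts = starts        # np.int64 gene starts
        self.ends = ends            # np.int64 gene ends
        self.families = families    # list[int]
        self.origins = origins      # list[str]
        self.paths = paths          # list[tuple]
        self.time = time            # PAM since root
        self.n_sub = n_sub
        self.gc_bias = gc_bias      # offset of the lineage's target GC from 0.5

    def copy(self) -> "_Lineage":
        return _Lineage(
            self.codes.copy(),
            self.starts.copy(),
            self.ends.copy(),
            list(self.families),
            list(self.origins),
            list(self.paths),
            self.time,
            self.n_sub,
            self.gc_bias,
        )

    @property
    def n_genes(self) -> int:
        return int(self.starts.size)


def _zipf_length(rng: np.random.Generator, exponent: float, max_len: int) -> int:
    while True:
        length = int(rng.zipf(exponent))
        if length <= max_len:
            return length


def _apply_deletion(lin: _Lineage, pos: int, length: int) -> None:
    end = min(pos + length, lin.codes.size)
    if end <= pos:
        return
    lin.codes = np.delete(lin.codes, np.s_[pos:end])
    removed_s = np.minimum(lin.starts, end) - np.minimum(lin.starts, pos)
    removed_e = np.minimum(lin.ends, end) - np.minimum(lin.ends, pos)
    lin.starts = lin.starts - removed_s
    lin.ends = lin.ends - removed_e
    dead = np.nonzero(lin.ends <= lin.starts)[0]
    if dead.size:
        lin.starts = np.delete(lin.starts, dead)
        lin.ends = np.delete(lin.ends, dead)
        for idx in dead[::-1]:
            del lin.families[idx]
            del lin.origins[idx]
            del lin.paths[idx]


def _apply_insertion(lin: _Lineage, pos: int, content: np.ndarray) -> None:
    length = content.size
    lin.codes = np.insert(lin.codes, pos, content)
    # genes strictly containing pos grow; genes at/after pos shift
    lin.starts = lin.starts + np.where(lin.starts >= pos, length, 0)
    lin.ends = lin.ends + np.where(lin.ends > pos, length, 0)


def _mutate(lin: _Lineage, pam: float, config: SimConfig,
            rng: np.random.Generator) -> None:
    """Substitutions and indels over an event-free stretch of ``pam`` PAM."""
    if pam <= 0 or lin.codes.size == 0:
        return
    length = lin.codes.size
    n_sub = rng.poisson(length * pam / 100.0)
    if n_sub:
        pos = rng.integers(0, length, size=n_sub)
        if config.gc_drift == 0.0:
            # uniform targets compose additively in Z4, so repeated hits
            # at one site (including reversions) are handled exactly
            shifts = rng.integers(1, 4, size=n_sub)
            delta = np.bincount(pos, weights=shifts, minlength=length).astype(
                np.int64
            )
            lin.codes = ((lin.codes.astype(np.int64) + delta) % 4).astype(np.uint8)
        else:
            # GC-biased targets: A/T vs C/G drawn per the lineage's current
            # target GC; repeated hits at one site resolve last-event-wins
            g = float(np.clip(0.5 + lin.gc_bias, 0.05, 0.95))
            pi = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
            targets = rng.choice(4, size=n_sub, p=pi).astype(np.uint8)
            cur = lin.codes[pos]
            redraw = targets == cur
            while redraw.any():
                targets[redraw] = rng.choice(
                    4, size=int(redraw.sum()), p=pi
                ).astype(np.uint8)
                redraw = targets == cur
            lin.codes[pos] = targets
        lin.n_sub += int(n_sub)
    n_indel = rng.poisson(length * config.indel_rate * pam)
    for _ in range(n_indel):
        size = _zipf_length(rng, config.zipf_exponent, config.max_indel_len)
        if rng.random() < 0.5:
            if lin.codes.size == 0:
                continue
            pos = int(rng.integers(0, lin.codes.size))
            _apply_deletion(lin, pos, size)
        else:
            pos = int(rng.integers(0, lin.codes.size + 1))
            content = rng.integers(0, 4, size=size).astype(np.uint8)
            _apply_insertion(lin, pos, content)


def _insert_gene(lin: _Lineage, gene_codes: np.ndarray, family: int,
                 origin: str, path: tuple, rng: np.random.Generator) -> None:
    """Insert a gene copy at a uniformly chosen inter-gene slot."""
    slot = int(rng.integers(0, lin.n_genes + 1))
    if slot < lin.n_genes:
        pos = int(lin.starts[slot])
    else:
        pos = int(lin.codes.size)
    length = gene_codes.size
    lin.codes = np.insert(lin.codes, pos, gene_codes)
    lin.starts = lin.starts + np.where(lin.starts >= pos, length, 0)
    lin.ends = lin.ends + np.where(lin.ends > pos, length, 0)
    lin.starts = np.insert(lin.starts, slot, pos)
    lin.ends = np.insert(lin.ends, slot, pos + length)
    lin.families.insert(slot, family)
    lin.origins.insert(slot, origin)
    lin.paths.insert(slot, path)


def _advance(lin: _Lineage, to_time: float, config: SimConfig,
             rng: np.random.Generator) -> None:
    """Evolve a lineage from its current time to ``to_time``.

    Duplication events are drawn at their own Poisson times inside the
    stretch; substitutions and indels fill the event-free sub-intervals so
    a young duplicate accrues mutations only after it is born.
    """
    delta = to_time - lin.time
    if delta <= 0:
        lin.time = to_time
        return
    n_dup = 0
    if config.dup_rate > 0 and lin.n_genes > 0:
        n_dup = rng.poisson(config.dup_rate * lin.n_genes * delta)
    dup_times = np.sort(rng.uniform(lin.time, to_time, size=n_dup)) if n_dup else []
    t = lin.time
    for td in dup_times:
        _mutate(lin, td - t, config, rng)
        if lin.n_genes > 0:
            g = int(rng.integers(0, lin.n_genes))
            gene_codes = lin.codes[lin.starts[g] : lin.ends[g]].copy()
            if gene_codes.size:
                _insert_gene(
                    lin,
                    gene_codes,
                    lin.families[g],
                    "duplication",
                    lin.paths[g] + (("dup", float(td)),),
                    rng,
                )
        t = td
    _mutate(lin, to_time - t, config, rng)
    if config.gc_drift > 0:
        lin.gc_bias += float(
            rng.normal(0.0, config.gc_drift * np.sqrt(delta / 100.0))
        )
    lin.time = to_time


# ---------------------------------------------------------------------------
# whole-tree evolution


def evolve(
    tree: dendropy.Tree, config: SimConfig
) -> tuple[dict[str, SimGenome], HomologyMap]:
    """Evolve a root genome down ``tree``; returns leaf genomes + truth map."""
    config.validate()
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    if not leaves:
        raise DataError("tree has no leaves")
    labels = [leaf.taxon.label if leaf.taxon else leaf.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate leaf labels in tree")

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))

    # node times in PAM from the root
    node_time: dict[int, float] = {id(tree.seed_node): 0.0}
    node_label: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        node_label[id(node)] = (
            node.taxon.label if node.taxon is not None else node.label
        ) or "root"
        if node.parent_node is not None:
            node_time[id(node)] = node_time[id(node.parent_node)] + (
                node.edge.length or 0.0
            )

    genome_len = config.n_genes * config.gene_len
    root = _Lineage(
        codes=rng.integers(0, 4, size=genome_len).astype(np.uint8),
        starts=np.arange(config.n_genes, dtype=np.int64) * config.gene_len,
        ends=(np.arange(config.n_genes, dtype=np.int64) + 1) * config.gene_len,
        families=list(range(config.n_genes)),
        origins=["vertical"] * config.n_genes,
        paths=[()] * config.n_genes,
        time=0.0,
    )

    # event queue over branches; each branch is keyed by its child node
    counter = 0
    events: list[tuple[float, int, str, object]] = []
    active: dict[int, _Lineage] = {}
    branch_end: dict[int, float] = {}

    def activate(child: dendropy.Node, state: _Lineage) -> None:
        nonlocal counter
        key = id(child)
        active[key] = state
        t0, t1 = state.time, node_time[key]
        branch_end[key] = t1
        heapq.heappush(events, (t1, counter, "node", child))
        counter += 1
        if config.lgt_rate > 0 and state.n_genes > 0 and t1 > t0:
            n_lgt = rng.poisson(config.lgt_rate * state.n_genes * (t1 - t0))
            for t_ev in rng.uniform(t0, t1, size=n_lgt):
                heapq.heappush(events, (float(t_ev), counter, "lgt", child))
                counter += 1

    seed_children = list(tree.seed_node.child_nodes())
    if not seed_children:  # single-leaf degenerate tree
        raise DataError("tree must have at least one internal node")
    for child in seed_children:
        activate(child, root.copy())

    genomes: dict[str, SimGenome] = {}
    records: list[GeneRecord] = []

    while events:
        t_ev, _, kind, node = heapq.heappop(events)
        key = id(node)
        if key not in active:
            continue
        if kind == "lgt":
            donors = [k for k in active if k != key and branch_end[k] >= t_ev]
            if not donors:
                continue
            donor_key = donors[int(rng.integers(0, len(donors)))]
            donor = active[donor_key]
            _advance(donor, t_ev, config, rng)
            recipient = active[key]
            _advance(recipient, t_ev, config, rng)
            if donor.n_genes == 0:
                continue
            g = int(rng.integers(0, donor.n_genes))
            gene_codes = donor.codes[donor.starts[g] : donor.ends[g]].copy()
            if gene_codes.size == 0:
                continue
            event = (
                "lgt",
                float(t_ev),
                node_label[donor_key],
                node_label[key],
            )
            _insert_gene(
                recipient, gene_codes, donor.families[g], "lgt",
                donor.paths[g] + (event,), rng,
            )
        else:  # reached the child node ending this branch
            state = active.pop(key)
            del branch_end[key]
            _advance(state, t_ev, config, rng)
            if node.is_leaf():
                label = node_label[key]
                genes = list(zip(state.starts.tolist(), state.ends.tolist()))
                genomes[label] = SimGenome(
                    leaf_id=label,
                    sequence=decode(state.codes),
                    genes=genes,
                    family_ids=list(state.families),
                    origin=list(state.origins),
                    n_substitutions=state.n_sub,
                )
                for gi, (fam, orig, path) in enumerate(
                    zip(state.families, state.origins, state.paths)
                ):
                    records.append(GeneRecord(label, gi, fam, orig, path))
            else:
                children = node.child_nodes()
                for i, child in enumerate(children):
                    activate(child, state.copy() if i < len(children) - 1 else state)

    return genomes, HomologyMap(records, config.n_genes)


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf sums of branch lengths as a DistanceMatrix.

    Labels are sorted; duplicate leaf labels raise :class:`DataError`.
    """
    taxa = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        if label in taxa:
            raise DataError(f"duplicate leaf label: {label!r}")
        taxa[label] = leaf.taxon
    labels = sorted(taxa)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, kind="distance",
                          method={"method": "patristic"})
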