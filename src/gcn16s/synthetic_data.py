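"""Seeded generators for trees, sequences, copy-number traits, lineages and
mock communities.

All generators are pure functions of their seed, and the pieces share one id
namespace: a Yule tree is grown, sequences evolve along it under Jukes-Cantor
substitutions plus geometric-length indels (with the true alignment tracked
column by column, so positional rates have an exact oracle), the copy-number
trait evolves either as clamped-rounded Brownian motion or as a function of
planted sequence motifs, and lineages come from depth cuts of the same tree.
Copy numbers live on the empirically observed 1..21 copies/genome range and
the trait tail is kept rare, mirroring the strong right skew of real
copy-number data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .community_correction import CommunityProfile, reads_from_cells
from .phylo_estimator import PhyloTree
from .sequence_prep import SeqRecord
from .taxonomy_estimator import RANKS

NUCS = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the simulator; defaults give a desk-scale but non-trivial
    corpus (300 tips, 800 nt, visible divergence, 1..21 copy range)."""

    n_tips: int = 300
    birth_rate: float = 1.0
    seq_length: int = 800
    substitution_rate: float = 0.05  # expected substitutions/site per unit branch
    indel_rate: float = 0.005  # indel events/site per unit branch
    indel_geom_p: float = 0.5  # geometric length distribution of indels
    trait_model: str = "motif-determined"  # or "brownian-clamped"
    trait_bounds: tuple[float, float] = (1.0, 21.0)
    trait_base: float = 5.0
    n_motifs: int = 5
    motif_length: int = 10
    motif_effects: Optional[tuple[float, ...]] = None
    # default random effect magnitudes; the range is sized so the trait SD
    # lands near the empirical copies/genome spread (mean ~5, SD ~2.7)
    motif_effect_range: tuple[float, float] = (2.0, 3.5)
    # clade sizes (fraction of tips) eligible to carry a motif
    motif_clade_range: tuple[float, float] = (0.25, 0.75)
    # probability that a clade tip has lost its motif (imperfect phylogenetic
    # conservation: the trait-bearing locus decays in some lineages, so tree
    # proximity only approximates the sequence-determined trait)
    motif_flip_rate: float = 0.0
    noise_sd: float = 0.25
    bm_sigma2: float = 8.0  # Brownian variance per unit branch
    root_value: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.trait_bounds
        if not (1 <= lo <= hi):
            raise ValueError("trait bounds must satisfy 1 <= low <= high")
        if min(self.birth_rate, self.substitution_rate, self.indel_rate) < 0:
            raise ValueError("rates must be >= 0")

    @classmethod
    def recovery(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Parameter-recovery conditions: 2000 tips, 5 strong motifs,
        trait noise SD 0.25."""
        kw = dict(n_tips=2000, seq_length=300, n_motifs=5, noise_sd=0.25, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def benchmark(cls, seed: int = 7, **overrides) -> "SimulationConfig":
        """Method-comparison conditions: 300 tips and a trait shaped by many
        clade-borne loci of modest effect, so copy numbers vary at every
        phylogenetic scale (strong signal, but not piecewise-constant over a
        handful of clades)."""
        kw = dict(
            n_tips=300, seq_length=400, substitution_rate=0.02, n_motifs=12,
            motif_effect_range=(0.7, 1.4), motif_clade_range=(0.05, 0.5),
            motif_flip_rate=0.15, noise_sd=0.25, seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


# ---------------------------------------------------------------------------
# tree

def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Yule pure-birth tree grown to n_tips; exponential waiting times are
    spread over the open lineages, so branch lengths are exchangeable."""
    if config.n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(config.seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node.edge.length = 0.0
    open_nodes = [tree.seed_node]
    while len(open_nodes) < config.n_tips:
        wait = rng.exponential(1.0 / (config.birth_rate * len(open_nodes)))
        for node in open_nodes:
            node.edge.length += wait
        i = rng.integers(len(open_nodes))
        node = open_nodes.pop(i)
        for _ in range(2):
            child = node.new_child()
            child.edge.length = 0.0
            open_nodes.append(child)
    final_wait = rng.exponential(1.0 / (config.birth_rate * len(open_nodes)))
    for node in open_nodes:
        node.edge.length += final_wait
    for k, node in enumerate(open_nodes, start=1):
        node.taxon = taxon_ns.new_taxon(f"t{k}")
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# sequences

@dataclass
class EvolvedSequences:
    """Tip sequences plus the exact alignment implied by the indel history.

    ``alignment`` maps id -> gapped row (all rows equal length); the root row
    is included under id 'root' and is the natural mutation-rate reference.
    ``records`` are the ungapped tip sequences.
    """

    records: list[SeqRecord]
    alignment: dict[str, str]
    root_id: str = "root"


def evolve_sequences(
    ptree: PhyloTree,
    config: SimulationConfig,
    motifs: Optional[Sequence[str]] = None,
) -> EvolvedSequences:
    """Jukes-Cantor substitutions + geometric indels along each branch.

    Sequences are lists of (column_id, base) so insertion columns created on
    any branch are globally ordered, which yields the true alignment without
    re-alignment. Optional motifs are each planted on one mid-sized clade
    (written over the sequence at that clade's stem, at a motif-specific
    offset), so motif presence is clade-structured — phylogenetically
    conserved, like real trait-bearing loci — and close to balanced across
    tips. Motifs may subsequently decay by mutation; trait generators read
    presence from the final sequences, so traits stay exact functions of
    sequence content.
    """
    if config.seq_length < 100:
        raise ValueError("root sequence length must be >= 100")
    rng = _rng(config.seed + 1)
    L = config.seq_length
    root_seq = rng.choice(NUCS, size=L).tolist()

    # choose one stem node per motif among clades holding 25-75% of the tips
    tree = ptree.tree
    plant_at: dict[int, list[tuple[int, str]]] = {}
    if motifs:
        n_tips = len(ptree.tip_labels)
        clade_size: dict[int, int] = {}
        for node in tree.postorder_node_iter():
            clade_size[id(node)] = (1 if node.is_leaf() else
                                    sum(clade_size[id(c)] for c in node.child_nodes()))
        lo_c, hi_c = config.motif_clade_range
        candidates = [node for node in tree.preorder_node_iter()
                      if not node.is_leaf() and node.parent_node is not None
                      and lo_c * n_tips <= clade_size[id(node)] <= hi_c * n_tips]
        if not candidates:
            candidates = [node for node in tree.preorder_node_iter()
                          if not node.is_leaf() and node.parent_node is not None]
        gap = L // (len(motifs) + 1)
        order = rng.permutation(len(candidates))
        for mi, motif in enumerate(motifs):
            # distinct stems, so motif presence patterns are not collinear
            stem = candidates[int(order[mi % len(candidates)])]
            off = gap * (mi + 1) - len(motif) // 2
            # re-write the motif at every node of the clade: inside the clade
            # it behaves as a purifying-selected functional locus, outside it
            # is free to never arise
            for node in stem.preorder_iter():
                plant_at.setdefault(id(node), []).append((off, motif.upper()))

    # every column ever created lives in one global ordered master list; an
    # insertion column is spliced in right after its left neighbor, so every
    # lineage's sequence stays an ordered subsequence of the master list and
    # the true multiple alignment falls out for free
    root_cols = [("root", i) for i in range(L)]
    master: list = list(root_cols)
    next_insert = [0]

    def fresh_column(left_col):
        next_insert[0] += 1
        cid = ("ins", next_insert[0])
        pos = master.index(left_col) + 1 if left_col is not None else 0
        master.insert(pos, cid)
        return cid

    def evolve_branch(seq: list, length: float, rng: np.random.Generator) -> list:
        seq = list(seq)
        # substitutions: JC, P(change) = 3/4 (1 - exp(-4/3 mu t))
        mu_t = config.substitution_rate * length
        p_change = 0.75 * (1.0 - np.exp(-4.0 * mu_t / 3.0))
        hits = np.flatnonzero(rng.random(len(seq)) < p_change)
        for i in hits:
            col, base = seq[i]
            choices = [b for b in "ACGT" if b != base]
            seq[i] = (col, choices[rng.integers(3)])
        # indels: Poisson number of events, geometric lengths
        n_events = rng.poisson(config.indel_rate * length * len(seq))
        for _ in range(n_events):
            size = int(rng.geometric(config.indel_geom_p))
            if rng.random() < 0.5 and len(seq) > size:  # deletion
                start = int(rng.integers(len(seq) - size + 1))
                del seq[start : start + size]
            else:  # insertion
                at = int(rng.integers(len(seq) + 1))
                for s in range(size):
                    left = seq[at + s - 1][0] if at + s > 0 else None
                    col = fresh_column(left)
                    seq.insert(at + s, (col, str(NUCS[rng.integers(4)])))
        return seq

    seqs: dict[int, list] = {id(tree.seed_node): [(c, b) for c, b in zip(root_cols, root_seq)]}
    branch_rngs = _rng(config.seed + 2)
    flip_rng = _rng(config.seed + 5)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child_rng = _rng(int(branch_rngs.integers(2**31)))
        seq = evolve_branch(
            seqs[id(node.parent_node)], float(node.edge.length or 0.0), child_rng
        )
        for off, motif in plant_at.get(id(node), ()):
            off = min(off, len(seq) - len(motif))
            if node.is_leaf() and flip_rng.random() < config.motif_flip_rate:
                # the locus decayed in this lineage: scramble instead of plant
                for s in range(len(motif)):
                    col, _ = seq[off + s]
                    seq[off + s] = (col, str(NUCS[flip_rng.integers(4)]))
                continue
            for s, base in enumerate(motif):
                col, _ = seq[off + s]
                seq[off + s] = (col, base)
        seqs[id(node)] = seq

    # build the alignment over the union of surviving columns
    tip_nodes = list(tree.leaf_node_iter())
    rows = {"root": seqs[id(tree.seed_node)]}
    for node in tip_nodes:
        rows[node.taxon.label] = seqs[id(node)]
    all_cols = set()
    for row in rows.values():
        all_cols.update(c for c, _ in row)
    ordered = [c for c in master if c in all_cols]
    col_pos = {c: i for i, c in enumerate(ordered)}
    alignment = {}
    for rid, row in rows.items():
        arr = ["-"] * len(ordered)
        for c, b in row:
            arr[col_pos[c]] = b
        alignment[rid] = "".join(arr)
    records = [
        SeqRecord(id=node.taxon.label, seq="".join(b for _, b in seqs[id(node)]))
        for node in tip_nodes
    ]
    return EvolvedSequences(records=records, alignment=alignment)


def random_motifs(config: SimulationConfig) -> list[str]:
    rng = _rng(config.seed + 3)
    return ["".join(rng.choice(NUCS, size=config.motif_length)) for _ in range(config.n_motifs)]


# ---------------------------------------------------------------------------
# traits

def evolve_gcn(
    ptree: PhyloTree,
    config: SimulationConfig,
    sequences: Optional[EvolvedSequences] = None,
    motifs: Optional[Sequence[str]] = None,
) -> tuple[dict[str, float], dict]:
    """Tip copy-number values; returns (trait map, ground-truth metadata).

    brownian-clamped: Brownian motion from the root value, rounded to
    integers and clamped to the trait bounds (phylogenetically conserved,
    like real copy numbers). motif-determined: base + sum of per-motif
    effects over motifs present in the tip sequence + Gaussian noise,
    clamped; the trait is then an exact function of sequence content.
    """
    lo, hi = config.trait_bounds
    rng = _rng(config.seed + 4)
    if config.trait_model == "brownian-clamped":
        values: dict[int, float] = {id(ptree.tree.seed_node): config.root_value}
        out: dict[str, float] = {}
        for node in ptree.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            t = float(node.edge.length or 0.0)
            step = rng.normal(0.0, np.sqrt(config.bm_sigma2 * t)) if t > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
            if node.is_leaf():
                out[node.taxon.label] = float(np.clip(round(values[id(node)]), lo, hi))
        return out, {"model": "brownian-clamped", "root_value": config.root_value}
    if config.trait_model == "motif-determined":
        if sequences is None:
            raise ValueError("motif-determined traits need evolved sequences")
        if motifs is None:
            motifs = random_motifs(config)
        effects = config.motif_effects
        if effects is None:
            lo_e, hi_e = config.motif_effect_range
            effects = tuple(rng.choice([-1.0, 1.0]) * rng.uniform(lo_e, hi_e)
                            for _ in motifs)
        out = {}
        presence = {}
        for rec in sequences.records:
            present = [m in rec.seq for m in motifs]
            presence[rec.id] = present
            val = config.trait_base + sum(e for e, p in zip(effects, present) if p)
            val += rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            out[rec.id] = float(np.clip(val, lo, hi))
        return out, {"model": "motif-determined", "motifs": list(motifs),
                     "effects": list(effects), "presence": presence,
                     "base": config.trait_base}
    raise ValueError(f"unknown trait model {config.trait_model!r}")


# ---------------------------------------------------------------------------
# lineages

def derive_lineages(
    ptree: PhyloTree, ranks: int = 7, deepest_cut: float = 0.6
) -> dict[str, list[str]]:
    """Nested taxonomy from depth cuts of the tree.

    The tree is cut at ranks-1 evenly spaced depths up to ``deepest_cut`` of
    the tip depth; the clade a tip sits in at each cut names its taxon at
    that rank (the species rank is the tip itself), so every named taxon is
    monophyletic by construction and lineages are consistent with the tree.
    The deepest cut sits well above the tips because real reference
    taxonomies are coarse — a genus pools many sequences — which is exactly
    what costs taxonomy aggregation accuracy relative to tree-aware methods.
    """
    tree = ptree.tree
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length or 0.0)
    tip_depths = [depth[id(lf)] for lf in tree.leaf_node_iter()]
    max_depth = min(tip_depths)
    cuts = [max_depth * deepest_cut * (k + 1) / (ranks - 1) for k in range(ranks - 1)]

    # ancestor of each tip at each cut depth
    lineages: dict[str, list[str]] = {}
    clade_names: dict[tuple[int, int], str] = {}
    counter = [0]

    def clade_name(level: int, node_id: int) -> str:
        key = (level, node_id)
        if key not in clade_names:
            counter[0] += 1
            clade_names[key] = f"T{level + 1}.{counter[0]}"
        return clade_names[key]

    for lf in tree.leaf_node_iter():
        path = []
        node = lf
        while node is not None:
            path.append(node)
            node = node.parent_node
        path.reverse()  # root ... tip
        names = []
        for level, cut in enumerate(cuts):
            # the head of the edge crossing the cut depth: these nodes
            # partition the tips into monophyletic groups
            anc = path[-1]
            for node in path:
                if depth[id(node)] > cut + 1e-12:
                    anc = node
                    break
            names.append(clade_name(level, id(anc)))
        names.append(lf.taxon.label)  # species rank = the tip itself
        lineages[lf.taxon.label] = names[: len(RANKS)]
    return lineages


# ---------------------------------------------------------------------------
# mock communities

def make_mock_community(
    preset: str = "even",
    n: int = 10,
    gcn: Optional[Sequence[float]] = None,
    total_cells: float = 1e5,
    seed: int = 0,
) -> CommunityProfile:
    """A defined community of n strains with known cells and copy numbers.

    'even': equal cell fractions (10 strains at 10% each by default);
    'staggered': log-spaced, strictly decreasing fractions spanning ~3 orders
    of magnitude. Copy numbers default to seeded integers in 1..15.
    """
    if n < 2:
        raise ValueError("need at least 2 strains")
    rng = _rng(seed)
    taxa = [f"strain{i+1}" for i in range(n)]
    if preset == "even":
        fractions = np.full(n, 1.0 / n)
    elif preset == "staggered":
        raw = np.logspace(0, -3, n)
        fractions = raw / raw.sum()
    else:
        raise ValueError(f"unknown preset {preset!r}")
    cells = fractions * total_cells
    if gcn is None:
        gcn = rng.integers(1, 16, size=n).astype(float)
    gcn = np.asarray(gcn, dtype=float)
    profile = CommunityProfile(taxa=taxa, cell_counts=cells, gcn=gcn)
    profile.read_fraction = reads_from_cells(cells, gcn)
    return profile


# ---------------------------------------------------------------------------
# one-call benchmark dataset

@dataclass
class Benchmark:
    """A fully consistent simulated study: tree, sequences, alignment,
    traits, lineages and ground-truth metadata sharing one id namespace."""

    tree: PhyloTree
    sequences: EvolvedSequences
    traits: dict[str, float]
    truth: dict
    lineages: dict[str, list[str]]
    config: SimulationConfig


def make_benchmark(config: Optional[SimulationConfig] = None) -> Benchmark:
    cfg = config or SimulationConfig()
    tree = simulate_tree(cfg)
    motifs = random_motifs(cfg) if cfg.trait_model == "motif-determined" else None
    seqs = evolve_sequences(tree, cfg, motifs=motifs)
    traits, truth = evolve_gcn(tree, cfg, sequences=seqs, motifs=motifs)
    lineages = derive_lineages(tree)
    return Benchmark(tree, seqs, traits, truth, lineages, cfg)
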