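"""Synthetic fixtures with planted ground truth.

Every generator draws from its own named pseudorandom stream derived from a
single integer seed, so outputs are bitwise-reproducible and adding a new
generator never perturbs existing fixtures.  The fixtures emulate the
structures the scoring pipeline consumes — taxonomies, pathway-membership
gold standards, high- and low-throughput evidence with known true-positive
content, and mutated sequence families with a nested ortholog-group
hierarchy — at desk scale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import BenchmarkLabel
from .genome import ParsedProtein
from .model import (
    EvidenceRecord,
    GoldStandard,
    OrthologGroup,
    OrthologyHierarchy,
    Pair,
    ProteinRef,
    TaxonomyTree,
    canonical_pair,
)

__all__ = [
    "make_taxonomy",
    "make_gold_standard",
    "implied_positive_pairs",
    "make_ranked_benchmark",
    "make_ht_experiment",
    "make_lt_evidence",
    "make_proteomes",
    "emit_fasta",
    "SyntheticProteomes",
    "DEFAULT_TAXON",
]

#: Organism used for single-organism evidence fixtures.
DEFAULT_TAXON = "TAX1"


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named pseudorandom stream: one seed, independent streams per generator."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# Taxonomy


def make_taxonomy(n_species: int, depth: int, seed: int) -> TaxonomyTree:
    """Balanced-ish random single-rooted tree with ``n_species`` leaves.

    Leaves are named SP1..SPn; internal nodes N1..; the root is "root".
    Max root-to-leaf path length is ``depth + 1`` edges.
    """
    if n_species < 1 or depth < 1:
        raise ValueError("n_species and depth must be >= 1")
    rng = _rng(seed, "taxonomy")
    parent: dict[str, str] = {}
    counter = [0]

    def build(node: str, leaves: list[str], d: int) -> None:
        if d <= 0 or len(leaves) <= 1:
            for leaf in leaves:
                parent[leaf] = node
            return
        k = int(min(len(leaves), 2 + rng.integers(0, 2)))
        # random partition into k non-empty parts, order-preserving
        cuts = sorted(rng.choice(np.arange(1, len(leaves)), size=k - 1, replace=False)) if k > 1 else []
        parts = np.split(np.array(leaves, dtype=object), cuts)
        for part in parts:
            part = list(part)
            if len(part) == 1:
                parent[part[0]] = node
                continue
            counter[0] += 1
            child = f"N{counter[0]}"
            parent[child] = node
            build(child, part, d - 1)

    species = [f"SP{i + 1}" for i in range(n_species)]
    build("root", species, depth)
    return TaxonomyTree(parent, "root")


# ---------------------------------------------------------------------------
# Gold standard


def make_gold_standard(
    n_proteins: int,
    n_pathways: int,
    mean_size: int,
    seed: int,
    n_excluded: int = 0,
) -> GoldStandard:
    """Random, possibly overlapping pathway-membership sets.

    Proteins are P0001..; pathway sizes are Poisson around ``mean_size``
    (at least 2).  ``n_excluded`` extra homology-dominated sets are added
    and flagged excluded (they never contribute to truth labels).
    """
    if n_proteins <= 0 or n_pathways <= 0 or mean_size <= 0:
        raise ValueError("sizes must be positive")
    if mean_size > n_proteins:
        raise ValueError("mean_size cannot exceed n_proteins")
    rng = _rng(seed, "gold")
    proteins = np.array([f"P{i + 1:04d}" for i in range(n_proteins)], dtype=object)
    sets: dict[str, list[str]] = {}
    for i in range(n_pathways + n_excluded):
        size = int(np.clip(rng.poisson(mean_size), 2, n_proteins))
        members = rng.choice(proteins, size=size, replace=False)
        sets[f"map{i + 1:03d}"] = sorted(members)
    excluded = {f"map{i + 1:03d}" for i in range(n_pathways, n_pathways + n_excluded)}
    return GoldStandard(sets, excluded_sets=excluded)


def implied_positive_pairs(gold: GoldStandard) -> set[frozenset[str]]:
    """All co-member protein-id pairs of the non-excluded sets (oracle use)."""
    out: set[frozenset[str]] = set()
    for members in gold.active_sets.values():
        mem = sorted(members)
        for i, p in enumerate(mem):
            for q in mem[i + 1 :]:
                out.add(frozenset((p, q)))
    return out


def _ref(pid: str, taxon: str) -> ProteinRef:
    return ProteinRef(taxon, pid)


def _sample_positive_pair(gold: GoldStandard, rng: np.random.Generator, taxon: str) -> Pair:
    sets = [sorted(m) for m in gold.active_sets.values() if len(m) >= 2]
    members = sets[int(rng.integers(0, len(sets)))]
    i, j = rng.choice(len(members), size=2, replace=False)
    return canonical_pair(_ref(members[i], taxon), _ref(members[j], taxon))


def _sample_negative_pair(gold: GoldStandard, rng: np.random.Generator, taxon: str) -> Optional[Pair]:
    annotated = sorted(gold.annotated)
    for _ in range(200):
        i, j = rng.choice(len(annotated), size=2, replace=False)
        p, q = annotated[i], annotated[j]
        if not gold.co_member(p, q):
            return canonical_pair(_ref(p, taxon), _ref(q, taxon))
    return None


# ---------------------------------------------------------------------------
# Ranked benchmark with a planted precision step function


def make_ranked_benchmark(
    gold: GoldStandard,
    strata: Sequence[tuple[float, float]],
    n_pairs: int,
    seed: int,
    taxon: str = DEFAULT_TAXON,
) -> tuple[list[Pair], list[float], list[bool]]:
    """Ranked pairs whose true precision is a known step function of rank.

    ``strata`` is a sequence of (fraction_of_ranking, precision); fractions
    must sum to 1.  Returns (pairs ranked best-first, descending raw scores,
    planted truth), where each rank slot holds a gold-positive pair with its
    stratum's probability and a both-annotated negative pair otherwise.
    """
    if abs(sum(f for f, _ in strata) - 1.0) > 1e-9:
        raise ValueError("stratum fractions must sum to 1")
    rng = _rng(seed, "ranked-benchmark")
    sizes = [int(round(f * n_pairs)) for f, _ in strata]
    sizes[-1] = n_pairs - sum(sizes[:-1])
    pairs: list[Pair] = []
    truth: list[bool] = []
    seen: set[Pair] = set()
    for size, (_, precision) in zip(sizes, strata):
        for _ in range(size):
            # the truth coin is fixed per rank slot; only the pair is retried
            # on duplicates, so collisions cannot skew the planted rate
            is_pos = bool(rng.random() < precision)
            for _attempt in range(200):
                pair = (
                    _sample_positive_pair(gold, rng, taxon)
                    if is_pos
                    else _sample_negative_pair(gold, rng, taxon)
                )
                if pair is not None and pair not in seen:
                    break
            else:
                raise RuntimeError("could not sample enough distinct pairs; enlarge the gold standard")
            seen.add(pair)
            pairs.append(pair)
            truth.append(is_pos)
    raw = list(np.linspace(1.0, 0.0, num=n_pairs, endpoint=False))
    return pairs, raw, truth


# ---------------------------------------------------------------------------
# HT experiment with planted topology


@dataclass
class SyntheticExperiment:
    """An HT experiment fixture plus its planted truth."""

    publication_id: str
    method_term: str
    pairs: list[Pair]
    truth: dict[Pair, bool] = field(default_factory=dict)

    def records(self, source_db: str = "synthdb") -> list[EvidenceRecord]:
        return [
            EvidenceRecord(pair=p, publication_id=self.publication_id, method_term=self.method_term, source_db=source_db)
            for p in self.pairs
        ]


def make_ht_experiment(
    gold: GoldStandard,
    n_pairs: int,
    true_fraction: float,
    topology_strength: float,
    seed: int,
    taxon: str = DEFAULT_TAXON,
    clique_size: int = 6,
    method_term: str = "MI:0676",
    publication_id: str = "9000001",
) -> SyntheticExperiment:
    """One high-throughput experiment with planted true pairs.

    ``true_fraction`` of the pairs are gold co-members.  With probability
    ``topology_strength`` a true pair is laid down inside a within-pathway
    clique of ``clique_size`` proteins (so its endpoints share interactors
    and the raw shared-neighbor score is high); remaining pairs are placed
    as isolated edges (raw score 0).  False pairs are both-annotated
    non-co-members, isolated.
    """
    if n_pairs < 25:
        raise ValueError("an HT experiment needs at least 25 pairs")
    if not 0.0 <= true_fraction <= 1.0 or not 0.0 <= topology_strength <= 1.0:
        raise ValueError("true_fraction and topology_strength must be in [0,1]")
    rng = _rng(seed, "ht-experiment")
    n_true = int(round(n_pairs * true_fraction))
    edges: dict[Pair, bool] = {}

    # clique-structured true pairs: whole pathways sliced into cliques
    n_clique_true = int(round(n_true * topology_strength))
    big_sets = [sorted(m) for m in gold.active_sets.values() if len(m) >= clique_size]
    rng.shuffle(big_sets)
    used: set[str] = set()
    planted = 0
    for members in big_sets:
        avail = [p for p in members if p not in used]
        while len(avail) >= clique_size and planted < n_clique_true:
            clique = avail[:clique_size]
            avail = avail[clique_size:]
            used.update(clique)
            for i, p in enumerate(clique):
                for q in clique[i + 1 :]:
                    pair = canonical_pair(_ref(p, taxon), _ref(q, taxon))
                    if pair not in edges:
                        edges[pair] = True
                        planted += 1
        if planted >= n_clique_true:
            break

    while planted < n_true:
        pair = _sample_positive_pair(gold, rng, taxon)
        if pair not in edges:
            edges[pair] = True
            planted += 1

    attempts = 0
    while len(edges) < n_pairs and attempts < 50 * n_pairs:
        pair = _sample_negative_pair(gold, rng, taxon)
        attempts += 1
        if pair is not None and pair not in edges:
            edges[pair] = False
    if len(edges) < n_pairs:
        raise RuntimeError("could not place enough distinct false pairs; enlarge the gold standard")

    pairs = sorted(edges)
    return SyntheticExperiment(
        publication_id=publication_id,
        method_term=method_term,
        pairs=pairs,
        truth=dict(edges),
    )


# ---------------------------------------------------------------------------
# LT evidence


def make_lt_evidence(
    gold: GoldStandard,
    method_term: str,
    n_pairs: int,
    tp_rate: float,
    seed: int,
    taxon: str = DEFAULT_TAXON,
    pairs_per_publication: int = 5,
    source_db: str = "synthdb",
) -> list[EvidenceRecord]:
    """Low-throughput evidence for one detection method.

    Each pair is a gold positive with probability ``tp_rate``; pairs are
    spread over many small publications (each far below the HT threshold).
    """
    if not 0.0 <= tp_rate <= 1.0:
        raise ValueError("tp_rate must be in [0,1]")
    if pairs_per_publication >= 25:
        raise ValueError("LT publications must stay below the HT threshold")
    rng = _rng(seed, "lt-evidence")
    records = []
    seen: set[Pair] = set()
    for i in range(n_pairs):
        is_pos = bool(rng.random() < tp_rate)
        for _attempt in range(200):
            pair = (
                _sample_positive_pair(gold, rng, taxon)
                if is_pos
                else _sample_negative_pair(gold, rng, taxon)
            )
            if pair is not None and pair not in seen:
                break
        else:
            raise RuntimeError("could not sample enough distinct LT pairs")
        seen.add(pair)
        pub = f"80{i // pairs_per_publication + 1:05d}"
        records.append(
            EvidenceRecord(pair=pair, publication_id=pub, method_term=method_term, source_db=source_db)
        )
    return records


# ---------------------------------------------------------------------------
# Proteomes and orthology hierarchy

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SyntheticProteomes:
    """Mutated sequence families over a taxonomy, with their true orthology."""

    proteomes: dict[str, list[ParsedProtein]]
    sequences: dict[ProteinRef, str]
    hierarchy: OrthologyHierarchy
    family_of: dict[ProteinRef, int]

    def reference_collection(self) -> dict[ProteinRef, str]:
        return dict(self.sequences)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(seq.size) < rate
    out = seq.copy()
    out[mask] = _AA[rng.integers(0, len(_AA), size=int(mask.sum()))]
    return out


def make_proteomes(
    tree: TaxonomyTree,
    orthogroups_per_level: int,
    paralog_rate: float,
    seq_length: int,
    seed: int,
    mutation_rate: float = 0.02,
) -> SyntheticProteomes:
    """Sequence families evolved down the taxonomy, with nested ortholog groups.

    Each of ``orthogroups_per_level`` families starts from a random ancestral
    sequence at the root and accumulates point substitutions along every
    branch (``mutation_rate`` per residue per branch).  Each species carries
    one copy per family, plus an extra in-paralog with probability
    ``paralog_rate``.  Ortholog groups are emitted per family at every
    internal taxonomy node (nested via parent_group), so the family is
    recoverable at any level.
    """
    if orthogroups_per_level < 1 or seq_length < 10:
        raise ValueError("need at least one family and seq_length >= 10")
    if not 0.0 <= paralog_rate <= 1.0:
        raise ValueError("paralog_rate must be in [0,1]")
    rng = _rng(seed, "proteomes")
    species = tree.leaves()
    proteomes: dict[str, list[ParsedProtein]] = {sp: [] for sp in species}
    sequences: dict[ProteinRef, str] = {}
    family_of: dict[ProteinRef, int] = {}
    members_by_family: dict[int, list[ProteinRef]] = {}

    for fam in range(1, orthogroups_per_level + 1):
        node_seq: dict[str, np.ndarray] = {
            tree.root: _AA[rng.integers(0, len(_AA), size=seq_length)]
        }
        # evolve breadth-first down the tree
        stack = [tree.root]
        while stack:
            node = stack.pop()
            for child in tree.children(node):
                node_seq[child] = _mutate(node_seq[node], mutation_rate, rng)
                stack.append(child)
        for sp in species:
            n_copies = 1 + (1 if rng.random() < paralog_rate else 0)
            for c in range(n_copies):
                suffix = "" if c == 0 else "b"
                pid = f"{sp}_F{fam:03d}{suffix}"
                seq = node_seq[sp] if c == 0 else _mutate(node_seq[sp], mutation_rate, rng)
                ref = ProteinRef(sp, pid, display_name=f"F{fam:03d}", description=f"family {fam} protein")
                proteomes[sp].append(
                    ParsedProtein(
                        protein_id=pid,
                        sequence="".join(seq),
                        gene_name=f"F{fam:03d}",
                        description=f"family {fam} protein",
                        organism_name=sp,
                    )
                )
                sequences[ref] = "".join(seq)
                family_of[ref] = fam
                members_by_family.setdefault(fam, []).append(ref)

    groups: list[OrthologGroup] = []
    internal = sorted(tree.nodes - set(species))
    node_group_id = {}
    for fam, members in members_by_family.items():
        for node in internal:
            inside = [m for m in members if tree.is_ancestor(node, m.organism_taxon)]
            if not inside:
                continue
            node_group_id[(fam, node)] = f"OG{fam:03d}@{node}"
    for (fam, node), gid in node_group_id.items():
        # parent group: nearest strict ancestor node that also has a group
        parent_gid = None
        for anc in tree.path_to_root(node)[1:]:
            if (fam, anc) in node_group_id:
                parent_gid = node_group_id[(fam, anc)]
                break
        inside = [m for m in members_by_family[fam] if tree.is_ancestor(node, m.organism_taxon)]
        groups.append(OrthologGroup(gid, node, frozenset(inside), parent_gid))
    hierarchy = OrthologyHierarchy(groups, tree=tree)
    return SyntheticProteomes(proteomes, sequences, hierarchy, family_of)


def emit_fasta(proteins: Sequence[ParsedProtein], dialect: str = "generic", width: int = 60) -> str:
    """Serialize proteins as FASTA in a given header dialect.

    ``uniprot`` and ``generic`` round-trip arbitrary identifiers through
    :func:`funlink.genome.parse_fasta`; ``refseq`` emits the bracketed
    organism convention (ids that are not RefSeq accessions fall back to the
    generic grammar on parsing).
    """
    lines = []
    for p in proteins:
        desc = p.description or "synthetic protein"
        if dialect == "uniprot":
            header = f"sp|{p.protein_id}|{p.protein_id}_SYN {desc}"
            if p.organism_name:
                header += f" OS={p.organism_name}"
            if p.gene_name:
                header += f" GN={p.gene_name}"
        elif dialect == "refseq":
            header = f"{p.protein_id} {desc}"
            if p.organism_name:
                header += f" [{p.organism_name}]"
        elif dialect == "generic":
            header = f"{p.protein_id} {desc}"
        else:
            raise ValueError(f"unknown emission dialect {dialect!r}")
        lines.append(f">{header}")
        for i in range(0, len(p.sequence), width):
            lines.append(p.sequence[i : i + width])
    return "\n".join(lines) + "\n"
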