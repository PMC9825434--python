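"""Core domain types shared by every pipeline stage.

The interacting unit throughout is a protein-coding locus, identified by an
opaque string within one organism.  Association edges are unordered pairs of
distinct loci; all scores are symmetric, so pairs are canonicalized once on
construction and compared by value everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np

__all__ = [
    "ProteinRef",
    "Pair",
    "canonical_pair",
    "SelfPairError",
    "EvidenceRecord",
    "CHANNELS",
    "TaxonomyTree",
    "OrthologGroup",
    "OrthologyHierarchy",
    "GoldStandard",
    "CalibrationCurve",
    "ScoredEdge",
    "GRADES",
]

#: The seven evidence channels scored separately before combination.
CHANNELS = frozenset(
    {
        "experiments",
        "database",
        "textmining",
        "coexpression",
        "neighborhood",
        "fusion",
        "cooccurrence",
    }
)

#: Three-tier per-dataset confidence grades.
GRADES = ("high", "medium", "exploratory")


class SelfPairError(ValueError):
    """Raised when both endpoints of a pair are the same locus."""


@dataclass(frozen=True, order=True)
class ProteinRef:
    """A protein-coding locus in one organism.

    Ordering is by ``(organism_taxon, protein_id)``, which also defines the
    canonical orientation of a :class:`Pair`.  ``display_name`` and
    ``description`` are carried for reporting only and excluded from
    identity/ordering.
    """

    organism_taxon: str
    protein_id: str
    display_name: Optional[str] = field(default=None, compare=False)
    description: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.organism_taxon:
            raise ValueError("organism_taxon must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.organism_taxon, self.protein_id)

    def __str__(self) -> str:  # "taxon.protein" token used in files
        return f"{self.organism_taxon}.{self.protein_id}"


@dataclass(frozen=True, order=True)
class Pair:
    """Unordered pair of distinct loci, stored in canonical orientation.

    Use :func:`canonical_pair` to construct; the constructor trusts its
    arguments to already be ordered.
    """

    a: ProteinRef
    b: ProteinRef

    def __post_init__(self) -> None:
        if self.a.key == self.b.key:
            raise SelfPairError(f"self-pair is invalid: {self.a}")
        if self.a.key > self.b.key:
            raise ValueError("Pair endpoints not in canonical order; use canonical_pair()")

    def __iter__(self) -> Iterator[ProteinRef]:
        yield self.a
        yield self.b

    def other(self, p: ProteinRef) -> ProteinRef:
        if p.key == self.a.key:
            return self.b
        if p.key == self.b.key:
            return self.a
        raise KeyError(f"{p} is not an endpoint of {self}")


def canonical_pair(a: ProteinRef, b: ProteinRef) -> Pair:
    """Return the unordered pair (a, b) in canonical (lexicographic) order.

    Commutative and idempotent; rejects self-pairs.
    """
    if a.key == b.key:
        raise SelfPairError(f"self-pair is invalid: {a}")
    return Pair(a, b) if a.key < b.key else Pair(b, a)


@dataclass(frozen=True)
class EvidenceRecord:
    """One pair observation from one publication, method and source database."""

    pair: Pair
    publication_id: str
    method_term: Optional[str]
    source_db: str
    channel: str = "experiments"
    physical: bool = True

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.channel == "experiments" and not self.method_term:
            raise ValueError("experiments-channel records require a method_term")


class TaxonomyTree:
    """Single-rooted taxonomy used for LCA lookups and scope checks."""

    def __init__(self, parent: Mapping[str, str], root: str):
        self.parent: dict[str, str] = dict(parent)
        self.root = root
        self.nodes: set[str] = set(self.parent) | {root}
        self._validate()
        self._children: dict[str, list[str]] = {}
        for child, par in self.parent.items():
            self._children.setdefault(par, []).append(child)

    def _validate(self) -> None:
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        for child, par in self.parent.items():
            if par not in self.nodes:
                raise ValueError(f"parent {par!r} of {child!r} is not a node")
        # cycle check: every node must reach the root
        for node in self.parent:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle detected through {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "TaxonomyTree":
        """Build from (child, parent) edges; a node with empty parent is the root."""
        parent: dict[str, str] = {}
        root: Optional[str] = None
        nodes: set[str] = set()
        for child, par in edges:
            nodes.add(child)
            if par == "" or par is None:
                if root is not None and root != child:
                    raise ValueError("multiple roots declared")
                root = child
            else:
                nodes.add(par)
                parent[child] = par
        if root is None:
            # infer: the unique node never appearing as a child
            candidates = nodes - set(parent)
            if len(candidates) != 1:
                raise ValueError(f"cannot infer a unique root (candidates: {sorted(candidates)})")
            root = candidates.pop()
        return cls(parent, root)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.nodes

    def _require(self, taxon: str) -> None:
        if taxon not in self.nodes:
            raise KeyError(f"unknown taxon {taxon!r}")

    def path_to_root(self, taxon: str) -> list[str]:
        """Node itself first, root last."""
        self._require(taxon)
        path = [taxon]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def depth(self, taxon: str) -> int:
        return len(self.path_to_root(taxon)) - 1

    def lca(self, x: str, y: str) -> str:
        """Deepest node ancestral to (or equal to) both x and y."""
        self._require(x)
        self._require(y)
        anc_x = set(self.path_to_root(x))
        for node in self.path_to_root(y):
            if node in anc_x:
                return node
        return self.root  # unreachable: root is always shared

    def is_ancestor(self, ancestor: str, node: str) -> bool:
        """True if ``ancestor`` lies on node's path to the root (or equals it)."""
        self._require(ancestor)
        return ancestor in self.path_to_root(node)

    def leaves(self) -> list[str]:
        return sorted(n for n in self.nodes if n not in self._children)

    def children(self, taxon: str) -> list[str]:
        self._require(taxon)
        return sorted(self._children.get(taxon, []))


def lca(tree: TaxonomyTree, x: str, y: str) -> str:
    """Module-level convenience wrapper around :meth:`TaxonomyTree.lca`."""
    return tree.lca(x, y)


@dataclass(frozen=True)
class OrthologGroup:
    """A set of genes descended from one ancestral gene at a taxonomic level."""

    group_id: str
    level: str
    members: frozenset[ProteinRef]
    parent_group: Optional[str] = None


class OrthologyHierarchy:
    """Nested ortholog groups indexed by member protein.

    Groups nest: a group's ``parent_group`` sits at an ancestral (shallower)
    taxonomic level and is a superset in the evolutionary sense, though the
    files list membership explicitly per group.
    """

    def __init__(self, groups: Iterable[OrthologGroup], tree: Optional[TaxonomyTree] = None):
        self.groups: dict[str, OrthologGroup] = {}
        self._by_protein: dict[tuple[str, str], list[str]] = {}
        for g in groups:
            if g.group_id in self.groups:
                raise ValueError(f"duplicate group id {g.group_id!r}")
            self.groups[g.group_id] = g
            for m in g.members:
                self._by_protein.setdefault(m.key, []).append(g.group_id)
        if tree is not None:
            self.validate(tree)

    def validate(self, tree: TaxonomyTree) -> None:
        for g in self.groups.values():
            for m in g.members:
                if not tree.is_ancestor(g.level, m.organism_taxon):
                    raise ValueError(
                        f"group {g.group_id}: level {g.level} is not ancestral to "
                        f"member organism {m.organism_taxon}"
                    )
            if g.parent_group is not None:
                parent = self.groups.get(g.parent_group)
                if parent is None:
                    raise ValueError(f"group {g.group_id}: unknown parent {g.parent_group!r}")
                if not tree.is_ancestor(parent.level, g.level):
                    raise ValueError(
                        f"group {g.group_id}: parent level {parent.level} not ancestral "
                        f"to level {g.level}"
                    )

    def groups_of(self, protein: ProteinRef) -> list[OrthologGroup]:
        return [self.groups[gid] for gid in self._by_protein.get(protein.key, [])]

    def group_at_level(self, protein: ProteinRef, level: str) -> Optional[OrthologGroup]:
        """The protein's group whose level is exactly ``level`` (None if absent)."""
        hits = [g for g in self.groups_of(protein) if g.level == level]
        if not hits:
            return None
        if len(hits) > 1:
            hits.sort(key=lambda g: g.group_id)
        return hits[0]

    def parent_of(self, group: OrthologGroup) -> Optional[OrthologGroup]:
        if group.parent_group is None:
            return None
        return self.groups[group.parent_group]

    def add_group(self, group: OrthologGroup) -> None:
        if group.group_id in self.groups:
            raise ValueError(f"duplicate group id {group.group_id!r}")
        self.groups[group.group_id] = group
        for m in group.members:
            self._by_protein.setdefault(m.key, []).append(group.group_id)


class GoldStandard:
    """Pathway-membership sets used as benchmark truth.

    Sets flagged as excluded (homology-dominated pathways) never contribute
    to truth labels: a protein annotated only in excluded sets counts as
    unannotated.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        excluded_sets: Iterable[str] = (),
    ):
        self.sets: dict[str, frozenset[str]] = {
            pid: frozenset(members) for pid, members in sets.items()
        }
        self.excluded_sets: frozenset[str] = frozenset(excluded_sets)
        self._memberships: dict[str, frozenset[str]] = {}
        acc: dict[str, set[str]] = {}
        for pid, members in self.sets.items():
            if pid in self.excluded_sets:
                continue
            for prot in members:
                acc.setdefault(prot, set()).add(pid)
        self._memberships = {p: frozenset(s) for p, s in acc.items()}

    @property
    def active_sets(self) -> dict[str, frozenset[str]]:
        return {p: m for p, m in self.sets.items() if p not in self.excluded_sets}

    @property
    def annotated(self) -> frozenset[str]:
        """Proteins appearing in at least one non-excluded set."""
        return frozenset(self._memberships)

    def memberships(self, protein_id: str) -> frozenset[str]:
        return self._memberships.get(protein_id, frozenset())

    def co_member(self, p1: str, p2: str) -> bool:
        return bool(self.memberships(p1) & self.memberships(p2))

    def __bool__(self) -> bool:
        return bool(self._memberships)


class CalibrationCurve:
    """Monotone map from raw score to confidence in [0, 1].

    Piecewise-linear between breakpoints; clamped to the first/last
    confidence outside the fitted range.
    """

    def __init__(self, breakpoints, confidences):
        bp = np.asarray(breakpoints, dtype=float)
        cf = np.asarray(confidences, dtype=float)
        if bp.ndim != 1 or bp.shape != cf.shape or bp.size == 0:
            raise ValueError("breakpoints and confidences must be equal-length 1-D, non-empty")
        if np.any(np.diff(bp) < 0):
            raise ValueError("breakpoints must be ascending")
        if np.any(np.diff(cf) < -1e-12):
            raise ValueError("confidences must be non-decreasing")
        if cf.min() < -1e-12 or cf.max() > 1 + 1e-12:
            raise ValueError("confidences must lie in [0, 1]")
        # collapse duplicate x (keep last = upper envelope after isotonic fit)
        self.breakpoints = bp
        self.confidences = np.clip(cf, 0.0, 1.0)

    def __call__(self, raw):
        return np.interp(raw, self.breakpoints, self.confidences)

    def __repr__(self) -> str:
        return f"CalibrationCurve({len(self.breakpoints)} breakpoints)"


@dataclass
class ScoredEdge:
    """One network edge with per-channel and combined confidences."""

    pair: Pair
    channel_scores: dict[str, float] = field(default_factory=dict)
    combined: float = 0.0
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        for ch, s in self.channel_scores.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"channel score out of [0,1]: {ch}={s}")
        if not 0.0 <= self.combined <= 1.0:
            raise ValueError(f"combined score out of [0,1]: {self.combined}")
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
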