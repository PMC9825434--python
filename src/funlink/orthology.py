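"""Interolog transfer of scored associations between organisms.

Orthologs of associated proteins are assumed to be likewise associated.  For
each source edge the ortholog sets of both endpoints in the target organism
are looked up at the taxonomic level of the last common ancestor of the two
organisms.  The transferred score is the source score, damped by a
clade-depth transfer factor and divided by the product of the co-ortholog
counts (a paralogy penalty: many-to-many transfers are ambiguous and each
candidate interolog gets a proportionally smaller share).  Candidates landing
on the same target pair from several source edges are merged by noisy-OR.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .combination import combine_scores
from .model import (
    OrthologyHierarchy,
    Pair,
    ProteinRef,
    ScoredEdge,
    TaxonomyTree,
    canonical_pair,
)

__all__ = ["orthologs_at_level", "transfer_network", "TransferFactors"]


class TransferFactors:
    """Clade-depth -> transfer factor in (0, 1].

    Depth is the distance of the transfer level (the LCA of the two
    organisms) from the taxonomy root; deeper levels mean closer relatives.
    ``strict=True`` raises on a depth with no configured factor; otherwise
    the factor of the closest shallower configured depth applies, defaulting
    to ``default`` when none is configured at all.
    """

    def __init__(self, factors: Mapping[int, float] | None = None, default: float = 1.0, strict: bool = False):
        self.factors = dict(factors or {})
        for d, f in self.factors.items():
            if not 0.0 < f <= 1.0:
                raise ValueError(f"transfer factor at depth {d} out of (0,1]: {f}")
        if not 0.0 < default <= 1.0:
            raise ValueError(f"default transfer factor out of (0,1]: {default}")
        self.default = default
        self.strict = strict

    def __call__(self, depth: int) -> float:
        if depth in self.factors:
            return self.factors[depth]
        if self.strict:
            raise KeyError(f"no transfer factor configured for clade depth {depth}")
        shallower = [d for d in self.factors if d < depth]
        if shallower:
            return self.factors[max(shallower)]
        return self.default


def orthologs_at_level(
    hierarchy: OrthologyHierarchy,
    protein: ProteinRef,
    level: str,
    target_organism: str,
    tree: TaxonomyTree,
) -> frozenset[ProteinRef]:
    """Target-organism members of the protein's ortholog group at ``level``.

    Empty set if the protein has no group at that level.  The level must be
    ancestral to (or equal to) the target organism.
    """
    if not tree.is_ancestor(level, target_organism):
        raise ValueError(f"level {level!r} is not ancestral to target organism {target_organism!r}")
    group = hierarchy.group_at_level(protein, level)
    if group is None:
        return frozenset()
    return frozenset(m for m in group.members if m.organism_taxon == target_organism)


def transfer_network(
    source_edges: Sequence[ScoredEdge],
    hierarchy: OrthologyHierarchy,
    tree: TaxonomyTree,
    target_organism: str,
    transfer_factor: TransferFactors | Mapping[int, float] | None = None,
    allow_self_transfer: bool = False,
) -> list[ScoredEdge]:
    """Transfer a scored network to ``target_organism`` via interologs.

    For a source edge (a, b, s) the transfer level is lca(source organism,
    target organism); every ortholog pair (a', b') at that level receives a
    candidate score s * factor(level depth) / (n_a * n_b), where n_a, n_b
    count the target co-orthologs of a and b.  Candidates on the same target
    pair merge by noisy-OR (prior 0).  Self-pairs are discarded, and edges
    already native to the target organism are skipped unless
    ``allow_self_transfer`` (to avoid double counting on re-transfer).
    Channel scores transfer with the same arithmetic as the combined score.
    """
    if isinstance(transfer_factor, TransferFactors):
        factors = transfer_factor
    else:
        factors = TransferFactors(transfer_factor)
    if target_organism not in tree:
        raise KeyError(f"unknown taxon {target_organism!r}")

    combined_cands: dict[Pair, list[float]] = {}
    channel_cands: dict[Pair, dict[str, list[float]]] = {}
    for edge in source_edges:
        src_org = edge.pair.a.organism_taxon
        if edge.pair.b.organism_taxon != src_org:
            raise ValueError(f"cross-organism source edge not transferable: {edge.pair}")
        if src_org == target_organism and not allow_self_transfer:
            continue
        level = tree.lca(src_org, target_organism)
        factor = factors(tree.depth(level))
        orth_a = orthologs_at_level(hierarchy, edge.pair.a, level, target_organism, tree)
        orth_b = orthologs_at_level(hierarchy, edge.pair.b, level, target_organism, tree)
        if not orth_a or not orth_b:
            continue
        penalty = len(orth_a) * len(orth_b)
        damp = factor / penalty
        for ap in orth_a:
            for bp in orth_b:
                if ap.key == bp.key:
                    continue
                tp = canonical_pair(ap, bp)
                combined_cands.setdefault(tp, []).append(edge.combined * damp)
                ch_map = channel_cands.setdefault(tp, {})
                for ch, s in edge.channel_scores.items():
                    ch_map.setdefault(ch, []).append(s * damp)

    out = []
    for pair in sorted(combined_cands):
        combined = combine_scores(combined_cands[pair], prior=0.0)
        channels = {
            ch: combine_scores(vals, prior=0.0) for ch, vals in sorted(channel_cands[pair].items())
        }
        out.append(ScoredEdge(pair=pair, channel_scores=channels, combined=combined))
    return out
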