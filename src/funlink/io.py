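"""Readers and writers for the plain-text exchange formats.

All formats are TSV or FASTA.  Link files follow the protein-links download
convention: scores are serialized as integers x1000 (round half away from
zero); internal computation stays in full precision.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .experiments import MethodOntology
from .model import (
    EvidenceRecord,
    GoldStandard,
    OrthologGroup,
    OrthologyHierarchy,
    ProteinRef,
    ScoredEdge,
    TaxonomyTree,
    canonical_pair,
)

__all__ = [
    "read_taxonomy",
    "write_taxonomy",
    "read_orthology",
    "write_orthology",
    "read_gold_standard",
    "write_gold_standard",
    "read_evidence",
    "write_evidence",
    "read_mitab",
    "read_ontology",
    "write_ontology",
    "read_scores",
    "read_links",
    "write_links",
    "score_to_int",
]

PathLike = Union[str, Path]


def _lines(path: PathLike) -> list[str]:
    text = Path(path).read_text()
    return [ln.rstrip("\n") for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def score_to_int(score: float) -> int:
    """Serialize a [0,1] score as an integer x1000, half away from zero."""
    return int(math.floor(score * 1000 + 0.5))


def _parse_token(token: str) -> ProteinRef:
    """Parse a "taxon.protein_id" token (first dot splits)."""
    taxon, _, pid = token.partition(".")
    if not pid:
        raise ValueError(f"malformed protein token {token!r} (expected taxon.protein_id)")
    return ProteinRef(taxon, pid)


# -- taxonomy ---------------------------------------------------------------


def read_taxonomy(path: PathLike) -> TaxonomyTree:
    """child <TAB> parent per line; the root has an empty parent field."""
    edges = []
    for ln in _lines(path):
        parts = ln.split("\t")
        child = parts[0]
        parent = parts[1] if len(parts) > 1 else ""
        edges.append((child, parent))
    return TaxonomyTree.from_edges(edges)


def write_taxonomy(tree: TaxonomyTree, path: PathLike) -> None:
    lines = [f"{tree.root}\t"]
    for child in sorted(tree.parent):
        lines.append(f"{child}\t{tree.parent[child]}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- orthology --------------------------------------------------------------


def read_orthology(path: PathLike, tree: Optional[TaxonomyTree] = None) -> OrthologyHierarchy:
    """group_id <TAB> level <TAB> parent_group_or_- <TAB> member tokens (comma-sep)."""
    groups = []
    for ln in _lines(path):
        gid, level, parent, members = ln.split("\t")
        groups.append(
            OrthologGroup(
                group_id=gid,
                level=level,
                parent_group=None if parent == "-" else parent,
                members=frozenset(_parse_token(tok) for tok in members.split(",") if tok),
            )
        )
    return OrthologyHierarchy(groups, tree=tree)


def write_orthology(hierarchy: OrthologyHierarchy, path: PathLike) -> None:
    lines = []
    for gid in sorted(hierarchy.groups):
        g = hierarchy.groups[gid]
        members = ",".join(sorted(str(m) for m in g.members))
        lines.append(f"{g.group_id}\t{g.level}\t{g.parent_group or '-'}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- gold standard ----------------------------------------------------------


def read_gold_standard(path: PathLike, exclusions: Optional[PathLike] = None) -> GoldStandard:
    """pathway_id <TAB> comma-separated protein ids; exclusions one id per line."""
    sets = {}
    for ln in _lines(path):
        pid, members = ln.split("\t")
        sets[pid] = frozenset(m for m in members.split(",") if m)
    excluded: Iterable[str] = ()
    if exclusions is not None:
        excluded = _lines(exclusions)
    return GoldStandard(sets, excluded_sets=excluded)


def write_gold_standard(
    gold: GoldStandard, path: PathLike, exclusions_path: Optional[PathLike] = None
) -> None:
    lines = [f"{pid}\t{','.join(sorted(members))}" for pid, members in sorted(gold.sets.items())]
    Path(path).write_text("\n".join(lines) + "\n")
    if exclusions_path is not None:
        Path(exclusions_path).write_text("\n".join(sorted(gold.excluded_sets)) + ("\n" if gold.excluded_sets else ""))


# -- evidence ---------------------------------------------------------------

_EVIDENCE_HEADER = "idA\tidB\ttaxonA\ttaxonB\tpubmed_id\tmethod_MI_term\tsource_db"


def read_evidence(path: PathLike) -> list[EvidenceRecord]:
    """MITAB-inspired 7-column TSV (see the module docstring of experiments)."""
    records = []
    for ln in _lines(path):
        if ln == _EVIDENCE_HEADER:
            continue
        ida, idb, taxa, taxb, pmid, method, source = ln.split("\t")
        pair = canonical_pair(ProteinRef(taxa, ida), ProteinRef(taxb, idb))
        records.append(
            EvidenceRecord(pair=pair, publication_id=pmid, method_term=method, source_db=source)
        )
    return records


def write_evidence(records: Iterable[EvidenceRecord], path: PathLike) -> None:
    lines = [_EVIDENCE_HEADER]
    for r in records:
        lines.append(
            "\t".join(
                (
                    r.pair.a.protein_id,
                    r.pair.b.protein_id,
                    r.pair.a.organism_taxon,
                    r.pair.b.organism_taxon,
                    r.publication_id,
                    r.method_term or "",
                    r.source_db,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


_MI_RE = re.compile(r"MI:\d{4}")
_PMID_RE = re.compile(r"pubmed:(\d+)")
_TAXID_RE = re.compile(r"taxid:(-?\d+)")


def read_mitab(path: PathLike, source_db: str = "mitab") -> list[EvidenceRecord]:
    """Read genuine PSI-MI TAB 2.x rows onto the evidence model.

    Uses columns 1-2 (interactor ids), 7 (detection method), 9 (publication)
    and 10-11 (interactor taxa).  Identifier namespaces are stripped to the
    accession; rows without a PubMed id or MI method term are skipped.
    """
    records = []
    for ln in _lines(path):
        cols = ln.split("\t")
        if len(cols) < 11 or cols[0].lower().startswith("#id"):
            continue
        ida = cols[0].split(":", 1)[-1]
        idb = cols[1].split(":", 1)[-1]
        method = _MI_RE.search(cols[6])
        pmid = _PMID_RE.search(cols[8])
        taxa = _TAXID_RE.search(cols[9])
        taxb = _TAXID_RE.search(cols[10])
        if not (method and pmid and taxa and taxb):
            continue
        pair = canonical_pair(ProteinRef(taxa.group(1), ida), ProteinRef(taxb.group(1), idb))
        records.append(
            EvidenceRecord(
                pair=pair,
                publication_id=pmid.group(1),
                method_term=method.group(0),
                source_db=source_db,
            )
        )
    return records


# -- method ontology --------------------------------------------------------


def read_ontology(path: PathLike) -> MethodOntology:
    """term <TAB> parent, one edge per line; multiple parents allowed."""
    parents: dict[str, set[str]] = {}
    for ln in _lines(path):
        parts = ln.split("\t")
        term = parts[0]
        parents.setdefault(term, set())
        if len(parts) > 1 and parts[1]:
            parents[term].add(parts[1])
    return MethodOntology(parents)


def write_ontology(ontology: MethodOntology, path: PathLike) -> None:
    lines = []
    for term in sorted(ontology.terms):
        pars = sorted(ontology.parents.get(term, ()))
        if not pars:
            lines.append(f"{term}\t")
        else:
            lines.extend(f"{term}\t{p}" for p in pars)
    Path(path).write_text("\n".join(lines) + "\n")


# -- scores and links -------------------------------------------------------


def read_scores(path: PathLike) -> list[float]:
    """One score per line (first whitespace-delimited field)."""
    return [float(ln.split()[0]) for ln in _lines(path)]


_LINK_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experiments",
    "database",
    "textmining",
)


def write_links(edges: Sequence[ScoredEdge], path: PathLike) -> None:
    """protein-links style TSV: tokens, one int x1000 column per channel, combined."""
    header = ["protein1", "protein2", *_LINK_CHANNELS, "combined_score"]
    lines = ["\t".join(header)]
    for e in sorted(edges, key=lambda e: e.pair):
        row = [str(e.pair.a), str(e.pair.b)]
        row += [str(score_to_int(e.channel_scores.get(ch, 0.0))) for ch in _LINK_CHANNELS]
        row.append(str(score_to_int(e.combined)))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_links(path: PathLike) -> list[ScoredEdge]:
    lines = _lines(path)
    if not lines:
        return []
    header = lines[0].split("\t")
    channels = header[2:-1]
    edges = []
    for ln in lines[1:]:
        cols = ln.split("\t")
        pair = canonical_pair(_parse_token(cols[0]), _parse_token(cols[1]))
        scores = {ch: int(v) / 1000.0 for ch, v in zip(channels, cols[2:-1]) if int(v) > 0}
        edges.append(ScoredEdge(pair=pair, channel_scores=scores, combined=int(cols[-1]) / 1000.0))
    return edges
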