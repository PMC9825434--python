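"""User-proteome pipeline: FASTA ingest, best-hit orthology placement,
consensus functional annotation with taxonomic scope restriction, and
network prediction for the upload.

A submitted proteome is aligned against the reference sequence collection;
each protein is placed into the ortholog-group hierarchy at the level of the
last common ancestor of the user-specified taxon and its best hit's taxon
(falling back to a direct one-to-one ortholog when no group exists there).
Functional terms are then assigned by consensus over the annotated members
of the most specific group, climbing to parent groups until a consensus is
found, and never outside a term's historical taxonomic scope.  Finally the
reference networks are transferred onto the upload through the interolog
machinery.
"""

from __future__ import annotations

import io as _io
import re
import secrets
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Protocol, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .model import (
    OrthologGroup,
    OrthologyHierarchy,
    ProteinRef,
    ScoredEdge,
    TaxonomyTree,
)
from .orthology import TransferFactors, transfer_network

__all__ = [
    "ParsedProtein",
    "BestHit",
    "FunctionalTerm",
    "Placement",
    "parse_fasta",
    "KmerToyAligner",
    "find_best_hits",
    "place_in_hierarchy",
    "annotate_function",
    "predict_upload_network",
    "AMINO_ALPHABET",
]

#: 20 standard residues plus ambiguity/selenocysteine/stop codes.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU*")


@dataclass(frozen=True)
class ParsedProtein:
    """One record of a submitted proteome."""

    protein_id: str
    sequence: str
    gene_name: Optional[str] = None
    description: Optional[str] = None
    organism_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.protein_id!r} contains non-amino-acid characters: "
                f"{''.join(sorted(bad))}"
            )


@dataclass(frozen=True)
class BestHit:
    """Highest-scoring alignment of one query against the reference."""

    query: str
    subject: ProteinRef
    score: float
    identical: bool = False  # exact sequence match (proteome resubmission)


@dataclass(frozen=True)
class FunctionalTerm:
    """A pathway / functional-subsystem term with its annotation history.

    The term's taxonomic scope is the LCA of every organism previously
    annotated with it; the term is never assigned outside that clade.
    """

    term_id: str
    source_catalog: str  # GO-BP | GO-MF | GO-CC | KEGG | keywords | compartments | tissues
    annotated_organisms: frozenset[str]

    def scope(self, tree: TaxonomyTree) -> str:
        orgs = sorted(self.annotated_organisms)
        if not orgs:
            raise ValueError(f"term {self.term_id} has no annotation history")
        node = orgs[0]
        for org in orgs[1:]:
            node = tree.lca(node, org)
        return node


@dataclass(frozen=True)
class Placement:
    """Where a submitted protein lands in the orthology hierarchy."""

    query: str
    level: str
    group_id: Optional[str]  # None => direct one-to-one ortholog
    ortholog: ProteinRef  # the best hit
    direct_identity: bool = False

    @property
    def one_to_one(self) -> bool:
        return self.group_id is None


# ---------------------------------------------------------------------------
# FASTA parsing

_UNIPROT_RE = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|\s]+)\|(?P<entry>\S+)$")
_ENSEMBL_RE = re.compile(r"^ENS[A-Z]*P\d+(?:\.\d+)?$")
_REFSEQ_RE = re.compile(r"^(?:[NXYW]P_\d+(?:\.\d+)?)$")


def _parse_uniprot(first: str, rest: str) -> Optional[dict]:
    m = _UNIPROT_RE.match(first)
    if not m:
        return None
    gene = None
    organism = None
    desc = rest
    gm = re.search(r"\bGN=(\S+)", rest)
    if gm:
        gene = gm.group(1)
    om = re.search(r"\bOS=(.+?)(?=\s+\w\w=|$)", rest)
    if om:
        organism = om.group(1).strip()
    desc = re.split(r"\s+\w\w=", rest)[0].strip() or None
    return {"protein_id": m.group("acc"), "gene_name": gene, "description": desc, "organism_name": organism}


def _parse_ensembl(first: str, rest: str) -> Optional[dict]:
    if not _ENSEMBL_RE.match(first):
        return None
    gene = None
    gm = re.search(r"\bgene_symbol:(\S+)", rest)
    if gm:
        gene = gm.group(1)
    else:
        gm = re.search(r"\bgene:(\S+)", rest)
        if gm:
            gene = gm.group(1)
    dm = re.search(r"\bdescription:(.+)$", rest)
    desc = dm.group(1).strip() if dm else None
    return {"protein_id": first, "gene_name": gene, "description": desc, "organism_name": None}


def _parse_refseq(first: str, rest: str) -> Optional[dict]:
    if not _REFSEQ_RE.match(first):
        return None
    organism = None
    desc = rest or None
    om = re.search(r"\[([^\]]+)\]\s*$", rest)
    if om:
        organism = om.group(1)
        desc = rest[: om.start()].strip() or None
    return {"protein_id": first, "gene_name": None, "description": desc, "organism_name": organism}


def _parse_generic(first: str, rest: str) -> dict:
    return {"protein_id": first, "gene_name": None, "description": rest or None, "organism_name": None}


_DIALECTS = {
    "uniprot": _parse_uniprot,
    "ensembl": _parse_ensembl,
    "refseq": _parse_refseq,
    "generic": _parse_generic,
}


def _parse_header(header: str, dialect: str) -> dict:
    parts = header.split(None, 1)
    first = parts[0] if parts else ""
    rest = parts[1].strip() if len(parts) > 1 else ""
    if dialect == "auto":
        for name in ("uniprot", "ensembl", "refseq"):
            fields = _DIALECTS[name](first, rest)
            if fields is not None:
                return fields
        return _parse_generic(first, rest)
    fields = _DIALECTS[dialect](first, rest)
    if fields is None:
        return _parse_generic(first, rest)
    return fields


def parse_fasta(
    source: Union[str, TextIO],
    dialect: str = "auto",
) -> list[ParsedProtein]:
    """Parse a FASTA proteome, recognizing common header dialects.

    ``dialect`` is one of auto / uniprot / ensembl / refseq / generic;
    under ``auto`` each record's header is matched against the UniProt
    (``db|ACC|ENTRY`` with ``GN=`` / ``OS=`` fields), Ensembl (``ENS*P``
    accession with ``gene:`` / ``gene_symbol:`` fields) and RefSeq
    (versioned accession with bracketed organism) grammars, falling back to
    the generic first-token-as-id convention.

    Duplicate identifiers, empty sequences and non-amino-acid characters
    are hard errors.
    """
    if dialect not in ("auto", *_DIALECTS):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(source, str) and "\n" in source:
        handle: TextIO = _io.StringIO(source)
    else:
        handle = source  # path or open handle; SeqIO accepts both
    proteins = []
    for record in SeqIO.parse(handle, "fasta"):
        fields = _parse_header(record.description, dialect)
        proteins.append(ParsedProtein(sequence=str(record.seq).upper(), **fields))
    if not proteins:
        raise ValueError("no FASTA records found")
    seen: dict[str, int] = {}
    for p in proteins:
        seen[p.protein_id] = seen.get(p.protein_id, 0) + 1
    dups = sorted(pid for pid, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate sequence identifiers: {', '.join(dups)}")
    return proteins


# ---------------------------------------------------------------------------
# Alignment (pluggable contract)


class Aligner(Protocol):
    """Search contract: align one query against a reference collection.

    Returns (subject_id, score) for every reference passing the aligner's
    internal reporting threshold; an empty list means no hit.
    """

    def search(self, query: str, reference: Mapping[str, str]) -> list[tuple[str, float]]: ...


class KmerToyAligner:
    """Built-in exact k-mer prefiltered Smith-Waterman search.

    A deliberately small, dependency-free stand-in for a production
    translated-search tool: candidate subjects must share at least one
    exact k-mer with the query, and candidates are then scored by local
    alignment under BLOSUM62 with affine gaps.  Suitable for toy-scale
    reference collections only.
    """

    def __init__(self, k: int = 4, min_score: float = 40.0):
        self.k = k
        self.min_score = min_score
        self._aligner = PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = -11
        self._aligner.extend_gap_score = -1

    def _kmers(self, seq: str) -> set[str]:
        k = self.k
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    def search(self, query: str, reference: Mapping[str, str]) -> list[tuple[str, float]]:
        qk = self._kmers(query)
        safe_q = re.sub(r"[^ACDEFGHIKLMNPQRSTVWYXBZ]", "X", query)
        hits = []
        for sid, seq in reference.items():
            if not (qk & self._kmers(seq)):
                continue
            safe_s = re.sub(r"[^ACDEFGHIKLMNPQRSTVWYXBZ]", "X", seq)
            score = float(self._aligner.score(safe_q, safe_s))
            if score >= self.min_score:
                hits.append((sid, score))
        return hits


def find_best_hits(
    queries: Sequence[ParsedProtein],
    reference: Mapping[ProteinRef, str],
    aligner: Optional[Aligner] = None,
) -> tuple[dict[str, BestHit], list[str]]:
    """Best reference hit per query; queries without a hit are unplaced.

    Ties on score break lexicographically by subject id.  Returns
    (hits keyed by query id, list of unplaced query ids).
    """
    if not reference:
        raise ValueError("reference sequence collection is empty")
    if aligner is None:
        aligner = KmerToyAligner()
    by_id = {str(ref): seq for ref, seq in reference.items()}
    refs = {str(ref): ref for ref in reference}
    hits: dict[str, BestHit] = {}
    unplaced: list[str] = []
    for q in queries:
        try:
            found = aligner.search(q.sequence, by_id)
        except Exception as exc:  # aligner failures carry query context
            raise RuntimeError(f"aligner failed on query {q.protein_id!r}") from exc
        if not found:
            unplaced.append(q.protein_id)
            continue
        sid, score = min(found, key=lambda t: (-t[1], t[0]))
        subject = refs[sid]
        hits[q.protein_id] = BestHit(
            query=q.protein_id,
            subject=subject,
            score=score,
            identical=(by_id[sid] == q.sequence),
        )
    return hits, unplaced


# ---------------------------------------------------------------------------
# Placement and annotation


def place_in_hierarchy(
    hit: BestHit,
    user_taxon: str,
    tree: TaxonomyTree,
    hierarchy: OrthologyHierarchy,
) -> Placement:
    """Place a protein in the group hierarchy via its best hit.

    The placement level is the LCA of the user-specified taxon and the best
    hit's taxon; the protein joins the hit's group at that level, or becomes
    a direct one-to-one ortholog of the hit when no such group exists.  An
    identical sequence in a matching proteome maps directly to its hit.
    """
    org = hit.subject.organism_taxon
    if org not in tree:
        raise KeyError(f"unknown taxon {org!r} (best hit {hit.subject})")
    if user_taxon not in tree:
        raise KeyError(f"unknown taxon {user_taxon!r}")
    level = tree.lca(user_taxon, org)
    if hit.identical and org == user_taxon:
        return Placement(hit.query, level, None, hit.subject, direct_identity=True)
    group = hierarchy.group_at_level(hit.subject, level)
    if group is None:
        return Placement(hit.query, level, None, hit.subject)
    return Placement(hit.query, level, group.group_id, hit.subject)


def annotate_function(
    placement: Optional[Placement],
    hierarchy: OrthologyHierarchy,
    terms: Mapping[str, FunctionalTerm],
    member_annotations: Mapping[tuple[str, str], Iterable[str]],
    user_taxon: str,
    tree: TaxonomyTree,
    consensus_fraction: float = 0.5,
) -> set[str]:
    """Consensus functional annotation of one placed protein.

    At the most specific group, candidate terms are those carried by at
    least ``consensus_fraction`` of the group's annotated pre-existing
    members (members without any annotation do not enter the denominator).
    If no member carries any annotation the consensus climbs to the parent
    group, stopping at the hierarchy root.  Every candidate is discarded
    unless the user taxon lies inside the term's taxonomic scope.
    ``member_annotations`` maps (organism_taxon, protein_id) -> term ids.
    An unplaced protein (None) gets an empty annotation set.
    """
    if not 0.0 < consensus_fraction <= 1.0:
        raise ValueError("consensus_fraction must be in (0, 1]")
    if placement is None:
        return set()

    def consensus_over(members: Iterable[ProteinRef]) -> Optional[set[str]]:
        counts: dict[str, int] = {}
        annotated = 0
        for m in members:
            tids = set(member_annotations.get(m.key, ()))
            if not tids:
                continue
            annotated += 1
            for t in tids:
                counts[t] = counts.get(t, 0) + 1
        if annotated == 0:
            return None
        return {t for t, c in counts.items() if c / annotated >= consensus_fraction}

    if placement.one_to_one:
        candidates = consensus_over([placement.ortholog]) or set()
    else:
        group = hierarchy.groups[placement.group_id]
        candidates = None
        while group is not None:
            candidates = consensus_over(group.members)
            if candidates is not None:
                break
            group = hierarchy.parent_of(group)
        if candidates is None:
            candidates = set()

    assigned = set()
    for tid in candidates:
        term = terms.get(tid)
        if term is None:
            continue
        if tree.is_ancestor(term.scope(tree), user_taxon):
            assigned.add(tid)
    return assigned


# ---------------------------------------------------------------------------
# Network prediction for the upload


def _placement_hierarchy(
    placements: Iterable[Placement],
    hierarchy: OrthologyHierarchy,
    upload_taxon: str,
) -> OrthologyHierarchy:
    """Build the orthology mapping implied by the placements.

    Only placement-derived groups enter: a group placement contributes its
    reference group augmented with the submitted protein; a one-to-one
    placement contributes a private two-member group at the placement level.
    Restricting to these groups keeps the interolog lookup unambiguous — in
    particular a resubmitted reference proteome maps one-to-one onto itself
    rather than through whole species-level families.
    """
    extra_members: dict[str, set[ProteinRef]] = {}
    private: list[OrthologGroup] = []
    for pl in placements:
        query_ref = ProteinRef(upload_taxon, pl.query)
        if pl.one_to_one:
            private.append(
                OrthologGroup(
                    group_id=f"__1to1__{pl.query}",
                    level=pl.level,
                    members=frozenset({pl.ortholog, query_ref}),
                )
            )
        else:
            extra_members.setdefault(pl.group_id, set()).add(query_ref)
    groups = list(private)
    for gid, extra in extra_members.items():
        g = hierarchy.groups[gid]
        groups.append(OrthologGroup(g.group_id, g.level, g.members | frozenset(extra)))
    return OrthologyHierarchy(groups)


def predict_upload_network(
    placements: Sequence[Placement],
    source_edges: Sequence[ScoredEdge],
    hierarchy: OrthologyHierarchy,
    tree: TaxonomyTree,
    user_taxon: str,
    transfer_factor: Optional[TransferFactors] = None,
    rng=None,
    existing_ids: Iterable[str] = (),
) -> tuple[list[ScoredEdge], str]:
    """Predict the upload's network by interolog transfer through placements.

    Returns (edges over the submitted protein ids, submission identifier).
    The identifier is an opaque random token, collision-checked against
    ``existing_ids``.  With no placements an empty network is returned with
    a warning.
    """
    taken = set(existing_ids)
    while True:
        token = secrets.token_hex(6) if rng is None else "".join(
            "0123456789abcdef"[rng.integers(0, 16)] for _ in range(12)
        )
        submission_id = f"FLNK{token}"
        if submission_id not in taken:
            break
    if not placements:
        warnings.warn("no placed proteins; predicted network is empty")
        return [], submission_id
    aug = _placement_hierarchy(placements, hierarchy, user_taxon)
    edges = transfer_network(
        source_edges,
        aug,
        tree,
        target_organism=user_taxon,
        transfer_factor=transfer_factor,
        allow_self_transfer=True,
    )
    # keep only edges between submitted proteins
    submitted = {ProteinRef(user_taxon, pl.query).key for pl in placements}
    edges = [e for e in edges if e.pair.a.key in submitted and e.pair.b.key in submitted]
    return edges, submission_id
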