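import numpy as np
import pytest

from funlink.genome import (
    BestHit,
    FunctionalTerm,
    KmerToyAligner,
    annotate_function,
    find_best_hits,
    parse_fasta,
    place_in_hierarchy,
    predict_upload_network,
)
from funlink.model import (
    OrthologGroup,
    OrthologyHierarchy,
    ProteinRef,
    ScoredEdge,
    TaxonomyTree,
    canonical_pair,
)
from funlink.synthetic import emit_fasta, make_proteomes, make_taxonomy


def ref(taxon, pid):
    return ProteinRef(taxon, pid)


class TestParseFasta:
    def test_uniprot_dialect(self):
        text = ">sp|P12345|NAME_HUMAN Some protein OS=Homo sapiens GN=ABC1\nMKV\n"
        (p,) = parse_fasta(text)
        assert p.protein_id == "P12345"
        assert p.gene_name == "ABC1"
        assert p.organism_name == "Homo sapiens"
        assert p.description == "Some protein"

    def test_ensembl_dialect(self):
        text = ">ENSP00000354587.2 pep gene:ENSG00000142192 gene_symbol:APP description:amyloid precursor\nMLPGLALLL\n"
        (p,) = parse_fasta(text)
        assert p.protein_id == "ENSP00000354587.2"
        assert p.gene_name == "APP"
        assert "amyloid" in p.description

    def test_refseq_dialect(self):
        text = ">NP_000477.1 serum albumin preproprotein [Homo sapiens]\nMKWVTFISLLFLFSSAYS\n"
        (p,) = parse_fasta(text)
        assert p.protein_id == "NP_000477.1"
        assert p.organism_name == "Homo sapiens"
        assert p.description == "serum albumin preproprotein"

    def test_generic_fallback(self):
        (p,) = parse_fasta(">prot1 hypothetical protein\nMGG\n")
        assert p.protein_id == "prot1"
        assert p.description == "hypothetical protein"

    def test_duplicate_ids_hard_error(self):
        text = ">p1 first\nMA\n>p1 second\nMG\n"
        with pytest.raises(ValueError, match="p1"):
            parse_fasta(text)

    def test_bad_residues_named(self):
        with pytest.raises(ValueError, match="prot1"):
            parse_fasta(">prot1\nMKV123\n")

    def test_sequences_lossless_and_wrapped(self):
        seq = "MKVLAT" * 30
        text = emit_fasta(
            parse_fasta(f">p1 test\n{seq}\n"), dialect="generic", width=60
        )
        (p,) = parse_fasta(text)
        assert p.sequence == seq

    @pytest.mark.parametrize("dialect", ["uniprot", "generic"])
    def test_emit_parse_round_trip(self, dialect):
        tree = make_taxonomy(2, 1, seed=4)
        prots = make_proteomes(tree, 3, paralog_rate=0.0, seq_length=40, seed=4)
        sp = tree.leaves()[0]
        out = parse_fasta(emit_fasta(prots.proteomes[sp], dialect=dialect))
        assert [p.protein_id for p in out] == [p.protein_id for p in prots.proteomes[sp]]
        assert [p.sequence for p in out] == [p.sequence for p in prots.proteomes[sp]]


class TestFindBestHits:
    def test_identical_sequence_is_best_hit(self):
        tree = make_taxonomy(3, 2, seed=1)
        prots = make_proteomes(tree, 4, paralog_rate=0.0, seq_length=50, seed=1)
        reference = prots.reference_collection()
        sp = tree.leaves()[0]
        queries = prots.proteomes[sp]
        hits, unplaced = find_best_hits(queries, reference)
        assert not unplaced
        for q in queries:
            assert hits[q.protein_id].subject == ref(sp, q.protein_id)
            assert hits[q.protein_id].identical

    def test_best_hit_recovers_family(self):
        tree = make_taxonomy(4, 2, seed=2)
        prots = make_proteomes(tree, 5, paralog_rate=0.0, seq_length=60, seed=2)
        species = tree.leaves()
        query_sp = species[0]
        # reference excludes the query species: hits must be family members elsewhere
        reference = {
            r: s for r, s in prots.sequences.items() if r.organism_taxon != query_sp
        }
        queries = prots.proteomes[query_sp]
        hits, unplaced = find_best_hits(queries, reference)
        assert not unplaced
        for q in queries:
            qref = ref(query_sp, q.protein_id)
            assert prots.family_of[hits[q.protein_id].subject] == prots.family_of[qref]

    def test_no_hit_is_unplaced(self):
        queries = parse_fasta(">q1 query\n" + "W" * 40 + "\n")
        reference = {ref("A", "r1"): "MKVLATGHH" * 5}
        hits, unplaced = find_best_hits(queries, reference, aligner=KmerToyAligner(min_score=30))
        assert unplaced == ["q1"]

    def test_tie_breaks_lexicographically(self):
        seq = "MKVLATGHHA" * 5
        queries = parse_fasta(f">q1 query\n{seq}\n")
        reference = {ref("A", "r2"): seq, ref("A", "r1"): seq}
        hits, _ = find_best_hits(queries, reference)
        assert hits["q1"].subject.protein_id == "r1"

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            find_best_hits([], {})


class TestPlacement:
    @pytest.fixture
    def setting(self):
        tree = TaxonomyTree({"A": "X", "B": "X", "C": "R", "X": "R"}, "R")
        hier = OrthologyHierarchy(
            [
                OrthologGroup("ogX", "X", frozenset({ref("B", "b1")})),
                OrthologGroup("ogR", "R", frozenset({ref("B", "b1"), ref("C", "c1")}), None),
            ],
            tree=tree,
        )
        return tree, hier

    def test_group_placement_at_lca(self, setting):
        tree, hier = setting
        hit = BestHit("q1", ref("B", "b1"), 100.0)
        pl = place_in_hierarchy(hit, "A", tree, hier)
        assert pl.level == "X" and pl.group_id == "ogX"

    def test_fallback_one_to_one(self, setting):
        tree, hier = setting
        hit = BestHit("q1", ref("C", "c1"), 80.0)
        pl = place_in_hierarchy(hit, "A", tree, hier)
        # c1 has no group at level R? it has ogR; move hit to a groupless protein
        hit2 = BestHit("q2", ref("C", "c2"), 80.0)
        pl2 = place_in_hierarchy(hit2, "A", tree, hier)
        assert pl.group_id == "ogR"
        assert pl2.one_to_one and pl2.ortholog == ref("C", "c2")

    def test_level_is_ancestor_of_both(self, setting):
        tree, hier = setting
        for user_taxon, hit_taxon in [("A", "B"), ("A", "C"), ("C", "B")]:
            pl = place_in_hierarchy(BestHit("q", ref(hit_taxon, "z"), 1.0), user_taxon, tree, hier)
            assert tree.is_ancestor(pl.level, user_taxon)
            assert tree.is_ancestor(pl.level, hit_taxon)

    def test_resubmission_maps_directly(self, setting):
        tree, hier = setting
        hit = BestHit("b1", ref("B", "b1"), 200.0, identical=True)
        pl = place_in_hierarchy(hit, "B", tree, hier)
        assert pl.direct_identity and pl.one_to_one

    def test_unknown_hit_taxon_errors(self, setting):
        tree, hier = setting
        with pytest.raises(KeyError):
            place_in_hierarchy(BestHit("q", ref("Z", "z1"), 1.0), "A", tree, hier)


class TestAnnotateFunction:
    @pytest.fixture
    def setting(self):
        tree = TaxonomyTree({"A": "X", "B": "X", "C": "R", "X": "R"}, "R")
        members_x = frozenset({ref("B", f"b{i}") for i in range(4)})
        hier = OrthologyHierarchy(
            [
                OrthologGroup("ogX", "X", members_x, "ogR"),
                OrthologGroup("ogR", "R", members_x | {ref("C", "c1")}, None),
            ],
            tree=tree,
        )
        terms = {
            "T1": FunctionalTerm("T1", "KEGG", frozenset({"B", "C"})),  # scope R
            "T2": FunctionalTerm("T2", "GO-BP", frozenset({"B"})),  # scope B
            "T3": FunctionalTerm("T3", "KEGG", frozenset({"C"})),  # scope C
        }
        return tree, hier, terms

    def test_consensus_threshold(self, setting):
        tree, hier, terms = setting
        ann = {("B", f"b{i}"): {"T1"} for i in range(3)}
        ann[("B", "b3")] = {"T2"}
        from funlink.genome import Placement

        pl = Placement("q1", "X", "ogX", ref("B", "b0"))
        out = annotate_function(pl, hier, terms, ann, "A", tree, consensus_fraction=0.5)
        assert "T1" in out  # 3 of 4 annotated members
        assert "T2" not in out  # 1 of 4, below threshold (and out of scope anyway)

    def test_parent_fallback_when_group_unannotated(self, setting):
        tree, hier, terms = setting
        ann = {("C", "c1"): {"T1"}}  # only the parent-level member is annotated
        from funlink.genome import Placement

        pl = Placement("q1", "X", "ogX", ref("B", "b0"))
        out = annotate_function(pl, hier, terms, ann, "A", tree)
        assert out == {"T1"}

    def test_scope_restriction(self, setting):
        tree, hier, terms = setting
        # unanimous consensus on T3, but T3's scope is the clade C only
        ann = {("B", f"b{i}"): {"T3"} for i in range(4)}
        from funlink.genome import Placement

        pl = Placement("q1", "X", "ogX", ref("B", "b0"))
        assert annotate_function(pl, hier, terms, ann, "A", tree) == set()

    def test_unplaced_protein_empty(self, setting):
        tree, hier, terms = setting
        assert annotate_function(None, hier, terms, {}, "A", tree) == set()

    @pytest.mark.parametrize("seed", range(100))
    def test_scope_never_violated_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        tree = make_taxonomy(int(rng.integers(3, 8)), 3, seed=seed)
        species = tree.leaves()
        prots = make_proteomes(tree, 3, paralog_rate=0.2, seq_length=20, seed=seed)
        # random terms with random annotation histories
        terms = {}
        ann = {}
        for t in range(5):
            orgs = rng.choice(species, size=int(rng.integers(1, len(species) + 1)), replace=False)
            terms[f"T{t}"] = FunctionalTerm(f"T{t}", "KEGG", frozenset(orgs))
            for r in prots.sequences:
                if rng.random() < 0.3:
                    ann.setdefault(r.key, set()).add(f"T{t}")
        user_taxon = species[int(rng.integers(0, len(species)))]
        hit_org = species[int(rng.integers(0, len(species)))]
        hit_prot = next(r for r in prots.sequences if r.organism_taxon == hit_org)
        from funlink.genome import place_in_hierarchy

        pl = place_in_hierarchy(BestHit("q", hit_prot, 50.0), user_taxon, tree, prots.hierarchy)
        out = annotate_function(pl, prots.hierarchy, terms, ann, user_taxon, tree)
        for tid in out:
            assert tree.is_ancestor(terms[tid].scope(tree), user_taxon)


class TestPredictUploadNetwork:
    def _reference_world(self, seed=3):
        tree = make_taxonomy(3, 2, seed=seed)
        prots = make_proteomes(tree, 5, paralog_rate=0.0, seq_length=50, seed=seed)
        sp = tree.leaves()[0]
        own = sorted(
            (r for r in prots.sequences if r.organism_taxon == sp), key=lambda r: r.protein_id
        )
        edges = [
            ScoredEdge(pair=canonical_pair(own[i], own[i + 1]), combined=0.4 + 0.1 * i)
            for i in range(len(own) - 1)
        ]
        return tree, prots, sp, edges

    def test_resubmission_identity_round_trip(self):
        tree, prots, sp, edges = self._reference_world()
        queries = prots.proteomes[sp]
        hits, _ = find_best_hits(queries, prots.reference_collection())
        placements = [place_in_hierarchy(h, sp, tree, prots.hierarchy) for h in hits.values()]
        rng = np.random.default_rng(0)
        net, sub_id = predict_upload_network(placements, edges, prots.hierarchy, tree, sp, rng=rng)
        assert sub_id.startswith("FLNK")
        assert {e.pair for e in net} == {e.pair for e in edges}
        expected = {e.pair: e.combined for e in edges}
        for e in net:
            assert e.combined == pytest.approx(expected[e.pair])

    def test_zero_placements_empty_network(self):
        tree, prots, sp, edges = self._reference_world()
        with pytest.warns(UserWarning):
            net, _ = predict_upload_network([], edges, prots.hierarchy, tree, sp)
        assert net == []

    def test_sister_species_transfer_bounded(self):
        tree, prots, sp, edges = self._reference_world()
        other = tree.leaves()[1]
        queries = prots.proteomes[other]
        reference = {
            r: s for r, s in prots.sequences.items() if r.organism_taxon != other
        }
        hits, _ = find_best_hits(queries, reference)
        placements = [place_in_hierarchy(h, other, tree, prots.hierarchy) for h in hits.values()]
        net, _ = predict_upload_network(placements, edges, prots.hierarchy, tree, other)
        assert len(net) <= len(edges)
        for e in net:
            assert e.pair.a.organism_taxon == other
            assert e.combined <= max(x.combined for x in edges) + 1e-12
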