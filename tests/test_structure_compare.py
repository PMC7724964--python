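"""Interface mapping and peptide similarity against complex structures."""

import itertools

import gemmi
import numpy as np
import pytest

import prmprofiler as pp
from prmprofiler.errors import FormatError
from prmprofiler.structure_compare import SIMILARITY_GROUPS, align_registers_identity

AA3 = {
    "A": "ALA", "G": "GLY", "S": "SER", "W": "TRP", "D": "ASP",
    "K": "LYS", "L": "LEU", "P": "PRO", "T": "THR", "E": "GLU",
}


def build_structure(chains):
    """Toy structure: chains given as (name, sequence-or-resname-list).

    Residues are spaced 10 A apart per chain, chains 50 A apart, so nothing
    is in contact; only chain composition matters for these tests.
    """
    st = gemmi.Structure()
    st.name = "TOY"
    model = gemmi.Model("1")
    for ci, (name, residues) in enumerate(chains):
        chain = gemmi.Chain(name)
        for ri, res3 in enumerate(residues):
            res = gemmi.Residue()
            res.name = AA3.get(res3, res3)
            res.seqid = gemmi.SeqId(ri + 1, " ")
            for aname, elem, dx in (("N", "N", -1.2), ("CA", "C", 0.0), ("C", "C", 1.2)):
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(elem)
                atom.pos = gemmi.Position(10.0 * ri + dx, 50.0 * ci, 0.0)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


class TestSimilarityGroups:
    def test_every_residue_covered(self):
        covered = set().union(*SIMILARITY_GROUPS.values())
        assert covered == set(pp.ALPHABET_20)

    def test_symmetric_and_reflexive(self):
        for a, b in itertools.product(pp.ALPHABET_20, repeat=2):
            assert pp.similar(a, b) == pp.similar(b, a)
        assert all(pp.similar(a, a) for a in pp.ALPHABET_20)


class TestPercentSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("WPF", "FPY", 100.0),  # aromatic, Pro, aromatic
            ("WAD", "WAD", 100.0),
            ("WAD", "DWA", 0.0),    # no pair shares a group at this register
        ],
    )
    def test_examples(self, a, b, expected):
        assert pp.percent_similarity(a, b) == expected

    def test_ptm_positions_excluded(self):
        assert pp.percent_similarity("WSD", "WAD", ptm_positions=[1]) == 100.0

    def test_all_positions_masked_is_missing(self):
        assert pp.percent_similarity("WAD", "WAD", mask=[]) is None

    def test_similarity_dominates_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = "".join(rng.choice(list(pp.ALPHABET_20), 8))
            b = "".join(rng.choice(list(pp.ALPHABET_20), 8))
            assert pp.percent_similarity(a, b) >= pp.percent_identity(a, b)


class TestPercentIdentity:
    def test_examples(self):
        assert pp.percent_identity("WAPTAP", "WAPTAP") == 100.0
        assert pp.percent_identity("W" * 9 + "A", "W" * 10) == 90.0
        assert pp.percent_identity("WADKLM", "WADAAA", mask=range(6)) == 50.0


class TestAlignPeptides:
    def test_identical_peptides_align_at_zero(self):
        aln = pp.align_peptides("WAPTAP", "WAPTAP")
        assert aln.offset == 0 and aln.similarity == 100.0

    def test_motif_register_with_masked_similarity(self):
        aln = pp.align_peptides("GPTAPG", "APTAPA")
        assert aln.offset == 0
        # over the shared-motif positions the peptides are fully similar
        assert pp.percent_similarity("GPTAPG", "APTAPA", mask=range(1, 5)) == 100.0

    def test_disjoint_composition_reports_zero(self):
        aln = pp.align_peptides("WWWW", "DDDD")
        assert aln.similarity == 0.0

    def test_brute_force_register_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = "".join(rng.choice(list(pp.ALPHABET_20), rng.integers(3, 9)))
            b = "".join(rng.choice(list(pp.ALPHABET_20), rng.integers(3, 9)))
            got = pp.align_peptides(a, b)
            best = -1.0
            for off in range(-len(b) + 3, len(a) - 2):
                s0, s1 = max(0, off), min(len(a), len(b) + off)
                if s1 - s0 < 3:
                    continue
                hits = sum(
                    1 for s in range(s0, s1) if pp.similar(a[s], b[s - off])
                )
                best = max(best, 100.0 * hits / (s1 - s0))
            assert got.similarity == pytest.approx(best)


class TestExtractCandidatePairs:
    def test_prm_and_short_chain_pairing(self):
        query = "W" * 60 + "D" * 60
        st = build_structure([("A", query), ("B", "WADKLWAD")])
        pairs = pp.extract_candidate_pairs(st, query)
        assert len(pairs) == 1
        assert (pairs[0].prm_chain, pairs[0].peptide_chain) == ("A", "B")

    def test_chain_beyond_30_residues_not_a_peptide(self):
        query = "W" * 60 + "D" * 60
        st = build_structure(
            [("A", query), ("B", "WADKLWAD"), ("C", "K" * 31)]
        )
        pairs = pp.extract_candidate_pairs(st, query)
        assert len(pairs) == 1  # the 31-mer is neither peptide nor PRM-like

    def test_modified_residue_flagged_as_ptm(self):
        query = "W" * 60 + "D" * 60
        st = build_structure([("A", query), ("B", ["TRP", "ALA", "SEP", "ASP", "LYS"])])
        (pair,) = pp.extract_candidate_pairs(st, query)
        assert pair.peptide_seq == "WASDK"  # phosphoserine mapped to Ser
        assert pair.ptm_positions == frozenset({2})

    def test_no_short_chain_yields_empty(self):
        query = "W" * 60
        st = build_structure([("A", query), ("B", "K" * 40)])
        assert pp.extract_candidate_pairs(st, query) == []

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("not a structure\n")
        with pytest.raises(FormatError):
            pp.extract_candidate_pairs(bad, "WAD")


class TestContactMap:
    def test_planted_contacts_recovered_exactly(self, toy_complex):
        pair = pp.extract_candidate_pairs(
            toy_complex.pdb_string, toy_complex.prm_sequence
        )[0]
        assert pp.contact_map(pair, cutoff=5.0) == toy_complex.contacts

    def test_tight_cutoff_empties_map(self, toy_complex):
        pair = pp.extract_candidate_pairs(
            toy_complex.pdb_string, toy_complex.prm_sequence
        )[0]
        assert pp.contact_map(pair, cutoff=3.0) == frozenset()

    def test_monotone_in_cutoff(self, toy_complex):
        pair = pp.extract_candidate_pairs(
            toy_complex.pdb_string, toy_complex.prm_sequence
        )[0]
        c4 = pp.contact_map(pair, cutoff=4.0)
        c5 = pp.contact_map(pair, cutoff=5.0)
        assert c4 <= c5

    def test_gly_contact_uses_calpha_surrogate(self, default_spec, toy_complex):
        gly = set(default_spec.complex_geometry.gly_positions)
        contact_peps = {j for _, j in toy_complex.contacts}
        assert gly & contact_peps  # the fixture plants a Gly contact
        pair = pp.extract_candidate_pairs(
            toy_complex.pdb_string, toy_complex.prm_sequence
        )[0]
        got = pp.contact_map(pair, cutoff=5.0)
        assert all(j in {j2 for _, j2 in got} for j in gly & contact_peps)


class TestSelectBestMatch:
    def cand(self, pdb_id, sim, full_id, iface_id=None):
        return pp.StructurePair(
            pdb_id=pdb_id, prm_chain="A", peptide_chain="B",
            prm_seq="W" * 40, peptide_seq="WADKL",
            scores={
                "peptide_similarity": sim,
                "full_identity": full_id,
                "interface_identity": iface_id,
            },
        )

    def test_highest_similarity_wins(self):
        best = pp.select_best_match(
            [self.cand("1AAA", 90, 40), self.cand("2BBB", 80, 95)]
        )
        assert best.pdb_id == "1AAA"

    def test_similarity_tie_breaks_by_identity(self):
        best = pp.select_best_match(
            [self.cand("1AAA", 85, 96), self.cand("2BBB", 85, 50)]
        )
        assert best.pdb_id == "1AAA"

    def test_identity_floor_excludes_all(self):
        assert pp.select_best_match(
            [self.cand("1AAA", 99, 8), self.cand("2BBB", 99, 10)]
        ) is None

    def test_input_order_invariant(self):
        cands = [self.cand("1AAA", 85, 96), self.cand("2BBB", 85, 50),
                 self.cand("3CCC", 90, 40)]
        import itertools as it
        picks = {
            pp.select_best_match(list(perm)).pdb_id
            for perm in it.permutations(cands)
        }
        assert picks == {"3CCC"}


class TestScoreAndBreakdown:
    def test_toy_complex_scores_perfectly_against_itself(self, toy_complex):
        pair = pp.extract_candidate_pairs(
            toy_complex.pdb_string, toy_complex.prm_sequence
        )[0]
        pair = pp.score_candidate(
            pair, [toy_complex.peptide_sequence], toy_complex.prm_sequence
        )
        assert pair.scores["full_identity"] == 100.0
        assert pair.scores["interface_identity"] == 100.0
        assert pair.scores["peptide_similarity"] == 100.0
        bd = pp.similarity_breakdown(pair)
        assert bd["contact"] == 100.0

    def test_breakdown_separates_contact_from_non_contact(self, toy_complex):
        pair = pp.extract_candidate_pairs(
            toy_complex.pdb_string, toy_complex.prm_sequence
        )[0]
        pp.contact_map(pair)
        # phage peptide similar only at contact positions, dissimilar elsewhere
        contact_peps = sorted({j for _, j in pair.contacts})
        probe = []
        for j, aa in enumerate(pair.peptide_seq):
            if j in contact_peps:
                probe.append(aa)
            else:
                probe.append("D" if aa not in "DENQ" else "W")
        probe = "".join(probe)
        pair = pp.score_candidate(pair, [probe], toy_complex.prm_sequence)
        bd = pp.similarity_breakdown(pair)
        assert bd["contact"] == 100.0
        assert bd["non_contact"] < 100.0

    def test_masks_partition_the_register(self, toy_complex):
        pair = pp.extract_candidate_pairs(
            toy_complex.pdb_string, toy_complex.prm_sequence
        )[0]
        pair = pp.score_candidate(
            pair, [toy_complex.peptide_sequence], toy_complex.prm_sequence
        )
        aln = pair.scores["peptide_alignment"]
        span = set(range(*aln.span))
        contacts = {j for _, j in pair.contacts}
        n_c, n_nc = len(span & contacts), len(span - contacts)
        bd = pp.similarity_breakdown(pair)
        total = pp.percent_similarity(
            pair.peptide_seq, toy_complex.peptide_sequence, mask=span
        )
        combined = (bd["contact"] * n_c + bd["non_contact"] * n_nc) / (n_c + n_nc)
        assert combined == pytest.approx(total)


def test_register_identity_helper_is_exact():
    off, ident = align_registers_identity("PTAP", "GGPTAPGG")
    assert off == 2 and ident == 100.0
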