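"""Alignment, PWM weighting, specificity scores, flanking and trimming."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import prmprofiler as pp
from prmprofiler.errors import InsufficientDataError
from conftest import make_alignment


def recs(seqs, prm="TEST"):
    return [pp.PeptideRecord(s, prm) for s in seqs]


class TestClusterAndAlign:
    def test_identical_peptides_form_one_cluster(self):
        aln = pp.cluster_and_align(recs(["WAPTAP"] * 5))
        assert aln.offsets == [0] * 5
        assert aln.rows == ["WAPTAP"] * 5
        assert aln.outliers == []

    def test_motif_anchored_offsets(self):
        # brute-force over relative offsets, the PTAP columns must align
        aln = pp.cluster_and_align(recs(["GAPTAPGG", "AAPTAPGA", "PTAPGAAA"]))
        assert aln.offsets == [2, 2, 0]
        start = {r.strip("-"): len(r) - len(r.lstrip("-")) for r in aln.rows}
        cols = {s.find("PTAP") + start[s] for s in start}
        assert len(cols) == 1  # fully conserved PTAP columns

    def test_seedless_peptide_flagged_outlier(self):
        motif = [f"{x}GWPTAPG{x}" for x in "ADEFHIKLM"]  # 9 sharing WPTAPG
        lone = "YRYRYRYRY"  # shares no 3-mer with the others
        aln = pp.cluster_and_align(recs(motif + [lone]))
        assert [r.sequence for r, _ in aln.outliers] == [lone]
        assert aln.n_rows == 9

    def test_fewer_than_two_peptides_errors(self):
        with pytest.raises(InsufficientDataError):
            pp.cluster_and_align(recs(["WAPTAP"]))

    def test_mutually_seedless_keeps_one_with_warning(self):
        seqs = ["WADEF", "KLMNQ", "RSTVY"]
        with pytest.warns(UserWarning, match="no peptides share seeds"):
            aln = pp.cluster_and_align(recs(seqs))
        assert aln.n_rows == 1
        assert len(aln.outliers) == 2

    def test_every_peptide_is_row_or_outlier(self, peptides_and_truth):
        ps, _ = peptides_and_truth
        aln = pp.cluster_and_align(ps.unique_records())
        seqs = [r.sequence for r in aln.records] + [
            r.sequence for r, _ in aln.outliers
        ]
        assert sorted(seqs) == sorted(ps.unique_sequences)

    def test_override_alignment_is_used_verbatim(self):
        seqs = ["WAPTAP", "APTAPG"]
        aln = pp.cluster_and_align(
            recs(seqs), override_alignment={"WAPTAP": 0, "APTAPG": 1}
        )
        assert aln.rows == ["WAPTAP-", "-APTAPG"]


class TestBuildPwm:
    def test_example_column_weights(self):
        prof = pp.build_pwm(make_alignment(["W", "W", "W", "A", "L"]))
        get = lambda a: prof.w[prof.alphabet.index(a), 0]
        assert get("W") == pytest.approx(0.36)
        assert get("A") == pytest.approx(0.12)
        assert get("L") == pytest.approx(0.12)
        assert prof.sp[0] == pytest.approx(0.6)

    def test_fully_conserved_column(self):
        prof = pp.build_pwm(make_alignment(["W", "W", "W"]))
        i = prof.alphabet.index("W")
        assert prof.f[i, 0] == 1.0 and prof.w[i, 0] == 1.0
        assert prof.sp[0] == 1.0
        assert np.all(prof.w[np.arange(19) != i, 0] == 0.0)

    def test_uniform_column_has_zero_weights(self):
        # one row per alphabet letter: max f == min f, so every weight is 0
        prof = pp.build_pwm(make_alignment(list(pp.ALPHABET_NO_CYS)))
        assert np.all(prof.w == 0.0) and prof.sp[0] == 0.0

    def test_pads_excluded_from_depth(self):
        prof = pp.build_pwm(make_alignment(["WA-", "WAG", "-AG"]))
        # terminal columns have depth 2
        assert prof.f[prof.alphabet.index("W"), 0] == 1.0
        assert prof.f[prof.alphabet.index("G"), 2] == 1.0

    def test_weights_bounded_by_frequencies(self, recovered_profile):
        p = recovered_profile
        assert np.all(p.w <= p.f + 1e-15) and np.all(p.w >= 0)
        np.testing.assert_allclose(p.f.sum(axis=0), 1.0, atol=1e-12)


class TestSpecificityPotential:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=19))
    def test_closed_form_identity(self, raw):
        # SP as the sum of weights equals the column frequency range
        f = np.zeros((19, 1))
        vals = np.array(raw) / np.sum(raw)
        f[: len(vals), 0] = vals
        w = f * (f.max(axis=0) - f.min(axis=0))
        assert abs(w.sum() - (f.max() - f.min())) < 1e-12

    def test_input_order_invariance(self, peptides_and_truth):
        ps, _ = peptides_and_truth
        p1 = pp.build_profile(ps)
        shuffled = pp.PeptideSet(
            ps.prm_id, ps.prm_family, list(reversed(ps.records))
        )
        p2 = pp.build_profile(shuffled)
        np.testing.assert_array_equal(np.sort(p1.sp), np.sort(p2.sp))
        assert p1.spt == pytest.approx(p2.spt)

    def test_adding_modal_residue_never_decreases_sp(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            col = list(rng.choice(list(pp.ALPHABET_NO_CYS), size=rng.integers(2, 12)))
            before = pp.build_pwm(make_alignment(col)).sp[0]
            modal = max(set(col), key=col.count)
            after = pp.build_pwm(make_alignment(col + [modal])).sp[0]
            assert after >= before - 1e-12


class TestGlycineFlank:
    def test_specific_terminus_gains_gly_column(self):
        # N-terminal SP = 1; C-terminal column is 4-way split (SP = 0.25)
        prof = pp.build_pwm(make_alignment(["WAD", "WAE", "WAK", "WAL"]))
        out = pp.glycine_flank(prof)
        assert out.gly_flank == {"N": True, "C": False}
        assert out.f[out.alphabet.index("G"), 0] == 1.0
        assert out.sp[0] == 1.0

    def test_weak_terminus_unchanged(self):
        rows = ["WDEKA", "ADEKG", "GDEKL", "KDEKW", "LDEKD"]  # terminal SP = 0.2
        prof = pp.build_pwm(make_alignment(rows))
        assert prof.sp[0] < 0.33 and prof.sp[-1] < 0.33
        out = pp.glycine_flank(prof)
        assert out.gly_flank == {"N": False, "C": False}
        assert out.n_positions == prof.n_positions

    def test_both_termini_trigger_independently(self):
        prof = pp.build_pwm(make_alignment(["WADPW", "WAEPW"]))
        out = pp.glycine_flank(prof)
        assert out.gly_flank == {"N": True, "C": True}
        assert out.n_positions == prof.n_positions + 2

    def test_rows_not_reaching_terminus_get_pads(self):
        prof = pp.build_pwm(make_alignment(["WAD-", "WADE"]))
        out = pp.glycine_flank(prof)
        assert out.alignment.rows == ["GWAD--", "GWADEG"]


class TestTrimAndScore:
    def sp_profile(self, sp):
        # a minimal profile whose sp vector is prescribed
        sp = np.asarray(sp, dtype=float)
        f = np.tile(sp, (19, 1)) / 19
        return pp.SpecificityProfile(
            prm_id="X", alphabet=pp.ALPHABET_NO_CYS, f=f, w=f, sp=sp
        )

    def test_trims_weak_flanks_and_sums_spt(self):
        out = pp.trim_and_score(self.sp_profile([0.1, 0.5, 1.0, 0.4, 0.15]))
        assert out.trim == (1, 4)
        assert out.spt == pytest.approx(1.9)
        assert out.classes == ("specific", "specific", "specific")

    def test_interior_weak_position_kept_but_not_summed(self):
        out = pp.trim_and_score(self.sp_profile([0.5, 0.1, 0.5]))
        assert out.trim == (0, 3)
        assert out.spt == pytest.approx(1.0)
        assert out.classes == ("specific", "non-specific", "specific")

    def test_all_weak_yields_empty_profile(self):
        out = pp.trim_and_score(self.sp_profile([0.1, 0.15, 0.05]))
        assert out.is_empty and out.spt == 0.0
        assert "no significant profile" in out.flags


class TestProfileGate:
    def gated(self, n, spt):
        f = np.ones((19, 1)) / 19
        p = pp.SpecificityProfile(
            prm_id="X", alphabet=pp.ALPHABET_NO_CYS, f=f, w=f,
            sp=np.array([1.0]), spt=spt, n_peptides=n,
        )
        return bool(pp.profile_gate([p]))

    def test_gates(self):
        assert not self.gated(4, 3.0)   # too few peptides
        assert not self.gated(10, 0.8)  # too unspecific
        assert not self.gated(10, 1.0)  # SPt must exceed 1
        assert self.gated(5, 1.01)


class TestParameterRecovery:
    def test_planted_profile_recovered(self, peptides_and_truth, recovered_profile):
        """Planted specific positions, their modal residues, and outliers."""
        ps, truth = peptides_and_truth
        p = recovered_profile
        start = {
            r.strip("-"): len(r) - len(r.lstrip("-")) for r in p.alignment.rows
        }
        lo, _ = p.trim
        from collections import Counter
        from scipy.stats import pearsonr

        for k in sorted(truth.planted.specific):
            cols = Counter(
                start[rec.sequence] + cs + k
                for rec, cs, fl in zip(ps.records, truth.core_starts, truth.outlier_flags)
                if not fl and rec.sequence in start
            )
            j = cols.most_common(1)[0][0] - lo
            assert 0 <= j < p.n_positions
            rec_f = p.f[:, j]
            planted = np.array(
                [truth.planted.positions[k].get(a, 0.0) for a in p.alphabet]
            )
            assert p.alphabet[rec_f.argmax()] == truth.planted.modal_residue(k)
            assert pearsonr(rec_f, planted)[0] >= 0.9
        flagged = {r.sequence for r, _ in p.alignment.outliers}
        planted_out = {
            rec.sequence
            for rec, fl in zip(ps.records, truth.outlier_flags)
            if fl
        }
        assert planted_out <= flagged


def test_render_logo_outputs(tmp_path, recovered_profile):
    out = tmp_path / "logo.png"
    pp.render_logo(recovered_profile, out)
    assert out.stat().st_size > 1000
    # empty profile gets a placeholder, not an exception
    empty = pp.trim_and_score(
        TestTrimAndScore().sp_profile([0.05, 0.1])
    )
    pp.render_logo(empty, tmp_path / "empty.png")
    assert (tmp_path / "empty.png").exists()
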