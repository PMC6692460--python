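"""Prohormone processing: translation, ORFs, cleavage, excision, masses."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight
from hypothesis import given, settings
from hypothesis import strategies as st

from kininmine import (
    CleavageRuleSet,
    ContractError,
    InputError,
    NucleotideRecord,
    PrecursorRecord,
    average_mass,
    core_position_summary,
    excise_peptides,
    find_kinin_core,
    find_orfs,
    mine_precursor,
    peptide_table,
    predict_cleavage_sites,
    translate_six_frames,
)
from kininmine.prohormone import AMIDE_SHIFT, WATER_MASS

CODON_TABLE = {}
for b1 in "TCAG":
    for b2 in "TCAG":
        for b3 in "TCAG":
            CODON_TABLE[b1 + b2 + b3] = str(Seq(b1 + b2 + b3).translate())

COMP = str.maketrans("ACGT", "TGCA")


def oracle_translate(seq: str, frame: int) -> str:
    """Plain codon-lookup translation, independent of the implementation."""
    s = seq if frame > 0 else seq.translate(COMP)[::-1]
    off = abs(frame) - 1
    out = []
    for i in range(off, len(s) - 2, 3):
        out.append(CODON_TABLE[s[i : i + 3]])
    return "".join(out)


class TestTranslation:
    def test_single_codon(self):
        frames = translate_six_frames(NucleotideRecord("x", "ATG"))
        assert frames[1] == "M"
        assert frames[-1] == "H"  # CAT
        assert frames[2] == frames[3] == frames[-2] == frames[-3] == ""

    def test_stop_sentinel(self):
        frames = translate_six_frames(NucleotideRecord("x", "ATGAAATAA"))
        assert frames[1] == "MK*"

    def test_bad_alphabet_names_position(self):
        with pytest.raises(InputError, match="position 4"):
            NucleotideRecord("x", "ATGU")

    def test_against_codon_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 300))))
            frames = translate_six_frames(NucleotideRecord("r", seq))
            for f in (1, 2, 3, -1, -2, -3):
                assert frames[f] == oracle_translate(seq, f), (seq, f)


class TestOrfs:
    def test_simple_orf(self):
        calls = find_orfs(NucleotideRecord("x", "ATGAAATAA"))
        assert len(calls) == 1
        top = calls[0]
        assert (top.protein, top.coding_length_nt, top.partial) == ("MK", 6, False)
        assert top.length_with_stop_nt == 9

    def test_no_atg_gives_empty(self):
        assert find_orfs(NucleotideRecord("x", "CCCCCC")) == []

    def test_longest_first_and_reverse_strand(self):
        # forward frame +1: MKKK* ; reverse strand carries a shorter ORF
        seq = "ATGAAGAAAAAATAAGGG"
        calls = find_orfs(NucleotideRecord("x", seq))
        assert calls[0].protein.startswith("MKKK")
        assert all(
            len(calls[i].protein) >= len(calls[i + 1].protein)
            for i in range(len(calls) - 1)
        )

    def test_coding_length_matches_protein(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        for call in find_orfs(NucleotideRecord("r", seq)):
            assert call.coding_length_nt == 3 * len(call.protein)


class TestCleavage:
    def test_worked_repeat_unit(self, default_rules):
        sites = predict_cleavage_sites(PrecursorRecord("t", "DTFGPWGGKR"), default_rules)
        assert [(s.position, s.kind) for s in sites] == [(10, "dibasic")]

    def test_no_basic_no_sites(self, default_rules):
        assert predict_cleavage_sites(PrecursorRecord("t", "AAAAAA"), default_rules) == []

    def test_proline_blocks_site(self, default_rules):
        assert predict_cleavage_sites(PrecursorRecord("t", "AAKRPA"), default_rules) == []

    def test_monobasic_r_needs_upstream_basic(self, default_rules):
        # K at -4 relative to the lone R licenses cleavage
        sites = predict_cleavage_sites(PrecursorRecord("t", "AKRAAAGAARAA"), default_rules)
        positions = {s.position for s in sites}
        assert 3 in positions  # KR dibasic
        assert 10 in positions  # lone R with R at -6? K at ...
        lone = predict_cleavage_sites(PrecursorRecord("t", "AAAAAAAARAA"), default_rules)
        assert lone == []

    def test_signal_peptide_masks_sites(self, default_rules):
        with_signal = PrecursorRecord("t", "AAKRAAAKRA", signal_end=5)
        sites = predict_cleavage_sites(with_signal, default_rules)
        assert [s.position for s in sites] == [9]

    def test_optional_pairs_flag(self):
        rec = PrecursorRecord("t", "AAKKAA")
        assert predict_cleavage_sites(rec, CleavageRuleSet()) == []
        on = CleavageRuleSet(optional_pairs_enabled=True)
        assert [s.position for s in predict_cleavage_sites(rec, on)] == [4]


class TestExcision:
    def test_worked_repeat_excision(self, default_rules):
        rec = PrecursorRecord("t", "DTFGPWGGKR")
        peps = excise_peptides(rec, predict_cleavage_sites(rec, default_rules), default_rules)
        assert len(peps) == 1
        pep = peps[0]
        assert (pep.sequence, pep.amidated, pep.source_span) == ("DTFGPWG", True, (1, 10))
        assert pep.core is not None and (pep.core.x1, pep.core.x2) == ("G", "P")

    def test_no_sites_whole_sequence(self, default_rules):
        rec = PrecursorRecord("t", "ADTFGPWGG")
        peps = excise_peptides(rec, [], default_rules)
        assert len(peps) == 1
        assert peps[0].sequence == "ADTFGPWG" and peps[0].amidated

    def test_unsorted_sites_rejected(self, default_rules):
        rec = PrecursorRecord("t", "AKRAAKRA")
        sites = predict_cleavage_sites(rec, default_rules)[::-1]
        with pytest.raises(ContractError):
            excise_peptides(rec, sites, default_rules)

    def test_fragments_tile_the_precursor(self, default_rules):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(list("AKRPGDEFSWQ"), size=int(rng.integers(1, 60))))
            rec = PrecursorRecord("t", seq)
            sites = predict_cleavage_sites(rec, default_rules)
            peps = excise_peptides(rec, sites, default_rules)
            bounds = [0] + [s.position for s in sites]
            if not sites or sites[-1].position != len(seq):
                bounds.append(len(seq))
            fragments = [
                (bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)
            ]
            assert "".join(seq[a - 1 : b] for a, b in fragments) == seq
            emitted = {p.source_span for p in peps}
            assert emitted <= set(fragments)


class TestKininCore:
    @pytest.mark.parametrize(
        "seq, x1, x2",
        [("QFSPWG", "S", "P"), ("AGDHFGSWG", "G", "S"), ("DTFSAWG", "S", "A")],
    )
    def test_core_detection(self, seq, x1, x2):
        core = find_kinin_core(seq, amidated=True)
        assert core is not None and (core.x1, core.x2) == (x1, x2)

    def test_amidation_required(self):
        assert find_kinin_core("QFSPWG", amidated=False) is None

    def test_wrong_anchor_rejected(self):
        assert find_kinin_core("QFSPWA", amidated=True) is None


class TestAverageMass:
    def test_single_glycine(self):
        mass, rounded = average_mass("G", amidated=False)
        assert mass == pytest.approx(75.0672, abs=1e-3)
        assert rounded == 75

    @pytest.mark.parametrize(
        "seq, printed", [("QFSPWG", 720), ("DKDQTFNPWG", 1206), ("AVRSPTARNDAARAKQEDGEEDEERSFAPWG", 3446)]
    )
    def test_published_values(self, seq, printed):
        assert average_mass(seq, amidated=True)[1] == printed

    def test_unknown_residue(self):
        with pytest.raises(InputError):
            average_mass("QFX", amidated=False)

    def test_against_biopython(self):
        for seq in ("QFSPWG", "DTFGPWG", "GDDGDTSFTPWG", "W", "ACDEFGHIKLMNPQRSTVWY"):
            ours, _ = average_mass(seq, amidated=False)
            ref = molecular_weight(seq, "protein", monoisotopic=False)
            assert ours == pytest.approx(ref, abs=0.1)

    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_additivity_and_amide_shift(self, a, b):
        m_ab = average_mass(a + b, amidated=False)[0]
        m_a = average_mass(a, amidated=False)[0]
        m_b = average_mass(b, amidated=False)[0]
        assert m_ab == pytest.approx(m_a + m_b - WATER_MASS, abs=1e-9)
        assert average_mass(a, amidated=True)[0] - m_a == pytest.approx(AMIDE_SHIFT)

    def test_rounding_half_away_from_zero(self):
        # mass arithmetic aside, the convention itself
        assert average_mass("G", False)[1] == math.floor(average_mass("G", False)[0] + 0.5)


class TestSummaries:
    def test_x1_x2_counts(self, rm_kinins):
        prec, _ = _as_peptides(rm_kinins)
        table, excluded = core_position_summary(prec)
        x2 = table[table.position == "X2"].set_index("residue")["count"].to_dict()
        assert x2 == {"P": 15, "S": 1, "A": 1}
        assert excluded == []

    def test_empty_input(self):
        table, excluded = core_position_summary([])
        assert table.empty and excluded == []

    def test_peptide_table_columns(self, rm_kinins):
        peps, _ = _as_peptides(rm_kinins)
        df = peptide_table(peps)
        assert list(df.columns) == [
            "name", "sequence", "amidated", "core", "X1", "X2",
            "span_start", "span_end", "mass_da", "mass_rounded",
        ]
        assert (df.core == 1).all()


def _as_peptides(table):
    """Published kinin rows as mined-peptide objects (mined from a scaffold
    precursor so spans and cores come from the real pipeline)."""
    from kininmine.prohormone import MaturePeptide

    peps = []
    cursor = 0
    for row in table.itertuples():
        seq = row.sequence
        span = (cursor + 1, cursor + len(seq) + 3)
        cursor += len(seq) + 3
        mass, rounded = average_mass(seq, amidated=True)
        peps.append(
            MaturePeptide(
                sequence=seq, amidated=True, source_span=span,
                core=find_kinin_core(seq, True), mass_da=mass,
                mass_rounded=rounded, name=row.name,
            )
        )
    return peps, cursor


class TestMinePrecursor:
    def test_roundtrip_against_generator_truth(self, default_rules):
        from kininmine.synthetic import generate_precursor

        for seed in (0, 1, 2):
            prec, truth = generate_precursor(17, seed=seed, rules=default_rules)
            mined = mine_precursor(prec, default_rules)
            assert [(p.sequence, p.amidated, p.source_span) for p in mined] == [
                (t.sequence, t.amidated, t.source_span) for t in truth
            ]
            assert [p.core for p in mined] == [t.core for t in truth]
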