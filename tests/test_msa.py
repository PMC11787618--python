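"""Progressive alignment, conservation classes, and residue mapping."""

import numpy as np
import pytest

from helpers import oracle_global
from synortho.msa import (
    CLASS_EQUIV_ALL,
    CLASS_IDENTICAL_ALL,
    CLASS_NOT_CONSERVED,
    MSA,
    align_family,
    conserved_columns,
    map_residue,
)
from synortho.synthetic import SimulationConfig, simulate


class TestAlignFamily:
    def test_identical_pair_aligns_gap_free(self):
        msa = align_family([("a", "MKTAYIAK"), ("b", "MKTAYIAK")])
        assert msa.aligned("a") == "MKTAYIAK"
        assert msa.aligned("b") == "MKTAYIAK"

    def test_single_gap_pair_matches_enumeration_optimum(self):
        msa = align_family([("a", "ACDE"), ("b", "ACE")])
        assert msa.aligned("a") == "ACDE"
        assert msa.aligned("b").count("-") == 1
        # the realized pairwise score equals the exhaustive optimum
        score = 0.0
        in_gap = False
        from synortho.align import BLOSUM62, encode

        for x, y in zip(msa.aligned("a"), msa.aligned("b")):
            if x == "-" or y == "-":
                score -= 0.5 if in_gap else 10.5
                in_gap = True
            else:
                score += float(BLOSUM62[encode(x)[0], encode(y)[0]])
                in_gap = False
        assert score == pytest.approx(oracle_global("ACDE", "ACE", 10.0, 0.5))

    def test_rows_recover_inputs(self):
        seqs = [("a", "MKTAYIAK"), ("b", "MKTAYIK"), ("c", "MKTWYIAK")]
        msa = align_family(seqs)
        for rid, seq in seqs:
            assert msa.sequence(rid) == seq

    def test_indel_free_family_aligns_without_gaps(self):
        # moderate divergence: ungapped alignment is the clear optimum, so the
        # columns must equal the ancestral positions
        genomes, truth = simulate(SimulationConfig(n_genomes=6, seed=4, divergence=0.15))
        members = [
            (g.genome_id, g.gene(truth.genomes[g.genome_id].member_gene).protein)
            for g in genomes
        ]
        msa = align_family(members)
        assert msa.width == len(members[0][1])
        assert all("-" not in msa.aligned(gid) for gid, _ in members)

    def test_input_order_invariance(self):
        seqs = [("a", "MKTAYIAK"), ("b", "MKTAYIK"), ("c", "MKTWYIAK"), ("d", "MRTWYIAK")]
        msa1 = align_family(seqs)
        msa2 = align_family(list(reversed(seqs)))
        for rid, _ in seqs:
            assert msa1.aligned(rid) == msa2.aligned(rid)

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_family([("a", "MKT")])

    def test_width_bounds(self):
        seqs = [("a", "MKTAYIAK"), ("b", "MKAYIK"), ("c", "MKTWYIIAK")]
        msa = align_family(seqs)
        assert max(len(s) for _, s in seqs) <= msa.width <= sum(len(s) for _, s in seqs)


class TestConservedColumns:
    def _msa(self, rows):
        return MSA(rows)

    def test_identical_column_classes(self):
        msa = self._msa([("a", "IAG"), ("b", "IAG"), ("c", "IVG")])
        rep = conserved_columns(msa, reference="a")
        assert rep.columns[0].conservation_class == CLASS_IDENTICAL_ALL
        assert rep.columns[1].conservation_class == CLASS_NOT_CONSERVED
        assert rep.columns[2].conservation_class == CLASS_IDENTICAL_ALL

    def test_ilv_column_is_equivalent_in_all(self):
        msa = self._msa([("a", "I"), ("b", "I"), ("c", "V"), ("d", "L")])
        rep = conserved_columns(msa, reference="a")
        assert rep.columns[0].conservation_class == CLASS_EQUIV_ALL
        assert rep.columns[0].in_equivalence_set

    def test_identical_implies_equivalent(self):
        msa = self._msa([("a", "GI"), ("b", "GI"), ("c", "GI")])
        rep = conserved_columns(msa, reference="a")
        for col in rep.columns:
            assert col.conservation_class == CLASS_IDENTICAL_ALL
        # all-G column is equivalent via its singleton class, not via {I,L,V}
        assert not rep.columns[0].in_equivalence_set
        assert rep.columns[1].in_equivalence_set

    def test_gap_vetoes_conservation(self):
        msa = self._msa([("a", "IA"), ("b", "I-")])
        rep = conserved_columns(msa, reference="a")
        assert rep.columns[0].gap_free
        assert not rep.columns[1].gap_free
        assert rep.columns[1].conservation_class == CLASS_NOT_CONSERVED

    def test_group_classes(self):
        msa = self._msa([("a", "IK"), ("b", "IK"), ("c", "VQ"), ("d", "LQ")])
        groups = {"a": "group-I", "b": "group-I", "c": "group-II", "d": "group-II"}
        rep = conserved_columns(msa, groups=groups, reference="a")
        col2 = rep.columns[1]
        assert col2.per_group["group-I"] == "identical-in-group"
        assert col2.per_group["group-II"] == "identical-in-group"
        assert col2.conservation_class == "identical-in-group"

    def test_planted_constrained_columns_recovered_exactly(self, basic_fixture):
        _, genomes, truth = basic_fixture
        lo, hi = truth.coil_interval
        frags = [
            (g.genome_id, g.gene(truth.genomes[g.genome_id].member_gene).protein[lo - 1 : hi])
            for g in genomes
        ]
        msa = align_family(frags)
        rep = conserved_columns(msa, reference=genomes[0].genome_id)
        found = sorted(c.column for c in rep.equivalent_all_columns())
        planted = sorted(r - lo + 1 for r in truth.constrained_columns)
        assert found == planted

    def test_missing_reference_rejected(self):
        msa = self._msa([("a", "I"), ("b", "I")])
        with pytest.raises(ValueError):
            conserved_columns(msa, reference="zz")


class TestMapResidue:
    def test_identity_on_identical_sequences(self):
        msa = align_family([("a", "MKTAYIAK"), ("b", "MKTAYIAK")])
        for r in range(1, 9):
            assert map_residue(msa, "a", r, "b") == r

    def test_gap_target_returns_gap(self):
        msa = MSA([("a", "ACDE"), ("b", "AC-E")])
        assert map_residue(msa, "a", 3, "b") == "GAP"
        assert map_residue(msa, "a", 4, "b") == 3

    def test_roundtrip_where_defined(self):
        msa = align_family([("a", "MKTAYIAKQRQI"), ("b", "MKTYIAKQRQI")])
        for r in range(1, 13):
            fwd = map_residue(msa, "a", r, "b")
            if fwd != "GAP":
                assert map_residue(msa, "b", fwd, "a") == r

    def test_out_of_range_errors(self):
        msa = MSA([("a", "ACDE"), ("b", "ACDE")])
        with pytest.raises(ValueError):
            map_residue(msa, "a", 5, "b")

    def test_offset_mapping_through_leading_gap(self):
        # b misses the first 10 residues of a: b's residue k maps to a's k+10
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        msa = align_family([("a", "MKTAYIAKQR" + core), ("b", core)])
        assert map_residue(msa, "b", 1, "a") == 11
        assert map_residue(msa, "a", 11, "b") == 1


class TestMSAValidation:
    def test_all_gap_column_rejected(self):
        with pytest.raises(ValueError):
            MSA([("a", "A-C"), ("b", "A-C")])

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            MSA([("a", "AC"), ("b", "ACD")])
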