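"""Identity computation and the strict 40%/55% naming thresholds."""

import itertools

import numpy as np
import pytest

from cypome.formats import ProteinRecord
from cypome.nomenclature import (NomenclatureConfig, assign_families,
                                 assign_subfamilies_and_numbers, global_align,
                                 identity_matrix, name_cypome,
                                 percent_identity)


class TestAlignmentAndIdentity:
    def test_identical_sequences_align_without_gaps(self):
        ga, gb = global_align("ACDE", "ACDE")
        assert (ga, gb) == ("ACDE", "ACDE")
        pid, cov = percent_identity((ga, gb))
        assert pid == 100.0 and cov == 1.0

    def test_length_mismatch_gives_terminal_gap(self):
        ga, gb = global_align("ACDE", "ACD")
        assert len(ga) == 4 and gb.count("-") == 1
        assert gb.endswith("-")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "A")

    def test_single_mismatch_identity(self):
        pid, cov = percent_identity(("ACDE", "ACDF"))
        assert pid == 75.0 and cov == 1.0

    def test_disjoint_overlap_reports_zero(self):
        pid, cov = percent_identity(("AC--", "--DE"))
        assert pid == 0.0 and cov == 0.0

    def test_identity_matrix_diagonal_and_symmetry(self):
        recs = [ProteinRecord(f"r{i}", "MACDEFGHIK" * 5) for i in range(3)]
        ident, cov, ids = identity_matrix(recs)
        assert np.allclose(ident, 100.0)
        assert np.allclose(cov, 1.0)
        assert ids == ["r0", "r1", "r2"]


def _matrix(ids, pairs, default=10.0):
    """Symmetric identity matrix from {frozenset(pair): identity}."""
    n = len(ids)
    ident = np.full((n, n), default)
    np.fill_diagonal(ident, 100.0)
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        ident[i, j] = ident[j, i] = v
    return ident, np.ones((n, n))


class TestThresholdStrictness:
    def test_exactly_40_percent_is_not_same_family(self):
        ids = ["q1", "q2"]
        ident, cov = _matrix(ids, {("q1", "q2"): 40.0})
        fams = assign_families(ident, cov, ids, {})
        assert fams["q1"].family != fams["q2"].family

    def test_just_above_40_percent_is_same_family(self):
        ids = ["q1", "q2"]
        ident, cov = _matrix(ids, {("q1", "q2"): 40.1})
        fams = assign_families(ident, cov, ids, {})
        assert fams["q1"].family == fams["q2"].family

    def test_exactly_55_percent_is_not_same_subfamily(self):
        ids = ["q1", "q2"]
        ident, cov = _matrix(ids, {("q1", "q2"): 55.0})
        fams = assign_families(ident, cov, ids, {})
        done = assign_subfamilies_and_numbers(fams, ident, cov, ids)
        assert done["q1"].family == done["q2"].family
        assert done["q1"].subfamily != done["q2"].subfamily

    def test_just_above_55_percent_is_same_subfamily(self):
        ids = ["q1", "q2"]
        ident, cov = _matrix(ids, {("q1", "q2"): 55.1})
        fams = assign_families(ident, cov, ids, {})
        done = assign_subfamilies_and_numbers(fams, ident, cov, ids)
        assert done["q1"].subfamily == done["q2"].subfamily
        assert [done["q1"].gene_number, done["q2"].gene_number] == [1, 2]


class TestFamilyAssignment:
    def test_query_anchors_to_best_reference_family(self):
        ids = ["q1", "ref_cyp4"]
        ident, cov = _matrix(ids, {("q1", "ref_cyp4"): 62.0})
        fams = assign_families(ident, cov, ids, {"ref_cyp4": "CYP4"})
        a = fams["q1"]
        assert a.family == "CYP4" and not a.novel_family
        assert a.anchor == "ref_cyp4" and a.anchor_identity == 62.0

    def test_low_coverage_pair_is_unreliable(self):
        ids = ["q1", "ref_cyp4"]
        ident, cov = _matrix(ids, {("q1", "ref_cyp4"): 62.0})
        cov[0, 1] = cov[1, 0] = 0.3  # fragment-against-full-length overlap
        fams = assign_families(ident, cov, ids, {"ref_cyp4": "CYP4"})
        assert fams["q1"].novel_family

    def test_transitive_trio_forms_one_novel_family(self):
        ids = ["q1", "q2", "q3"]
        ident, cov = _matrix(ids, {("q1", "q2"): 50, ("q2", "q3"): 50,
                                   ("q1", "q3"): 20})
        fams = assign_families(ident, cov, ids, {})
        assert len({a.family for a in fams.values()}) == 1
        assert fams["q1"].family == "CYP9001"

    def test_isolated_query_gets_own_novel_family(self):
        ids = ["only"]
        ident, cov = _matrix(ids, {})
        fams = assign_families(ident, cov, ids, {})
        assert fams["only"].novel_family

    @pytest.mark.filterwarnings("ignore:.*single-linkage chaining")
    def test_single_linkage_matches_transitive_closure_oracle(self, rng):
        """Family partition equals brute-force transitive closure of the
        >threshold relation on random cohorts."""
        for _ in range(30):
            n = int(rng.integers(4, 21))
            ids = [f"s{i:02d}" for i in range(n)]
            ident = np.full((n, n), 0.0)
            for i in range(n):
                for j in range(i + 1, n):
                    v = float(rng.choice([15.0, 35.0, 45.0, 70.0]))
                    ident[i, j] = ident[j, i] = v
            np.fill_diagonal(ident, 100.0)
            cov = np.ones((n, n))
            fams = assign_families(ident, cov, ids, {})
            # oracle: repeated boolean closure of the adjacency relation
            adj = ident > 40.0
            np.fill_diagonal(adj, True)
            closure = adj.copy()
            for _ in range(n):
                closure = closure | (closure @ closure)
            for i, j in itertools.combinations(range(n), 2):
                same = fams[ids[i]].family == fams[ids[j]].family
                assert same == bool(closure[i, j])


class TestNaming:
    def test_subfamily_letters_and_gene_numbers(self):
        ids = ["qa", "qb", "qc"]
        ident, cov = _matrix(ids, {("qa", "qb"): 70.0, ("qa", "qc"): 45.0,
                                   ("qb", "qc"): 45.0})
        fams = assign_families(ident, cov, ids, {})
        done = assign_subfamilies_and_numbers(fams, ident, cov, ids)
        assert [done[i].full_name for i in ids] == \
               ["CYP9001A1", "CYP9001A2", "CYP9001B1"]

    def test_name_format_family_subfamily_number(self):
        ids = ["z"]
        ident, cov = _matrix(ids, {})
        fams = assign_families(ident, cov, ids, {},
                               NomenclatureConfig(novel_family_start=17))
        done = assign_subfamilies_and_numbers(fams, ident, cov, ids)
        assert done["z"].full_name == "CYP17A1"

    def test_input_permutation_leaves_names_invariant(self, rng):
        recs = [ProteinRecord(f"g{i}", s) for i, s in enumerate([
            "MACDEFGHIKLMNPQRSTVWYACDEFGHIK" * 3,
            "MACDEFGHIKLMNPQRSTVWYACDEFGHIR" * 3,
            "MWYVTSRQPNMLKIHGFEDCAWYVTSRQPN" * 3,
        ])]
        names1 = {a.id: a.full_name for a in name_cypome(recs).values()}
        shuffled = [recs[2], recs[0], recs[1]]
        names2 = {a.id: a.full_name for a in name_cypome(shuffled).values()}
        assert names1 == names2
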