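"""Property tables, column classification, polymorphism detection, logos."""

import math

import numpy as np
import pytest

from sdpscan.conservation import (
    ConservationError,
    PropertyTable,
    annotate_property_change,
    classify_columns,
    column_frequencies,
    detect_group_polymorphisms,
    group_consensus,
    information_content,
    shading_bin,
)
from sdpscan.seqio import AMINO_ACIDS, AlignedFamily
from sdpscan.synthetic_data import (
    FamilySpec,
    default_polymorphic_columns,
    simulate_family,
)

# Independent lookup oracle for the five residue categorizations, typed in
# from scratch as label -> member strings (deliberately a different data
# layout than the implementation's).
ORACLE = {
    "charge": [("positive", "RHK"), ("negative", "DE"),
               ("uncharged", "ANCQGILMFPSTWYV")],
    "hydrophobicity": [("hydrophobic", "ILVCAMF"),
                       ("neutral/hydrophilic", "GYWHKTREQDNSP")],
    "size": [("small", "AGCS"), ("medium", "VTNPD"),
             ("large", "QEHKRFYWMIL")],
    "polarity": [("charged polar", "HRKED"), ("uncharged polar", "QTSNYW"),
                 ("non-polar", "AGVLIPFM")],
    "flexibility": [("high", "KEMQR"), ("moderate", "DFHILNWY"),
                    ("low", "CSTV"), ("limited", "A"), ("restricted", "P")],
}


def oracle_label(dim, aa):
    for label, members in ORACLE[dim]:
        if aa in members:
            return label
    return None


TABLES = PropertyTable.load()


class TestPropertyTables:
    def test_all_400_ordered_pairs_match_oracle(self):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                changes, unclassified = annotate_property_change(a, b, TABLES)
                got = {dim: (la, lb) for dim, la, lb in changes}
                for dim in ORACLE:
                    la, lb = oracle_label(dim, a), oracle_label(dim, b)
                    if la is None or lb is None:
                        assert dim in unclassified
                    elif la != lb:
                        assert got[dim] == (la, lb)
                    else:
                        assert dim not in got
                        assert dim not in unclassified

    def test_exactly_cysteine_polarity_and_glycine_flexibility_unclassified(self):
        assert TABLES.unclassified("polarity") == {"C"}
        assert TABLES.unclassified("flexibility") == {"G"}
        for dim in ("charge", "hydrophobicity", "size"):
            assert TABLES.unclassified(dim) == set()

    def test_repair_option_fills_the_two_gaps(self):
        repaired = PropertyTable.load(repair=True)
        assert repaired.label("polarity", "C") == "non-polar"
        assert repaired.label("flexibility", "G") == "high"

    def test_antisymmetry_over_all_pairs(self):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                fwd, un_f = annotate_property_change(a, b, TABLES)
                rev, un_r = annotate_property_change(b, a, TABLES)
                assert sorted(un_f) == sorted(un_r)
                assert sorted((d, lb, la) for d, la, lb in fwd) == sorted(rev)

    def test_non_standard_residue_errors(self):
        with pytest.raises(ConservationError):
            annotate_property_change("X", "A", TABLES)


class TestKnownSubstitutions:
    def test_ala_vs_ile_size_and_flexibility(self):
        changes, unclassified = annotate_property_change("A", "I", TABLES)
        assert ("size", "small", "large") in changes
        assert ("flexibility", "limited", "moderate") in changes
        dims = {d for d, _, _ in changes}
        assert dims == {"size", "flexibility", "hydrophobicity"} - {"hydrophobicity"} \
            or dims == {"size", "flexibility"}
        assert unclassified == []

    def test_lys_vs_arg_fully_conservative(self):
        changes, unclassified = annotate_property_change("K", "R", TABLES)
        assert changes == []
        assert unclassified == []

    def test_his_vs_tyr(self):
        changes, _ = annotate_property_change("H", "Y", TABLES)
        assert ("charge", "positive", "uncharged") in changes
        assert ("polarity", "charged polar", "uncharged polar") in changes
        assert {d for d, _, _ in changes} == {"charge", "polarity"}

    def test_cys_vs_tyr_polarity_unclassified(self):
        changes, unclassified = annotate_property_change("C", "Y", TABLES)
        assert unclassified == ["polarity"]
        assert ("size", "small", "large") in changes


# ---------------------------------------------------- frequencies / logo IC


class TestFrequencies:
    def test_unanimous_column(self, tiny_family):
        f = column_frequencies(tiny_family, tiny_family.ids, 1)  # all 'M'
        assert f[AMINO_ACIDS.index("M")] == 1.0

    def test_gap_excluded(self):
        fam = AlignedFamily(
            records=[("a", "A"), ("b", "A"), ("c", "G"), ("d", "-")],
            class_of={k: "C" for k in "abcd"},
        )
        f = column_frequencies(fam, fam.ids, 1)
        assert f[AMINO_ACIDS.index("A")] == pytest.approx(2 / 3)
        assert f[AMINO_ACIDS.index("G")] == pytest.approx(1 / 3)

    def test_all_gap_flagged(self):
        fam = AlignedFamily(
            records=[("a", "-A"), ("b", "-A")], class_of={"a": "C", "b": "C"}
        )
        assert column_frequencies(fam, fam.ids, 1) is None

    def test_sums_to_one(self, planted_family):
        fam, _ = planted_family
        rng = np.random.default_rng(0)
        for col in rng.integers(1, fam.ncols + 1, size=10):
            f = column_frequencies(fam, fam.ids, int(col))
            assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_column_out_of_range(self, tiny_family):
        with pytest.raises(ConservationError):
            column_frequencies(tiny_family, tiny_family.ids, 99)


class TestInformationContent:
    def test_closed_forms(self):
        one = np.zeros(20)
        one[3] = 1.0
        assert information_content(one) == pytest.approx(math.log2(20))
        assert information_content(np.full(20, 0.05)) == pytest.approx(0.0)
        two = np.zeros(20)
        two[0] = two[1] = 0.5
        assert information_content(two) == pytest.approx(math.log2(20) - 1)

    def test_bounds(self, planted_family):
        fam, _ = planted_family
        for col in range(1, 40):
            f = column_frequencies(fam, fam.ids, col)
            assert 0 <= information_content(f) <= math.log2(20) + 1e-12


class TestGroupConsensus:
    def _fam(self, residues):
        return AlignedFamily(
            records=[(f"s{i}", r) for i, r in enumerate(residues)],
            class_of={f"s{i}": "C" for i in range(len(residues))},
        )

    def test_nine_of_ten_meets_080(self):
        fam = self._fam(["K"] * 9 + ["R"])
        assert group_consensus(fam, fam.ids, 1, 0.8) == "K"

    def test_seven_of_ten_fails_080(self):
        fam = self._fam(["K"] * 7 + ["R"] * 3)
        assert group_consensus(fam, fam.ids, 1, 0.8) is None

    def test_threshold_one_requires_unanimity(self):
        fam = self._fam(["K"] * 9 + ["R"])
        assert group_consensus(fam, fam.ids, 1, 1.0) is None
        fam2 = self._fam(["K"] * 10)
        assert group_consensus(fam2, fam2.ids, 1, 1.0) == "K"

    def test_majority_gapped_column_yields_none(self):
        fam = self._fam(["-", "-", "-", "K", "K"])
        assert group_consensus(fam, fam.ids, 1, 0.8) is None


# ------------------------------------------------- polymorphism detection


class TestDetectPolymorphisms:
    def test_planted_ala_vs_ile(self):
        fam = AlignedFamily(
            records=[(f"m{i}", "KAK") for i in range(3)]
            + [(f"b{i}", "KIK") for i in range(3)],
            class_of={f"{c}{i}": "GA3OX" for c in "mb" for i in range(3)},
            clade_of={
                **{f"m{i}": "monocot" for i in range(3)},
                **{f"b{i}": "brassicales" for i in range(3)},
            },
        )
        recs = detect_group_polymorphisms(
            fam, [f"m{i}" for i in range(3)], [f"b{i}" for i in range(3)],
            0.8, TABLES,
        )
        assert [r.column for r in recs] == [2]
        r = recs[0]
        assert (r.consensus_a, r.consensus_b) == ("A", "I")
        dims = {d for d, _, _ in r.property_changes}
        assert ("size", "small", "large") in r.property_changes
        assert ("flexibility", "limited", "moderate") in r.property_changes
        assert "charge" not in dims and "polarity" not in dims

    def test_conservative_substitution_empty_changes(self):
        fam = AlignedFamily(
            records=[("m0", "K"), ("m1", "K"), ("b0", "R"), ("b1", "R")],
            class_of={k: "C" for k in ("m0", "m1", "b0", "b1")},
        )
        recs = detect_group_polymorphisms(fam, ["m0", "m1"], ["b0", "b1"], 0.8)
        assert len(recs) == 1
        assert recs[0].property_changes == []

    def test_unconserved_group_gives_no_record(self):
        # group B only 60% 'Y' at threshold 0.8
        fam = AlignedFamily(
            records=[(f"a{i}", "H") for i in range(5)]
            + [(f"b{i}", "Y" if i < 3 else "H") for i in range(5)],
            class_of={f"{c}{i}": "C" for c in "ab" for i in range(5)},
        )
        recs = detect_group_polymorphisms(
            fam, [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)], 0.8
        )
        assert recs == []

    def test_overlapping_groups_error(self, tiny_family):
        with pytest.raises(ConservationError):
            detect_group_polymorphisms(tiny_family, ["a1", "a2"], ["a2", "b1"])

    def test_perfect_recovery_at_zero_noise(self, planted_family):
        fam, truth = planted_family
        recs = detect_group_polymorphisms(
            fam,
            fam.members_of_clade("monocot"),
            fam.members_of_clade("brassicales"),
            0.8, TABLES,
        )
        found = {r.column for r in recs}
        assert found == set(truth.polymorphic_columns)

    def test_recall_decreases_with_noise(self):
        recalls = []
        planted = default_polymorphic_columns(5, 300)
        for noise in (0.0, 0.1, 0.3):
            hits = total = 0
            for seed in range(3):
                fam, truth = simulate_family(
                    FamilySpec(
                        planted_polymorphisms=planted, noise=noise, seed=seed
                    )
                )
                recs = detect_group_polymorphisms(
                    fam,
                    fam.members_of_clade("monocot"),
                    fam.members_of_clade("brassicales"),
                    0.8, TABLES,
                )
                found = {r.column for r in recs}
                hits += len(found & set(truth.polymorphic_columns))
                total += len(truth.polymorphic_columns)
            recalls.append(hits / total)
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]


# --------------------------------------------------------- column reports


class TestClassifyColumns:
    def _three_class_family(self):
        rows = {
            "GA3OX": "MKSVA",
            "GA20OX": "MKGTA",
            "GA2OX": "MKGCA",
        }
        records, class_of = [], {}
        for cls, row in rows.items():
            for i in range(3):
                sid = f"{cls}_{i}"
                records.append((sid, row))
                class_of[sid] = cls
        return AlignedFamily(records=records, class_of=class_of)

    def test_unanimous_column_core_conserved(self):
        fam = self._three_class_family()
        reports = classify_columns(fam, 0.8)
        assert reports[0].category == "core_conserved"  # all 'M'
        assert reports[0].shading == "100"

    def test_class_characteristic_column(self):
        fam = self._three_class_family()
        reports = classify_columns(fam, 0.8)
        # column 3: GA3OX 'S', the other two classes share 'G'
        assert reports[2].category == "class_characteristic"
        assert reports[2].detail == "GA3OX"
        # column 4: V/T/C all differ -> no class against shared background
        assert reports[3].category == "unconserved"

    @staticmethod
    def _by_clade_classes(fam):
        # classifier needs >= 2 classes; use the clades as the class labels
        return AlignedFamily(
            records=list(fam.records),
            class_of={sid: fam.clade_of[sid] for sid in fam.ids},
            clade_of=dict(fam.clade_of),
        )

    def test_clade_polymorphic_column_flagged(self, planted_family):
        fam, truth = planted_family
        reports = classify_columns(
            self._by_clade_classes(fam), 0.8, clades=("monocot", "brassicales")
        )
        by_col = {r.column: r for r in reports}
        for col in truth.polymorphic_columns:
            assert by_col[col].category == "clade_polymorphic"

    def test_pocket_flags_attached(self, planted_family):
        fam, _ = planted_family
        reports = classify_columns(
            self._by_clade_classes(fam), 0.8, pocket_flags={3: "substrate_contact"}
        )
        assert {r.column: r.pocket_flag for r in reports}[3] == "substrate_contact"

    def test_small_class_skipped_with_warning(self):
        fam = AlignedFamily(
            records=[("a1", "MK"), ("a2", "MK"), ("b1", "MK"), ("c1", "MR"),
                     ("c2", "MR")],
            class_of={"a1": "A", "a2": "A", "b1": "B", "c1": "C", "c2": "C"},
        )
        with pytest.warns(UserWarning, match="B"):
            reports = classify_columns(fam, 0.8)
        assert reports[0].category == "core_conserved"


def test_shading_bins_are_the_printed_ones():
    assert shading_bin(1.0) == "100"
    assert shading_bin(0.85) == "80-100"
    assert shading_bin(0.8) == "80-100"
    assert shading_bin(0.65) == "60-80"
    assert shading_bin(0.59) == "<60"
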