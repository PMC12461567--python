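"""Tuning-site screen: numbering, extraction, OH-rule, groups, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from opsinspec.sites import (
    DEFAULT_SITES,
    OH_RESIDUES,
    AlignedOpsinSet,
    classify_oh_substitution,
    extract_site_matrix,
    identical_profile_groups,
    lambda_table_stats,
    load_lambda_max_table,
    load_site_geometry,
    load_site_residues,
    map_numbering,
    predict_site_shifts,
    site_matrix_from_long,
)


class TestNumbering:
    def test_ungapped_reference_is_identity(self):
        aln = AlignedOpsinSet({"ref": "MKVL", "other": "MK-L"},
                              reference_id="ref")
        mapping = map_numbering(aln)
        assert mapping == {1: 0, 2: 1, 3: 2, 4: 3}

    def test_reference_gap_shifts_positions(self):
        # hand-checked: gap at column 2 means position 3 sits at column 3
        aln = AlignedOpsinSet({"ref": "MK-VL", "other": "MKAVL"},
                              reference_id="ref")
        mapping = map_numbering(aln)
        assert mapping == {1: 0, 2: 1, 3: 3, 4: 4}

    def test_roundtrip_on_nongap_columns(self):
        aln = AlignedOpsinSet({"ref": "M-KV-LA", "other": "MAKVALA"},
                              reference_id="ref")
        mapping = map_numbering(aln)
        inverse = {col: pos for pos, col in mapping.items()}
        for pos, col in mapping.items():
            assert inverse[col] == pos

    def test_missing_reference_rejected(self):
        aln = AlignedOpsinSet({"a": "MK", "b": "ML"}, reference_id="a")
        with pytest.raises(ValueError):
            map_numbering(aln, "zebrafish")


class TestSiteExtraction:
    def test_mouse_row_matches_packaged_residues(self, synthetic_alignment):
        matrix = extract_site_matrix(synthetic_alignment)
        assert matrix.loc["mouse", list(DEFAULT_SITES)].tolist() == \
            ["F", "T", "I", "A", "F", "S", "T", "S"]

    def test_platypus_red_shift_sites(self, synthetic_alignment):
        matrix = extract_site_matrix(synthetic_alignment)
        assert matrix.loc["platypus", 197] == "S"
        assert matrix.loc["platypus", 302] == "Y"

    def test_matches_brute_force_indexing(self):
        aln = AlignedOpsinSet({"ref": "MKV-LAQ", "two": "MRVWLAT"},
                              reference_id="ref")
        matrix = extract_site_matrix(aln, sites=(2, 4, 6))
        # brute force: walk the reference, counting non-gaps
        ref = aln.sequences["ref"]
        cols = [i for i, r in enumerate(ref) if r != "-"]
        for site in (2, 4, 6):
            assert matrix.loc["two", site] == aln.sequences["two"][cols[site - 1]]

    def test_site_beyond_reference_rejected(self, synthetic_alignment):
        with pytest.raises(ValueError, match="outside"):
            extract_site_matrix(synthetic_alignment, sites=(9999,))


class TestOhRule:
    def test_loss_of_serine_near_beta_ionone_is_blue(self):
        pred = classify_oh_substitution("S", "A", d_beta=2.5, d_rsb=12.1)
        assert pred.prediction == "blue"

    def test_gain_of_serine_near_beta_ionone_is_red(self):
        pred = classify_oh_substitution("A", "S", d_beta=9.8, d_rsb=16.4)
        assert pred.prediction == "red"

    def test_equidistant_site_predicts_nothing(self):
        pred = classify_oh_substitution("F", "S", d_beta=9.6, d_rsb=9.9)
        assert pred.prediction == "none"

    def test_oh_to_oh_substitution_predicts_nothing(self):
        pred = classify_oh_substitution("T", "S", d_beta=10.0, d_rsb=15.4)
        assert pred.prediction == "none"

    def test_loss_of_oh_near_schiff_base_is_red(self):
        pred = classify_oh_substitution("S", "N", d_beta=16.4, d_rsb=9.4)
        assert pred.prediction == "red"  # asparagine carries no OH group

    def test_red_blue_symmetry_over_all_residue_pairs(self):
        flip = {"red": "blue", "blue": "red", "none": "none"}
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for a, b in itertools.combinations(residues, 2):
            fwd = classify_oh_substitution(a, b, 4.0, 12.0).prediction
            rev = classify_oh_substitution(b, a, 4.0, 12.0).prediction
            assert rev == flip[fwd]

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            classify_oh_substitution("X", "S", 5.0, 10.0)

    def test_all_packaged_markers_reproduced(self):
        """Every annotated substitution in the packaged site table must be
        reproduced by the classifier at its default settings."""
        long = load_site_residues()
        geometry = load_site_geometry()
        mouse = long[long.species == "mouse"].set_index("site")["residue"]
        marked = long[(long.expected_shift != "") & (long.species != "mouse")]
        assert len(marked) > 0
        for _, row in marked.iterrows():
            geo = geometry.loc[row.site]
            pred = classify_oh_substitution(
                mouse[row.site], row.residue,
                d_beta=float(geo.d_beta_angstrom),
                d_rsb=float(geo.d_rsb_angstrom), site=int(row.site))
            assert pred.prediction == row.expected_shift, \
                f"{row.species} {pred.substitution}"


class TestProfileGroups:
    def test_packaged_tables_give_19nm_divergence(self, packaged_site_matrix):
        groups = identical_profile_groups(packaged_site_matrix,
                                          load_lambda_max_table())
        assert groups.max_range_nm == 19.0
        top = groups.groups.iloc[0]["species"].split(",")
        assert "reindeer" in top and "horseshoe bat" in top
        assert top == sorted(top)

    def test_all_distinct_profiles_are_singletons(self):
        matrix = pd.DataFrame({152: list("AST"), 155: list("TTT")},
                              index=["a", "b", "c"])
        matrix.index.name = "species"
        lmax = pd.DataFrame({"species": ["a", "b", "c"],
                             "lambda_max_nm": [470, 480, 490]})
        groups = identical_profile_groups(matrix, lmax)
        assert (groups.groups["n"] == 1).all()
        assert groups.max_range_nm == 0.0

    def test_toy_pair_gives_hand_computed_range(self):
        matrix = pd.DataFrame({152: list("AAB"), 155: list("TTT")},
                              index=["a", "b", "c"])
        lmax = pd.DataFrame({"species": ["a", "b", "c"],
                             "lambda_max_nm": [470, 490, 480]})
        groups = identical_profile_groups(matrix, lmax)
        assert groups.max_range_nm == 20.0

    def test_invariant_to_species_and_site_order(self, packaged_site_matrix):
        lmax = load_lambda_max_table()
        base = identical_profile_groups(packaged_site_matrix, lmax)
        shuffled = packaged_site_matrix.iloc[::-1, ::-1]
        again = identical_profile_groups(shuffled, lmax)
        assert again.max_range_nm == base.max_range_nm
        assert again.max_range_profile == base.max_range_profile

    def test_empty_overlap_rejected(self, packaged_site_matrix):
        lmax = pd.DataFrame({"species": ["zebrafish"], "lambda_max_nm": [470]})
        with pytest.raises(ValueError):
            identical_profile_groups(packaged_site_matrix, lmax)


class TestLambdaStats:
    def test_packaged_table_mean_and_range(self):
        stats = lambda_table_stats(load_lambda_max_table())
        assert stats.n_species == 22
        assert stats.mean_reported == 484.4
        assert stats.range_nm == 23.0
        assert stats.min_nm == 474.0 and stats.max_nm == 497.0

    def test_mean_agrees_with_independent_summation(self):
        table = load_lambda_max_table()
        stats = lambda_table_stats(table)
        total = 0.0
        for v in table["lambda_max_nm"]:
            total += float(v)
        assert stats.mean_nm == total / len(table)

    def test_platypus_shift_vs_mouse(self):
        stats = lambda_table_stats(load_lambda_max_table(),
                                   reference_species="mouse")
        assert stats.shifts_nm["platypus"] == 17.0

    def test_single_species_table(self):
        lmax = pd.DataFrame({"species": ["mouse"], "lambda_max_nm": [480.0]})
        stats = lambda_table_stats(lmax, reference_species="mouse")
        assert stats.range_nm == 0.0
        assert stats.shifts_nm["mouse"] == 0.0

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            lambda_table_stats(load_lambda_max_table(),
                               reference_species="axolotl")


class TestAlignmentScreen:
    def test_alignment_route_matches_packaged_matrix(self, synthetic_alignment,
                                                     packaged_site_matrix):
        matrix = extract_site_matrix(synthetic_alignment)
        pd.testing.assert_frame_equal(
            matrix.sort_index(), packaged_site_matrix.sort_index(),
            check_names=False)

    def test_predictions_cover_all_non_reference_deviations(
            self, packaged_site_matrix):
        preds = predict_site_shifts(packaged_site_matrix)
        mouse = packaged_site_matrix.loc["mouse"]
        expected = sum(
            (packaged_site_matrix.loc[sp] != mouse).sum()
            for sp in packaged_site_matrix.index if sp != "mouse")
        assert len(preds) == expected
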