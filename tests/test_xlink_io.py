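"""PSM table ingest, identification filtering, site-pair collapse."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from httxl.simulate import random_psm_table
from httxl.xlink_io import (
    ColumnError,
    CrosslinkPSM,
    FilterCriteria,
    SitePair,
    apply_identification_filters,
    collapse_to_site_pairs,
    read_psm_table,
    write_psm_table,
)


def make_psm(**overrides) -> CrosslinkPSM:
    base = dict(
        allele_label="Q23",
        spectrum_id="s1",
        score=20.0,
        delta_score=0.5,
        mass_error=3.5,
        tic_fraction=0.2,
        min_bond_cleavages=5,
        peptide_len_a=8,
        peptide_len_b=9,
        site_a=943,
        site_b=1559,
    )
    base.update(overrides)
    return CrosslinkPSM(**base)


class TestReadWrite:
    def test_well_formed_table_parses_row_per_record(self, tmp_path):
        path = tmp_path / "psms.tsv"
        write_psm_table([make_psm(spectrum_id=f"s{i}") for i in range(3)], path)
        psms, dropped = read_psm_table(path)
        assert len(psms) == 3
        assert dropped.empty

    def test_missing_score_column_is_named_in_error(self, tmp_path):
        path = tmp_path / "psms.tsv"
        write_psm_table([make_psm()], path)
        text = path.read_text().replace("score", "ldscore", 1)
        path.write_text(text)
        with pytest.raises(ColumnError, match="score"):
            read_psm_table(path)

    def test_dialect_remaps_foreign_headers(self, tmp_path):
        path = tmp_path / "psms.tsv"
        write_psm_table([make_psm()], path)
        path.write_text(path.read_text().replace("score", "ld_score", 1))
        psms, _ = read_psm_table(path, dialect={"score": "ld_score"})
        assert psms[0].score == 20.0

    def test_unparseable_rows_are_reported_not_dropped_silently(self, tmp_path):
        path = tmp_path / "psms.tsv"
        write_psm_table([make_psm(spectrum_id=f"s{i}") for i in range(2)], path)
        lines = path.read_text().splitlines()
        lines[2] = lines[2].replace("20.0", "n/a", 1)
        path.write_text("\n".join(lines) + "\n")
        psms, dropped = read_psm_table(path)
        assert len(psms) == 1
        assert len(dropped) == 1
        assert "drop_reason" in dropped.columns

    def test_simulator_table_round_trips_identically(self, tmp_path):
        original = random_psm_table(50, seed=3)
        path = tmp_path / "sim.tsv"
        write_psm_table(original, path)
        recovered, dropped = read_psm_table(path)
        assert dropped.empty
        assert recovered == original


class TestFilters:
    def test_psm_meeting_every_criterion_is_retained(self):
        assert apply_identification_filters([make_psm()]) == [make_psm()]

    def test_score_just_below_cutoff_is_removed(self):
        assert apply_identification_filters([make_psm(score=16.9)]) == []

    @pytest.mark.parametrize(
        "field, failing",
        [
            ("mass_error", 4.0),  # strict bound
            ("peptide_len_a", 5),
            ("peptide_len_b", 5),
            ("delta_score", 0.9),  # strict bound
            ("tic_fraction", 0.09),
            ("min_bond_cleavages", 3),
        ],
    )
    def test_each_criterion_excludes_on_its_own(self, field, failing):
        assert apply_identification_filters([make_psm(**{field: failing})]) == []

    @pytest.mark.parametrize(
        "field, passing",
        [("mass_error", -3.9), ("tic_fraction", 0.1), ("min_bond_cleavages", 4),
         ("score", 17.0), ("peptide_len_a", 6)],
    )
    def test_inclusive_boundaries_pass(self, field, passing):
        assert len(apply_identification_filters([make_psm(**{field: passing})])) == 1

    def test_empty_input_allowed(self):
        assert apply_identification_filters([]) == []

    def test_survivors_match_row_by_row_recheck(self):
        """Oracle: independent per-row re-check of each printed criterion."""
        psms = random_psm_table(1000, seed=11)
        got = apply_identification_filters(psms)
        expected = []
        for p in psms:  # brute-force restatement, one clause per criterion
            if abs(p.mass_error) >= 4:
                continue
            if p.peptide_len_a < 6 or p.peptide_len_b < 6:
                continue
            if p.delta_score >= 0.9:
                continue
            if p.tic_fraction < 0.1:
                continue
            if p.min_bond_cleavages < 4:
                continue
            if p.score < 17:
                continue
            expected.append(p)
        assert got == expected

    def test_filtering_is_idempotent(self):
        once = apply_identification_filters(random_psm_table(500, seed=5))
        assert apply_identification_filters(once) == once

    @given(
        seed=st.integers(0, 50),
        field=st.sampled_from(
            ["max_mass_error_ppm", "min_peptide_length", "max_delta_score",
             "min_tic", "min_bond_cleavages", "min_score"]
        ),
    )
    @settings(max_examples=40, deadline=None)
    def test_relaxing_any_single_threshold_is_monotone(self, seed, field):
        psms = random_psm_table(200, seed=seed)
        strict = FilterCriteria()
        sign = +1 if field.startswith("max") else -1
        relaxed = dataclasses.replace(
            strict, **{field: getattr(strict, field) + sign * 2}
        )
        assert len(apply_identification_filters(psms, relaxed)) >= len(
            apply_identification_filters(psms, strict)
        )


class TestCollapse:
    def test_duplicate_observations_merge_with_support(self):
        psms = [make_psm(spectrum_id="a"), make_psm(spectrum_id="b")]
        pairs, self_links = collapse_to_site_pairs(psms)
        assert pairs == [SitePair(943, 1559)]
        assert pairs[0].support == 2
        assert self_links == []

    def test_unordered_pairs_canonicalize(self):
        psms = [
            make_psm(site_a=178, site_b=174),
            make_psm(site_a=174, site_b=178),
        ]
        pairs, _ = collapse_to_site_pairs(psms)
        assert [(p.i, p.j) for p in pairs] == [(174, 178)]

    def test_self_links_are_excluded_and_reported(self):
        psms = [make_psm(), make_psm(site_a=100, site_b=100)]
        pairs, self_links = collapse_to_site_pairs(psms)
        assert len(pairs) == 1
        assert len(self_links) == 1

    def test_mixed_allele_labels_rejected(self):
        psms = [make_psm(), make_psm(allele_label="Q78")]
        with pytest.raises(ValueError, match="mixed allele"):
            collapse_to_site_pairs(psms)

    def test_support_totals_conserved_on_random_tables(self):
        psms = [p for p in random_psm_table(400, seed=9) if p.site_a != p.site_b]
        pairs, self_links = collapse_to_site_pairs(psms)
        assert len(pairs) <= len(psms)
        assert sum(p.support for p in pairs) == len(psms)
        assert not self_links

    def test_recovers_simulator_ground_truth(self, simulated):
        pairs, _ = collapse_to_site_pairs(
            apply_identification_filters(simulated.psms)
        )
        observed = {(p.i, p.j) for p in pairs}
        planted = {(p.i, p.j) for p in simulated.true_contacts} | {
            (p.i, p.j) for p in simulated.decoys
        }
        assert observed <= planted
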