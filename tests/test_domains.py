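"""Domain partition construction and crosslink-depletion detection."""

import numpy as np
import pytest

from httxl.domains import (
    CoverageProfile,
    build_partition,
    coverage_profile,
    detect_uncrosslinked_region,
)
from httxl.xlink_io import SitePair


class TestBuildPartition:
    def test_default_landmarks_give_printed_boundaries(self):
        part = build_partition()
        assert [(n, s, e) for n, s, e in part.segments] == [
            ("NTD-I", 1, 500),
            ("NTD-II", 501, 1219),
            ("CTD-I", 1220, 1799),
            ("UCD", 1800, 2300),
            ("CTD-II", 2301, 3144),
        ]
        assert part.hinge_midpoint == 1219

    def test_partition_covers_chain_exactly_once(self):
        part = build_partition()
        assert sum(e - s + 1 for _, s, e in part.segments) == part.chain_length

    def test_scaled_down_chain_still_covered(self):
        part = build_partition(100, 20, (38, 42), (60, 80))
        assert part.segments[0] == ("NTD-I", 1, 20)
        assert part.segments[-1][2] == 100
        assert sum(e - s + 1 for _, s, e in part.segments) == 100

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(minor_site=1200),  # at/after hinge start
            dict(ucd_interval=(1100, 2300)),  # UCD before hinge end
            dict(ucd_interval=(1800, 3144)),  # UCD reaches chain end
        ],
    )
    def test_landmark_ordering_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_partition(**{**dict(chain_length=3144), **kwargs})

    def test_domain_lookup_at_boundaries(self):
        part = build_partition()
        assert part.domain_of(500) == "NTD-I"
        assert part.domain_of(501) == "NTD-II"
        assert part.domain_of(1219) == "NTD-II"
        assert part.domain_of(1220) == "CTD-I"
        assert part.domain_of(3144) == "CTD-II"

    def test_bed_like_export_is_one_based_inclusive(self, tmp_path):
        part = build_partition()
        path = tmp_path / "partition.txt"
        part.to_bed_like(path)
        rows = [l.split("\t") for l in path.read_text().splitlines() if not l.startswith("#")]
        assert rows[0] == ["NTD-I", "1", "500"]
        assert rows[-1] == ["CTD-II", "2301", "3144"]


class TestCoverageProfile:
    def test_single_pair_window_one(self):
        profile = coverage_profile([SitePair(10, 3000)], 3144, window=1)
        nonzero = np.nonzero(profile.counts)[0] + 1
        assert set(nonzero) == {9, 10, 11, 2999, 3000, 3001}

    def test_empty_contacts_all_zero(self):
        profile = coverage_profile([], 3144, window=25)
        assert not profile.counts.any()

    def test_matches_brute_force_window_count(self, simulated):
        pairs = list(simulated.true_contacts)
        w = 25
        profile = coverage_profile(pairs, 3144, window=w)
        endpoints = []
        for p in pairs:
            endpoints += [p.i, p.j]
        for r in [1, 100, 1219, 1800, 2300, 3000, 3144]:
            brute = sum(1 for e in endpoints if r - w <= e <= r + w)
            assert profile.counts[r - 1] == brute

    def test_window_larger_than_chain_rejected(self):
        with pytest.raises(ValueError):
            coverage_profile([], 40, window=25)


class TestDetectUncrosslinked:
    def test_uniformly_dense_profile_yields_nothing(self):
        profile = CoverageProfile(
            counts=np.full(1000, 5), window=10, lysine_mask=np.ones(1000, bool)
        )
        assert detect_uncrosslinked_region(profile) == []

    def test_crosslink_free_chain_with_lysines_is_one_full_interval(self):
        profile = CoverageProfile(
            counts=np.zeros(1000, int), window=10, lysine_mask=np.ones(1000, bool)
        )
        assert detect_uncrosslinked_region(profile) == [(1, 1000)]

    def test_interval_never_overlaps_involved_residues(self):
        counts = np.zeros(2000, int)
        counts[:700] = 4
        counts[1500:] = 4
        mask = np.zeros(2000, bool)
        mask[700:1500:40] = True
        (iv,) = detect_uncrosslinked_region(
            CoverageProfile(counts=counts, window=10, lysine_mask=mask)
        )
        assert counts[iv[0] - 1 : iv[1]].max() <= 1

    def test_boundaries_land_in_uninformative_gap_midpoint(self):
        counts = np.zeros(2000, int)
        counts[:700] = 4
        counts[1500:] = 4
        mask = np.zeros(2000, bool)
        mask[800] = mask[1100] = mask[1400] = True
        (iv,) = detect_uncrosslinked_region(
            CoverageProfile(counts=counts, window=10, lysine_mask=mask)
        )
        # raw run is [701, 1500]; lysine evidence spans [801, 1401];
        # boundaries at the midpoints of the uninformative gaps
        assert iv == ((700 + 800) // 2 + 1, (1400 + 1500) // 2 + 1)

    def test_too_few_lysines_disqualifies_a_run(self):
        counts = np.zeros(1000, int)
        mask = np.zeros(1000, bool)
        mask[500] = True
        profile = CoverageProfile(counts=counts, window=10, lysine_mask=mask)
        assert detect_uncrosslinked_region(profile, min_lysines=3) == []

    def test_short_runs_are_ignored(self):
        counts = np.full(1000, 5)
        counts[400:500] = 0
        mask = np.ones(1000, bool)
        profile = CoverageProfile(counts=counts, window=10, lysine_mask=mask)
        assert detect_uncrosslinked_region(profile, min_span=300) == []

    def test_lysine_mask_required(self):
        profile = CoverageProfile(counts=np.zeros(100, int), window=5)
        with pytest.raises(ValueError):
            detect_uncrosslinked_region(profile)
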