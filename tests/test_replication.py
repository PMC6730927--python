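import numpy as np
import pytest

from asmob.errors import ReplicationError
from asmob.mag_qc import MagQuality
from asmob.records import SamRecordLite
from asmob.replication import (
    CoverageProfile,
    ReplicationConfig,
    depth_array,
    eligible_mags,
    estimate_irep,
    irep_by_function,
    window_coverage,
    windows_from_depth,
)
from asmob.synthetic import sample_positions

from .oracles import window_means_oracle


def _sam(reads, contig="c1"):
    return [
        SamRecordLite(read_id=f"r{i}", ref_id=contig, pos=p, read_len=l, mapped=True)
        for i, (p, l) in enumerate(reads)
    ]


class TestWindowCoverage:
    def test_uniform_depth_gives_uniform_windows(self):
        # back-to-back reads of length 100 tile the contig at depth 1
        reads = [(p, 100) for p in range(1, 10_001, 100)] * 10
        profiles = window_coverage(
            _sam(reads), {"c1": 10_000}, {"c1": "M1"},
            ReplicationConfig(window_size=1000, step=100, min_windows=10),
        )
        np.testing.assert_allclose(profiles["M1"].window_means, 10.0)

    def test_boundary_window_count(self):
        config = ReplicationConfig(window_size=5000, step=100)
        profiles = window_coverage(
            _sam([(1, 100)]), {"c1": 5000}, {"c1": "M1"}, config
        )
        assert profiles["M1"].window_means.size == 1

    def test_window_count_formula(self):
        config = ReplicationConfig(window_size=5000, step=100)
        profiles = window_coverage(
            _sam([(1, 100)]), {"c1": 14_000}, {"c1": "M1"}, config
        )
        assert profiles["M1"].window_means.size == (14_000 - 5000) // 100 + 1

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(19)
        L = 4000
        reads = [
            (int(rng.integers(1, L - 50)), int(rng.integers(30, 150)))
            for _ in range(300)
        ]
        config = ReplicationConfig(window_size=500, step=77, min_windows=1)
        profiles = window_coverage(_sam(reads), {"c1": L}, {"c1": "M1"}, config)
        expected = window_means_oracle(L, reads, 500, 77)
        np.testing.assert_allclose(profiles["M1"].window_means, expected)

    def test_fragmented_mag_is_an_error(self):
        with pytest.raises(ReplicationError, match="too fragmented"):
            window_coverage(
                _sam([(1, 100)]), {"c1": 900}, {"c1": "M1"},
                ReplicationConfig(window_size=5000, step=100),
            )


class TestEstimate:
    def test_exactly_uniform_coverage_is_flat(self):
        est = estimate_irep(CoverageProfile("M", np.full(500, 25.0)))
        assert est.slope == 0.0 and est.irep == 1.0 and est.reliable

    def test_doubling_coverage_leaves_irep_unchanged(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 2000)
        w = 40 * 2.0 ** (1 - x) * (1 + 0.02 * rng.standard_normal(x.size))
        a = estimate_irep(CoverageProfile("M", w))
        b = estimate_irep(CoverageProfile("M", 2 * w))
        assert b.irep == pytest.approx(a.irep, rel=1e-9)
        assert b.slope == pytest.approx(a.slope, rel=1e-9)

    def test_contig_orientation_is_irrelevant(self):
        """Origin/terminus orientation of a contig is unknown; reversing the
        genomic-order profile must not move the estimate."""
        x = np.linspace(0, 1, 1500)
        w = 30 * 1.7 ** (1 - x)
        a = estimate_irep(CoverageProfile("M", w))
        b = estimate_irep(CoverageProfile("M", w[::-1].copy()))
        assert b.irep == pytest.approx(a.irep, rel=1e-9)

    def test_direct_synthesis_recovers_ptr_two(self):
        # window values follow c(x) = c_min * p^x along the genome, with
        # window positions drawn uniformly on [0, 1]
        rng = np.random.default_rng(12)
        x = np.sort(rng.random(19_951))
        w = 100.0 * 2.0**x
        est = estimate_irep(CoverageProfile("M", w))
        assert 1.9 <= est.irep <= 2.1

    def test_read_sampled_recovery_within_five_percent(self):
        rng = np.random.default_rng(9)
        L, depth, rl = 500_000, 50, 100
        config = ReplicationConfig()
        for ptr in (1.0, 2.0):
            n = int(depth * L / rl)
            pos = sample_positions(rng, n, ptr, L) + 1
            d = depth_array(L, pos, np.full(n, rl))
            w = windows_from_depth(d, config.window_size, config.step)
            est = estimate_irep(CoverageProfile("M", w), config)
            assert est.irep == pytest.approx(ptr, rel=0.05)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ReplicationError, match="need >= 50"):
            estimate_irep(CoverageProfile("M", np.full(30, 5.0)))

    def test_zero_coverage_window_rejected(self):
        w = np.concatenate([np.zeros(20), np.full(200, 5.0)])
        with pytest.raises(ReplicationError, match="zero-coverage"):
            estimate_irep(CoverageProfile("M", w))


class TestEligibility:
    @pytest.mark.parametrize(
        "completeness,contamination,expected",
        [(80.0, 2.9, True), (80.0, 3.0, False), (74.9, 1.0, False), (75.0, 0.0, True)],
    )
    def test_gate(self, completeness, contamination, expected):
        q = MagQuality("M", completeness, contamination, "medium")
        assert (("M" in eligible_mags([q])) is expected)

    def test_strict_config_available(self):
        q = MagQuality("M", 90.0, 2.5, "high")
        assert "M" in eligible_mags([q])
        assert "M" not in eligible_mags([q], ReplicationConfig(max_contamination=2.0))


class TestGrouping:
    def test_mag_contributes_to_every_encoded_function(self):
        from asmob.replication import ReplicationEstimate

        est = ReplicationEstimate("M1", 0.5, 2**0.5, 0.99, True, 100)
        table = irep_by_function([est], {"M1": {"arrA", "dsrD"}})
        assert sorted(table["function"]) == ["arrA", "dsrD"]
        assert np.allclose(table["log_irep"], np.log(2**0.5))

    def test_empty_inputs_empty_table(self):
        assert irep_by_function([], {}).empty
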