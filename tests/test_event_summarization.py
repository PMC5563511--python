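import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdetect.event_summarization import (
    detect_events,
    event_statistic,
    irwin_hall_cdf,
    irwin_hall_pvalue,
    results_frame,
    summarize_event,
)
from asdetect.splice_model import EventDefinition, EventType, enumerate_all_events
from asdetect.synthetic_data import SimConfig, design_groups, simulate_counts, simulate_gene_models
from asdetect.term_inference import DesignSpec


def cassette_event(n_skip=2):
    return EventDefinition(
        "ev", "g", EventType.CASSETTE_EXON,
        ("h1", "h2", "h3"), tuple(f"s{i}" for i in range(n_skip)),
    )


IR_EVENT = EventDefinition("ir", "g", EventType.INTRON_RETENTION, ("h1",), ("s0",))


class TestEventStatistic:
    def test_direct_sum(self):
        p = {"h1": 0.01, "h2": 0.02, "h3": 0.03, "s0": 0.98, "s1": 0.99}
        assert event_statistic(p, cassette_event()) == pytest.approx(0.09, abs=1e-12)

    def test_null_center(self):
        p = dict.fromkeys(["h1", "h2", "h3", "s0", "s1"], 0.5)
        assert event_statistic(p, cassette_event()) == pytest.approx(2.5, abs=1e-12)

    def test_extreme_zero(self):
        assert event_statistic({"h1": 0.0, "s0": 1.0}, IR_EVENT) == 0.0

    def test_missing_term_is_an_error(self):
        with pytest.raises(KeyError, match="s0"):
            event_statistic({"h1": 0.1}, IR_EVENT)

    @given(st.permutations([0.11, 0.52, 0.93]))
    @settings(deadline=None)
    def test_invariant_under_permutation_within_sets(self, hs):
        base = {"h1": 0.11, "h2": 0.52, "h3": 0.93, "s0": 0.3, "s1": 0.7}
        perm = dict(zip(["h1", "h2", "h3"], hs)) | {"s0": 0.7, "s1": 0.3}
        ev = cassette_event()
        assert event_statistic(base, ev) == pytest.approx(event_statistic(perm, ev), abs=1e-12)


class TestIrwinHallCdf:
    @pytest.mark.parametrize("x,n,expected", [
        (0.05, 1, 0.05),
        (0.4, 2, 0.08),          # x^2/2
        (1.0, 5, 1.0 / 120.0),   # 1/n!
    ])
    def test_lower_tail_closed_form(self, x, n, expected):
        assert irwin_hall_cdf(x, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", range(1, 13))
    def test_boundary_and_symmetry(self, n):
        assert irwin_hall_cdf(0.0, n) == 0.0
        assert irwin_hall_cdf(float(n), n) == 1.0
        assert irwin_hall_cdf(n / 2.0, n) == pytest.approx(0.5, abs=1e-12)
        for x in np.linspace(0.05, n - 0.05, 17):
            assert irwin_hall_cdf(x, n) + irwin_hall_cdf(n - x, n) == pytest.approx(
                1.0, abs=1e-10)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_strictly_increasing(self, n):
        grid = np.linspace(1e-6, n - 1e-6, 200)
        vals = [irwin_hall_cdf(x, n) for x in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_monte_carlo_agreement(self, rng):
        """Empirical CDF of sums of uniforms matches the closed form."""
        n_draws = 200_000
        for n in (2, 3, 4):
            sums = rng.random((n_draws, n)).sum(axis=1)
            for x in (0.5, 1.0, n / 2.0, n - 1.0):
                emp = np.mean(sums <= x)
                f = irwin_hall_cdf(x, n)
                se = math.sqrt(max(f * (1 - f), 1e-12) / n_draws)
                assert abs(emp - f) < 3 * se + 1e-9

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="x must be"):
            irwin_hall_cdf(-0.1, 3)
        with pytest.raises(ValueError, match="x must be"):
            irwin_hall_cdf(3.1, 3)
        with pytest.raises(ValueError, match="n must be"):
            irwin_hall_cdf(1.0, 13)


class TestIrwinHallPvalue:
    def test_lower_tail_doubling(self):
        p, direction = irwin_hall_pvalue(1.0, 5)
        assert p == pytest.approx(2.0 / 120.0, abs=1e-12)
        assert direction == "spliced_in"

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_median_gives_p_one(self, n):
        p, _ = irwin_hall_pvalue(n / 2.0, n)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_upper_tail(self):
        p, direction = irwin_hall_pvalue(2.9, 3)
        assert p == pytest.approx(2 * 0.1 ** 3 / 6.0, abs=1e-12)
        assert direction == "spliced_out"

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=60)
    def test_swapping_sets_preserves_p_and_flips_direction(self, a, b):
        ev = EventDefinition("e", "g", EventType.INTRON_RETENTION, ("a",), ("b",))
        swapped = EventDefinition("e", "g", EventType.INTRON_RETENTION, ("b",), ("a",))
        p = {"a": a, "b": b}
        x = event_statistic(p, ev)
        x_sw = event_statistic(p, swapped)
        assert x_sw == pytest.approx(2 - x, abs=1e-9)
        pv, d = irwin_hall_pvalue(min(max(x, 0), 2), 2)
        pv_sw, d_sw = irwin_hall_pvalue(min(max(x_sw, 0), 2), 2)
        assert pv == pytest.approx(pv_sw, abs=1e-9)
        if abs(irwin_hall_cdf(min(max(x, 0), 2), 2) - 0.5) > 1e-9:
            assert d != d_sw


class TestDetectEvents:
    @pytest.fixture()
    def planted_study(self):
        cfg = SimConfig(seed=101, n_genes=30, exons_per_gene=(3, 3),
                        cassette_fraction=0.5, ir_fraction=0.0, effect_size=4.0)
        graphs = simulate_gene_models(cfg)
        counts, truth = simulate_counts(graphs, cfg)
        events = enumerate_all_events(graphs)
        spec = DesignSpec.from_groups(design_groups(cfg), "B - A")
        return counts, events, spec, truth

    def test_planted_events_detected_with_direction(self, planted_study):
        counts, events, spec, truth = planted_study
        results, _ = detect_events(counts, events, spec, alpha=0.05)
        detected = {r.event_id: r.direction for r in results}
        hits = [e for e in truth.events["event_id"] if e in detected]
        assert len(hits) / len(truth.events) >= 0.9
        true_dir = dict(zip(truth.events["event_id"], truth.events["direction"]))
        assert all(detected[e] == true_dir[e] for e in hits)

    def test_label_permutation_flips_direction(self, planted_study):
        counts, events, spec, truth = planted_study
        res_fwd, _ = detect_events(counts, events, spec, alpha=0.05)
        res_rev, _ = detect_events(counts, events, spec.negated(), alpha=0.05)
        fwd = {r.event_id: r.direction for r in res_fwd}
        rev = {r.event_id: r.direction for r in res_rev}
        shared = set(fwd) & set(rev)
        assert shared
        assert all(fwd[e] != rev[e] for e in shared)

    def test_output_sorted_by_p(self, planted_study):
        counts, events, spec, _ = planted_study
        results, _ = detect_events(counts, events, spec, alpha=1.0, keep_all=True)
        ps = [r.p_overall for r in results]
        assert ps == sorted(ps)

    def test_bh_correction_is_monotone_and_larger(self, planted_study):
        counts, events, spec, _ = planted_study
        res, _ = detect_events(counts, events, spec, alpha=1.0, correction="bh",
                               keep_all=True)
        with_adj = [r for r in res if r.p_adjusted is not None]
        assert with_adj
        assert all(r.p_adjusted >= r.p_overall - 1e-15 for r in with_adj)

    def test_results_frame_columns(self, planted_study):
        counts, events, spec, _ = planted_study
        res, _ = detect_events(counts, events, spec, alpha=0.05)
        df = results_frame(res)
        assert list(df.columns)[:4] == ["event_id", "gene_id", "event_type", "n"]
        assert (df["p_overall"] <= 0.05).all()

    def test_summarize_event_consistency(self):
        p = {"h1": 0.01, "s0": 0.99}
        res = summarize_event(p, IR_EVENT)
        assert res.x_e == pytest.approx(0.02)
        assert res.n_terms == 2
        assert res.direction == "spliced_in"
        assert res.p_overall == pytest.approx(2 * 0.02 ** 2 / 2, abs=1e-12)
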