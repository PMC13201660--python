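"""Modification calling, site stoichiometry, filtering and signal summaries."""

import math
import random

import numpy as np
import pandas as pd
import pytest

import riboslicer as rl


class TestCallModified:
    @pytest.mark.parametrize(
        "prob,expected", [(0.94, False), (0.95, True), (0.96, True)]
    )
    def test_threshold_boundary_inclusive(self, prob, expected):
        assert rl.call_modified({10: prob})[10] is expected

    def test_empty_map_gives_no_calls(self):
        assert rl.call_modified({}) == {}

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            rl.call_modified({3: 1.5})


def _mod_readset(probs_per_read, start=0, end=100, ref_length=400, **kw):
    records = [
        rl.ReadRecord(f"m{i}", start, end, mod_probs=dict(p))
        for i, p in enumerate(probs_per_read)
    ]
    return rl.ReadSet(records, ref_length=ref_length, **kw)


class TestSiteStoichiometry:
    def test_fraction_of_probability_carrying_reads(self):
        rs = _mod_readset([{50: 0.99}] * 6 + [{50: 0.01}] * 4)
        table = rl.site_stoichiometry(rs)
        row = table.set_index("position").loc[51]
        assert row.mod_ratio == pytest.approx(0.6)
        assert row.n_prob_reads == 10

    def test_position_without_records_absent_not_zero(self):
        rs = _mod_readset([{50: 0.99}] * 5)
        table = rl.site_stoichiometry(rs)
        assert 61 not in set(table.position)

    def test_low_coverage_flagged(self):
        rs = _mod_readset([{50: 0.99}] * 5)
        table = rl.site_stoichiometry(rs, rl.ModConfig(min_coverage=30))
        assert bool(table.iloc[0].low_coverage)

    def test_mismatch_ratio_excludes_deletions(self, small_ref):
        upos = small_ref.sequence.find("T", 50, 150)
        records = []
        for i in range(10):
            if i < 3:
                records.append(rl.ReadRecord(f"c{i}", 0, 200, basecalls={upos: "C"},
                                             has_sequence=True, mod_probs={upos: 0.99}))
            elif i < 5:
                records.append(rl.ReadRecord(f"d{i}", 0, 200,
                                             deletions=[(upos, 1)], has_sequence=True))
            else:
                records.append(rl.ReadRecord(f"u{i}", 0, 200, has_sequence=True,
                                             mod_probs={upos: 0.99}))
        rs = rl.ReadSet(records, ref_length=small_ref.length)
        pileup = rl.mismatch_pileup(rs, small_ref)
        table = rl.site_stoichiometry(rs, rl.ModConfig(min_coverage=5),
                                      pileup=pileup, ref=small_ref)
        row = table.set_index("position").loc[upos + 1]
        # 3 C calls among 10 - 2 deleted = 8 informative bases
        assert row.mismatch_c_ratio == pytest.approx(3 / 8)

    def test_invariant_under_read_order(self):
        probs = [{50: 0.99}, {50: 0.01}, {50: 0.97}, {60: 0.5}] * 5
        rs1 = _mod_readset(probs)
        shuffled = probs[:]
        random.Random(1).shuffle(shuffled)
        rs2 = _mod_readset(shuffled)
        t1 = rl.site_stoichiometry(rs1).drop(columns=["condition"])
        t2 = rl.site_stoichiometry(rs2).drop(columns=["condition"])
        pd.testing.assert_frame_equal(t1, t2)

    def test_ratio_monotone_in_prob_threshold(self):
        rng = np.random.default_rng(12)
        probs = [{50: float(p)} for p in rng.random(200)]
        rs = _mod_readset(probs)
        ratios = [
            rl.site_stoichiometry(rs, rl.ModConfig(prob_threshold=t)).iloc[0].mod_ratio
            for t in (0.2, 0.5, 0.8, 0.95, 0.99)
        ]
        assert ratios == sorted(ratios, reverse=True)


class TestFilterSites:
    def _stoich(self, ratios_by_cond):
        frames = []
        for cond, ratios in ratios_by_cond.items():
            frames.append(
                pd.DataFrame(
                    {
                        "position": list(ratios),
                        "mod_ratio": list(ratios.values()),
                        "mismatch_c_ratio": np.nan,
                        "coverage": 500,
                        "n_prob_reads": 500,
                        "condition": cond,
                        "precursor": "all",
                        "low_coverage": False,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_retained_when_any_condition_reaches_threshold(self):
        df = self._stoich({"nuc": {100: 0.12}, "cyt": {100: 0.08}})
        assert rl.filter_sites(df) == [100]

    def test_removed_when_below_in_every_condition(self):
        df = self._stoich({"nuc": {100: 0.05}, "cyt": {100: 0.08}})
        assert rl.filter_sites(df) == []

    @pytest.mark.parametrize("ratio,kept", [(0.10, True), (0.0999, False)])
    def test_boundary_is_inclusive(self, ratio, kept):
        df = self._stoich({"a": {7: ratio}})
        assert (rl.filter_sites(df) == [7]) is kept

    def test_per_condition_mode(self):
        df = self._stoich({"nuc": {100: 0.12, 200: 0.5}, "cyt": {100: 0.08, 200: 0.4}})
        assert rl.filter_sites(df, per_condition=True) == [200]

    def test_ivt_alone_yields_nothing(self):
        df = self._stoich({"IVT": {100: 0.0, 200: 0.01, 300: 0.0}})
        assert rl.filter_sites(df) == []

    def test_planted_separation_across_seeds(self, small_ref):
        """Sites at stoichiometry >= 0.5 vs an IVT control at 0: the filter
        retains exactly the modified set, with no IVT false positives."""
        ts = rl.TemplateSet([rl.TemplateEntry("A", 1, 400, "mature")], ref_length=400)
        seq = np.frombuffer(small_ref.sequence.encode(), dtype="S1")
        upos = [int(p) + 1 for p in np.flatnonzero(seq == b"T")[:5]]
        for seed in range(20):
            planted = [(p, 0.5 + 0.5 * (i % 2)) for i, p in enumerate(upos)]
            cfg = rl.SimConfig(seed=seed, n_reads=100,
                               template_proportions={"A": 1.0},
                               planted_sites=planted)
            mod = rl.simulate_modifications(
                rl.simulate_reads(ts, cfg, 400).reads, cfg, small_ref
            )
            ivt_cfg = rl.SimConfig(seed=seed + 1000, n_reads=100,
                                   template_proportions={"A": 1.0})
            ivt = rl.simulate_modifications(
                rl.simulate_reads(ts, ivt_cfg, 400).reads, ivt_cfg, small_ref
            )
            cfg_mod = rl.ModConfig(min_coverage=50)
            stoich = {
                "mod": rl.site_stoichiometry(mod, cfg_mod, condition="mod"),
                "IVT": rl.site_stoichiometry(ivt, cfg_mod, condition="IVT"),
            }
            assert rl.filter_sites(stoich, cfg_mod) == sorted(upos)


class TestStoichiometryRecovery:
    @pytest.mark.parametrize("target", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_planted_ratio_recovered_within_binomial_error(self, target):
        ref = rl.make_reference(length=2000, seed=5, name="r2k")
        ts = rl.TemplateSet([rl.TemplateEntry("A", 1, 2000, "mature")], 2000)
        seq = np.frombuffer(ref.sequence.encode(), dtype="S1")
        site = int(np.flatnonzero(seq == b"T")[100]) + 1
        cfg = rl.SimConfig(seed=31, n_reads=500, template_proportions={"A": 1.0},
                           planted_sites=[(site, target)])
        rs = rl.simulate_modifications(
            rl.simulate_reads(ts, cfg, 2000).reads, cfg, ref
        )
        table = rl.site_stoichiometry(rs)
        got = table.set_index("position").loc[site].mod_ratio
        # oracle: a modified read draws prob ~ N(0.99, 0.02) and is called
        # modified iff >= 0.95, so detection sensitivity is Phi(2) ~ 0.977
        from scipy.stats import norm

        expected = target * norm.sf((0.95 - 0.99) / 0.02)
        tol = 3 * math.sqrt(max(expected * (1 - expected), 1e-4) / 500)
        assert abs(got - expected) <= tol


class TestPrecursorStoichiometry:
    def _setup(self):
        ref = rl.make_reference(length=1000, seed=6, name="r1k")
        ts = rl.TemplateSet(
            [rl.TemplateEntry("LONG", 1, 1000, "precursor"),
             rl.TemplateEntry("SHORT", 1, 400, "precursor")],
            ref_length=1000,
        )
        seq = np.frombuffer(ref.sequence.encode(), dtype="S1")
        upos_all = np.flatnonzero(seq == b"T")
        inside_short = int(upos_all[upos_all < 380][10]) + 1
        outside_short = int(upos_all[upos_all > 500][10]) + 1
        return ref, ts, inside_short, outside_short

    def test_rows_respect_precursor_intervals(self):
        ref, ts, inside, outside = self._setup()
        cfg = rl.SimConfig(seed=8, n_reads=400,
                           template_proportions={"LONG": 0.5, "SHORT": 0.5},
                           planted_sites=[(inside, 1.0), (outside, 1.0)])
        rs = rl.simulate_modifications(
            rl.simulate_reads(ts, cfg, 1000).reads, cfg, ref
        )
        asg = rl.assign_reads(rs, ts)
        mat = rl.precursor_stoichiometry(rs, asg, ts, sites=[inside, outside])
        assert mat.loc["LONG", inside] == pytest.approx(1.0, abs=0.05)
        assert mat.loc["LONG", outside] == pytest.approx(1.0, abs=0.05)
        assert math.isnan(mat.loc["SHORT", outside])  # outside its interval

    def test_hypomodified_species_stand_out(self):
        """An aberrant species planted at low stoichiometry shows a markedly
        lower row than the faithfully modified precursor (34S/36S-C picture)."""
        ref, ts, inside, _ = self._setup()
        cfg_hi = rl.SimConfig(seed=9, n_reads=300, template_proportions={"LONG": 1.0},
                              planted_sites=[(inside, 0.9)])
        cfg_lo = rl.SimConfig(seed=10, n_reads=300, template_proportions={"SHORT": 1.0},
                              planted_sites=[(inside, 0.1)])
        hi = rl.simulate_modifications(rl.simulate_reads(ts, cfg_hi, 1000).reads,
                                       cfg_hi, ref)
        lo = rl.simulate_modifications(rl.simulate_reads(ts, cfg_lo, 1000).reads,
                                       cfg_lo, ref)
        rs = rl.ReadSet(hi.records + lo.records, ref_length=1000)
        asg = rl.assign_reads(rs, ts)
        mat = rl.precursor_stoichiometry(rs, asg, ts, sites=[inside])
        assert mat.loc["LONG", inside] > 0.8
        assert mat.loc["SHORT", inside] < 0.2

    def test_all_row_is_coverage_weighted_mean(self):
        ref, ts, inside, outside = self._setup()
        cfg = rl.SimConfig(seed=12, n_reads=500,
                           template_proportions={"LONG": 0.6, "SHORT": 0.4},
                           planted_sites=[(inside, 0.7)])
        rs = rl.simulate_modifications(
            rl.simulate_reads(ts, cfg, 1000).reads, cfg, ref
        )
        asg = rl.assign_reads(rs, ts)
        mat = rl.precursor_stoichiometry(rs, asg, ts, sites=[inside])
        # weights: number of probability-carrying reads per precursor
        groups = {}
        for a, r in zip(asg, rs.records):
            groups.setdefault(a.template, []).append(r)
        num = den = 0.0
        for name, recs in groups.items():
            n = sum(1 for r in recs if r.mod_probs and (inside - 1) in r.mod_probs)
            if n:
                num += mat.loc[name, inside] * n
                den += n
        assert mat.loc["all", inside] == pytest.approx(num / den)


class TestSignalWindowSummary:
    def _table(self, values_by_offset):
        rows = []
        for off, vals in values_by_offset.items():
            for i, v in enumerate(vals):
                rows.append({"read_id": f"r{i}", "offset": off, "z_mean": v})
        return pd.DataFrame(rows)

    def test_constant_signal_gives_zero_summary(self):
        table = self._table({off: [0.0, 0.0, 0.0] for off in range(-10, 11)})
        s = rl.signal_window_summary(table, locus=100)
        assert np.allclose(s.mean_of_means, 0)
        assert np.allclose(s.semi_sd_lower, 0)
        assert np.allclose(s.semi_sd_upper, 0)
        assert s.n_reads == 3

    def test_window_covers_exactly_21_offsets(self):
        table = self._table({off: [0.1] for off in range(-10, 11)})
        assert len(rl.signal_window_summary(table, 5).offsets) == 21

    def test_asymmetric_semi_deviations(self):
        # means {-1,-1,2}: mean 0, lower semi-SD 1 (from the two -1s),
        # upper semi-SD 2 (from the single +2)
        vals = {off: [0.0, 0.0, 0.0] for off in range(-10, 11)}
        vals[0] = [-1.0, -1.0, 2.0]
        s = rl.signal_window_summary(self._table(vals), 7)
        i = list(s.offsets).index(0)
        assert s.mean_of_means[i] == pytest.approx(0.0)
        assert s.semi_sd_lower[i] == pytest.approx(1.0)
        assert s.semi_sd_upper[i] == pytest.approx(2.0)

    def test_missing_offsets_rejected(self):
        table = self._table({off: [0.1] for off in range(-10, 10)})  # missing +10
        with pytest.raises(ValueError, match="missing offsets"):
            rl.signal_window_summary(table, 3)

    def test_no_reads_rejected(self):
        with pytest.raises(ValueError, match="no reads"):
            rl.signal_window_summary(
                pd.DataFrame(columns=["read_id", "offset", "z_mean"]), 3
            )
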