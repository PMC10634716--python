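import numpy as np
import pandas as pd
import pytest

from conftest import make_contact_frame
from factorfinder import extrusion as ex
from factorfinder.fragments import ClassParams
from factorfinder.synthetic import recovery_config, simulate_dataset
from factorfinder.types import GenomicInterval, Motif, SignalPeak


def motif_at(center, strand="+", chrom="chrT"):
    return Motif(GenomicInterval(chrom, center - 9, center + 10, strand))


class TestPsCurve:
    def test_single_length_single_bin(self):
        curve = ex.ps_curve(np.full(500, 50_000.0))
        assert (curve.counts > 0).sum() == 1

    def test_normalization_any_input(self):
        rng = np.random.default_rng(1)
        curve = ex.ps_curve(rng.uniform(2e3, 5e6, 10_000))
        assert np.isclose((curve.freq * curve.widths).sum(), 1.0)

    def test_power_law_slope_recovered(self):
        rng = np.random.default_rng(2)
        u = rng.random(300_000)
        s = 1e4 * (1e6 / 1e4) ** u  # density proportional to 1/s
        curve = ex.ps_curve(s, s_min=1e4, s_max=1e6)
        assert ex.ps_curve(s, s_min=1e4, s_max=1e6).loglog_slope() == \
            pytest.approx(-1.0, abs=0.05)
        assert curve.loglog_slope() == pytest.approx(-1.0, abs=0.05)

    def test_no_cis_contacts_rejected(self):
        with pytest.raises(ValueError):
            ex.ps_curve(np.array([]))


def _convergence_fixture(n_total=100, n_conv=10, n_at_cbs2=0):
    """One '+' CBS at 50 kb; partners 20 kb downstream; n_conv of them on a
    '-' motif. Optionally a second, shallow CBS."""
    c = 50_000
    rows = []
    for i in range(n_total):
        conv = i < n_conv
        partner = 70_000 if conv else 70_500 + 137 * i
        rows.append((c - 20, "+", 40, partner, "+", 40))
    for i in range(n_at_cbs2):
        rows.append((200_000 - 20, "+", 40, 230_000 + 91 * i, "+", 40))
    frame = make_contact_frame(rows)
    cbs = [motif_at(c)] + ([motif_at(200_000)] if n_at_cbs2 else [])
    minus = [motif_at(70_000, "-")]
    return frame, cbs, minus


class TestFullyExtruded:
    def test_point_formula(self):
        frame, cbs, minus = _convergence_fixture()
        est = ex.fully_extruded_fraction(frame, cbs, minus)
        # 10/100 convergent, occupancy correction 0.5 -> 5%
        assert est.point == pytest.approx(5.0)
        assert est.n_fragments == 100 and est.n_convergent == 10

    def test_min_frags_excludes_shallow_cbs_from_range(self):
        frame, cbs, minus = _convergence_fixture(n_at_cbs2=49)
        est = ex.fully_extruded_fraction(frame, cbs, minus)
        assert est.n_cbs == 1  # the 49-fragment CBS is excluded
        assert np.isnan(
            est.per_cbs.loc[est.per_cbs["center"] == 200_000, "pct"]
        ).all()

    def test_no_eligible_cbs_rejected(self):
        frame, cbs, minus = _convergence_fixture(n_total=20, n_conv=2)
        with pytest.raises(ValueError):
            ex.fully_extruded_fraction(frame, cbs, minus)

    def test_invariant_under_contact_duplication(self):
        frame, cbs, minus = _convergence_fixture()
        est1 = ex.fully_extruded_fraction(frame, cbs, minus)
        doubled = pd.concat([frame, frame], ignore_index=True)
        est2 = ex.fully_extruded_fraction(doubled, cbs, minus)
        assert est2.point == pytest.approx(est1.point)

    def test_non_plus_cbs_rejected(self):
        frame, cbs, minus = _convergence_fixture()
        with pytest.raises(ValueError):
            ex.fully_extruded_fraction(frame, [motif_at(50_000, "-")], minus)


class TestAnnotateRegion:
    def _seg(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])

    def test_single_state_fills_window(self):
        seg = self._seg([("chrT", 0, 2_000_000, "Quies")])
        ann = ex.annotate_region(motif_at(1000), seg, window=100_000)
        assert ann.state_fractions == {"Quies": pytest.approx(1.0)}

    def test_k27ac_bp_counts_union(self):
        seg = self._seg([("chrT", 0, 2_000_000, "Quies")])
        peaks = [
            SignalPeak(GenomicInterval("chrT", 5000, 5500), 1.0),
            SignalPeak(GenomicInterval("chrT", 9000, 9500), 1.0),
        ]
        ann = ex.annotate_region(motif_at(1000), seg, peaks_k27ac=peaks,
                                 window=100_000)
        assert ann.k27ac_bp == 1000

    def test_minus_motif_window_is_leftward(self):
        seg = self._seg([("chrT", 0, 50_000, "A"), ("chrT", 50_000, 200_000, "B")])
        ann = ex.annotate_region(motif_at(60_000, "-"), seg, window=20_000)
        assert ann.window.start == 40_000
        assert ann.state_fractions["A"] == pytest.approx(0.5, abs=1e-3)

    def test_truncated_at_chromosome_start_flagged(self):
        seg = self._seg([("chrT", 0, 50_000, "A")])
        ann = ex.annotate_region(motif_at(5000, "-"), seg, window=20_000)
        assert ann.truncated
        assert len(ann.window) == 5001

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(6)
        edges = np.sort(rng.choice(np.arange(1, 10_000), 20, replace=False))
        bounds = np.concatenate([[0], edges, [10_000]])
        states = rng.choice(["A", "B", "C"], len(bounds) - 1)
        seg = self._seg([
            ("chrT", int(s), int(e), st)
            for s, e, st in zip(bounds[:-1], bounds[1:], states)
        ])
        ann = ex.annotate_region(motif_at(2000), seg, window=5000)
        per_bp = {}
        for bp in range(2000, 7000):
            k = np.searchsorted(bounds, bp, side="right") - 1
            per_bp[states[k]] = per_bp.get(states[k], 0) + 1
        for state, n in per_bp.items():
            assert ann.state_fractions[state] == pytest.approx(n / 5000)


class TestGroupStates:
    def test_manual_map_top_quantile_membership(self):
        anns = []
        for i in range(10):
            frac = 0.95 if i == 3 else 0.1 * i / 10
            anns.append(ex.RegionAnnotation(
                cbs=motif_at(1000 + 10_000 * i),
                window=GenomicInterval("chrT", 0, 100),
                state_fractions={"Quies": frac, "TssA": 1 - frac},
                k27ac_bp=0, pol2_peaks=0,
            ))
        mapping = {"Quies": ex.QUIESCENT, "TssA": ex.ACTIVE}
        _, frac, members = ex.group_states(anns, mapping=mapping)
        assert 3 in members[ex.QUIESCENT]
        assert len(members[ex.QUIESCENT]) == 2  # ceil(0.2 * 10)

    def test_auto_clustering_recovers_planted_groups(self):
        sim = simulate_dataset(recovery_config(n_bound=45), seed=7)
        tr = sim.truth
        anns = [
            ex.annotate_region(m, tr.segmentation, tr.k27ac_peaks,
                               tr.pol2_peaks)
            for m in tr.bound_plus
        ]
        mapping, _, members = ex.group_states(anns)
        assert mapping == tr.state_to_group
        # top-20% members have the planted group as their own annotation
        for g, idx in members.items():
            planted = [tr.groups_plus[i] for i in idx]
            assert all(p == g for p in planted)

    def test_identical_regions_tie_takes_lowest_indices(self):
        anns = [
            ex.RegionAnnotation(
                cbs=motif_at(1000 + 10_000 * i),
                window=GenomicInterval("chrT", 0, 100),
                state_fractions={"Quies": 0.5, "TssA": 0.5},
                k27ac_bp=0, pol2_peaks=0,
            )
            for i in range(10)
        ]
        mapping = {"Quies": ex.QUIESCENT, "TssA": ex.ACTIVE}
        _, _, members = ex.group_states(anns, mapping=mapping)
        assert members[ex.QUIESCENT].tolist() == [0, 1]

    def test_too_few_states_rejected(self):
        anns = [ex.RegionAnnotation(
            cbs=motif_at(1000), window=GenomicInterval("chrT", 0, 100),
            state_fractions={"A": 1.0}, k27ac_bp=0, pol2_peaks=0,
        )]
        with pytest.raises(ValueError):
            ex.group_states(anns)


class TestLoopSize:
    def test_constant_lengths(self):
        c = 50_000
        rows = [(c - 20, "+", 40, c + 100_000, "+", 40) for _ in range(30)]
        frame = make_contact_frame(rows)
        sizes = ex.loop_size_by_stratum(frame, [motif_at(c)],
                                        {"all": np.array([0])})
        assert sizes["all"].mean_log10 == pytest.approx(5.0, abs=1e-4)
        assert sizes["all"].kb == pytest.approx(100.0, rel=1e-3)

    def test_single_fragment_stratum(self):
        c = 50_000
        frame = make_contact_frame([(c - 20, "+", 40, c + 200_000, "+", 40)])
        sizes = ex.loop_size_by_stratum(frame, [motif_at(c)],
                                        {"solo": np.array([0])})
        assert sizes["solo"].n == 1
        assert sizes["solo"].mean_log10 == pytest.approx(np.log10(200_000),
                                                         abs=1e-3)

    def test_empty_stratum_omitted(self):
        frame = make_contact_frame([(100, "+", 40, 200, "+", 40)])
        sizes = ex.loop_size_by_stratum(frame, [motif_at(50_000)],
                                        {"empty": np.array([0])})
        assert sizes == {}

    def test_monotone_in_planted_scale(self):
        """Stochastically larger planted distances give larger estimates."""
        means = []
        for lam in (5.0, 5.3, 5.6):
            cfg = recovery_config(
                n_bound=15, depth_mean=80,
                group_log10_size={
                    ex.ACTIVE: lam, ex.POLYCOMB_BIVALENT: lam,
                    ex.QUIESCENT: lam,
                },
            )
            sim = simulate_dataset(cfg, seed=23)
            sizes = ex.loop_size_by_stratum(
                sim.contacts, sim.truth.bound_plus,
                {"all": np.arange(len(sim.truth.bound_plus))},
            )
            means.append(sizes["all"].mean_log10)
        assert means[0] < means[1] < means[2]


class TestCohesinEffect:
    def test_two_cbs_constant_difference(self):
        rows = []
        for c in (50_000, 300_000):
            for _ in range(10):
                # TF fragments contact at 10^5 bp, nucleosomes at 10^4.5
                rows.append((c - 20, "+", 40, c - 20 + 100_000, "+", 40))
                rows.append((c - 73, "+", 147, c - 73 + 31_623, "+", None))
        frame = make_contact_frame(rows)
        cbs = [motif_at(50_000), motif_at(300_000)]
        eff, se, per = ex.cohesin_effect(frame, cbs)
        assert len(per) == 2
        assert eff == pytest.approx(5.0 - np.log10(31_623), abs=1e-3)

    def test_zero_planted_effect_within_noise(self):
        cfg = recovery_config(n_bound=25, depth_mean=100,
                              class_effect_delta=0.0)
        sim = simulate_dataset(cfg, seed=29)
        eff, se, _ = ex.cohesin_effect(sim.contacts, sim.truth.bound_plus)
        assert abs(eff) <= 3 * se

    def test_no_dual_class_cbs_rejected(self):
        frame = make_contact_frame([(980, "+", 40, 50_000, "+", 40)])
        with pytest.raises(ValueError):
            ex.cohesin_effect(frame, [motif_at(1000)])


def test_strand_flip_mirrors_extrusion_windows():
    """All strand-dependent windows mirror under global strand flips."""
    seg = pd.DataFrame(
        [("chrT", 0, 200_000, "A")], columns=["chrom", "start", "end", "state"]
    )
    plus = ex.annotate_region(motif_at(100_000, "+"), seg, window=50_000)
    minus = ex.annotate_region(motif_at(100_000, "-"), seg, window=50_000)
    assert plus.window.start == 100_000 and minus.window.end == 100_001
    assert len(plus.window) == len(minus.window) - 1 or \
        len(plus.window) == len(minus.window)
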