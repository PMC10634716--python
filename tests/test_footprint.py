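import numpy as np
import pytest

from conftest import make_contact_frame
from factorfinder.footprint import (
    CoverageProfile, Rad21Level, cohesin_footprint, coverage_metaplot,
    footprint_difference, stratify_rad21,
)
from factorfinder.fragments import PartnerOrientation
from factorfinder.synthetic import recovery_config, simulate_dataset
from factorfinder.types import GenomicInterval, Motif, SignalPeak


def motif_at(center, strand="+", chrom="chrT"):
    return Motif(GenomicInterval(chrom, center - 9, center + 10, strand))


class TestMetaplot:
    def test_single_fragment_block(self):
        c = 10_000
        frame = make_contact_frame([(c - 20, "+", 40, c + 50_000, "+", 40)])
        profs = coverage_metaplot(frame, [motif_at(c)], flank=100)
        cov = profs["<80"].coverage
        offsets = profs["<80"].offsets
        expect = ((offsets >= -20) & (offsets <= 19)).astype(int)
        # the partner fragment is 50 kb away: outside every window
        assert np.array_equal(cov, expect)

    def test_zero_contacts_zero_profile(self):
        frame = make_contact_frame([])
        profs = coverage_metaplot(frame, [motif_at(1000)], flank=50)
        assert all(p.empty and (p.coverage == 0).all() for p in profs.values())

    def test_no_motifs_empty_profile(self):
        frame = make_contact_frame([(100, "+", 40, 900, "-", 40)])
        profs = coverage_metaplot(frame, [], flank=50)
        assert all((p.coverage == 0).all() for p in profs.values())

    def test_mass_conservation_against_per_bp_loop(self):
        """Total profile mass equals the summed per-bp overlap widths."""
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(60):
            pos = int(rng.integers(500, 3000))
            ln = int(rng.integers(20, 120))
            rows.append((pos, "+", ln, pos + int(rng.integers(200, 9000)),
                         "-", None))
        frame = make_contact_frame(rows)
        motifs = [motif_at(1000), motif_at(2500, "-")]
        flank = 120
        profs = coverage_metaplot(frame, motifs, flank=flank)
        total = sum(int(p.coverage.sum()) for p in profs.values())
        # brute force: count (fragment, motif, bp) covered triples
        from factorfinder.fragments import side_table
        brute = 0
        for row in side_table(frame).itertuples():
            for m in motifs:
                for off in range(-flank, flank + 1):
                    bp = m.center + off
                    if row.start <= bp < row.end:
                        brute += 1
        assert total == brute

    def test_nucleosome_phasing_autocorrelation(self):
        sim = simulate_dataset(
            recovery_config(n_bound=80, n_decoy=40, depth_mean=80,
                            spacing=50_000),
            seed=11,
        )
        profs = coverage_metaplot(sim.contacts, sim.truth.bound_motifs,
                                  flank=500)
        x = profs[">=150"].coverage.astype(float)
        x -= x.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1:]
        lag = 150 + int(np.argmax(ac[150:260]))
        assert abs(lag - 200) <= 10


class TestDifference:
    def test_symmetric_profile_is_zero(self):
        prof = CoverageProfile(5, np.array([4, 3, 2, 1, 0, 9, 0, 1, 2, 3, 4]))
        assert (footprint_difference(prof) == 0).all()

    def test_flank_zero_empty(self):
        prof = CoverageProfile(0, np.array([7]))
        assert footprint_difference(prof).size == 0

    def test_strand_flip_negates_difference(self):
        """Exact antisymmetry: flipping every motif strand reverses the
        oriented profile and negates the footprint difference."""
        sim = simulate_dataset(
            recovery_config(n_bound=30, n_decoy=10, depth_mean=40),
            seed=17,
        )
        motifs = sim.truth.bound_motifs
        flipped = [
            Motif(GenomicInterval(m.interval.chrom, m.interval.start,
                                  m.interval.end,
                                  "-" if m.strand == "+" else "+"),
                  score=m.score, name=m.name)
            for m in motifs
        ]
        a = coverage_metaplot(sim.contacts, motifs, flank=80)
        b = coverage_metaplot(sim.contacts, flipped, flank=80)
        for lab in a:
            assert np.array_equal(footprint_difference(a[lab]),
                                  -footprint_difference(b[lab]))


class TestStratify:
    def _peaks(self, signals, centers=None):
        out = []
        for i, s in enumerate(signals):
            c = 1000 * (i + 1) if centers is None else centers[i]
            out.append(SignalPeak(GenomicInterval("chrT", c - 10, c + 10),
                                  signal_value=float(s)))
        return out

    def test_quantile_rule_on_1_to_100(self):
        motifs = [motif_at(1000 * (i + 1)) for i in range(100)]
        peaks = self._peaks(range(1, 101))
        levels = stratify_rad21(motifs, peaks)
        # 75th percentile of 1..100 is 75.25: HIGH = signals 76..100
        assert [l is Rad21Level.HIGH for l in levels] == \
            [s >= 76 for s in range(1, 101)]
        assert [l is Rad21Level.LOW for l in levels] == \
            [s <= 25 for s in range(1, 101)]

    def test_peak_beyond_max_dist_unassigned(self):
        motifs = [motif_at(1000), motif_at(5000), motif_at(9000)]
        peaks = self._peaks([50.0, 10.0, 90.0], centers=[1070, 5010, 9010])
        levels = stratify_rad21(motifs, peaks)
        assert levels[0] is Rad21Level.UNASSIGNED  # nearest peak 60 bp away
        assert levels[1] is Rad21Level.LOW
        assert levels[2] is Rad21Level.HIGH

    def test_all_equal_signals_all_unassigned(self):
        motifs = [motif_at(1000 * (i + 1)) for i in range(8)]
        levels = stratify_rad21(motifs, self._peaks([5.0] * 8))
        assert all(l is Rad21Level.UNASSIGNED for l in levels)


@pytest.fixture(scope="module")
def planted():
    sim = simulate_dataset(
        recovery_config(n_bound=120, bound_plus_frac=0.5, depth_mean=120,
                        spacing=100_000, cohesin_frac=0.25),
        seed=11,
    )
    strata = stratify_rad21(sim.truth.bound_motifs, sim.truth.rad21_peaks)
    return sim, strata, cohesin_footprint(
        sim.contacts, sim.truth.bound_motifs, strata
    )


class TestCohesinFootprint:

    def test_signal_only_in_upstream_high_stratum(self, planted):
        sim, strata, res = planted
        up_high = res[(PartnerOrientation.UPSTREAM_FRAGMENT, Rad21Level.HIGH)]
        assert not up_high["empty"]
        sig = up_high["diff"][20:60].mean()
        assert sig > 0
        for key, entry in res.items():
            if key == (PartnerOrientation.UPSTREAM_FRAGMENT, Rad21Level.HIGH):
                continue
            if key[1] is Rad21Level.UNASSIGNED:
                continue
            other = entry["diff"][20:60].mean() if not entry["empty"] else 0.0
            assert other < 0.1 * sig

    def test_high_strata_match_planted_cohesin_flags(self, planted):
        sim, strata, _ = planted
        flagged = set(np.flatnonzero(sim.truth.cohesin_flags))
        high = {i for i, l in enumerate(strata) if l is Rad21Level.HIGH}
        low = {i for i, l in enumerate(strata) if l is Rad21Level.LOW}
        assert high <= flagged
        assert not (low & flagged)

    def test_no_longrange_fragments_all_empty(self):
        frame = make_contact_frame([(980, "+", 100, 2000, "-", 100)])
        res = cohesin_footprint(frame, [motif_at(1000)],
                                [Rad21Level.HIGH])
        assert all(entry["empty"] for entry in res.values())
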