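"""Initiation energetics, elongation rates and the TASEP simulator."""

import math

import numpy as np
import pytest

from ribopred.translation import (
    InitiationParams,
    RateProfile,
    RbsTooShortError,
    compute_rate_profiles,
    elongation_rates,
    exact_steady_state,
    initiation_energy_breakdown,
    initiation_rate,
    read_transim_input,
    tasep_simulate,
    transim_translation_rate,
    write_transim_input,
)
from ribopred.sequence_io import GeneRecord, translate_cds


def profile(alpha, k, beta=1.0, ell=1, gid="g"):
    return RateProfile(gene_id=gid, alpha=alpha, hop_rates=np.asarray(k, float),
                       beta=beta, footprint=ell)


class TestInitiationRate:
    CDS = "ATG" + "AAA" * 30 + "TAA"

    def test_alpha_equals_prefactor_at_zero_energy(self):
        params = InitiationParams()
        # alpha = A_scale * exp(-dG/RT); dG = 0 -> alpha = A_scale
        assert params.a_scale * math.exp(0.0) == pytest.approx(params.a_scale)
        # and a factor RT*ln(10) of energy costs exactly one decade
        utr = "A" * 9 + "AGGAGG" + "AAAAA"
        a1 = initiation_rate(utr, self.CDS)
        bd = initiation_energy_breakdown(utr, self.CDS)
        expected = params.a_scale * math.exp(-bd["dg_total"] / params.rt)
        assert a1 == pytest.approx(expected)

    def test_decade_per_rt_ln10(self):
        params = InitiationParams()
        assert math.exp(-(params.rt * math.log(10)) / params.rt) == (
            pytest.approx(0.1)
        )

    def test_perfect_sd_unstructured_is_order_one(self):
        # consensus AGGAGG at the optimal spacing in an unstructured
        # (unpairable) poly-A context
        utr = "A" * 9 + "AGGAGG" + "AAAAA"
        bd = initiation_energy_breakdown(utr, self.CDS)
        params = InitiationParams()
        assert bd["dg_duplex_spacing"] == params.perfect_duplex_energy
        alpha = initiation_rate(utr, self.CDS)
        assert 0.01 <= alpha <= 1.0

    def test_sd_vs_hairpin_ratio_exceeds_1e3(self):
        cds = self.CDS
        utr_good = "A" * 9 + "AGGAGG" + "AAAAA"
        utr_bad = "C" * 6 + "GGGGGAAAACCCCC"  # no SD, strong stem
        ratio = initiation_rate(utr_good, cds) / initiation_rate(utr_bad, cds)
        assert ratio > 1e3

    def test_short_utr_discarded(self):
        with pytest.raises(RbsTooShortError):
            initiation_rate("A" * 10, self.CDS)

    def test_rate_profile_discard_reason(self):
        recs = [
            GeneRecord(gene_id="ok", utr5="A" * 25, cds=self.CDS,
                       protein=translate_cds(self.CDS)),
            GeneRecord(gene_id="short", utr5="A" * 5, cds=self.CDS,
                       protein=translate_cds(self.CDS)),
        ]
        rates, discarded = compute_rate_profiles(recs)
        assert list(rates.index) == ["ok"]
        assert discarded == [("short", "RBS_TOO_SHORT")]


class TestElongationRates:
    def test_uniform_dwell(self):
        cds = "ATG" + "AAA" * 99 + "TAA"  # 100 sense codons
        dwell = {"ATG": 0.1, "AAA": 0.1}
        hop, rate = elongation_rates(cds, dwell)
        assert rate == pytest.approx(10.0)
        assert np.allclose(hop, 10.0) and len(hop) == 100

    def test_halving_dwell_doubles_rate(self):
        cds = "ATG" + "GCAAAA" * 10 + "TAA"
        d1 = {"ATG": 0.1, "GCA": 0.2, "AAA": 0.05}
        d2 = {c: v / 2 for c, v in d1.items()}
        _, r1 = elongation_rates(cds, d1)
        _, r2 = elongation_rates(cds, d2)
        assert r2 == pytest.approx(2 * r1)

    def test_harmonic_mean_two_codons(self):
        cds = "ATGGCATAA"  # sense codons ATG, GCA
        _, rate = elongation_rates(cds, {"ATG": 0.1, "GCA": 0.3})
        assert rate == pytest.approx(2 / 0.4)

    def test_nonpositive_dwell_is_error(self):
        with pytest.raises(ValueError):
            elongation_rates("ATGGCATAA", {"ATG": 0.1, "GCA": 0.0})


class TestTasep:
    def test_zero_alpha_gives_zero_flux(self):
        res = tasep_simulate(profile(0.0, np.ones(10)), t_burn=5, t_measure=50,
                             seed=3)
        assert res.translation_rate == 0.0
        assert np.all(res.density == 0.0)

    def test_seed_determinism(self):
        p = profile(0.5, np.ones(30), beta=2.0, ell=3)
        r1 = tasep_simulate(p, t_burn=50, t_measure=500, seed=11)
        r2 = tasep_simulate(p, t_burn=50, t_measure=500, seed=11)
        assert r1.terminations == r2.terminations
        assert r1.collisions == r2.collisions
        assert np.array_equal(r1.density, r2.density)

    def test_different_seeds_differ(self):
        p = profile(0.5, np.ones(30))
        r1 = tasep_simulate(p, t_burn=50, t_measure=500, seed=1)
        r2 = tasep_simulate(p, t_burn=50, t_measure=500, seed=2)
        assert r1.terminations != r2.terminations or not np.array_equal(
            r1.density, r2.density
        )

    def test_low_density_current(self):
        # open TASEP, alpha = 0.1 << 1: current -> alpha (1 - alpha)
        p = profile(0.1, np.ones(200), beta=10.0)
        res = tasep_simulate(p, t_burn=3000, t_measure=200000, seed=5)
        assert res.translation_rate == pytest.approx(0.09, rel=0.03)

    def test_matches_exact_oracle_L6(self):
        p = profile(1.0, np.ones(6), beta=1.0)
        exact = exact_steady_state(p)
        res = tasep_simulate(p, t_burn=500, t_measure=30000, seed=7)
        assert res.translation_rate == pytest.approx(
            exact["current"], abs=3 * res.flux_se
        )

    def test_extended_footprint_maximal_current_bound(self):
        ell = 10
        p = profile(10.0, np.ones(400), beta=10.0, ell=ell)
        res = tasep_simulate(p, t_burn=4000, t_measure=40000, seed=9)
        bound = 1.0 / (1.0 + math.sqrt(ell)) ** 2
        assert res.translation_rate <= bound + 3 * res.flux_se

    def test_particle_conservation(self):
        # flux in == flux out at stationarity: initiations ~ terminations
        p = profile(0.3, np.ones(40), beta=5.0, ell=2)
        res = tasep_simulate(p, t_burn=500, t_measure=20000, seed=13)
        max_on_lattice = 40 // 2 + 1
        assert abs(res.initiations - res.terminations) <= max_on_lattice

    def test_alpha_monotonicity_of_current(self):
        k = np.ones(60)
        lo = np.mean([
            tasep_simulate(profile(0.05, k), t_burn=200, t_measure=5000,
                           seed=s).translation_rate for s in range(4)
        ])
        hi = np.mean([
            tasep_simulate(profile(0.2, k), t_burn=200, t_measure=5000,
                           seed=s).translation_rate for s in range(4)
        ])
        assert hi > lo

    def test_densities_are_probabilities(self):
        p = profile(5.0, np.ones(30), beta=5.0, ell=4)
        res = tasep_simulate(p, t_burn=200, t_measure=5000, seed=17)
        assert np.all(res.density >= 0.0) and np.all(res.density <= 1.0 + 1e-12)

    def test_collisions_positive_under_jamming(self):
        # slow termination bottleneck: hops at the end get blocked
        p = profile(5.0, np.ones(20), beta=0.05)
        res = tasep_simulate(p, t_burn=200, t_measure=2000, seed=19)
        assert res.collisions > 0

    def test_translation_rate_accessor(self):
        p = profile(1.0, np.ones(6))
        res = tasep_simulate(p, t_burn=100, t_measure=1000, seed=23)
        assert transim_translation_rate(res) == pytest.approx(
            res.terminations / 1000.0
        )


class TestExactSteadyState:
    def test_two_state_system(self):
        # L=1: empty <-> occupied; current = alpha*beta/(alpha+beta) = 1/2
        p = profile(1.0, [1.0], beta=1.0)
        out = exact_steady_state(p)
        assert out["current"] == pytest.approx(0.5)
        assert out["n_states"] == 2

    def test_zero_alpha_zero_current(self):
        out = exact_steady_state(profile(0.0, np.ones(4)))
        assert out["current"] == pytest.approx(0.0, abs=1e-12)

    def test_stationarity_flux_balance(self):
        # initiation flux equals termination flux in steady state
        p = profile(0.7, [1.0, 2.0, 0.5, 1.5], beta=0.8)
        out = exact_steady_state(p)
        assert out["initiation_flux"] == pytest.approx(out["current"], rel=1e-8)

    def test_footprint_two_state_count(self):
        # L=4, ell=2: configurations of non-overlapping dimers
        out = exact_steady_state(profile(1.0, np.ones(4), ell=2))
        assert out["n_states"] == 8

    def test_state_space_guard(self):
        with pytest.raises(ValueError, match="state space"):
            exact_steady_state(profile(1.0, np.ones(20)), max_states=100)


class TestTransimDialect:
    def test_round_trip(self, tmp_path):
        cds = "ATG" + "GCA" * 5 + "TAA"
        recs = [GeneRecord(gene_id="g1", utr5="AGGAGGAAAAA", cds=cds,
                           protein=translate_cds(cds))]
        path = tmp_path / "transim.tsv"
        write_transim_input(recs, path)
        back = read_transim_input(path)
        assert back == [("g1", "AGGAGGAAAAA", cds)]

    def test_bad_start_position(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("name\tsequence\tstart\ng\tACGT\t9\n")
        with pytest.raises(ValueError, match="start"):
            read_transim_input(path)
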