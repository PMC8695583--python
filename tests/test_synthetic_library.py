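"""Generator properties: determinism, library composition, kinetics, oligos."""

import numpy as np
import pytest

from spacerscreen import synthetic_library as sim
from spacerscreen.sequence_features import count_tg, extended_minus10


@pytest.fixture(scope="module")
def cfg():
    return sim.SimConfig(seed=7)


class TestGenerateLibrary:
    def test_deterministic_given_seed(self, cfg):
        a = sim.generate_library(cfg)
        b = sim.generate_library(cfg)
        assert [c.spacer.seq for c in a] == [c.spacer.seq for c in b]

    def test_library_size(self, cfg):
        clones = sim.generate_library(cfg)
        non_ctrl = [c for c in clones if not c.is_control]
        assert len(non_ctrl) == 96 * 12
        assert sum(c.is_control for c in clones) == cfg.n_controls

    def test_base_frequencies_uniform(self):
        cfg = sim.SimConfig(seed=3, lengths=(17,), n_per_length=10_000, n_controls=0)
        clones = sim.generate_library(cfg)
        seqs = "".join(c.spacer.seq for c in clones)
        for base in "ACGT":
            assert seqs.count(base) / len(seqs) == pytest.approx(0.25, abs=0.01)


class TestAssignStrength:
    def test_tg_damping_by_construction(self, cfg):
        st = cfg.strength
        rng = sim.substream(0, "x")
        plain = sim.Clone("a", sim.SpacerSeq("A" * 17))
        tg3 = sim.Clone("b", sim.SpacerSeq("TGATGAAAAAAAAAAAA"))  # TGs away from the ext -10
        # compare deterministic parts by zeroing the lognormal spread
        cfg0 = sim.SimConfig(seed=0, strength=sim.StrengthParams(
            tg_damp=st.tg_damp, tandem_damp=st.tandem_damp, sigma_log=0.0))
        sa = sim.assign_strength(plain, cfg0, rng)
        sb = sim.assign_strength(tg3, cfg0, rng)
        k = count_tg(tg3.spacer)
        assert sb / sa == pytest.approx(st.tg_damp**k)

    def test_mean_strength_peaks_at_17(self):
        # n large enough that the 17 vs 16/18 bp margin exceeds sampling error
        cfg = sim.SimConfig(seed=7, n_per_length=400, n_controls=0)
        rng = sim.substream(cfg.seed, "strength")
        clones = sim.generate_library(cfg)
        for c in clones:
            sim.assign_strength(c, cfg, rng)
        means = {
            L: np.mean([c.true_strength for c in clones
                        if not c.is_control and c.spacer.length == L])
            for L in cfg.lengths
        }
        assert max(means, key=means.get) == 17
        assert means[17] > means[13]

    def test_within_length_variation_about_tenfold(self):
        # lognormal spread sized so the 96-clone max/min ratio is ~10
        cfg = sim.SimConfig(seed=5, strength=sim.StrengthParams(tg_damp=1.0, tandem_damp=1.0))
        rng = sim.substream(cfg.seed, "strength")
        clones = [c for c in sim.generate_library(cfg)
                  if not c.is_control and c.spacer.length == 17]
        for c in clones:
            sim.assign_strength(c, cfg, rng)
        s = np.array([c.true_strength for c in clones])
        assert 4 < s.max() / s.min() < 40

    def test_control_gets_background(self, cfg):
        c = sim.Clone("c", sim.SpacerSeq("A" * 17), is_control=True)
        sim.assign_strength(c, cfg, sim.substream(0, "y"))
        assert c.true_strength == cfg.strength.background


class TestSelection:
    def _library(self, cfg):
        rng = sim.substream(cfg.seed, "strength")
        clones = [c for c in sim.generate_library(cfg) if not c.is_control]
        for c in clones:
            sim.assign_strength(c, cfg, rng)
        return clones

    def test_p_kill_zero_keeps_all(self):
        cfg = sim.SimConfig(seed=1, selection=sim.SelectionParams(p_kill=0.0))
        clones = self._library(cfg)
        surv, table = sim.apply_selection(clones, cfg, sim.substream(1, "sel"))
        assert len(surv) == len(clones)
        assert (table["survival"] == 1.0).all()

    def test_certain_cull_removes_everything(self):
        cfg = sim.SimConfig(seed=1, selection=sim.SelectionParams(tox_threshold=0.0, p_kill=1.0))
        clones = self._library(cfg)
        surv, _ = sim.apply_selection(clones, cfg, sim.substream(1, "sel"))
        assert surv == []

    def test_seventeen_bp_yield_reduced_vs_15bp(self):
        # toxicity culls the strong-promoter-rich optimal-spacer group hardest
        cfg = sim.SimConfig(seed=2, n_per_length=500)
        clones = self._library(cfg)
        _, table = sim.apply_selection(clones, cfg, sim.substream(2, "sel"))
        t = table.set_index("length")["survival"]
        assert t[17] < 0.5 * t[15] + 0.2  # markedly lower colony yield at 17 bp
        assert t[17] < t[12]

    def test_extended_minus10_enriched_in_survivors(self):
        cfg = sim.SimConfig(seed=4, lengths=(17,), n_per_length=5000, n_controls=0)
        clones = self._library(cfg)
        surv, _ = sim.apply_selection(clones, cfg, sim.substream(4, "sel"))
        pre = np.mean([extended_minus10(c.spacer).has_extended_minus10 for c in clones])
        post = np.mean([extended_minus10(c.spacer).has_extended_minus10 for c in surv])
        assert post > pre


class TestSupercoilingParams:
    def test_gc_half_no_jitter_hits_reference(self):
        cfg = sim.SimConfig(seed=1, supercoiling=sim.SupercoilingParams(jitter=0.0))
        c = sim.Clone("x", sim.SpacerSeq("ACGTACGTACGTACGT"))  # GC = 0.5
        sim.assign_supercoiling_params(c, cfg, sim.substream(0, "sc"))
        assert c.sigma_opt == pytest.approx(cfg.supercoiling.sigma_ref)

    def test_gc_rich_more_negative_than_at_rich(self):
        cfg = sim.SimConfig(seed=1, supercoiling=sim.SupercoilingParams(jitter=0.0))
        rng = sim.substream(0, "sc")
        gc_rich = sim.Clone("g", sim.SpacerSeq("GCGCGCGCGCGCGCGA"))
        at_rich = sim.Clone("a", sim.SpacerSeq("ATATATATATATATAG"))
        assert sim.assign_supercoiling_params(gc_rich, cfg, rng) < sim.assign_supercoiling_params(
            at_rich, cfg, rng
        )

    def test_optima_unimodal_near_reference(self, cfg):
        rng = sim.substream(cfg.seed, "sc")
        clones = [c for c in sim.generate_library(cfg) if not c.is_control]
        opts = np.array([sim.assign_supercoiling_params(c, cfg, rng) for c in clones])
        assert abs(np.median(opts) - cfg.supercoiling.sigma_ref) < 0.005


class TestTimecourse:
    def _clone(self, cfg, strength=300.0, sigma_opt=None):
        c = sim.Clone("t", sim.SpacerSeq("ACGTACGTACGTACGT"))
        c.true_strength = strength
        c.sigma_opt = sigma_opt if sigma_opt is not None else cfg.supercoiling.sigma_ref
        return c

    def test_zero_strength_stays_at_blank(self, cfg):
        c = self._clone(cfg, strength=0.0)
        ts = sim.simulate_timecourse(c, 0.0, cfg)
        assert np.abs(ts.rfu - cfg.noise.blank_rfu).max() < 6 * cfg.noise.rfu_sd

    def test_deterministic_given_seed(self, cfg):
        c = self._clone(cfg)
        a = sim.simulate_timecourse(c, 0.0, cfg)
        b = sim.simulate_timecourse(c, 0.0, cfg)
        np.testing.assert_array_equal(a.rfu, b.rfu)
        np.testing.assert_array_equal(a.od600, b.od600)

    def test_negative_condition_rejected(self, cfg):
        with pytest.raises(ValueError):
            sim.simulate_timecourse(self._clone(cfg), -1.0, cfg)

    def test_relaxation_preferring_clone_rises_in_stationary_phase(self, cfg):
        # optimum at the relaxed stationary-phase sigma -> late expression
        c = self._clone(cfg, sigma_opt=cfg.supercoiling.sigma_stat)
        ts = sim.simulate_timecourse(c, 0.0, cfg)
        rfu = ts.rfu - cfg.noise.blank_rfu
        i10 = np.searchsorted(ts.time, 10.0)
        assert rfu[-1] > 1.3 * rfu[i10]  # still climbing between 10 h and 15 h

    def test_sigma_trajectory_anchors(self, cfg):
        sc = cfg.supercoiling
        t = sim.time_grid(cfg)
        sig0 = sim.sigma_trajectory(t, 0.0, cfg)
        sig17 = sim.sigma_trajectory(t, sc.conc_ref, cfg)
        assert sig0[0] == pytest.approx(sc.sigma_exp, abs=1e-3)
        assert sig0[-1] == pytest.approx(sc.sigma_stat, abs=1e-3)
        # treatment shift matches the measured exponential/stationary anchors
        assert sig17[0] - sig0[0] == pytest.approx(sc.dsigma_treat_exp, abs=1e-4)
        assert sig17[-1] - sig0[-1] == pytest.approx(sc.dsigma_treat_stat, abs=1e-4)


class TestScreenPair:
    def test_no_coupling_gives_unit_ratio(self):
        cfg = sim.SimConfig(
            seed=9,
            lengths=(17,),
            n_per_length=40,
            n_controls=0,
            supercoiling=sim.SupercoilingParams(elong_penalty=0.0, width=10.0, jitter=0.0),
            noise=sim.NoiseParams(od_sd=0.0, rfu_sd=0.0),
        )
        clones = sim.pick_colonies(cfg)
        screen = sim.simulate_screen_pair(clones, cfg)
        piv = screen.pivot_table(index="clone_id", columns="condition", values="rfu")
        ratio = (piv[17.0] - cfg.noise.blank_rfu) / (piv[0.0] - cfg.noise.blank_rfu)
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-6)

    def test_mirrored_layout_metadata(self, cfg):
        clones = sim.pick_colonies(cfg)
        screen = sim.simulate_screen_pair(clones, cfg)
        untreated = screen[(screen.condition == 0) & ~screen.is_control]
        per_plate = untreated.groupby(["plate", "length"]).size()
        assert (per_plate == 8).all()  # 8 clones of each length per plate

    def test_monotone_dose_response_for_supercoiling_dependent_clone(self, cfg):
        c = sim.Clone("d", sim.SpacerSeq("GCGCGCGCGCGCGCGCG"))
        c.true_strength = 300.0
        c.sigma_opt = cfg.supercoiling.sigma_exp - 0.01  # well below any treated sigma
        cfg0 = sim.SimConfig(seed=cfg.seed, noise=sim.NoiseParams(od_sd=0.0, rfu_sd=0.0))
        grad = sim.simulate_dose_gradient([c], cfg0)
        rfu = grad.sort_values("condition")["rfu"].to_numpy() - cfg0.noise.blank_rfu
        assert np.all(np.diff(rfu) < 0)


class TestEmsaSimulation:
    def test_half_saturation_noise_free(self):
        s = sim.simulate_emsa(kd=100.0, n_hill=2.0, concs=[100.0], reps=1, noise_sd=0.0)
        assert s.theta[0, 0] == pytest.approx(0.5)

    def test_saturation(self):
        s = sim.simulate_emsa(kd=100.0, n_hill=2.0, concs=[1e7], reps=1, noise_sd=0.0)
        assert s.theta[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_reproducible(self):
        concs = np.geomspace(25, 3000, 12)
        a = sim.simulate_emsa(358.0, 2.0, concs, reps=4, noise_sd=0.02, seed=11)
        b = sim.simulate_emsa(358.0, 2.0, concs, reps=4, noise_sd=0.02, seed=11)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            sim.simulate_emsa(kd=-1.0, n_hill=2.0, concs=[1.0])


class TestOligoDesign:
    def test_scheme_and_overhangs(self):
        d = sim.design_oligos("ACGTACGTACGTACGT")
        assert d.top_oligo == "GGTCTCGGACA" + "ACGTACGTACGTACGT" + "TATACGAGACCGTGTCTATCAC"
        assert d.helper_oligo == "GTGATAGACACGGTCTCG"
        ins = sim.simulate_bsai(d)
        assert (ins.overhang_left, ins.overhang_right) == ("GACA", "TATA")

    def test_round_trip_recovers_spacer(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            L = int(rng.integers(12, 24))
            s = "".join(rng.choice(list("ACGT"), size=L))
            if "GGTCTC" in s or "GAGACC" in s:
                continue
            assert sim.simulate_bsai(sim.design_oligos(s)).spacer == s

    def test_internal_bsai_site_rejected(self):
        with pytest.raises(ValueError, match="BsaI"):
            sim.design_oligos("AAAGGTCTCAAAAAAA")
        with pytest.raises(ValueError, match="BsaI"):
            sim.design_oligos("AAAGAGACCAAAAAAA")

    def test_length_limits(self):
        with pytest.raises(ValueError):
            sim.design_oligos("ACGTACGTACG")  # 11 bp, below the library range


class TestPromoterFixtures:
    def test_promoter_table_shape_and_lengths(self):
        df = sim.make_promoter_table(n=200, seed=0)
        assert len(df) == 200
        lengths = df["spacer"].str.len()
        assert lengths.between(15, 21).all()
        assert lengths.mode()[0] == 17

    def test_gene_counts_columns(self):
        prom = sim.make_promoter_table(n=50, seed=1)
        counts = sim.make_gene_counts(prom, timepoints=4, seed=1)
        assert list(counts.columns) == ["gene", "cds_length", "t0", "t1", "t2", "t3"]
        assert (counts["cds_length"] > 0).all()
        assert (counts[["t0", "t1", "t2", "t3"]] >= 0).all().all()
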