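import numpy as np
import pytest

from deltacc import (
    CountMatrix,
    DecayModel,
    GenomicInterval,
    InjectedEffect,
    ValidationError,
    Viewpoint,
    delta_track,
    replicated_significant,
    simulate_experiment,
    simulate_significance,
    simulate_track,
    size_factors,
)
from deltacc.simulate import (
    default_scenario,
    fragment_distances,
    load_scenario,
    null_scenario,
    random_sequence,
)

from conftest import iv


def grid(n=500, width=300):
    return [iv(i * width, (i + 1) * width) for i in range(n)]


def centre_vp(fragments):
    mid_frag = fragments[len(fragments) // 2]
    return Viewpoint("v", mid_frag)


class TestFragmentDistances:
    def test_near_edge_convention(self):
        vp = Viewpoint("v", iv(1000, 1200))  # midpoint 1100
        frags = [iv(0, 500), iv(1000, 1200), iv(2000, 2500)]
        d = fragment_distances(frags, vp)
        assert list(d) == [600.0, 0.0, 900.0]


class TestSimulateTrack:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValidationError, match="seed"):
            simulate_track(grid(10), centre_vp(grid(10)), DecayModel())

    def test_same_seed_gives_identical_tracks(self):
        frags = grid(100)
        vp = centre_vp(frags)
        a = simulate_track(frags, vp, DecayModel(), seed=3)
        b = simulate_track(frags, vp, DecayModel(), seed=3)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_track(frags, vp, DecayModel(), seed=4)
        assert not np.array_equal(a.counts, c.counts)

    def test_mean_converges_to_decay_model(self):
        """Law of large numbers at three distances from the viewpoint."""
        model = DecayModel(amplitude=200.0, half_distance=5000.0)
        vp = Viewpoint("v", iv(0, 2))  # midpoint 1
        frags = [iv(0, 2), iv(50_000, 50_002), iv(200_000, 200_002)]
        mus = model.mean_at(fragment_distances(frags, vp))
        n_draws = 400
        total = np.zeros(3)
        for s in range(n_draws):
            total += simulate_track(frags, vp, model, seed=s).counts
        emp = total / n_draws
        se = np.sqrt((mus + mus**2 / model.dispersion) / n_draws)
        assert np.all(np.abs(emp - mus) <= 4 * se)

    def test_injected_fold_recovered_from_sample_means(self):
        model = DecayModel(amplitude=500.0, half_distance=50_000.0)
        frags = grid(600, width=500)  # 300 kb
        vp = Viewpoint("v", iv(0, 2))
        region = GenomicInterval("chr1", 100_000, 200_000)
        effect = InjectedEffect(region=region, fold=3.0)
        inside = np.array([f.overlaps(region) for f in frags])
        mu0 = model.mean_at(fragment_distances(frags, vp))
        n_draws = 500
        total_inside = 0.0
        for s in range(n_draws):
            t = simulate_track(frags, vp, model, effects=[effect], seed=s)
            total_inside += t.counts[inside].sum()
        expected_no_fold = n_draws * mu0[inside].sum()
        fold_hat = total_inside / expected_no_fold
        mu_eff = 3.0 * mu0[inside]
        var_total = n_draws * (mu_eff + mu_eff**2 / model.dispersion).sum()
        se_fold = np.sqrt(var_total) / expected_no_fold
        assert abs(fold_hat - 3.0) <= 2.58 * se_fold  # 99% CI

    def test_flank_restricted_effect_touches_one_side_only(self):
        model = DecayModel(amplitude=100.0, half_distance=1e9, dispersion=1e6)
        frags = grid(100, width=100)
        vp = Viewpoint("v", iv(5000, 5002))
        region = GenomicInterval("chr1", 0, 10_000)
        eff = InjectedEffect(region=region, fold=50.0, flank="upstream")
        t = simulate_track(frags, vp, model, effects=[eff], seed=0)
        up = [i for i, f in enumerate(frags) if (f.start + f.end) / 2 < 5001]
        down = [i for i, f in enumerate(frags) if (f.start + f.end) / 2 >= 5001]
        assert t.counts[up].mean() > 10 * t.counts[down].mean()


class TestSimulateExperiment:
    def test_depth_factor_recovered_by_size_factors(self):
        model = DecayModel()
        frags = grid(1500, width=300)
        vp = centre_vp(frags)
        tracks = [
            simulate_track(frags, vp, model, depth_factor=d, seed=100 + i,
                           sample_id=f"s{i}", condition="c", replicate=str(i))
            for i, d in enumerate([1.0, 1.0, 1.0, 2.0])
        ]
        f = size_factors(CountMatrix.from_tracks(tracks))
        ratio = f["s3"] / f[["s0", "s1", "s2"]].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_injected_fold_shows_positive_delta_in_that_condition(self):
        frags = grid(400, width=500)  # 200 kb
        vp = Viewpoint("v", iv(0, 2))
        region = GenomicInterval("chr1", 100_000, 150_000)
        model = DecayModel(amplitude=500.0, half_distance=50_000.0)
        inside = np.array([f.overlaps(region) for f in frags])
        positive = 0
        n_seeds = 20
        for s in range(n_seeds):
            cm = simulate_experiment(
                frags, vp,
                models={"A": model, "B": model},
                effects={"A": [InjectedEffect(region=region, fold=5.0)]},
                seed=s,
            )
            d = delta_track(cm, "A", "B")
            positive += d.delta[inside].sum() > 0
        assert positive == n_seeds

    def test_seed_required_and_duplicate_seeds_warn(self):
        frags = grid(10)
        vp = centre_vp(frags)
        models = {"A": DecayModel(), "B": DecayModel()}
        with pytest.raises(ValidationError):
            simulate_experiment(frags, vp, models)
        with pytest.warns(UserWarning, match="duplicate"):
            simulate_experiment(
                frags, vp, models, seed=1, sample_seeds=[5, 5, 6, 7]
            )


class TestSimulateSignificance:
    def test_background_never_replicates(self):
        """Background q ~ U(0.2, 1) analytically cannot pass q < 0.1 twice."""
        frags = grid(200)
        table = simulate_significance(frags, true_regions=[], seed=1)
        sets = replicated_significant({"esc": table})
        assert sets["esc"] == set()

    def test_true_region_fragments_all_replicate(self):
        frags = grid(50, width=100)
        region = GenomicInterval("chr1", 1000, 1500)  # fragments 10..14
        table = simulate_significance(frags, true_regions=[region], seed=2)
        sets = replicated_significant({"esc": table})
        assert sets["esc"] == {f for f in frags if f.overlaps(region)}
        assert len(sets["esc"]) == 5

    def test_seeded_regeneration_identical(self):
        frags = grid(30)
        a = simulate_significance(frags, seed=3)
        b = simulate_significance(frags, seed=3)
        assert a.data.equals(b.data)


class TestScenario:
    def test_default_scenario_builds_plausible_fragment_grid(self):
        frags, vp = default_scenario().build_fragments(seed=1)
        widths = np.array([f.width for f in frags])
        assert 2500 < len(frags) < 6000  # ~270 bp fragments over 1.1 Mb
        assert 150 < widths.mean() < 450
        assert vp.interval.start <= 550_000 < vp.interval.end

    def test_simulation_is_reproducible(self):
        sc = default_scenario()
        cm1, vp1, _, _ = sc.simulate(seed=5)
        cm2, vp2, _, _ = sc.simulate(seed=5)
        assert vp1 == vp2
        assert np.array_equal(cm1.matrix.to_numpy(), cm2.matrix.to_numpy())

    def test_null_scenario_has_no_effects(self):
        sc = null_scenario()
        _, vp = sc.build_fragments(seed=1)
        assert sc.effects(vp) == {}

    def test_default_scenario_injects_fold5_domain_at_350kb(self):
        sc = default_scenario()
        _, vp = sc.build_fragments(seed=1)
        effects = sc.effects(vp)
        assert list(effects) == ["neuron"]
        (eff,) = effects["neuron"]
        assert eff.fold == 5.0
        assert eff.region.start == vp.midpoint + 350_000
        assert eff.region.width == 100_000

    def test_unknown_scenario_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("no_such_key = 1\n")
        with pytest.raises(ValidationError, match="no_such_key"):
            load_scenario(p)

    def test_scenario_file_overrides_defaults(self, tmp_path):
        p = tmp_path / "s.cfg"
        p.write_text("effect_fold = 2.5\nchrom = chrQ\n")
        sc = load_scenario(p)
        assert sc["effect_fold"] == 2.5
        assert sc["chrom"] == "chrQ"
        assert sc["roi_radius"] == 500_000  # untouched default


class TestRandomSequence:
    def test_at_fraction_respected(self):
        seq = random_sequence(50_000, 0.58, seed=1)
        at = sum(seq.count(b) for b in "AT") / len(seq)
        assert at == pytest.approx(0.58, abs=0.01)

    def test_seeded_and_validated(self):
        assert random_sequence(100, 0.5, seed=2) == random_sequence(100, 0.5, seed=2)
        with pytest.raises(ValidationError):
            random_sequence(100, 1.5, seed=1)
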