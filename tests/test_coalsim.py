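"""Structured-coalescent simulator: analytic expectations, serial-sampling
constraints, demographic-event semantics and the model library."""

import numpy as np
import pytest

from mitodemes import coalsim as cs
from mitodemes.coalsim import (
    DemographicModel,
    Event,
    MigrationEpoch,
    ModelError,
    MutationModel,
    Prior,
    SampleGroup,
    SamplingScheme,
    SimulationError,
    draw_parameters,
    model_library,
    mutate,
    simulate_dataset,
    simulate_genealogy,
)


def one_deme(ne=1000.0):
    return DemographicModel(demes={"d": [(0.0, ne)]})


class TestSimulateGenealogy:
    def test_pair_coalescence_time_mean(self, rng):
        """E[T2] = Ne for a haploid pair (20,000 replicates, 3 SE)."""
        model = one_deme(1000.0)
        scheme = SamplingScheme([SampleGroup("g", "d", 2)])
        times = np.array(
            [simulate_genealogy(model, scheme, rng).tmrca() for _ in range(20_000)]
        )
        se = times.std() / np.sqrt(len(times))
        assert abs(times.mean() - 1000.0) < 3 * se

    def test_isolated_demes_cannot_coalesce(self, rng):
        model = DemographicModel(demes={"a": [(0.0, 100.0)], "b": [(0.0, 100.0)]})
        scheme = SamplingScheme([SampleGroup("x", "a", 2), SampleGroup("y", "b", 2)])
        with pytest.raises(SimulationError):
            simulate_genealogy(model, scheme, rng)

    def test_serial_tip_bounds_tmrca(self, rng):
        model = one_deme(50.0)  # small Ne: TMRCA would usually be << tau
        tau = 500.0
        scheme = SamplingScheme(
            [SampleGroup("new", "d", 1), SampleGroup("old", "d", 1, tau * 25.0, 0.0)]
        )
        for _ in range(200):
            g = simulate_genealogy(model, scheme, rng, tip_times_gen={"new": 0.0, "old": tau})
            assert g.tmrca() >= tau

    def test_migration_connects_demes(self, rng):
        model = DemographicModel(
            demes={"a": [(0.0, 500.0)], "b": [(0.0, 500.0)]},
            migration_epochs=[
                MigrationEpoch(0.0, np.inf, {"a": {"b": 0.01}, "b": {"a": 0.01}})
            ],
        )
        scheme = SamplingScheme([SampleGroup("x", "a", 3), SampleGroup("y", "b", 3)])
        g = simulate_genealogy(model, scheme, rng)
        assert g.tmrca() > 0

    def test_merge_event_joins_demes(self, rng):
        model = DemographicModel(
            demes={"a": [(0.0, 500.0)], "b": [(0.0, 500.0)]},
            events=[Event(100.0, "merge", "b", "a")],
        )
        scheme = SamplingScheme([SampleGroup("x", "a", 2), SampleGroup("y", "b", 2)])
        for seed in range(20):
            g = simulate_genealogy(model, scheme, np.random.default_rng(seed))
            children = g.children()
            for node in range(g.n_tips, len(g.parent)):
                demes = {g.tip_demes[c] for c in children[node] if c < g.n_tips}
                if demes == {"a", "b"}:  # cross-deme coalescence
                    assert g.time[node] >= 100.0

    def test_unknown_deme_rejected(self):
        with pytest.raises(ModelError):
            DemographicModel(
                demes={"a": [(0.0, 100.0)]},
                events=[Event(10.0, "merge", "z", "a")],
            )

    def test_epoch_size_change_effective(self, rng):
        """A 10x bottleneck backward of t=50 shortens pair TMRCA."""
        model = DemographicModel(demes={"d": [(0.0, 10_000.0), (50.0, 100.0)]})
        scheme = SamplingScheme([SampleGroup("g", "d", 2)])
        times = np.array(
            [simulate_genealogy(model, scheme, rng).tmrca() for _ in range(2_000)]
        )
        # E[T2] = E[T 1{T<50}] + P(T>50)(50 + 100) for exponential(1/1e4)
        surv = np.exp(-50 / 10_000)
        expected = 10_000 * (1 - surv) - 50 * surv + surv * (50 + 100)
        se = times.std() / np.sqrt(len(times))
        assert abs(times.mean() - expected) < 3 * se

    def test_determinism(self):
        model = one_deme()
        scheme = SamplingScheme([SampleGroup("g", "d", 5)])
        g1 = simulate_genealogy(model, scheme, 42)
        g2 = simulate_genealogy(model, scheme, 42)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.array_equal(g1.time, g2.time)


class TestMutate:
    def test_zero_rate_identical_sequences(self, rng):
        g = simulate_genealogy(one_deme(), SamplingScheme([SampleGroup("g", "d", 4)]), rng)
        aln = mutate(g, MutationModel(L=100, mu_site_gen=0.0), rng)
        assert len({s for s in aln.sequences()}) == 1

    def test_star_tree_pairwise_differences(self, rng):
        """Star genealogy, branch t: E[pairwise diff] ~ 2 t mu L."""
        import mitodemes.coalsim as c

        n, t, mu, L = 2, 200.0, 5e-6, 1000
        diffs = []
        for _ in range(5_000):
            g = c.Genealogy(
                parent=np.array([2, 2, -1]),
                time=np.array([0.0, 0.0, t]),
                n_tips=2,
                tip_ids=["a", "b"],
                tip_groups=["g", "g"],
                tip_demes=["d", "d"],
                node_deme=["d", "d", "d"],
            )
            aln = mutate(g, MutationModel(L=L, mu_site_gen=mu), rng)
            diffs.append((aln.matrix[0] != aln.matrix[1]).sum())
        diffs = np.array(diffs)
        expected = 2 * t * mu * L  # 2.0; saturation negligible
        se = diffs.std() / np.sqrt(len(diffs))
        assert abs(diffs.mean() - expected) < 3 * se

    def test_fixed_seed_reproducible(self):
        g = simulate_genealogy(one_deme(), SamplingScheme([SampleGroup("g", "d", 6)]), 7)
        a1 = mutate(g, MutationModel(L=500), 99)
        a2 = mutate(g, MutationModel(L=500), 99)
        assert np.array_equal(a1.matrix, a2.matrix)

    def test_transition_bias(self, rng):
        """kappa >> 1 makes nearly all changes transitions (A<->G, C<->T)."""
        g = cs.Genealogy(
            parent=np.array([1, -1]),
            time=np.array([0.0, 500.0]),
            n_tips=1,
            tip_ids=["a"],
            tip_groups=["g"],
            tip_demes=["d"],
            node_deme=["d", "d"],
        )
        root = np.zeros(2000, dtype=np.uint8)  # all A
        aln = mutate(g, MutationModel(L=2000, mu_site_gen=5e-5, ts_tv_ratio=1e6), rng, root)
        changed = aln.matrix[0][aln.matrix[0] != 0]
        assert len(changed) > 10
        assert np.all(changed == 2)  # A -> G only


class TestPriors:
    def test_fixed(self, rng):
        assert Prior("fixed", 1000.0).draw(rng) == 1000.0

    def test_degenerate_uniform(self, rng):
        assert Prior("uniform", 10.0, 10.0).draw(rng) == 10.0

    def test_loguniform_median(self, rng):
        draws = [Prior("loguniform", 1e2, 1e4).draw(rng) for _ in range(50_000)]
        assert 900 <= float(np.median(draws)) <= 1100

    def test_unknown_distribution_rejected(self, rng):
        with pytest.raises(ModelError):
            Prior("beta", 1.0, 2.0).draw(rng)

    def test_draw_order_stable(self, rng):
        priors = {"a": Prior("fixed", 1.0), "b": Prior("uniform", 0.0, 1.0)}
        params = draw_parameters(priors, rng)
        assert list(params) == ["a", "b"]


class TestModelLibrary:
    def test_model_a_group_sizes(self):
        template = model_library("A")
        sizes = [g.n for g in template.scheme.groups]
        assert sizes == [8, 8, 4, 3, 14, 55, 3, 3, 5, 6, 236]

    def test_g_vs_c_differ_only_in_migration(self, rng):
        params = {k: 1000.0 for k in model_library("G").priors}
        params["m_iron"] = 0.005
        params["m_medieval"] = 0.005
        mc = model_library("C").instantiate({k: v for k, v in params.items() if not k.startswith("m_")})
        mg = model_library("G").instantiate(params)
        assert mc.demes == mg.demes
        assert mc.events == mg.events
        assert not mc.migration_epochs and len(mg.migration_epochs) == 2

    def test_gst_east_block_membership(self):
        assert set(cs.GEOGROUP_EAST) == {
            "caltanissetta_enna",
            "catania_siracusa",
            "gela",
            "messina",
            "ragusa",
        }

    def test_gst_migration_blocks_disjoint(self):
        template = model_library("Gst")
        params = {k: (0.01 if k.startswith("m_") else 1000.0) for k in template.priors}
        model = template.instantiate(params)
        modern = next(
            me for me in model.migration_epochs if me.t_start_gen == 0.0
        )
        for src in cs.GEOGROUP_WEST:
            assert set(modern.rates[src]) <= set(cs.GEOGROUP_WEST)
        for src in cs.GEOGROUP_EAST:
            assert set(modern.rates[src]) <= set(cs.GEOGROUP_EAST)

    def test_unknown_model_rejected(self):
        with pytest.raises(ModelError):
            model_library("Z")

    def test_replacement_separates_pre_and_post_lineages(self, rng):
        """Under the forager/farmer discontinuity, lineages sampled after
        the replacement only meet pre-replacement lineages at or beyond
        the deep-ancestry merge."""
        template = model_library("C", sample_scale=0.25)
        params = {k: 2000.0 for k in template.priors}
        model = template.instantiate(params)
        tip_times = {
            g.name: g.age_mean_years / model.generation_time for g in template.scheme.groups
        }
        t_deep = cs.DEEP_ANCESTRY / model.generation_time
        for seed in range(5):
            g = simulate_genealogy(model, template.scheme, np.random.default_rng(seed), tip_times)
            meso = {
                i for i in range(g.n_tips) if g.tip_groups[i] == "uzzo_mesolithic"
            }
            children = g.children()
            # tips under each internal node
            for node in range(g.n_tips, len(g.parent)):
                stack, tips = [node], set()
                while stack:
                    x = stack.pop()
                    if x < g.n_tips:
                        tips.add(x)
                    else:
                        stack.extend(children[x])
                if tips & meso and tips - meso:
                    assert g.time[node] >= t_deep - 1e-9


class TestSimulateDataset:
    def test_model_a_total_rows(self):
        template = model_library("A")
        mut = MutationModel(L=200)
        ds = simulate_dataset(template, mut, 3)
        assert ds.alignment.n == 345  # sum of the 11 group sizes

    def test_same_seed_identical(self):
        template = model_library("C", sample_scale=0.25)
        mut = MutationModel(L=300)
        d1 = simulate_dataset(template, mut, 11)
        d2 = simulate_dataset(template, mut, 11)
        assert np.array_equal(d1.alignment.matrix, d2.alignment.matrix)
        assert d1.params == d2.params
        assert [m.age_bp for m in d1.metadata] == [m.age_bp for m in d2.metadata]

    def test_metadata_groups_match_scheme(self):
        template = model_library("A", sample_scale=0.25)
        ds = simulate_dataset(template, MutationModel(L=200), 5)
        by_group = {}
        for m in ds.metadata:
            by_group[m.group] = by_group.get(m.group, 0) + 1
        assert by_group == {g.name: g.n for g in template.scheme.groups}


class TestCrossSimulatorCalibration:
    def test_mean_tajimas_d_matches_msprime(self, rng):
        """Dual-route check: the simulator's mean Tajima's D equals
        msprime's under identical single-deme conditions (the shared,
        slightly negative neutral finite-sample expectation)."""
        msprime = pytest.importorskip("msprime")
        from mitodemes.sumstats import tajimas_d

        n, ne, mu, L, reps = 20, 1000.0, 2.5e-6, 2000, 1500
        model = one_deme(ne)
        scheme = SamplingScheme([SampleGroup("g", "d", n)])
        mine = []
        for _ in range(reps):
            g = simulate_genealogy(model, scheme, rng)
            d = tajimas_d(mutate(g, MutationModel(L=L, mu_site_gen=mu), rng))
            if d == d:
                mine.append(d)
        theirs = []
        for _ in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=ne, sequence_length=L,
                random_seed=int(rng.integers(1, 2**31)),
            )
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=int(rng.integers(1, 2**31)))
            d = mts.Tajimas_D()
            if d == d:
                theirs.append(float(d))
        mine, theirs = np.array(mine), np.array(theirs)
        se_diff = np.sqrt(mine.var() / len(mine) + theirs.var() / len(theirs))
        assert abs(mine.mean() - theirs.mean()) < 3 * se_diff
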