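"""Simulator unit tests: effect table, mutagenesis, activity, selection,
experiment determinism and read emission."""

import numpy as np
import pytest

from mistransevo import evo_sim as sim
from mistransevo.genetics import N_AA, STOP_AA, encode

SMALL = dict(
    reference=sim.synthetic_reference(40),
    bottleneck_size=100,
    depth=50,
    canonical_codons=(10, 20, 30),
)


def small_config(**over):
    kw = {**SMALL, **over}
    return sim.SimConfig(**kw)


class TestSyntheticReference:
    def test_deterministic_fixture(self):
        a = sim.synthetic_reference()
        b = sim.synthetic_reference()
        assert a.cds_sequence == b.cds_sequence
        assert len(a) == 861

    def test_canonical_codons_are_the_real_ones(self):
        ref = sim.synthetic_reference()
        for codon, expected in zip((104, 182, 238), ("GAA", "ATG", "GGT")):
            assert ref.cds_sequence[3 * (codon - 1) : 3 * codon] == expected


class TestEffectTable:
    def test_all_deleterious_mixture(self):
        cfg = small_config(p_neutral=0.0, p_deleterious=1.0, p_beneficial=0.0)
        table = sim.init_effect_table(cfg, np.random.default_rng(0))
        repertoire = {(c, a) for c, a, _ in table.canonical}
        for c in range(table.n_codons):
            for a in range(N_AA):
                if a == table.ref_aas[c] or (c, a) in repertoire:
                    continue
                assert table.effects[c, a] < 0

    def test_reference_amino_acid_is_neutral_and_stop_lethal(self):
        cfg = small_config()
        table = sim.init_effect_table(cfg, np.random.default_rng(1))
        body = table.ref_aas[:-1]
        assert np.allclose(table.effects[np.arange(len(body)), body], 0.0)
        assert np.allclose(table.effects[:, STOP_AA], -1.0)

    def test_deterministic_given_seed(self):
        cfg = small_config()
        t1 = sim.init_effect_table(cfg, np.random.default_rng(5))
        t2 = sim.init_effect_table(cfg, np.random.default_rng(5))
        assert np.array_equal(t1.effects, t2.effects)

    def test_empirical_mixture_fractions(self):
        # over 285*19 entries of the full-size reference, the deleterious
        # fraction should sit within 3 binomial sigma of p_deleterious
        cfg = sim.SimConfig()
        table = sim.init_effect_table(cfg, np.random.default_rng(2))
        repertoire = {(c, a) for c, a, _ in table.canonical}
        mask = np.ones_like(table.effects[:, :N_AA], dtype=bool)
        mask[np.arange(table.n_codons - 1), table.ref_aas[:-1]] = False
        mask[-1, :] = False  # terminal stop codon row has no reference aa
        for c, a in repertoire:
            mask[c, a] = False
        vals = table.effects[:, :N_AA][mask]
        frac_del = (vals < 0).mean()
        n = vals.size
        sigma = np.sqrt(cfg.p_deleterious * (1 - cfg.p_deleterious) / n)
        assert abs(frac_del - cfg.p_deleterious) < 3 * sigma

    def test_overlay_perturbs_copy_only(self):
        cfg = small_config()
        table = sim.init_effect_table(cfg, np.random.default_rng(3))
        before = table.effects.copy()
        mod = table.with_overlay({(5, 2): -0.5})
        assert mod.effects[5, 2] == pytest.approx(max(before[5, 2] - 0.5, -1.0))
        assert np.array_equal(table.effects, before)


class TestMutagenize:
    def test_rate_zero_is_identity(self):
        ref = SMALL["reference"]
        pop = np.tile(ref.codes, (20, 1))
        out = sim.mutagenize(pop, 0.0, sim._default_bias(), np.random.default_rng(0))
        assert np.array_equal(out, pop)

    def test_mean_mutation_count_matches_rate(self):
        ref = sim.synthetic_reference()
        pop = np.tile(ref.codes, (10_000, 1))
        out = sim.mutagenize(pop, 0.7, sim._default_bias(), np.random.default_rng(1))
        mean = (out != ref.codes[None, :]).sum(axis=1).mean()
        assert mean == pytest.approx(0.7, abs=0.03)

    def test_pure_transition_bias_only_mutates_a_to_g(self):
        ref = SMALL["reference"]
        pop = np.tile(ref.codes, (200, 1))
        out = sim.mutagenize(pop, 1.0, {"A>G": 1.0}, np.random.default_rng(2))
        changed = out != ref.codes[None, :]
        assert changed.any()
        assert (ref.codes[np.nonzero(changed)[1]] == 0).all()  # only A sites
        assert (out[changed] == 2).all()  # always to G


class TestCellActivity:
    def _table_with(self, cfg, codon, aa, s):
        table = sim.init_effect_table(cfg, np.random.default_rng(0))
        table.effects[codon, aa] = s
        return table

    def test_wild_type_without_mistranslation_is_exactly_one(self):
        cfg = small_config()
        table = sim.init_effect_table(cfg, np.random.default_rng(0))
        act = sim.cell_activity(
            cfg.reference.codes, cfg.reference, table, 0.0, 10,
            np.random.default_rng(1),
        )
        assert act == 1.0

    def test_single_known_effect_multiplies(self):
        cfg = small_config()
        ref = cfg.reference
        # make codon 5 mutate to a known amino acid with s = -0.1
        geno = ref.codes.copy()
        geno[12:15] = encode("AAA")  # codon 5 -> K
        from mistransevo.genetics import AA_INDEX

        table = self._table_with(cfg, 4, AA_INDEX["K"], -0.1)
        act = sim.cell_activity(geno, ref, table, 0.0, 5, np.random.default_rng(2))
        assert act == pytest.approx(0.9)

    def test_premature_stop_zeroes_activity(self):
        cfg = small_config()
        ref = cfg.reference
        geno = ref.codes.copy()
        geno[12:15] = encode("TAA")
        table = sim.init_effect_table(cfg, np.random.default_rng(0))
        act = sim.cell_activity(geno, ref, table, 0.0, 5, np.random.default_rng(3))
        assert act == 0.0

    def test_mistranslation_lowers_expected_activity(self):
        cfg = small_config(p_neutral=0.0, p_deleterious=1.0, p_beneficial=0.0)
        table = sim.init_effect_table(cfg, np.random.default_rng(4))
        pop = np.tile(cfg.reference.codes, (2000, 1))
        acts = sim.population_activities(
            pop, cfg.reference, table, 5e-3, 20, np.random.default_rng(5)
        )
        assert acts.mean() < 1.0
        assert (acts >= 0).all()

    def test_epsilon_zero_is_deterministic(self):
        cfg = small_config()
        table = sim.init_effect_table(cfg, np.random.default_rng(0))
        pop = np.tile(cfg.reference.codes, (10, 1))
        a = sim.population_activities(pop, cfg.reference, table, 0.0, 100,
                                      np.random.default_rng(1))
        b = sim.population_activities(pop, cfg.reference, table, 0.0, 100,
                                      np.random.default_rng(999))
        assert np.array_equal(a, b)


class TestSelectOnGradient:
    def test_inclusive_threshold_choice(self):
        cfg = small_config(base_concentration=0.5, n_concentrations=3,
                           survival_quorum=2, bottleneck_size=10)
        genotypes = np.tile(cfg.reference.codes, (10, 1))
        acts = np.ones(10)
        _, c_star, n_surv = sim.select_on_gradient(
            genotypes, acts, cfg, np.random.default_rng(0)
        )
        assert c_star == 1.0 and n_surv == 10

    def test_survivor_count_non_increasing_in_concentration(self):
        rng = np.random.default_rng(1)
        acts = rng.random(100) * 4
        cfg = small_config()
        counts = [(acts >= c).sum() for c in cfg.concentrations]
        assert counts == sorted(counts, reverse=True)

    def test_extinction_signal(self):
        cfg = small_config(survival_quorum=1000)
        genotypes = np.tile(cfg.reference.codes, (10, 1))
        with pytest.raises(sim.ExtinctionError):
            sim.select_on_gradient(genotypes, np.ones(10), cfg,
                                   np.random.default_rng(0))


class TestRunExperiment:
    def test_neutral_run_stays_ancestral(self):
        cfg = small_config(mutation_rate=0.0, mistranslation_rate=0.0,
                           generations=2)
        pops, table, truth = sim.run_experiment(cfg)
        for p in pops:
            assert (p.genotypes == cfg.reference.codes[None, :]).all()
        assert len(truth) == 0

    def test_fixed_seed_reproducible(self):
        cfg = small_config(generations=2, seed=11)
        _, _, t1 = sim.run_experiment(cfg)
        _, _, t2 = sim.run_experiment(cfg)
        assert t1.equals(t2)

    def test_truth_frequencies_match_population_counts(self):
        cfg = small_config(generations=2, seed=3)
        pops, _, truth = sim.run_experiment(cfg)
        B = cfg.bottleneck_size
        final = truth[truth["generation"] == 2]
        for _, row in final.iterrows():
            col = int(row["position"]) - 1
            code = "ACGT".index(row["alt"])
            assert (pops[2].genotypes[:, col] == code).sum() == row["count"]
            assert row["frequency"] == row["count"] / B


class TestStrongSelectionRound:
    def test_empty_overlay_equals_base_table(self):
        cfg = small_config(generations=2, seed=5)
        pops, table, _ = sim.run_experiment(cfg)
        a, ch_a = sim.strong_selection_round(pops[-1], cfg, table, None)
        b, ch_b = sim.strong_selection_round(pops[-1], cfg, table, {})
        assert np.array_equal(a.genotypes, b.genotypes)
        assert ch_a.equals(ch_b)

    def test_deterministic_under_seed(self):
        cfg = small_config(generations=2, seed=5)
        pops, table, _ = sim.run_experiment(cfg)
        overlay = sim.condition_overlay(table, "drugA", seed=1)
        _, ch1 = sim.strong_selection_round(pops[-1], cfg, table, overlay)
        _, ch2 = sim.strong_selection_round(pops[-1], cfg, table, overlay)
        assert ch1.equals(ch2)

    def test_condition_overlay_reproducible_and_never_reference(self):
        cfg = small_config()
        table = sim.init_effect_table(cfg, np.random.default_rng(0))
        o1 = sim.condition_overlay(table, "drugA", seed=7)
        o2 = sim.condition_overlay(table, "drugA", seed=7)
        assert o1 == o2
        for (codon, aa) in o1:
            assert aa != table.ref_aas[codon]


class TestEmitFastq:
    def test_error_free_reads_are_exact_copies(self):
        cfg = small_config(generations=1, seed=9)
        pops, _, _ = sim.run_experiment(cfg)
        records, truth = sim.emit_fastq(pops[-1], 20, 0.0,
                                        np.random.default_rng(0))
        from mistransevo.genetics import encode as enc

        genos = {p.tobytes() for p in pops[-1].genotypes}
        for rid, seq, quals in records:
            assert seq[:6] == "ACGTAC"
            assert enc(seq[6:]).tobytes() in genos
            assert (quals == 40).all()

    def test_observed_error_rate_matches_setting(self):
        cfg = small_config(generations=1, seed=9, mutation_rate=0.0)
        pops, _, _ = sim.run_experiment(cfg)
        rate = 5e-3
        records, _ = sim.emit_fastq(pops[-1], 200, rate,
                                    np.random.default_rng(1))
        ref = cfg.reference
        mism = sum(
            (encode(seq[6:]) != ref.codes).sum() for _, seq, _ in records
        )
        trials = 200 * len(ref)
        sigma = np.sqrt(rate * (1 - rate) * trials)
        assert abs(mism - rate * trials) < 4 * sigma

    def test_truth_is_the_sampled_frequencies(self):
        cfg = small_config(generations=1, seed=13)
        pops, _, _ = sim.run_experiment(cfg)
        records, truth = sim.emit_fastq(pops[-1], 30, 0.0,
                                        np.random.default_rng(2))
        mats = np.vstack([encode(seq[6:]) for _, seq, _ in records])
        for _, row in truth.iterrows():
            col = int(row["position"]) - 1
            code = "ACGT".index(row["alt"])
            assert row["frequency"] == pytest.approx(
                (mats[:, col] == code).mean()
            )


class TestConfigVariants:
    def test_yaml_round_trip_and_unknown_keys(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("bottleneck_size: 200\nmistranslation_rate: 1.0e-3\n")
        cfg = sim.SimConfig.from_yaml(path)
        assert cfg.bottleneck_size == 200
        assert cfg.mistranslation_rate == pytest.approx(1e-3)
        path.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            sim.SimConfig.from_yaml(path)

    def test_experiment_scale_preset(self):
        assert small_config().experiment_scale().bottleneck_size == 100_000

    def test_soft_threshold_survival_is_nested_and_reproducible(self):
        cfg = small_config(soft_threshold_steepness=4.0)
        genotypes = np.tile(cfg.reference.codes, (200, 1))
        acts = np.random.default_rng(0).uniform(0.2, 2.0, size=200)
        a = sim.select_on_gradient(genotypes, acts, cfg, np.random.default_rng(1))
        b = sim.select_on_gradient(genotypes, acts, cfg, np.random.default_rng(1))
        assert a[1] == b[1] and a[2] == b[2]
        # zero-activity cells are never resurrected by the logistic form
        with pytest.raises(sim.ExtinctionError):
            sim.select_on_gradient(genotypes, np.zeros(200), cfg,
                                   np.random.default_rng(2))

    def test_independent_phenotypic_table_is_used_when_supplied(self):
        cfg = small_config()
        geno_table = sim.init_effect_table(cfg, np.random.default_rng(0))
        # a phenotypic table where every mistranslation event is lethal
        lethal = sim.init_effect_table(
            small_config(p_neutral=0.0, p_deleterious=1.0, p_beneficial=0.0,
                         deleterious_shape=50.0, deleterious_scale=1.0),
            np.random.default_rng(1),
        )
        pop = np.tile(cfg.reference.codes, (500, 1))
        shared = sim.population_activities(
            pop, cfg.reference, geno_table, 0.05, 10, np.random.default_rng(2)
        )
        indep = sim.population_activities(
            pop, cfg.reference, geno_table, 0.05, 10, np.random.default_rng(2),
            phenotypic_table=lethal,
        )
        assert indep.mean() < shared.mean()
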