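"""Evolutionary loop: configuration, operators, and search behaviour."""

import numpy as np
import pytest

from trihelix import (
    ConfigError,
    GAConfig,
    MotifSpec,
    crossover,
    fitness,
    initialize_population,
    mutate,
    run,
    select_parents,
    validate_sequence,
)
from trihelix.fixtures import toy_design_space
from trihelix.ga import legal_cut_points
from trihelix.peptides import XY_ALPHABET

ALL = set("ACDEFGHIKLMNPQRSTVWYO")


def restricted(xaa=("P", "D"), yaa=("O", "K")):
    return {"Xaa": ALL - set(xaa), "Yaa": ALL - set(yaa)}


def pair_set(seq1, seq2, frame=2):
    return (
        validate_sequence(seq1, frame, id="A"),
        validate_sequence(seq2, frame, id="B"),
    )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,fragment",
        [
            ({"peptide_length": 20}, "21,40"),
            ({"peptide_length": 41}, "21,40"),
            ({"target_tm": 75.0}, "30,70"),
            ({"target_tm": 29.0}, "30,70"),
            ({"target_specificity": 36.0}, "10,35"),
            ({"crossover_rate": 1.5}, "0,1"),
            ({"composition": "AABB"}, "A2B"),
            ({"population_size": 1}, "at least 2"),
        ],
    )
    def test_out_of_range_rejected(self, kwargs, fragment):
        with pytest.raises(ConfigError, match=fragment.replace(",", ".")):
            GAConfig(**kwargs)

    def test_weights_switch_with_motif(self):
        assert GAConfig().weights == (0.5, 0.5, 0.0)
        motif = MotifSpec(trailing="GFOGER")
        assert GAConfig(motif=motif).weights == (0.4, 0.4, 0.2)

    def test_designated_register(self):
        assert GAConfig(composition="ABC").designated_register == (0, 1, 2)
        assert GAConfig(composition="A2B").designated_register == (0, 0, 1)

    def test_exhausted_exclusions_rejected(self):
        with pytest.raises(ConfigError):
            GAConfig(excluded={"Xaa": set(XY_ALPHABET)})


class TestMotifSpec:
    def test_requires_gly_on_frame(self):
        with pytest.raises(ConfigError, match="no Gly"):
            MotifSpec(leading="KDO")
        with pytest.raises(ConfigError, match="spacing"):
            MotifSpec(leading="GPGO")  # Gly at 0 and 2

    def test_length_bounds(self):
        with pytest.raises(ConfigError, match="3,15"):
            MotifSpec(leading="GP")
        with pytest.raises(ConfigError, match="3,15"):
            MotifSpec(leading="GPO" * 6)

    def test_empty_spec_rejected(self):
        with pytest.raises(ConfigError):
            MotifSpec()

    def test_gfoger_layout_centred_and_frame_aligned(self):
        config = GAConfig(
            composition="ABC", peptide_length=30, motif=MotifSpec(trailing="gfoger")
        )
        masks = config.motif_masks
        assert masks[:2] == (None, None)
        start, end = masks[2]
        assert end - start == 6 and start == 12
        assert config.frame_offset == (start + 0) % 3  # Gly leads the motif

    def test_a2b_shared_slot_motif_conflict(self):
        with pytest.raises(ConfigError, match="identical"):
            GAConfig(
                composition="A2B",
                motif=MotifSpec(leading="GFOGER", middle="GPOGPO"),
            ).slot_motifs()


class TestInitialization:
    def test_slot_counts_and_determinism(self):
        config = GAConfig(composition="A2B", population_size=8, rng_seed=5)
        pop1 = initialize_population(config, np.random.default_rng(5))
        pop2 = initialize_population(config, np.random.default_rng(5))
        assert pop1 == pop2
        assert all(len(ind) == 2 for ind in pop1)

    def test_motif_inserted_and_flanks_random(self):
        config = GAConfig(
            composition="ABC",
            peptide_length=30,
            motif=MotifSpec(leading="GFOGER"),
            rng_seed=0,
        )
        pop = initialize_population(config, np.random.default_rng(0))
        start, end = config.motif_masks[0]
        assert all(ind[0].residues[start:end] == "GFOGER" for ind in pop)
        flanks = {ind[0].residues[:start] for ind in pop}
        assert len(flanks) > 1

    def test_excluded_residues_never_drawn(self):
        config = GAConfig(
            composition="ABC", population_size=20, excluded=restricted()
        )
        pop = initialize_population(config, np.random.default_rng(1))
        for ind in pop:
            for p in ind:
                for i, ch in enumerate(p.residues):
                    phase = (i - p.frame_offset) % 3
                    if phase == 1:
                        assert ch in {"P", "D"}
                    elif phase == 2:
                        assert ch in {"O", "K"}

    def test_all_frames_appear_without_motif(self):
        config = GAConfig(composition="ABC", population_size=60)
        pop = initialize_population(config, np.random.default_rng(2))
        assert {ind[0].frame_offset for ind in pop} == {0, 1, 2}


class TestFitness:
    def test_formula_without_motif(self, toy_params):
        from trihelix import specificity_report

        space = toy_design_space()
        config = GAConfig(composition="A2B", peptide_length=21)
        helix_set = space.build(("P", "K", "D", "O", "P", "O", "D", "K"))
        result = fitness(helix_set, toy_params, config)
        report = specificity_report(list(helix_set), toy_params)
        assert result.score == 0.5 * report.specificity + 0.5 * report.ranked[0][1].tm
        assert result.best_register == report.best_register

    def test_register_bonus_sign(self, toy_params):
        space = toy_design_space()
        config = space.config  # motif mode: weights (0.4, 0.4, 0.2)
        helix_set = space.build(("P", "K", "D", "O", "P", "O", "D", "K"))
        result = fitness(helix_set, toy_params, config)
        base = 0.4 * result.specificity + 0.4 * result.tm
        # register term is exactly ±(0.2 * 50)
        assert result.score - base == pytest.approx(
            0.2 * (50.0 if result.best_register == (0, 0, 1) else -50.0)
        )


class TestSelection:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([3, 9, 1, 9], (1, 3)),
            ([9, 8, 7], (0, 1)),
            ([5, 5, 5], (0, 1)),
        ],
    )
    def test_top_two_with_tie_rule(self, scores, expected):
        population = [object()] * len(scores)
        assert select_parents(population, scores) == expected

    def test_population_too_small(self):
        with pytest.raises(ConfigError):
            select_parents([object()], [1.0])


class TestCrossover:
    def test_rate_zero_is_identity(self):
        p1 = pair_set("POG" * 7, "POG" * 7)
        p2 = pair_set("PKG" * 7, "PKG" * 7)
        child = crossover(p1, p2, 0.0, (None, None), np.random.default_rng(0))
        assert child == p1

    def test_gly_anchored_cut(self):
        p1 = pair_set("POG" * 7, "POG" * 7)
        p2 = pair_set("PKG" * 7, "PKG" * 7)
        legal = legal_cut_points(p1, (None, None))
        assert legal == [3, 6, 9, 12, 15, 18]
        seen = set()
        for seed in range(200):
            child = crossover(p1, p2, 1.0, (None, None), np.random.default_rng(seed))
            matches = [
                c
                for c in legal
                if child[0].residues == ("POG" * 7)[:c] + ("PKG" * 7)[c:]
            ]
            assert matches, "offspring is not a single Gly-anchored splice"
            seen.add(matches[0])
            assert child[0].residues[:3] == "POG" and child[0].residues[-3:] == "PKG"
        assert seen == set(legal)

    def test_cut_applied_at_same_index_on_all_strands(self):
        p1 = pair_set("POG" * 7, "DOG" * 7)
        p2 = pair_set("PKG" * 7, "DKG" * 7)
        child = crossover(p1, p2, 1.0, (None, None), np.random.default_rng(3))
        cut_a = next(
            c for c in range(3, 21, 3) if child[0].residues == ("POG" * 7)[:c] + ("PKG" * 7)[c:]
        )
        cut_b = next(
            c for c in range(3, 21, 3) if child[1].residues == ("DOG" * 7)[:c] + ("DKG" * 7)[c:]
        )
        assert cut_a == cut_b

    def test_motif_region_excluded_from_cut_draw(self):
        """No cut index interior to the masked triplets is ever drawn."""
        mask = (9, 18)
        p1 = pair_set("PKG" * 3 + "POG" * 3 + "PKG", "PKG" * 3 + "POG" * 3 + "PKG")
        p2 = pair_set("PAG" * 3 + "POG" * 3 + "PAG", "PAG" * 3 + "POG" * 3 + "PAG")
        legal = legal_cut_points(p1, (mask, mask))
        assert legal == [3, 6, 9, 18]
        assert not set(legal) & set(range(mask[0] + 1, mask[1]))
        for seed in range(500):
            child = crossover(p1, p2, 1.0, (mask, mask), np.random.default_rng(seed))
            assert any(
                child[0].residues
                == p1[0].residues[:c] + p2[0].residues[c:]
                for c in legal
            )

    def test_mismatched_frames_fall_back_to_copy(self):
        p1 = pair_set("POG" * 7, "POG" * 7, frame=2)
        p2 = pair_set("GPO" * 7, "GPO" * 7, frame=0)
        child = crossover(p1, p2, 1.0, (None, None), np.random.default_rng(0))
        assert child == p1


class TestMutation:
    def test_rate_zero_is_identity(self):
        helix_set = pair_set("POG" * 7, "PKG" * 7)
        out = mutate(helix_set, 0.0, {}, (None, None), np.random.default_rng(0))
        assert out == helix_set

    def test_rate_one_forced_alphabet_gives_pog(self):
        helix_set = pair_set("DKG" * 7, "EEG" * 7)
        excluded = {"Xaa": ALL - {"P"}, "Yaa": ALL - {"O"}}
        out = mutate(helix_set, 1.0, excluded, (None, None), np.random.default_rng(0))
        assert all(p.residues == "POG" * 7 for p in out)

    def test_gly_and_motif_positions_never_mutate(self):
        helix_set = pair_set("POG" * 7, "PKG" * 7)
        mask = (6, 12)
        for seed in range(50):
            out = mutate(
                helix_set, 1.0, {}, (mask, mask), np.random.default_rng(seed)
            )
            for before, after in zip(helix_set, out):
                assert after.residues[6:12] == before.residues[6:12]
                assert after.gly_positions == before.gly_positions
                for g in after.gly_positions:
                    assert after.residues[g] == "G"

    def test_excluded_residues_never_introduced(self):
        helix_set = pair_set("POG" * 7, "PKG" * 7)
        excluded = restricted()
        for seed in range(30):
            out = mutate(
                helix_set, 0.8, excluded, (None, None), np.random.default_rng(seed)
            )
            for p in out:
                for i, ch in enumerate(p.residues):
                    phase = (i - p.frame_offset) % 3
                    if phase == 1:
                        assert ch in {"P", "D"}
                    elif phase == 2:
                        assert ch in {"O", "K"}


class TestRun:
    def test_two_position_space_attains_brute_force_optimum(self, toy_params):
        """Search over 16 enumerable states finds the exhaustive optimum."""
        import itertools

        space = toy_design_space(population_size=16, max_rounds=60)
        config = GAConfig(
            **{
                **{
                    f: getattr(space.config, f)
                    for f in (
                        "composition", "peptide_length", "population_size",
                        "target_tm", "target_specificity", "motif", "max_rounds",
                    )
                },
                "excluded": {"Xaa": ALL - {"P"}, "Yaa": ALL - {"O", "K"}},
                "rng_seed": 11,
            }
        )
        # Xaa frozen to P: only the four Yaa flank sites search {O, K}
        best = max(
            fitness(
                space.build((("P",) + yk[:1] + ("P",) + yk[1:2] + ("P",) + yk[2:3] + ("P",) + yk[3:4])[0:8]),
                toy_params,
                config,
            ).score
            for yk in itertools.product("OK", repeat=4)
        )
        result = run(config, toy_params)
        assert result.fitness == pytest.approx(best, abs=1e-9)

    def test_elitism_keeps_best_fitness_monotone(self, toy_params):
        for seed in range(3):
            space = toy_design_space(rng_seed=seed, population_size=12, max_rounds=40)
            trace = run(space.config, toy_params).trace
            fits = [r.best_fitness for r in trace]
            assert all(b >= a - 1e-12 for a, b in zip(fits, fits[1:]))

    def test_seeded_determinism(self, toy_params):
        space = toy_design_space(rng_seed=7, population_size=12, max_rounds=30)
        r1 = run(space.config, toy_params)
        r2 = run(space.config, toy_params)
        assert r1.peptides == r2.peptides
        assert [g.best_fitness for g in r1.trace] == [
            g.best_fitness for g in r2.trace
        ]

    def test_motif_bytes_conserved_in_result(self, toy_params):
        space = toy_design_space(rng_seed=3, population_size=12, max_rounds=30)
        result = run(space.config, toy_params)
        for p in result.peptides:
            assert p.residues[3:18] == "GPOGPOGPOGPOGPO"

    def test_round_cap_returns_best_so_far(self, toy_params):
        space = toy_design_space(rng_seed=1, population_size=8, max_rounds=4)
        result = run(space.config, toy_params)
        assert result.status == "round-cap"
        assert not result.converged
        assert result.generations == 4
        assert len(result.trace) == 5  # generations 0..4 recorded

    def test_restart_retains_global_best(self, toy_params):
        space = toy_design_space(rng_seed=2, population_size=8, max_rounds=40)
        config = space.config
        config.restart_after = 5
        result = run(config, toy_params)
        assert result.fitness == pytest.approx(
            max(r.best_fitness for r in result.trace)
        )

    def test_convergence_stops_on_true_heterotrimer(self, toy_params):
        """A converged design's most stable assembly uses every slot."""
        from trihelix import specificity_report

        config = GAConfig(
            composition="ABC",
            peptide_length=27,
            population_size=100,
            target_tm=30.0,
            target_specificity=10.0,
            excluded=restricted(),
            motif=MotifSpec(trailing="GFOGER"),
            max_rounds=400,
            rng_seed=0,
        )
        result = run(config, toy_params)
        assert result.converged
        assert result.tm >= 30.0 and result.specificity >= 10.0
        report = specificity_report(list(result.peptides), toy_params)
        assert set(report.best_register) == {0, 1, 2}
        seqs = [p.residues for p in result.peptides]
        assert len(set(seqs)) == 3
        assert result.peptides[2].residues[
            config.motif_masks[2][0] : config.motif_masks[2][1]
        ] == "GFOGER"


class TestEvolutionInvariants:
    def test_every_individual_every_generation_is_lawful(self, toy_params):
        """Manual evolution: Gly periodicity, motif bytes and exclusions
        hold for every individual ever created."""
        config = GAConfig(
            composition="ABC",
            peptide_length=27,
            population_size=14,
            excluded=restricted(),
            motif=MotifSpec(trailing="GFOGER"),
            max_rounds=50,
            rng_seed=9,
        )
        rng = np.random.default_rng(9)
        masks = config.motif_masks
        start, end = masks[2]
        population = initialize_population(config, rng)
        for _ in range(20):
            for ind in population:
                for slot, p in enumerate(ind):
                    for i, ch in enumerate(p.residues):
                        phase = (i - p.frame_offset) % 3
                        if phase == 0:
                            assert ch == "G"
                        elif masks[slot] and masks[slot][0] <= i < masks[slot][1]:
                            continue
                        elif phase == 1:
                            assert ch in {"P", "D"}
                        else:
                            assert ch in {"O", "K"}
                assert ind[2].residues[start:end] == "GFOGER"
            scores = [fitness(ind, toy_params, config).score for ind in population]
            i1, i2 = select_parents(population, scores)
            p1, p2 = population[i1], population[i2]
            nxt = [p1, p2]
            while len(nxt) < config.population_size:
                child = crossover(p1, p2, 0.6, masks, rng)
                child = mutate(child, 0.2, config.excluded, masks, rng)
                nxt.append(child)
            population = nxt
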