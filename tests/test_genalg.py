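"""Genetic algorithm: variation operators, selection, and the main loop."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from novelforge import genalg as ga
from novelforge import sampler as sp
from novelforge.structio import AMINO_ACIDS

SEQ = hst.text(alphabet=AMINO_ACIDS, min_size=2, max_size=30)


class TestRecombine:
    def test_fusion_concatenates(self):
        rng = np.random.default_rng(0)
        child, op = ga.recombine("A" * 40, "C" * 40, rng,
                                 splice_probability=0.0, max_length=250)
        assert op == "fusion"
        assert child == "A" * 40 + "C" * 40

    def test_splice_cut_points_interior(self):
        """Splice children always keep ≥1 residue of a's prefix and ≥0 of
        b's suffix with interior cuts: the child never equals parent a
        with b fully appended, nor loses a entirely."""
        rng = np.random.default_rng(1)
        a, b = "A" * 10, "C" * 10
        for _ in range(500):
            child, op = ga.recombine(a, b, rng, splice_probability=1.0)
            assert op == "splice"
            n_a = child.count("A")
            n_c = child.count("C")
            assert 1 <= n_a <= len(a) - 1
            assert 1 <= n_c <= len(b) - 1
            assert child == "A" * n_a + "C" * n_c

    @settings(max_examples=200, derandomize=True)
    @given(a=SEQ, b=SEQ, seed=hst.integers(0, 2 ** 16))
    def test_provenance_every_position_from_a_parent(self, a, b, seed):
        rng = np.random.default_rng(seed)
        child, op = ga.recombine(a, b, rng)
        if op == "fusion":
            assert child == a + b
        else:
            # child = a-prefix + b-suffix with the cut letters matching
            ok = any(
                child == a[:x] + b[y - 1:]
                for x in range(1, len(a))
                for y in range(2, len(b) + 1)
            )
            assert ok

    def test_length_cap_respected(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            child, _ = ga.recombine("A" * 200, "C" * 200, rng, max_length=250)
            assert len(child) <= 250


class TestMutate:
    def test_rate_zero_identity(self):
        rng = np.random.default_rng(0)
        assert ga.mutate("ACDEFGHIKL", 0.0, rng) == "ACDEFGHIKL"

    def test_rate_one_changes_everything(self):
        rng = np.random.default_rng(1)
        seq = "ACDEFGHIKL" * 3
        out = ga.mutate(seq, 1.0, rng)
        assert all(a != b for a, b in zip(seq, out))

    def test_empirical_rate_matches(self):
        rng = np.random.default_rng(2)
        rate = 0.05
        seq = "ACDEFGHIKL" * 10
        n_pos = 0
        n_sub = 0
        while n_pos < 100_000:
            out = ga.mutate(seq, rate, rng)
            n_sub += sum(a != b for a, b in zip(seq, out))
            n_pos += len(seq)
        sigma = np.sqrt(n_pos * rate * (1 - rate))
        assert abs(n_sub - n_pos * rate) < 4 * sigma


class TestRefine:
    def test_zero_steps_identity(self, energy_model):
        rng = np.random.default_rng(0)
        assert ga.refine("ACDEFGHIKL", 0, energy_model, rng) == "ACDEFGHIKL"

    def test_expected_energy_descends(self, energy_model):
        deltas = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            seq = "".join(rng.choice(list(AMINO_ACIDS), 15))
            before = sp.composite_energy(seq, energy_model)
            out = ga.refine(seq, 30, energy_model, rng, temperature=1.0)
            deltas.append(sp.composite_energy(out, energy_model) - before)
        assert np.mean(deltas) < 0

    def test_deterministic_per_seed(self, energy_model):
        out1 = ga.refine("ACDEFGHIKL", 20, energy_model,
                         np.random.default_rng(7))
        out2 = ga.refine("ACDEFGHIKL", 20, energy_model,
                         np.random.default_rng(7))
        assert out1 == out2


def _pool(burials):
    return [SimpleNamespace(id=f"i{k}", burial=SimpleNamespace(value=b))
            for k, b in enumerate(burials)]


class TestStochasticSelect:
    def test_pool_at_target_identity(self):
        pool = _pool([0.5] * 100)
        out = ga.stochastic_select(pool, 100, np.random.default_rng(0))
        assert out == pool

    def test_equal_weights_match_hypergeometric_rate(self):
        """All burials equal, 120 → 100: each member survives with
        frequency 100/120 within Monte-Carlo error."""
        pool = _pool([0.4] * 120)
        rng = np.random.default_rng(1)
        n_trials = 2_000
        counts = np.zeros(120)
        for _ in range(n_trials):
            for ind in ga.stochastic_select(pool, 100, rng):
                counts[int(ind.id[1:])] += 1
        freq = counts / n_trials
        sigma = np.sqrt((100 / 120) * (20 / 120) / n_trials)
        assert np.all(np.abs(freq - 100 / 120) < 5 * sigma)

    def test_two_member_weight_ratio(self):
        """Survival odds proportional to burial: 0.8 vs 0.2 → 80%/20%."""
        pool = _pool([0.8, 0.2])
        rng = np.random.default_rng(2)
        n_trials = 10_000
        wins = sum(
            ga.stochastic_select(pool, 1, rng)[0].id == "i0"
            for _ in range(n_trials)
        )
        sigma = np.sqrt(n_trials * 0.8 * 0.2)
        assert abs(wins - 0.8 * n_trials) < 4 * sigma

    def test_zero_burial_still_selectable(self):
        pool = _pool([0.0, 0.0, 0.5])
        out = ga.stochastic_select(pool, 2, np.random.default_rng(3))
        assert len(out) == 2

    def test_selection_raises_mean_burial_in_expectation(self):
        """With variation disabled, repeated proportional selection
        enriches high-burial members (Monte Carlo over 10³ trials)."""
        rng = np.random.default_rng(4)
        burials = rng.uniform(0.1, 0.9, 120)
        pool = _pool(burials)
        pool_mean = burials.mean()
        survivor_means = [
            np.mean([i.burial.value
                     for i in ga.stochastic_select(pool, 100, rng)])
            for _ in range(1_000)
        ]
        assert np.mean(survivor_means) > pool_mean


class TestFragmentLibrary:
    def test_sizes_and_uniqueness(self, fragment_library):
        assert len(fragment_library) == 60
        seqs = [f.sequence.residues for f in fragment_library]
        assert len(set(seqs)) == len(seqs)
        assert all(len(s) == 40 for s in seqs)

    def test_single_fragment(self, energy_model):
        cfg = sp.SamplerConfig(n_replicas=1, temperatures=(1.0,),
                               steps_per_replica=10, seed=0)
        lib = ga.generate_fragment_library(n=1, length=12, cfg=cfg,
                                           model=energy_model)
        assert len(lib) == 1
        assert lib[0].sequence.length == 12


def small_cfg(**kw):
    defaults = dict(population_size=10, offspring_per_epoch=4, epochs=3,
                    refine_steps=5, max_child_length=100, annotate=False,
                    seed=13)
    defaults.update(kw)
    return ga.GAConfig(**defaults)


class TestRunGa:
    def test_population_constant_after_every_epoch(self, suite, energy_model,
                                                   fragment_library):
        res = ga.run_ga(small_cfg(epochs=4), suite, fragment_library,
                        model=energy_model)
        assert len(res.population) == 10
        assert len(res.archive) == 10 + 4 * 4

    def test_zero_epochs(self, suite, energy_model, fragment_library):
        res = ga.run_ga(small_cfg(epochs=0), suite, fragment_library,
                        model=energy_model)
        assert res.records == []
        assert len(res.population) == 10
        assert all(i.epoch == 0 for i in res.population)

    def test_reproducible_per_seed(self, suite, energy_model,
                                   fragment_library):
        r1 = ga.run_ga(small_cfg(), suite, fragment_library, model=energy_model)
        r2 = ga.run_ga(small_cfg(), suite, fragment_library, model=energy_model)
        assert [i.id for i in r1.population] == [i.id for i in r2.population]
        assert [i.sequence.residues for i in r1.archive] == \
               [i.sequence.residues for i in r2.archive]
        assert [r.mean_burial for r in r1.records] == \
               [r.mean_burial for r in r2.records]

    def test_lineage_acyclic_and_complete(self, suite, energy_model,
                                          fragment_library):
        res = ga.run_ga(small_cfg(epochs=5), suite, fragment_library,
                        model=energy_model)
        seen = set()
        for ind in res.archive:      # archive is in creation order
            parents, op, epoch = ind.lineage
            if op == "founder":
                assert parents == ()
            else:
                assert len(parents) == 2
                for p in parents:
                    assert p in seen    # parents strictly precede children
            seen.add(ind.id)

    def test_annotated_run_assigns_library_derived_folds(self, suite,
                                                         energy_model,
                                                         fragment_library):
        """A reference library built from founder sequences gives TM=1
        self-hits, so CATH labels accrue and compact unassigned
        candidates are called novel."""
        from novelforge import surrogates as sg

        refs = []
        for k, frag in enumerate(fragment_library[:2]):
            refs.append(sg.ReferenceEntry(
                f"ref{k}", sg.toy_structure_predictor(
                    frag.sequence.residues, f"ref{k}"
                ), f"1.{20 + k}.{k + 1}.10",
            ))
        annotated_suite = sg.surrogate_suite(library=refs)
        cfg = small_cfg(population_size=6, offspring_per_epoch=2, epochs=2,
                        max_child_length=60, annotate=True)
        res = ga.run_ga(cfg, annotated_suite, fragment_library[:8],
                        model=energy_model)
        assert res.annotations
        rec = res.records[-1]
        assert rec.cumulative_unique_cath >= 1
        # counters non-decreasing
        cath = [r.cumulative_unique_cath for r in res.records]
        novel = [r.cumulative_novel for r in res.records]
        assert cath == sorted(cath)
        assert novel == sorted(novel)


class TestCumulativeCensus:
    def test_empty_annotations_all_zero(self):
        assert ga.cumulative_census([], {}) == []

    def test_hand_tally(self):
        from novelforge.annotate import NoveltyCall

        def ind(i, epoch):
            return SimpleNamespace(id=i, epoch=epoch)

        def call(i, label, novel):
            return NoveltyCall(i, compact=novel or label is not None,
                               assigned_label=label, best_hit=None,
                               novel=novel)

        archive = [ind("a", 0), ind("b", 0), ind("c", 1), ind("d", 1),
                   ind("e", 2)]
        annotations = {
            "a": call("a", "1.10.8.10", False),
            "b": call("b", None, True),
            "c": call("c", "1.10.8.20", False),   # same CAT as "a"
            "d": call("d", "2.40.50.10", False),
            "e": call("e", None, True),
        }
        out = ga.cumulative_census(archive, annotations)
        assert out == [(0, 1, 1), (1, 2, 1), (2, 2, 2)]

    def test_missing_annotation_rejected(self):
        archive = [SimpleNamespace(id="x", epoch=0)]
        with pytest.raises(ValueError, match="x"):
            ga.cumulative_census(archive, {})

    def test_novel_clustering_merges_similar(self):
        from novelforge.annotate import NoveltyCall

        archive = [SimpleNamespace(id=i, epoch=k)
                   for k, i in enumerate(["n1", "n2", "n3"])]
        annotations = {
            i: NoveltyCall(i, True, None, None, True) for i in ["n1", "n2", "n3"]
        }
        # n2 matches n1; n3 matches neither
        tm = {("n1", "n2"): 0.9, ("n2", "n1"): 0.9}
        out = ga.cumulative_census(
            archive, annotations,
            pairwise_tm=lambda a, b: tm.get((a, b), 0.1),
        )
        assert out == [(0, 0, 1), (1, 0, 1), (2, 0, 2)]
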