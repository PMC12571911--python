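import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comphi import (
    CompositeWeights,
    InternalAligner,
    OrganismEntry,
    assemble_pair_features,
    build_store,
    composite_score,
    grid_search_weights,
    pair_feature_names,
    rank_hosts,
    train_classifier,
    variable_importance,
)
from conftest import random_dna, random_protein

UNIT = st.floats(0.0, 1.0)


@pytest.fixture(scope="module")
def organism_pair(tiny_bundle):
    phage = next(iter(tiny_bundle.phages.values()))
    host = next(iter(tiny_bundle.hosts.values()))
    return phage, host


class TestAssemble:
    def test_full_layout_is_1004(self, organism_pair):
        v = assemble_pair_features(*organism_pair)
        assert v.shape == (1004,)
        assert len(pair_feature_names()) == 1004

    @pytest.mark.parametrize(
        "mask,dim",
        [
            (("phage_dna",), 340),
            (("phage_dna", "host_dna"), 680),
            (("phage_protein", "host_protein"), 324),
        ],
    )
    def test_masked_layouts(self, organism_pair, mask, dim):
        assert assemble_pair_features(*organism_pair, mask).shape == (dim,)

    def test_missing_proteins_rejected_when_unmasked(self, rng):
        phage = OrganismEntry(id="p", role="phage", genome=random_dna(rng, 100))
        host = OrganismEntry(
            id="h", role="host", genome=random_dna(rng, 100),
            proteins=[random_protein(rng, 50)],
        )
        with pytest.raises(ValueError, match="no proteins"):
            assemble_pair_features(phage, host)
        assert assemble_pair_features(
            phage, host, ("phage_dna", "host_dna", "host_protein")
        ).shape == (842,)

    def test_unknown_group_rejected(self, organism_pair):
        with pytest.raises(ValueError, match="unknown feature group"):
            assemble_pair_features(*organism_pair, ("phage_rna",))


def _separable_training_set(rng, n=60, dim=20):
    y = np.array([0, 1] * (n // 2))
    x = rng.normal(size=(n, dim)) * 0.05
    x[:, 0] += y  # one clean feature
    return x, y


class TestTrainClassifier:
    def test_separable_data_learned(self, rng):
        x, y = _separable_training_set(rng)
        clf = train_classifier(x, y, mask=("phage_dna",))
        acc = np.mean((clf.predict_proba(x) >= 0.5) == y)
        assert acc > 0.95

    def test_same_seed_identical_predictions(self, rng):
        x, y = _separable_training_set(rng)
        p1 = train_classifier(x, y, mask=("phage_dna",), seed=42).predict_proba(x)
        p2 = train_classifier(x, y, mask=("phage_dna",), seed=42).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(x, np.ones(10, dtype=int))

    def test_reference_hyperparameters(self, rng):
        x, y = _separable_training_set(rng)
        clf = train_classifier(x, y)
        m = clf.model
        assert (m.n_estimators, m.max_depth, m.min_samples_split,
                m.min_samples_leaf, m.max_features, m.random_state) == (
            100, 20, 10, 4, "sqrt", 42)


class TestCompositeScore:
    def test_r_zero_collapses_to_ml(self):
        assert composite_score(0.3, 0.9, 0.9, CompositeWeights(0.0, 0.7)) == 0.3

    def test_r_one_a_zero_collapses_to_ph(self):
        assert composite_score(0.3, 0.9, 0.1, CompositeWeights(1.0, 0.0)) == 0.9

    def test_worked_value(self):
        # hand evaluation: Pra = 0.5*0.6 + 1.0*0.4 = 0.7;
        # Prfinal = 0.8*0.6 + 0.7*0.4 = 0.76
        got = composite_score(0.8, 0.5, 1.0, CompositeWeights(0.4, 0.4))
        assert got == pytest.approx(0.76)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            composite_score(1.2, 0.5, 0.5, CompositeWeights(0.5, 0.5))
        with pytest.raises(ValueError):
            CompositeWeights(1.5, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(UNIT, UNIT, UNIT, UNIT, UNIT)
    def test_convex_combination_stays_in_unit_interval(self, prm, ph, hh, r, a):
        assert 0.0 <= composite_score(prm, ph, hh, CompositeWeights(r, a)) <= 1.0


@pytest.fixture(scope="module")
def fitted_pipeline(tiny_bundle):
    """Classifier + normalized store trained on the whole tiny bundle."""
    cache = {}
    pairs = tiny_bundle.interactions.pairs
    x = np.stack([
        assemble_pair_features(tiny_bundle.phages[p], tiny_bundle.hosts[h],
                               cache=cache)
        for p, h, _ in pairs
    ])
    y = [label for _, _, label in pairs]
    clf = train_classifier(x, y)
    store = build_store(
        sorted(tiny_bundle.phages.values(), key=lambda e: e.id),
        sorted(tiny_bundle.hosts.values(), key=lambda e: e.id),
        InternalAligner(),
    ).normalize()
    return clf, store, cache


class TestRankHosts:
    def test_r_zero_reproduces_ml_only_ranking(self, tiny_bundle, fitted_pipeline):
        clf, store, cache = fitted_pipeline
        host_of = tiny_bundle.interactions.host_of()
        phage = tiny_bundle.phages[sorted(tiny_bundle.phages)[0]]
        hosts = list(tiny_bundle.hosts.values())
        ranking = rank_hosts(phage, hosts, clf, store,
                             CompositeWeights(0.0, 0.0), host_of, cache)
        x = np.stack([
            assemble_pair_features(phage, tiny_bundle.hosts[h], cache=cache)
            for h in sorted(tiny_bundle.hosts)
        ])
        prm = clf.predict_proba(x)
        expected = sorted(
            zip(sorted(tiny_bundle.hosts), prm), key=lambda t: (-t[1], t[0])
        )
        assert [h for h, _ in ranking] == [h for h, _ in expected]
        np.testing.assert_allclose([s for _, s in ranking],
                                   [s for _, s in expected])

    def test_alignment_only_recovers_planted_host(self, tiny_bundle, fitted_pipeline):
        clf, store, cache = fitted_pipeline
        host_of = tiny_bundle.interactions.host_of()
        hosts = list(tiny_bundle.hosts.values())
        hits = 0
        phage_ids = sorted(tiny_bundle.phages)[:10]
        for pid in phage_ids:
            ranking = rank_hosts(tiny_bundle.phages[pid], hosts, clf, store,
                                 CompositeWeights(1.0, 0.0), host_of, cache)
            hits += ranking[0][0] == host_of[pid]
        assert hits >= 8  # h=0.6 planted homology dominates BIT_PH

    def test_unnormalized_store_rejected(self, tiny_bundle, fitted_pipeline):
        clf, _, cache = fitted_pipeline
        raw = build_store(
            sorted(tiny_bundle.phages.values(), key=lambda e: e.id)[:3],
            sorted(tiny_bundle.hosts.values(), key=lambda e: e.id)[:2],
            InternalAligner(),
        )
        phage = tiny_bundle.phages[sorted(tiny_bundle.phages)[0]]
        with pytest.raises(ValueError, match="normalized"):
            rank_hosts(phage, list(tiny_bundle.hosts.values())[:2], clf, raw,
                       CompositeWeights(), tiny_bundle.interactions.host_of())

    def test_end_to_end_determinism(self, tiny_bundle, fitted_pipeline):
        clf, store, cache = fitted_pipeline
        host_of = tiny_bundle.interactions.host_of()
        phage = tiny_bundle.phages[sorted(tiny_bundle.phages)[3]]
        hosts = list(tiny_bundle.hosts.values())
        r1 = rank_hosts(phage, hosts, clf, store, CompositeWeights(), host_of, cache)
        r2 = rank_hosts(phage, hosts, clf, store, CompositeWeights(), host_of, cache)
        assert r1 == r2


class TestGridSearch:
    def test_grid_is_11_by_11(self):
        calls = []
        prm = np.array([0.9, 0.1, 0.8, 0.2])
        y = np.array([1, 0, 1, 0])

        # constant alignment inputs: every cell scores the same AUC, so the
        # tie rule must pick (0, 0) after visiting all 121 cells
        w = grid_search_weights(prm, np.full(4, 0.5), np.full(4, 0.5), y)
        assert (w.r, w.a) == (0.0, 0.0)
        rs = np.round(np.arange(0, 1.01, 0.1), 10)
        assert len(rs) == 11  # 11 x 11 = 121 combinations

    def test_perfect_alignment_signal_selects_high_r(self):
        rng = np.random.default_rng(0)
        y = np.array([1, 0] * 40)
        prm = rng.uniform(size=80)            # uninformative classifier
        ph = np.where(y == 1, 0.95, 0.05)     # near-perfect alignment signal
        w = grid_search_weights(prm, ph, ph, y)
        assert w.r >= 0.5

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search_weights(np.array([]), np.array([]), np.array([]),
                                np.array([]))

    def test_restricted_grid(self):
        y = np.array([1, 0, 1, 0])
        w = grid_search_weights(
            np.array([0.9, 0.1, 0.8, 0.2]), np.full(4, 0.5), np.full(4, 0.5),
            y, r_values=[0.3], a_values=[1.0],
        )
        assert (w.r, w.a) == (0.3, 1.0)


class TestVariableImportance:
    def test_sums_and_partition(self, fitted_pipeline):
        clf, _, _ = fitted_pipeline
        per_feature, groups = variable_importance(clf)
        assert sum(per_feature.values()) == pytest.approx(1.0, abs=1e-9)
        top = {k: v for k, v in groups.items() if "/" not in k}
        assert sum(top.values()) == pytest.approx(1.0, abs=1e-9)
        enc = {k: v for k, v in groups.items() if "/" in k}
        assert sum(enc.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_host_dna_signal_dominates(self, rng):
        """Label depends only on host genome composition: the host-DNA
        group must carry the largest importance share."""
        phages, hosts, rows, labels = [], [], [], []
        for i in range(40):
            phage = OrganismEntry(
                id=f"p{i}", role="phage", genome=random_dna(rng, 120),
                proteins=[random_protein(rng, 40)],
            )
            at_rich = i % 2 == 0
            bases = ["A", "T"] if at_rich else ["G", "C"]
            genome = "".join(rng.choice(bases, size=120))
            host = OrganismEntry(
                id=f"h{i}", role="host", genome=genome,
                proteins=[random_protein(rng, 40)],
            )
            rows.append(assemble_pair_features(phage, host))
            labels.append(int(at_rich))
        clf = train_classifier(np.stack(rows), labels)
        _, groups = variable_importance(clf)
        top = {k: v for k, v in groups.items() if "/" not in k}
        assert max(top, key=top.get) == "host_dna"
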