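"""The four-step network meta-prediction algorithm and its iterative variant."""

import numpy as np
import pytest

from netloc import (AnnotationTable, PPINetwork, PredictorConfig, VOCABULARY,
                    combine, iterate, membership_degree,
                    neighbor_location_probability, network_prediction,
                    predict_all, predict_protein)
from netloc.predictor import membership_vector
from netloc.simulate import SimulationConfig, simulate_dataset


def star_with(annotations):
    """Star center 'u' with one leaf per annotation set."""
    leaves = [f"v{i}" for i in range(len(annotations))]
    net = PPINetwork.from_edges([("u", leaf) for leaf in leaves])
    table = AnnotationTable("SCL",
                           {leaf: s for leaf, s in zip(leaves, annotations)
                            if s})
    return net, table


class TestNeighborLocationProbability:
    def test_unanimous_neighbors(self):
        net, table = star_with([{"Nucleus"}] * 4)
        assert neighbor_location_probability(net, table, "u", "Nucleus") == 1.0
        assert neighbor_location_probability(net, table, "u", "Golgi") == 0.0

    def test_no_annotated_neighbors(self):
        net, table = star_with([set()] * 3)
        assert neighbor_location_probability(net, table, "u", "Nucleus") == 0.0

    def test_fractional(self):
        net, table = star_with([{"Nucleus"}, {"Nucleus"}, {"ER"}, set()])
        assert neighbor_location_probability(net, table, "u", "Nucleus") == \
            pytest.approx(2 / 3)

    def test_unknown_protein_raises(self):
        net, table = star_with([{"Nucleus"}])
        with pytest.raises(KeyError):
            neighbor_location_probability(net, table, "zzz", "Nucleus")


class TestMembershipDegree:
    def test_zero_without_carrying_neighbor(self):
        net, table = star_with([{"Nucleus"}] * 3)
        assert membership_degree(net, table, "u", "Golgi") == 0.0

    def test_sole_neighbor_location_is_maximal(self):
        net, table = star_with([{"ER"}, set(), set()])
        values = {t: membership_degree(net, table, "u", t) for t in VOCABULARY}
        assert max(values, key=values.get) == "ER"
        assert values["ER"] > 0

    def test_extra_carrying_neighbor_strictly_increases(self):
        net1, table1 = star_with([{"Nucleus"}, {"ER"}])
        net2, table2 = star_with([{"Nucleus"}, {"ER"}, {"Nucleus"}])
        m1 = membership_degree(net1, table1, "u", "Nucleus")
        m2 = membership_degree(net2, table2, "u", "Nucleus")
        assert m2 > m1

    def test_vector_agrees_with_scalar_path(self):
        net, table = star_with([{"Nucleus", "ER"}, {"Nucleus"}, {"Golgi"},
                                set()])
        vec, n_annotated = membership_vector(net, table, "u")
        assert n_annotated == 3
        for k, term in enumerate(VOCABULARY):
            assert vec[k] == pytest.approx(
                membership_degree(net, table, "u", term))


class TestNetworkPrediction:
    def test_relative_threshold(self):
        # 4 of 5 neighbors say Nucleus, 1 says Cytoplasm: the Cytoplasm
        # membership is far below 0.75 x the Nucleus one
        net, table = star_with([{"Nucleus"}] * 4 + [{"Cytoplasm"}])
        config = PredictorConfig(C=0.75, theta_scl=1)
        assert network_prediction(net, table, "u", config, "SCL") == \
            {"Nucleus"}
        low_c = PredictorConfig(C=0.1, theta_scl=1)
        assert network_prediction(net, table, "u", low_c, "SCL") == \
            {"Nucleus", "Cytoplasm"}

    def test_gate_forces_empty(self):
        net, table = star_with([{"Nucleus"}] * 3)
        config = PredictorConfig(C=0.75, theta_scl=10)
        assert network_prediction(net, table, "u", config, "SCL") == frozenset()

    def test_all_zero_memberships_empty(self):
        net, table = star_with([set()] * 3)
        config = PredictorConfig(C=0.75, theta_scl=0)
        assert network_prediction(net, table, "u", config, "SCL") == frozenset()

    def test_argmax_always_included_when_gate_passes(self):
        net, table = star_with([{"Nucleus"}, {"ER"}, {"Nucleus", "Golgi"}])
        config = PredictorConfig(C=1.0, theta_scl=1)
        assert "Nucleus" in network_prediction(net, table, "u", config, "SCL")


class TestCombine:
    @staticmethod
    def _memberships(**kw):
        base = {s: np.zeros(11) for s in ("SCL", "MP", "YC")}
        for src, pairs in kw.items():
            for term, value in pairs.items():
                base[src][list(VOCABULARY).index(term)] = value
        return base

    def test_condition1_intersection(self):
        pred, prov = combine(
            "u", frozenset({"Nucleus", "Cytoplasm"}), frozenset(), frozenset(),
            frozenset({"Nucleus"}), frozenset(),
            self._memberships(SCL={"Nucleus": 0.9, "Cytoplasm": 0.8},
                              MP={"Cytoplasm": 0.5}),
            PredictorConfig())
        assert pred == {"Nucleus"}
        assert prov == "condition1"

    def test_fallback_to_mp(self):
        pred, prov = combine("u", frozenset(), frozenset(), frozenset(),
                             frozenset({"ER"}), frozenset(),
                             self._memberships(), PredictorConfig())
        assert pred == {"ER"}
        assert prov == "fallback"

    def test_fallback_configurable_to_yc(self):
        pred, _ = combine("u", frozenset(), frozenset(), frozenset(),
                          frozenset({"ER"}), frozenset({"Golgi"}),
                          self._memberships(),
                          PredictorConfig(fallback_source="YC"))
        assert pred == {"Golgi"}

    def test_agreement(self):
        pred, _ = combine(
            "u", frozenset({"Mitochondrion"}), frozenset(), frozenset(),
            frozenset({"Mitochondrion"}), frozenset({"Mitochondrion"}),
            self._memberships(SCL={"Mitochondrion": 1.0}), PredictorConfig())
        assert pred == {"Mitochondrion"}

    def test_condition2_argmax_consensus(self):
        # no direct-sequence overlap with the network set, but every source
        # with evidence ranks ER first
        memberships = self._memberships(SCL={"ER": 0.9, "Nucleus": 0.1},
                                        MP={"ER": 0.4})
        pred, prov = combine("u", frozenset({"Nucleus"}), frozenset(),
                             frozenset(), frozenset({"Golgi"}), frozenset(),
                             memberships, PredictorConfig())
        assert pred == {"ER"}
        assert prov == "condition2"


class TestPredictAll:
    def test_fully_annotated_network_passes_through(self):
        net = PPINetwork.from_edges([("A", "B"), ("B", "C")])
        scl = AnnotationTable("SCL", {p: {"Nucleus"} for p in "ABC"})
        mp = AnnotationTable("MP")
        yc = AnnotationTable("YC")
        result = predict_all(net, scl, mp, yc)
        assert dict(result.table.items()) == dict(scl.items())
        assert all(v == "experimental" for v in result.provenance.values())

    def test_single_unannotated_protein_recovers_neighbors_call(self):
        net = PPINetwork.from_edges([("u", "a"), ("u", "b"), ("u", "c"),
                                     ("a", "b"), ("b", "c"), ("a", "c")])
        scl = AnnotationTable("SCL", {p: {"Nucleus"} for p in "abc"})
        mp = AnnotationTable("MP", {"u": {"Nucleus"}})
        yc = AnnotationTable("YC")
        config = PredictorConfig(C=0.75, theta_scl=1, theta_mp=1, theta_yc=1)
        result = predict_all(net, scl, mp, yc, config)
        assert result.table["u"] == {"Nucleus"}

    def test_isolated_protein_falls_back_to_mp(self):
        net = PPINetwork.from_edges([("a", "b")], vertices=["u"])
        scl = AnnotationTable("SCL", {"a": {"ER"}, "b": {"ER"}})
        mp = AnnotationTable("MP", {"u": {"Golgi"}})
        yc = AnnotationTable("YC")
        result = predict_all(net, scl, mp, yc)
        assert result.table["u"] == {"Golgi"}
        assert result.provenance["u"] == "fallback"


class TestIterate:
    def _dataset(self, seed=0):
        config = SimulationConfig(n_proteins=80, n_communities=4,
                                  p_within=0.4, p_between=0.02, seed=seed)
        sim_net, ann = simulate_dataset(config)
        return sim_net.network, ann

    def test_single_round_equals_predict_all(self):
        net, ann = self._dataset()
        pc = PredictorConfig(theta_mp=1, theta_yc=1)
        result = iterate(net, ann.scl, ann.mp, ann.yc, pc, rounds=1)
        direct = predict_all(net, ann.scl, ann.mp, ann.yc, pc)
        assert result.rounds[0] == direct.table

    def test_fixed_point_persists(self):
        net, ann = self._dataset(seed=1)
        pc = PredictorConfig(theta_mp=1, theta_yc=1)
        result = iterate(net, ann.scl, ann.mp, ann.yc, pc, rounds=5)
        fp = result.fixed_point_round
        if fp is not None:
            for later in range(fp, len(result.rounds) + 1):
                assert result.rounds[later - 1] == result.rounds[fp - 1]

    def test_rounds_must_be_positive(self):
        net, ann = self._dataset()
        with pytest.raises(ValueError):
            iterate(net, ann.scl, ann.mp, ann.yc, rounds=0)


class TestAlgorithmProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_net_src_shrinks_as_c_rises(self, seed):
        config = SimulationConfig(n_proteins=100, n_communities=4, seed=seed,
                                  p_within=0.3, p_between=0.02)
        sim_net, ann = simulate_dataset(config)
        net = sim_net.network
        proteins = sorted(net.vertices)[:25]
        previous = None
        for c in (0.5, 0.75, 0.95):
            pc = PredictorConfig(C=c, theta_scl=1)
            sets = {p: network_prediction(net, ann.scl, p, pc, "SCL")
                    for p in proteins}
            if previous is not None:
                for p in proteins:
                    assert sets[p] <= previous[p]
            previous = sets

    @pytest.mark.parametrize("seed", range(5))
    def test_net_src_only_vanishes_as_theta_rises(self, seed):
        config = SimulationConfig(n_proteins=100, n_communities=4, seed=seed)
        sim_net, ann = simulate_dataset(config)
        net = sim_net.network
        proteins = sorted(net.vertices)[:25]
        previous = None
        for theta in (1, 5, 20, 200):
            pc = PredictorConfig(C=0.75, theta_scl=theta)
            sets = {p: network_prediction(net, ann.scl, p, pc, "SCL")
                    for p in proteins}
            if previous is not None:
                for p in proteins:
                    assert sets[p] == previous[p] or sets[p] == frozenset()
            previous = sets

    @pytest.mark.parametrize("seed", range(3))
    def test_pred_nonempty_when_fallback_nonempty(self, seed):
        config = SimulationConfig(n_proteins=100, n_communities=4, seed=seed)
        sim_net, ann = simulate_dataset(config)
        result = predict_all(sim_net.network, ann.scl, ann.mp, ann.yc)
        for p in ann.mp.annotated_proteins & sim_net.network.vertices:
            assert result.table[p] != frozenset()

    def test_permutation_equivariance(self):
        config = SimulationConfig(n_proteins=60, n_communities=3, seed=7)
        sim_net, ann = simulate_dataset(config)
        net = sim_net.network
        rename = {p: f"X{p}" for p in net.vertices}
        renamed_net = PPINetwork.from_edges(
            [(rename[u], rename[v]) for u, v in net.edges],
            vertices=rename.values())

        def renamed(table, source):
            return AnnotationTable(source, {rename[p]: set(terms)
                                            for p, terms in table.items()})

        pc = PredictorConfig(theta_mp=1, theta_yc=1)
        base = predict_all(net, ann.scl, ann.mp, ann.yc, pc)
        perm = predict_all(renamed_net, renamed(ann.scl, "SCL"),
                           renamed(ann.mp, "MP"), renamed(ann.yc, "YC"), pc)
        for p in net.vertices:
            assert perm.table[rename[p]] == base.table[p]

    @pytest.mark.parametrize("c", [0.25, 0.75, 1.0])
    def test_unanimous_neighborhood_recovered_exactly(self, c):
        # every neighbor of u agrees on one location in every source and the
        # fallback source carries it: PRED must be exactly that location
        net = PPINetwork.from_edges([("u", f"v{i}") for i in range(4)]
                                    + [("v0", "v1"), ("v2", "v3")])
        loc = {"Mitochondrion"}
        scl = AnnotationTable("SCL", {f"v{i}": loc for i in range(4)})
        mp = AnnotationTable("MP", {f"v{i}": loc for i in range(4)} | {"u": loc})
        yc = AnnotationTable("YC", {f"v{i}": loc for i in range(4)})
        pc = PredictorConfig(C=c, theta_scl=1, theta_mp=1, theta_yc=1)
        profile = predict_protein(net, scl, mp, yc, "u", pc)
        assert profile.pred == loc


class TestPredictorConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            PredictorConfig(C=1.5)
        with pytest.raises(ValueError):
            PredictorConfig(theta_scl=-1)
        with pytest.raises(ValueError):
            PredictorConfig(fallback_source="SCL")

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "config.json"
        path.write_text('{"C": 0.6, "theta_SCL": 2, "theta_MP": 30, '
                        '"theta_YC": 40}')
        pc = PredictorConfig.from_json(path)
        assert pc == PredictorConfig(C=0.6, theta_scl=2, theta_mp=30,
                                     theta_yc=40)
        assert pc.theta("YC") == 40
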