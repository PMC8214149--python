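"""Calpha distance mapping, satisfaction, state classes, random null."""

import numpy as np
import pytest

from xlmsn.assemble import ResidueLinkage
from xlmsn.chem import get_linker
from xlmsn.simulate import PlantedLinkage, make_toy_structures
from xlmsn.structure import (
    StructureModel,
    ca_distance,
    compare_to_null,
    null_histogram,
    random_null,
    read_structure,
    satisfaction,
    state_classify,
    structures_from_gemmi,
)


def _model(coords, names=None, model_id="m1"):
    return StructureModel(
        model_id=model_id,
        coords={k: np.array(v, dtype=float) for k, v in coords.items()},
        res_names=names or {k: "ALA" for k in coords},
    )


class TestReadStructure:
    def test_two_chain_ca_file(self, tmp_path):
        st, _ = make_toy_structures(
            1, [PlantedLinkage("A", 2, "B", 3, (7.0,))], seed=0)
        p = tmp_path / "toy.pdb"
        st.write_pdb(str(p))
        models = read_structure(p)
        assert len(models) == 1
        assert {c for c, _ in models[0].coords} == {"A", "B"}

    def test_four_model_file(self, tmp_path):
        st, _ = make_toy_structures(
            4, [PlantedLinkage("A", 2, "A", 6, (5.0, 6.0, 7.0, 8.0))], seed=0)
        p = tmp_path / "multi.pdb"
        st.write_pdb(str(p))
        models = read_structure(p, model_names=["s1", "s2", "s3", "s4"])
        assert [m.model_id for m in models] == ["s1", "s2", "s3", "s4"]

    def test_no_ca_is_an_error(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text(
            "ATOM      1  CB  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n")
        with pytest.raises(ValueError, match="no CA"):
            read_structure(p)


class TestCaDistance:
    def test_3_4_5_triangle(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (3, 4, 0)})
        assert ca_distance(m, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_identical_coordinates(self):
        m = _model({("A", 1): (1, 1, 1), ("A", 2): (1, 1, 1)})
        assert ca_distance(m, ("A", 1), ("A", 2)) == 0.0

    def test_unresolved_residue_is_none_not_zero(self):
        m = _model({("A", 1): (0, 0, 0)})
        assert ca_distance(m, ("A", 1), ("A", 99)) is None

    def test_ambiguity_interval_takes_minimum(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 5): (10, 0, 0),
                    ("A", 6): (4, 0, 0)})
        assert ca_distance(m, ("A", 1), ("A", (5, 6))) == pytest.approx(4.0)

    def test_chain_map_resolution(self):
        m = StructureModel("m1", {("X", 1): np.zeros(3),
                                  ("X", 2): np.array([2.0, 0, 0])},
                           {("X", 1): "LYS", ("X", 2): "GLU"},
                           chain_map={"PROT1": "X"})
        assert ca_distance(m, ("PROT1", 1), ("PROT1", 2)) == pytest.approx(2.0)


def _linkage(res_a, res_b, linker="SDASO-M"):
    rb = res_b if isinstance(res_b, tuple) else (res_b,)
    return ResidueLinkage("A", res_a, "A", rb, linker)


class TestSatisfaction:
    def test_all_within_threshold(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (10, 0, 0),
                    ("A", 3): (0, 5, 0)})
        rates, res = satisfaction(
            [_linkage(1, 2), _linkage(1, 3)], [m], get_linker("SDASO-M"))
        assert rates["m1"] == 1.0

    def test_half_violated(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (10, 0, 0),
                    ("A", 3): (31, 0, 0)})
        rates, _ = satisfaction(
            [_linkage(1, 2), _linkage(1, 3)], [m], get_linker("SDASO-M"))
        assert rates["m1"] == 0.5

    def test_boundary_distance_satisfies(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (30.0, 0, 0)})
        rates, res = satisfaction([_linkage(1, 2)], [m],
                                  get_linker("SDASO-M"))
        assert rates["m1"] == 1.0  # <= threshold, not <

    def test_long_linker_threshold_is_35(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (33, 0, 0)})
        rates_l, _ = satisfaction([_linkage(1, 2, "SDASO-L")], [m],
                                  get_linker("SDASO-L"))
        rates_m, _ = satisfaction([_linkage(1, 2)], [m],
                                  get_linker("SDASO-M"))
        assert rates_l["m1"] == 1.0 and rates_m["m1"] == 0.0

    def test_unresolved_excluded_from_denominator(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (10, 0, 0)})
        rates, res = satisfaction(
            [_linkage(1, 2), _linkage(1, 99)], [m], get_linker("SDASO-M"))
        assert rates["m1"] == 1.0
        assert res[1].distances["m1"] is None

    def test_rate_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        coords = {("A", 1): (0.0, 0.0, 0.0)}
        links = []
        for i in range(2, 30):
            coords[("A", i)] = tuple(rng.uniform(-40, 40, 3))
            links.append(_linkage(1, i))
        m = _model(coords)
        prev = 0.0
        for thr in (5.0, 15.0, 25.0, 35.0, 80.0):
            import dataclasses

            lk = dataclasses.replace(get_linker("SDASO-M"), max_ca_ca=thr)
            rate, _ = satisfaction(links, [m], lk)
            assert rate["m1"] >= prev
            prev = rate["m1"]


class TestStateClassify:
    @pytest.fixture()
    def four_models(self, tmp_path):
        # linkage 1 satisfied in s1-s3 only; linkage 2 in s4 only;
        # linkage 3 in all; linkage 4 in none
        plants = [
            PlantedLinkage("A", 2, "A", 10, (10.0, 12.0, 14.0, 50.0)),
            PlantedLinkage("A", 20, "A", 30, (50.0, 55.0, 60.0, 9.0)),
            PlantedLinkage("A", 40, "A", 50, (8.0, 8.0, 8.0, 8.0)),
            PlantedLinkage("A", 60, "A", 70, (90.0, 90.0, 90.0, 90.0)),
        ]
        st, _ = make_toy_structures(4, plants, seed=1)
        return structures_from_gemmi(
            st, model_names=["s1", "s2", "s3", "s4"])

    def test_planted_categories_recovered(self, four_models):
        links = [_linkage(2, 10), _linkage(20, 30), _linkage(40, 50),
                 _linkage(60, 70)]
        _, res = satisfaction(links, four_models, get_linker("SDASO-M"))
        cats = state_classify(res, ["s1", "s2", "s3", "s4"])
        assert cats["s1-s2-s3"] == 1
        assert cats["s4"] == 1
        assert sum(cats.values()) == 2  # all-4 and none excluded

    def test_category_space_is_14(self, four_models):
        _, res = satisfaction([_linkage(2, 10)], four_models,
                              get_linker("SDASO-M"))
        cats = state_classify(res, ["s1", "s2", "s3", "s4"])
        assert len(cats) == 14

    def test_partition_property(self, four_models):
        links = [_linkage(2, 10), _linkage(20, 30), _linkage(40, 50),
                 _linkage(60, 70)]
        _, res = satisfaction(links, four_models, get_linker("SDASO-M"))
        cats = state_classify(res, ["s1", "s2", "s3", "s4"])
        n_all = sum(1 for r in res if len(r.satisfied_set) == 4)
        n_none = sum(1 for r in res if len(r.satisfied_set) == 0)
        assert n_all + n_none + sum(cats.values()) == len(links)

    def test_non_four_models_warns_and_generalizes(self):
        m1 = _model({("A", 1): (0, 0, 0), ("A", 2): (10, 0, 0)}, model_id="s1")
        m2 = _model({("A", 1): (0, 0, 0), ("A", 2): (50, 0, 0)}, model_id="s2")
        _, res = satisfaction([_linkage(1, 2)], [m1, m2],
                              get_linker("SDASO-M"))
        with pytest.warns(UserWarning):
            cats = state_classify(res, ["s1", "s2"])
        assert len(cats) == 2  # 2^2 - 2
        assert cats["s1"] == 1


def _brute_null(model, cap):
    keys = list(model.coords)
    out = []
    for k in keys:
        if model.res_names[k] != "LYS":
            continue
        for x in keys:
            if x == k:
                continue
            d = float(np.linalg.norm(model.coords[k] - model.coords[x]))
            if d <= cap:
                out.append(d)
    return sorted(out)


class TestRandomNull:
    def test_three_residue_toy_with_one_lysine(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (3, 0, 0),
                    ("A", 3): (6, 0, 0)},
                   names={("A", 1): "LYS", ("A", 2): "ALA", ("A", 3): "GLU"})
        d = random_null(m, cap=100.0)
        assert sorted(d.tolist()) == [3.0, 6.0]

    def test_cap_below_all_distances(self):
        m = _model({("A", 1): (0, 0, 0), ("A", 2): (50, 0, 0)},
                   names={("A", 1): "LYS", ("A", 2): "ALA"})
        assert random_null(m, cap=10.0).size == 0

    def test_uncapped_count_is_combinatorial(self):
        rng = np.random.default_rng(5)
        coords, names = {}, {}
        for i in range(1, 31):
            coords[("A", i)] = tuple(rng.uniform(0, 50, 3))
            names[("A", i)] = "LYS" if i % 5 == 0 else "ALA"
        m = _model(coords, names)
        n_k = sum(1 for v in names.values() if v == "LYS")
        assert random_null(m, cap=np.inf).size == n_k * 29

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            n = int(rng.integers(10, 51))
            coords, names = {}, {}
            for i in range(1, n + 1):
                coords[("A", i)] = tuple(rng.uniform(0, 80, 3))
                names[("A", i)] = "LYS" if rng.random() < 0.15 else "GLU"
            if "LYS" not in names.values():
                names[("A", 1)] = "LYS"
            m = _model(coords, names)
            cap = float(rng.uniform(20, 120))
            got = sorted(random_null(m, cap=cap).tolist())
            assert np.allclose(got, _brute_null(m, cap))

    def test_no_lysine_is_an_error(self):
        m = _model({("A", 1): (0, 0, 0)}, names={("A", 1): "ALA"})
        with pytest.raises(ValueError, match="no lysine"):
            random_null(m, cap=100.0)

    def test_histogram_bins(self):
        d = np.array([1.0, 2.0, 7.0, 12.0])
        h = null_histogram(d, bin_width=5.0)
        assert h["count"].tolist() == [2, 1, 1]


class TestCompareToNull:
    def test_identical_samples(self):
        d = np.linspace(5, 50, 100)
        stat, p = compare_to_null(d, d)
        assert stat == 0.0 and p == 1.0

    def test_fully_separated_samples(self):
        stat, _ = compare_to_null(np.array([1.0, 2.0]), np.array([10.0, 11.0]))
        assert stat == 1.0

    def test_shifted_normal_detected(self):
        detected = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.normal(20.0, 5.0, 200)
            b = rng.normal(25.0, 5.0, 200)  # 1 sigma shift
            _, p = compare_to_null(a, b)
            if p < 0.05:
                detected += 1
        assert detected / n_seeds >= 0.95

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_to_null(np.array([]), np.array([1.0]))
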