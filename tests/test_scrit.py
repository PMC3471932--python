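import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scritscreen.errors import ContractError
from scritscreen.scrit import (
    VIABILITY,
    SCRITVector,
    build_scrit,
    component_index,
    primary_screen_select,
    read_scrit_table,
    replicate_consistency,
    truncate_scrit,
    write_scrit_table,
)


def make_wellstats(
    compounds=("cmpdA",),
    doses=(1.0, 10.0),
    conditions=("glu_plus", "glu_minus"),
    params=("tmrm_peripheral_integral",),
    replicates=("1",),
    value=lambda compound, rep, cond, dose, param: -0.5,
    viability=lambda compound, rep, cond, dose: 0.8,
    wells_per_cell=1,
):
    rows = []
    wid = 0
    for compound in compounds:
        for rep in replicates:
            for cond in conditions:
                for dose in doses:
                    for _ in range(wells_per_cell):
                        wid += 1
                        row = {
                            "well": f"W{wid:03d}",
                            "compound": compound,
                            "replicate": rep,
                            "dose": dose,
                            "condition": cond,
                            "role": "test",
                            "excluded": False,
                            "viability_rescaled": viability(compound, rep, cond, dose),
                        }
                        for p in params:
                            row[f"ks_{p}"] = value(compound, rep, cond, dose, p)
                        rows.append(row)
    return pd.DataFrame(rows)


def make_vector(values, compound="c", replicate="1", n_params=1, doses=None):
    values = np.asarray(values, float)
    if doses is None:
        per = len(values) // (n_params * 2)
        doses = list(range(1, per + 1))
    index = component_index(
        [f"p{i}" for i in range(n_params)], ("glu_plus", "glu_minus"), doses
    )
    return SCRITVector(compound=compound, replicate=replicate, values=values, index=index)


class TestComponentIndex:
    @given(p=st.integers(1, 7), c=st.integers(1, 2), d=st.integers(1, 12))
    @settings(max_examples=60, derandomize=True)
    def test_count_identity(self, p, c, d):
        idx = component_index(
            [f"p{i}" for i in range(p)],
            ["glu_plus", "glu_minus"][:c],
            list(np.geomspace(0.005, 100, d)),
        )
        assert len(idx) == p * c * d

    def test_ordering_parameter_major_then_condition_then_dose(self):
        idx = component_index(["a", "b"], ["glu_plus", "glu_minus"], [10.0, 1.0])
        assert idx == (
            ("a", "glu_plus", 1.0),
            ("a", "glu_plus", 10.0),
            ("a", "glu_minus", 1.0),
            ("a", "glu_minus", 10.0),
            ("b", "glu_plus", 1.0),
            ("b", "glu_plus", 10.0),
            ("b", "glu_minus", 1.0),
            ("b", "glu_minus", 10.0),
        )


class TestBuildScrit:
    @pytest.mark.parametrize(
        "n_params,n_doses,expected",
        [(2, 10, 40), (3, 10, 60), (7, 1, 14)],
    )
    def test_canonical_dimensions(self, n_params, n_doses, expected):
        params = [f"p{i}" for i in range(n_params - 1)] + [VIABILITY]
        doses = tuple(np.geomspace(0.005, 100, n_doses))
        stats = make_wellstats(doses=doses, params=params[:-1])
        result = build_scrit(stats, parameters=params)
        assert len(result.vectors) == 1
        assert len(result.vectors[0]) == expected

    def test_viability_enters_rescaled(self):
        stats = make_wellstats(params=(), viability=lambda *_: 0.6)
        vec = build_scrit(stats, parameters=[VIABILITY]).vectors[0]
        assert np.allclose(vec.values, 0.6)

    def test_row_order_never_matters(self):
        rng = np.random.default_rng(0)
        stats = make_wellstats(
            compounds=("a", "b"),
            value=lambda compound, rep, cond, dose, p: rng.standard_normal() * 0,
        )
        stats["ks_tmrm_peripheral_integral"] = rng.standard_normal(len(stats))
        shuffled = stats.sample(frac=1.0, random_state=1).reset_index(drop=True)
        v1 = build_scrit(stats, parameters=["tmrm_peripheral_integral"]).vectors
        v2 = build_scrit(shuffled, parameters=["tmrm_peripheral_integral"]).vectors
        for a, b in zip(v1, v2):
            assert a.compound == b.compound
            assert np.array_equal(a.values, b.values)

    def test_within_plate_duplicate_wells_averaged(self):
        calls = iter([0.2, 0.4] * 100)
        stats = make_wellstats(
            doses=(1.0,),
            conditions=("glu_plus",),
            wells_per_cell=2,
            value=lambda *_: next(calls),
        )
        vec = build_scrit(
            stats, parameters=["tmrm_peripheral_integral"], conditions=("glu_plus",)
        ).vectors[0]
        assert vec.values[0] == pytest.approx(0.3)

    def test_missing_cell_excludes_vector_with_reason(self):
        stats = make_wellstats(compounds=("a", "b"))
        stats = stats[
            ~((stats["compound"] == "b") & (stats["dose"] == 10.0))
        ]
        result = build_scrit(stats, parameters=["tmrm_peripheral_integral"])
        assert [v.compound for v in result.vectors] == ["a"]
        assert result.excluded[0]["compound"] == "b"
        assert "missing" in result.excluded[0]["reason"]

    def test_excluded_wells_ignored(self):
        stats = make_wellstats()
        stats.loc[0, "excluded"] = True
        result = build_scrit(stats, parameters=["tmrm_peripheral_integral"])
        assert result.excluded  # the whole vector is now incomplete

    def test_separate_replicates_give_separate_vectors(self):
        stats = make_wellstats(replicates=("1", "2", "3"))
        result = build_scrit(stats, parameters=["tmrm_peripheral_integral"])
        assert sorted(v.replicate for v in result.vectors) == ["1", "2", "3"]


class TestPrimaryScreenSelect:
    def make_14(self, ks=0.0, viability=1.0):
        params = [f"p{i}" for i in range(6)] + [VIABILITY]
        index = component_index(params, ("glu_plus", "glu_minus"), [100.0])
        values = [ks if p != VIABILITY else viability for p, _, _ in index]
        return SCRITVector("c", "1", np.array(values), index)

    def test_flat_vector_is_group_iv(self):
        call = primary_screen_select(self.make_14())
        assert not call.active
        assert call.group == "IV"
        assert call.triggers == ()

    def test_single_ks_above_cutoff_activates(self):
        vec = self.make_14()
        values = vec.values.copy()
        values[0] = 0.25
        call = primary_screen_select(
            SCRITVector("c", "1", values, vec.index)
        )
        assert call.active and call.group is None
        assert len(call.triggers) == 1

    def test_small_viability_drop_stays_inactive(self):
        # a 15-percentage-point drop in live fraction is below the 20% cutoff
        call = primary_screen_select(self.make_14(viability=1.0 - 2 * 0.15))
        assert not call.active

    def test_large_viability_drop_activates(self):
        call = primary_screen_select(self.make_14(viability=1.0 - 2 * 0.25))
        assert call.active

    def test_dose_series_vector_rejected(self):
        vec = make_vector(np.zeros(8), n_params=2)
        with pytest.raises(ContractError):
            primary_screen_select(vec)


class TestReplicateConsistency:
    def test_identical_replicates_kept(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(20)
        vecs = [make_vector(base, replicate=str(i)) for i in range(3)]
        kept, report = replicate_consistency(vecs)
        assert len(kept) == 3
        assert report.max_distance == 0.0
        assert not report.flagged

    def test_discordant_pair_flags_compound(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(40)
        noise = rng.standard_normal(40)
        # construct a replicate with Pearson distance well above threshold
        b = 0.6 * a + 0.8 * noise * a.std()
        vecs = [make_vector(a, replicate="1"), make_vector(b, replicate="2")]
        kept, report = replicate_consistency(vecs)
        assert report.max_distance > 0.2
        assert report.flagged
        assert kept == []

    def test_single_replicate_warns_but_passes(self):
        with pytest.warns(UserWarning, match="single replicate"):
            kept, report = replicate_consistency([make_vector(np.arange(8.0))])
        assert len(kept) == 1 and not report.flagged

    def test_mixed_compounds_rejected(self):
        with pytest.raises(ContractError):
            replicate_consistency(
                [make_vector(np.arange(8.0), compound="a"), make_vector(np.arange(8.0), compound="b")]
            )


class TestTruncate:
    def test_single_condition_halves_vector(self):
        vec = make_vector(np.arange(60.0), n_params=3)
        glu_plus = truncate_scrit(vec, conditions=["glu_plus"])
        assert len(glu_plus) == 30
        assert all(c == "glu_plus" for _, c, _ in glu_plus.index)

    def test_parameter_subset(self):
        vec = make_vector(np.arange(40.0), n_params=2)
        only = truncate_scrit(vec, parameters=["p0"])
        assert len(only) == 20

    def test_truncations_compose(self):
        vec = make_vector(np.arange(60.0), n_params=3)
        two_step = truncate_scrit(
            truncate_scrit(vec, conditions=["glu_minus"]), parameters=["p1"]
        )
        one_step = truncate_scrit(vec, conditions=["glu_minus"], parameters=["p1"])
        assert two_step.index == one_step.index
        assert np.array_equal(two_step.values, one_step.values)

    def test_empty_selection_rejected(self):
        vec = make_vector(np.arange(8.0))
        with pytest.raises(ContractError):
            truncate_scrit(vec, parameters=["nope"])


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        vecs = [
            make_vector(rng.uniform(-1, 1, 12), compound=c, replicate=r, n_params=3)
            for c in ("a", "b")
            for r in ("1", "2")
        ]
        path = tmp_path / "scrit.tsv"
        write_scrit_table(vecs, path)
        back = read_scrit_table(path)
        assert [v.item_id for v in back] == [v.item_id for v in vecs]
        for a, b in zip(vecs, back):
            assert a.index == b.index
            assert np.allclose(a.values, b.values)
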