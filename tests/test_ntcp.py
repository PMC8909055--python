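"""gEUD, the NTCP dose-response forms, and paired plan deltas."""

import numpy as np
import pytest

from ntcpselect.dvh import StructureDVH, mean_dose
from ntcpselect.ntcp import (ModelNotEvaluable, PlanNTCP, delta_ntcp,
                             evaluate_model, evaluate_plan, geud)
from ntcpselect.records import PatientCovariates, PlanRecord
from ntcpselect.registry import ModelRegistry, NTCPModelSpec, RegistryError


def make_model(**overrides):
    base = dict(
        model_id="m", organ="oar", endpoint="", form="lkb_probit",
        dose_summary={"metric": "mean_dose"},
        parameters={"td50": 50.0, "m": 0.2}, cts_weight=1.0,
    )
    base.update(overrides)
    return NTCPModelSpec(**base)


def plan_with(dvh, patient_id="P1", modality="photon"):
    return PlanRecord(patient_id, modality, [], {dvh.structure_id: dvh})


class TestGEUD:
    def test_a1_equals_mean_exactly(self, rng):
        edges = np.cumsum(rng.uniform(0.5, 2.0, 16))
        fracs = rng.dirichlet(np.ones(15))
        dvh = StructureDVH.from_differential("oar", 30.0, edges, fracs)
        assert geud(dvh, 1.0) == mean_dose(dvh)

    def test_uniform_dose_any_a(self):
        dvh = StructureDVH.uniform("oar", 10.0, 45.0)
        for a in (-5.0, 0.5, 1.0, 4.0, 20.0):
            assert geud(dvh, a) == pytest.approx(45.0, abs=0.01)

    def test_closed_form_half_zero_half_ten(self):
        dvh = StructureDVH.from_voxels("oar", 10.0, [0.0] * 5 + [10.0] * 5, 0.01)
        assert geud(dvh, 2.0) == pytest.approx(np.sqrt(50.0), abs=0.02)

    def test_monotone_in_a_and_bounded(self, rng):
        doses = rng.uniform(5, 60, 300)
        dvh = StructureDVH.from_voxels("oar", 10.0, doses, 0.1)
        values = [geud(dvh, a) for a in (0.5, 1.0, 2.0, 5.0, 12.0)]
        assert all(x <= y + 1e-9 for x, y in zip(values, values[1:]))
        assert doses.min() - 0.1 <= values[0] and values[-1] <= doses.max() + 0.1

    def test_a_zero_rejected(self):
        with pytest.raises(ValueError):
            geud(StructureDVH.uniform("oar", 1.0, 10.0), 0.0)

    def test_negative_a_all_zero_dose_undefined(self):
        # whole structure below the 1e-6 Gy "unirradiated" cutoff
        dvh = StructureDVH.from_differential("oar", 1.0, [0.0, 1e-7], [1.0])
        with pytest.raises(ValueError):
            geud(dvh, -1.0)


class TestForms:
    def test_lkb_probit_half_at_td50(self):
        model = make_model()
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 50.0))
        assert evaluate_model(model, plan) == pytest.approx(0.5, abs=1e-3)

    def test_lkb_probit_one_sigma_above(self):
        # TD50=50, m=0.2, S=60 -> Phi(1.0)
        model = make_model()
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 60.0))
        assert evaluate_model(model, plan) == pytest.approx(0.8413, abs=1e-3)

    def test_logistic_half_at_zero_linear_predictor(self):
        model = make_model(
            form="logistic_linear",
            parameters={"intercept": -4.0,
                        "terms": [{"feature": "mean_dose", "coef": 0.1}]},
        )
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 40.0))
        assert evaluate_model(model, plan) == pytest.approx(0.5, abs=1e-3)

    def test_loglogistic_half_at_d50(self):
        model = make_model(form="loglogistic_d50_gamma",
                           parameters={"d50": 55.0, "gamma50": 1.5})
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 55.0))
        assert evaluate_model(model, plan) == pytest.approx(0.5, abs=1e-3)

    def test_covariate_term(self):
        model = make_model(
            form="logistic_linear",
            parameters={"intercept": -2.0,
                        "terms": [{"feature": "covariate", "name": "chemo",
                                   "coef": 2.0}]},
        )
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 40.0))
        cov = PatientCovariates("P1", 50, 1, 0, "I", "RT-CHT", {"chemo": 1.0})
        assert evaluate_model(model, plan, cov) == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("model", [
        make_model(),
        make_model(form="lkb_probit", dose_summary={"metric": "geud", "a": 3.0}),
        make_model(form="logistic_linear",
                   parameters={"intercept": -4.0,
                               "terms": [{"feature": "mean_dose", "coef": 0.1}]}),
        make_model(form="loglogistic_d50_gamma",
                   parameters={"d50": 55.0, "gamma50": 1.5}),
    ])
    def test_monotone_in_dose_scaling(self, model, rng):
        doses = rng.uniform(10, 50, 200)
        dvh = StructureDVH.from_voxels("oar", 10.0, doses, 0.1)
        p_lo = evaluate_model(model, plan_with(dvh))
        p_hi = evaluate_model(model, plan_with(dvh.scaled(1.4)))
        assert p_hi >= p_lo - 1e-12

    def test_probability_bounds_extreme_parameters(self, rng):
        doses = rng.uniform(0, 80, 100)
        dvh = StructureDVH.from_voxels("oar", 10.0, doses, 0.1)
        for model in (
            make_model(parameters={"td50": 1.0, "m": 0.01}),
            make_model(form="loglogistic_d50_gamma",
                       parameters={"d50": 0.5, "gamma50": 8.0}),
            make_model(form="logistic_linear",
                       parameters={"intercept": 50.0,
                                   "terms": [{"feature": "mean_dose", "coef": 5.0}]}),
        ):
            p = evaluate_model(model, plan_with(dvh))
            assert 0.0 <= p <= 1.0 and np.isfinite(p)


class TestNotEvaluableAndDeltas:
    def test_missing_structure_raises(self):
        model = make_model(organ="parotid")
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 40.0))
        with pytest.raises(ModelNotEvaluable):
            evaluate_model(model, plan)

    def test_missing_covariate_raises(self):
        model = make_model(
            form="logistic_linear",
            parameters={"intercept": 0.0,
                        "terms": [{"feature": "covariate", "name": "chemo",
                                   "coef": 1.0}]},
        )
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 40.0))
        with pytest.raises(ModelNotEvaluable):
            evaluate_model(model, plan, None)

    def test_evaluate_plan_marks_not_evaluable_as_none(self):
        registry = ModelRegistry([
            make_model(model_id="ok", cts_weight=0.5),
            make_model(model_id="missing", organ="absent", cts_weight=0.5),
        ])
        plan = plan_with(StructureDVH.uniform("oar", 10.0, 40.0))
        result = evaluate_plan(registry, plan)
        assert result.probabilities["ok"] is not None
        assert result.probabilities["missing"] is None

    def test_identical_plans_zero_delta(self):
        p = PlanNTCP("P1", "photon", {"a": 0.3, "b": 0.05})
        q = PlanNTCP("P1", "proton", {"a": 0.3, "b": 0.05})
        assert delta_ntcp(p, q) == {"a": 0.0, "b": 0.0}

    def test_delta_values_and_sign(self):
        p = PlanNTCP("P1", "photon", {"a": 0.30, "b": 0.10})
        q = PlanNTCP("P1", "proton", {"a": 0.175, "b": 0.12})
        d = delta_ntcp(p, q)
        assert d["a"] == pytest.approx(12.5)
        assert d["b"] == pytest.approx(-2.0)

    def test_patient_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_ntcp(PlanNTCP("P1", "photon", {"a": 0.1}),
                       PlanNTCP("P2", "proton", {"a": 0.1}))

    def test_one_sided_not_evaluable_propagates(self):
        d = delta_ntcp(PlanNTCP("P1", "photon", {"a": 0.1, "b": None}),
                       PlanNTCP("P1", "proton", {"a": 0.05, "b": 0.1}))
        assert d["b"] is None


class TestRegistryStructure:
    def test_default_registry_shape(self, registry):
        assert len(registry) == 16
        assert len(registry.mbs_ids) == 7
        assert sum(registry.weights().values()) == pytest.approx(1.0, abs=1e-9)
        for mid in registry.mbs_ids:
            m = registry[mid]
            assert m.threshold_standard is not None
            assert m.threshold_young is not None
            assert m.threshold_young <= m.threshold_standard

    def test_weight_sum_violation_rejected(self):
        with pytest.raises(RegistryError):
            ModelRegistry([make_model(cts_weight=0.9)])

    def test_mbs_member_without_thresholds_rejected(self):
        with pytest.raises(RegistryError):
            make_model(mbs_member=True)

    def test_evidence_levels_split(self, registry):
        levels = [m.evidence_level for m in registry]
        assert levels.count(3) == 8 and levels.count(4) == 8
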