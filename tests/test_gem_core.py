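"""Model containers, JSON round-trips, and the FBA/FVA linear programs."""

import itertools
import math

import numpy as np
import pytest

from biliflux.gem_core import (
    Metabolite,
    ModelParseError,
    ModelValidationError,
    Reaction,
    StrainModel,
    fba,
    fva,
    read_model,
    validate_model,
    write_model,
)

from conftest import make_chain_model


def minimal_model() -> StrainModel:
    return StrainModel(
        strain_id="mini",
        metabolites=[Metabolite("x[e]", "e")],
        reactions=[Reaction("EX_x[e]", {"x[e]": -1.0}, -1.0, 1.0)],
        biomass_reaction_id="EX_x[e]",
        compartments={"e"},
    )


class TestModelIO:
    def test_minimal_model_roundtrip(self, tmp_path):
        path = tmp_path / "mini.json"
        write_model(minimal_model(), path)
        model = read_model(path)
        assert len(model.reactions) == 1
        assert model.reactions[0].stoichiometry == {"x[e]": -1.0}

    def test_roundtrip_preserves_semantics(self, tmp_path, chain_model):
        p1 = tmp_path / "a.json"
        write_model(chain_model, p1)
        back = read_model(p1)
        assert back.strain_id == chain_model.strain_id
        assert back.metabolite_ids() == chain_model.metabolite_ids()
        for r1, r2 in zip(chain_model.reactions, back.reactions):
            assert r1.id == r2.id
            assert r1.stoichiometry == r2.stoichiometry
            assert (r1.lower_bound, r1.upper_bound) == (r2.lower_bound, r2.upper_bound)

    def test_write_is_byte_deterministic(self, tmp_path, chain_model):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_model(chain_model, p1)
        write_model(chain_model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_extra_fields_survive_roundtrip(self, tmp_path):
        model = minimal_model()
        model.extras["source"] = "toy"
        p = tmp_path / "m.json"
        write_model(model, p)
        assert read_model(p).extras["source"] == "toy"

    def test_dangling_metabolite_names_offender(self, tmp_path):
        raw = """{
  "strain_id": "bad", "compartments": ["c"],
  "metabolites": [{"id": "a[c]", "compartment": "c"}],
  "reactions": [{"id": "R1", "stoichiometry": {"x[c]": -1.0}, "lower_bound": 0, "upper_bound": 1}],
  "biomass_reaction_id": "R1"
}"""
        p = tmp_path / "bad.json"
        p.write_text(raw)
        with pytest.raises(ModelValidationError, match=r"x\[c\]"):
            read_model(p)

    def test_missing_field_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"strain_id": "x"}')
        with pytest.raises(ModelParseError, match="compartments"):
            read_model(p)

    def test_refuses_to_write_invalid_bounds(self, tmp_path):
        model = minimal_model()
        model.reactions[0].lower_bound = 2.0  # lb > ub
        with pytest.raises(ModelValidationError, match="lower_bound"):
            write_model(model, tmp_path / "m.json")

    def test_exchange_with_two_metabolites_invalid(self):
        model = minimal_model()
        model.metabolites.append(Metabolite("y[e]", "e"))
        model.reactions[0].stoichiometry["y[e]"] = 1.0
        with pytest.raises(ModelValidationError, match="exactly one metabolite"):
            validate_model(model)


class TestFBA:
    def test_chain_maximum_is_uptake_limited(self, chain_model):
        res = fba(chain_model, "EX_B", "max")
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_blocked_interior_reaction_gives_zero(self):
        model = make_chain_model(ab_upper=0.0)
        res = fba(model, "EX_B", "max")
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_exchange_without_producer_is_zero(self, chain_model):
        # EX_B secretion requires production; minimizing uptake-free EX_B
        chain_model.get_reaction("EX_A").lower_bound = 0.0
        res = fba(chain_model, "EX_B", "max")
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_reaction_raises(self, chain_model):
        with pytest.raises(KeyError):
            fba(chain_model, "nope")

    def test_unbounded_status_reported(self):
        model = StrainModel(
            strain_id="ub",
            metabolites=[Metabolite("a[c]", "c")],
            reactions=[
                Reaction("IN", {"a[c]": 1.0}, 0.0, np.inf),
                Reaction("OUT", {"a[c]": -1.0}, 0.0, np.inf),
            ],
            biomass_reaction_id="OUT",
            compartments={"c"},
        )
        res = fba(model, "OUT", "max")
        assert res.status == "unbounded"

    def test_mass_balance_of_optimal_solution(self, uniform_community):
        res = fba(uniform_community, "community_biomass", "max")
        assert res.status == "optimal"
        balance = {}
        for rxn in uniform_community.reactions:
            for met, coef in rxn.stoichiometry.items():
                balance[met] = balance.get(met, 0.0) + coef * res.fluxes[rxn.id]
        assert max(abs(v) for v in balance.values()) <= 1e-6


class TestFVA:
    def test_chain_fva_brackets_flux(self, chain_model):
        lo, hi = fva(chain_model, "EX_B", 0.0, "EX_B")
        assert (lo, hi) == (pytest.approx(0.0, abs=1e-9), pytest.approx(10.0, abs=1e-8))

    def test_fixed_flux_reaction(self, chain_model):
        chain_model.get_reaction("AB").lower_bound = 3.0
        chain_model.get_reaction("AB").upper_bound = 3.0
        lo, hi = fva(chain_model, "AB", 0.0, "EX_B")
        assert lo == pytest.approx(3.0, abs=1e-9)
        assert hi == pytest.approx(3.0, abs=1e-9)

    def test_disconnected_metabolite_blocks_reaction(self):
        model = make_chain_model()
        model.metabolites.append(Metabolite("Z[c]", "c"))
        model.reactions.append(Reaction("ZR", {"Z[c]": 1.0}, -5.0, 5.0))
        lo, hi = fva(model, "ZR", 0.0, "EX_B")
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)

    def test_fraction_of_optimum_constrains_range(self, chain_model):
        chain_model.reactions.append(Reaction("EX_B2", {"B[c]": -1.0}, 0.0, 1000.0))
        lo, hi = fva(chain_model, "EX_B2", 1.0, "EX_B")
        # at the EX_B optimum (10), no flux is left for the second outlet
        assert hi == pytest.approx(0.0, abs=1e-7)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


def random_network(rng, n_max=6):
    """Small random bounded network; 0 is always feasible (lb<=0<=ub)."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, 4))
    S = np.zeros((m, n))
    for j in range(n):
        nz = rng.choice(m, size=int(rng.integers(1, m + 1)), replace=False)
        S[nz, j] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(nz))
    lb = rng.choice([-3.0, -2.0, -1.0, 0.0], size=n)
    ub = rng.choice([0.0, 1.0, 2.0, 4.0], size=n)
    return S, lb, ub


def vertex_enumeration_optimum(S, lb, ub, obj_index):
    """Exhaustive maximum of v[obj_index] over {S v = 0, lb <= v <= ub}.

    The polytope is bounded, so the optimum is attained at a vertex; every
    vertex fixes n - rank(S) coordinates at bounds, and the rest solve the
    equality system.  Independent of the LP solver path.
    """
    m, n = S.shape
    r = np.linalg.matrix_rank(S, tol=1e-10)
    best = -np.inf
    n_fixed = n - r
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        Sf = S[:, free]
        for sides in itertools.product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, side in zip(fixed, sides):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = -S[:, list(fixed)] @ v[list(fixed)]
            sol, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
            if np.linalg.norm(Sf @ sol - rhs) > 1e-8:
                continue
            v[free] = sol
            if (v >= lb - 1e-9).all() and (v <= ub + 1e-9).all():
                best = max(best, v[obj_index])
    if n_fixed == 0:
        # S full column rank: the only candidate is the equality solution
        pass
    return best


def model_from_arrays(S, lb, ub):
    m, n = S.shape
    mets = [Metabolite(f"m{i}[c]", "c") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"m{i}[c]": S[i, j] for i in range(m) if S[i, j] != 0}
        rxns.append(Reaction(f"R{j}", stoich, float(lb[j]), float(ub[j])))
    return StrainModel("rand", mets, rxns, "R0", {"c"})


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fba_matches_vertex_enumeration(seed):
    """FBA equals exhaustive polytope-vertex enumeration on small networks."""
    rng = np.random.default_rng(seed)
    for _ in range(20):
        S, lb, ub = random_network(rng)
        obj = int(rng.integers(0, S.shape[1]))
        model = model_from_arrays(S, lb, ub)
        res = fba(model, f"R{obj}", "max")
        expected = vertex_enumeration_optimum(S, lb, ub, obj)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(expected, abs=1e-6)


def test_scaling_bounds_scales_optimum(chain_model):
    base = fba(chain_model, "EX_B").objective_value
    for k in (0.5, 2.0, 7.25):
        scaled = make_chain_model(ab_upper=1000.0 * k, uptake_lb=-10.0 * k)
        scaled.get_reaction("EX_A").upper_bound = 1000.0 * k
        scaled.get_reaction("EX_B").upper_bound = 1000.0 * k
        assert fba(scaled, "EX_B").objective_value == pytest.approx(k * base, rel=1e-9)


def test_relaxing_a_bound_never_decreases_maximum(chain_model):
    base = fba(chain_model, "EX_B").objective_value
    chain_model.get_reaction("EX_A").lower_bound = -20.0
    assert fba(chain_model, "EX_B").objective_value >= base - 1e-9


def test_fba_agrees_with_cobra_on_toy_model(bundle):
    """Independent cross-check of the LP layer against COBRApy."""
    cobra = pytest.importorskip("cobra")
    src = bundle.strain_models[0]
    cm = cobra.Model(src.strain_id)
    cm.add_metabolites(
        [cobra.Metabolite(m.id, compartment=m.compartment) for m in src.metabolites]
    )
    for r in src.reactions:
        cr = cobra.Reaction(r.id)
        cm.add_reactions([cr])
        cr.add_metabolites({cm.metabolites.get_by_id(k): v for k, v in r.stoichiometry.items()})
        cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
    cm.objective = "BIOMASS"
    expected = cm.optimize().objective_value
    ours = fba(src, "BIOMASS").objective_value
    assert ours == pytest.approx(expected, abs=1e-6)
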