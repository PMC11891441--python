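import math

import pytest

from bofkit import builder, composition, validate
from bofkit.builder import (
    assemble_bof,
    build_bof,
    flatten_bof,
    remove_bof,
    resolve_all,
    resolve_pool,
    resolve_top,
)
from bofkit.chem import molar_mass, parse_formula
from bofkit.composition import (
    BofSpec,
    CompositionEntry,
    MaintenanceEntry,
    MaintenanceUnit,
    PseudoReactionSpec,
    Unit,
)
from bofkit.errors import CollisionError, ConversionError, NotFoundError, SpecError
from bofkit.fixtures import FixtureConfig, make_composition, make_toy_model

from conftest import tiny_model


def entry(mid, value, unit):
    return CompositionEntry(mid, value, Unit(unit))


# four dNTP-like monomers with easy formulas
DNTP_MODEL = {
    "d1_c": ("C10H12N5O6P", -2),
    "d2_c": ("C9H12N3O7P", -2),
    "d3_c": ("C10H12N5O7P", -2),
    "d4_c": ("C10H13N2O8P", -2),
    "a_c": ("CH2O", 0),
    "b_c": ("C2H4O2", 0),
}


class TestResolvePool:
    def test_equal_mole_fractions(self):
        model = tiny_model(DNTP_MODEL)
        spec = PseudoReactionSpec(
            "DNA", 2, [entry(f"d{i}_c", 0.25, "mol_per_mol") for i in range(1, 5)]
        )
        result = resolve_pool(spec, {}, model)
        assert all(v == pytest.approx(0.25) for v in result.mole_fractions.values())
        # pool mass by linearity: 0.25 * sum of monomer masses
        expected = 0.25 * sum(
            molar_mass(parse_formula(f)) for f, _ in (DNTP_MODEL[f"d{i}_c"] for i in range(1, 5))
        )
        assert result.pool_molar_mass == pytest.approx(expected, rel=1e-12)

    def test_mass_units_convert_through_molar_mass(self):
        # oracle: 0.6 g of CH2O (30.026 g/mol) vs 0.6 g of C2H4O2 (60.052)
        # -> mole ratio 2:1 -> fractions 2/3, 1/3
        model = tiny_model(DNTP_MODEL)
        spec = PseudoReactionSpec(
            "POOL", 2, [entry("a_c", 0.6, "g_per_gDW"), entry("b_c", 0.6, "g_per_gDW")]
        )
        result = resolve_pool(spec, {}, model)
        assert result.mole_fractions["a_c"] == pytest.approx(2 / 3, rel=1e-9)
        assert result.mole_fractions["b_c"] == pytest.approx(1 / 3, rel=1e-9)

    def test_percent_mol(self):
        model = tiny_model(DNTP_MODEL)
        spec = PseudoReactionSpec(
            "POOL", 2, [entry("a_c", 30, "percent_mol"), entry("b_c", 70, "percent_mol")]
        )
        result = resolve_pool(spec, {}, model)
        assert result.mole_fractions == pytest.approx({"a_c": 0.3, "b_c": 0.7})

    def test_fractions_sum_to_one(self):
        model = tiny_model(DNTP_MODEL)
        spec = PseudoReactionSpec(
            "POOL", 2, [entry("a_c", 1.7, "mmol_per_gDW"), entry("b_c", 2.9, "mmol_per_gDW")]
        )
        result = resolve_pool(spec, {}, model)
        assert sum(result.mole_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mass_unit_without_formula_errors(self):
        model = tiny_model({"x_c": (None, None), "a_c": ("CH2O", 0)})
        spec = PseudoReactionSpec(
            "POOL", 2, [entry("x_c", 0.5, "g_per_gDW"), entry("a_c", 0.5, "g_per_gDW")]
        )
        with pytest.raises(ConversionError, match="x_c"):
            resolve_pool(spec, {}, model)

    def test_missing_formula_molar_units_ok_but_mass_unknown(self, caplog):
        model = tiny_model({"x_c": (None, None), "a_c": ("CH2O", 0)})
        spec = PseudoReactionSpec(
            "POOL", 2, [entry("x_c", 0.5, "mol_per_mol"), entry("a_c", 0.5, "mol_per_mol")]
        )
        with caplog.at_level("WARNING"):
            result = resolve_pool(spec, {}, model)
        assert result.pool_formula is None
        assert result.pool_molar_mass is None

    def test_self_balanced_maintenance_leaves_pool_mass_unchanged(self):
        model = tiny_model(
            {
                "a_c": ("CH2O", 0),
                "atp_c": ("C10H12N5O13P3", -4),
                "h2o_c": ("H2O", 0),
                "adp_c": ("C10H12N5O10P2", -3),
                "pi_c": ("HO4P", -2),
                "h_c": ("H", 1),
            }
        )
        maint = [
            MaintenanceEntry("atp_c", -2.0, MaintenanceUnit.MOL_PER_MOL_POOL),
            MaintenanceEntry("h2o_c", -2.0, MaintenanceUnit.MOL_PER_MOL_POOL),
            MaintenanceEntry("adp_c", 2.0, MaintenanceUnit.MOL_PER_MOL_POOL),
            MaintenanceEntry("pi_c", 2.0, MaintenanceUnit.MOL_PER_MOL_POOL),
            MaintenanceEntry("h_c", 2.0, MaintenanceUnit.MOL_PER_MOL_POOL),
        ]
        bare = PseudoReactionSpec("P", 2, [entry("a_c", 1.0, "mol_per_mol")])
        with_maint = PseudoReactionSpec("P", 2, [entry("a_c", 1.0, "mol_per_mol")], maint)
        mw_bare = resolve_pool(bare, {}, model).pool_molar_mass
        mw_maint = resolve_pool(with_maint, {}, model).pool_molar_mass
        assert mw_maint == pytest.approx(mw_bare, rel=1e-12)


class TestResolveTop:
    def test_normalization_forced_fractions(self):
        model = tiny_model(
            {"p_c": ("C3H6O3", 0), "c_c": ("C6H12O6", 0), "l_c": ("C4H8O2", 0)}
        )
        spec = PseudoReactionSpec(
            "BIOMASS",
            1,
            [
                entry("p_c", 0.6, "g_per_gDW"),
                entry("c_c", 0.2, "g_per_gDW"),
                entry("l_c", 0.1, "g_per_gDW"),
            ],
        )
        result = resolve_top(spec, {}, model)
        assert result.scale_factor == pytest.approx(1 / 0.9, rel=1e-12)
        assert result.mass_fractions["p_c"] == pytest.approx(2 / 3, rel=1e-12)
        assert result.mass_fractions["c_c"] == pytest.approx(2 / 9, rel=1e-12)
        assert result.mass_fractions["l_c"] == pytest.approx(1 / 9, rel=1e-12)
        assert sum(result.mass_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_component_coefficient(self):
        # mass fraction 1.0, molar mass 100 -> 1.0 * 1000 / 100 = 10 mmol/gDW
        model = tiny_model({"s_c": ("C4H4O4", 0)})  # 4*12.011+4*1.008+4*15.999 = 116.072
        mw = molar_mass(parse_formula("C4H4O4"))
        spec = PseudoReactionSpec("BIOMASS", 1, [entry("s_c", 0.5, "g_per_gDW")])
        result = resolve_top(spec, {}, model)
        assert result.mass_fractions["s_c"] == pytest.approx(1.0)
        assert result.coefficients["s_c"] == pytest.approx(1000.0 / mw, rel=1e-12)

    def test_scale_invariance(self):
        model = tiny_model({"a_c": ("CH2O", 0), "b_c": ("C2H4O2", 0)})
        base = PseudoReactionSpec(
            "BIOMASS", 1, [entry("a_c", 0.4, "g_per_gDW"), entry("b_c", 0.5, "g_per_gDW")]
        )
        scaled = PseudoReactionSpec(
            "BIOMASS", 1, [entry("a_c", 2.8, "g_per_gDW"), entry("b_c", 3.5, "g_per_gDW")]
        )
        r1 = resolve_top(base, {}, model)
        r7 = resolve_top(scaled, {}, model)
        for mid in r1.coefficients:
            assert r7.coefficients[mid] == pytest.approx(r1.coefficients[mid], rel=1e-12)
        assert r7.scale_factor == pytest.approx(r1.scale_factor / 7, rel=1e-12)

    def test_unknown_molar_mass_fails_normalization(self):
        model = tiny_model({"x_c": (None, None)})
        spec = PseudoReactionSpec("BIOMASS", 1, [entry("x_c", 0.5, "g_per_gDW")])
        with pytest.raises(ConversionError, match="x_c"):
            resolve_top(spec, {}, model)

    def test_maintenance_passthrough_unscaled(self):
        model = tiny_model({"a_c": ("CH2O", 0), "atp_c": ("C10H12N5O13P3", -4)})
        spec = PseudoReactionSpec(
            "BIOMASS",
            1,
            [entry("a_c", 0.5, "g_per_gDW")],  # scale factor 2, must not touch maintenance
            [MaintenanceEntry("atp_c", -30.0, MaintenanceUnit.MMOL_PER_GDW)],
        )
        result = resolve_top(spec, {}, model)
        assert result.scale_factor == pytest.approx(2.0)
        assert result.maintenance_coeffs["atp_c"] == -30.0

    @pytest.mark.parametrize(
        "unit,factor",
        [("g_per_gDW", 1.0), ("mg_per_gDW", 1000.0), ("percent_DW_mass", 100.0)],
    )
    def test_unit_invariance_mass_units(self, unit, factor):
        model = tiny_model({"a_c": ("CH2O", 0), "b_c": ("C2H4O2", 0)})
        in_g = PseudoReactionSpec(
            "BIOMASS", 1, [entry("a_c", 0.4, "g_per_gDW"), entry("b_c", 0.5, "g_per_gDW")]
        )
        converted = PseudoReactionSpec(
            "BIOMASS",
            1,
            [entry("a_c", 0.4 * factor, unit), entry("b_c", 0.5 * factor, unit)],
        )
        ref = resolve_top(in_g, {}, model)
        out = resolve_top(converted, {}, model)
        for mid in ref.coefficients:
            assert out.coefficients[mid] == pytest.approx(ref.coefficients[mid], rel=1e-12)


class TestAssemble:
    def test_three_level_counts(self, built3):
        model, spec, top, pools, report = built3
        new_rxns = [r for r in model.reactions if r.endswith("_bof1")]
        new_mets = [m for m in model.metabolites if m.endswith("_bof1")]
        assert len(new_rxns) == 6
        assert len(new_mets) == 6

    def test_product_coefficient_exactly_one(self, built3):
        model, spec, top, pools, report = built3
        for rid in (r for r in model.reactions if r.endswith("_bof1")):
            stoich = model.reactions[rid].stoichiometry
            pool_products = [
                (mid, c) for mid, c in stoich.items() if c > 0 and mid.endswith("_bof1")
            ]
            assert len(pool_products) == 1
            assert pool_products[0][1] == 1.0

    def test_bounds_and_objective_untouched(self, built3):
        model, *_ = built3
        for rid in (r for r in model.reactions if r.endswith("_bof1")):
            assert model.reactions[rid].bounds == (0.0, 1000.0)
        assert model.objective != "BIOMASS_bof1"

    def test_collision_is_atomic(self, built3):
        model, spec, top, pools, _ = built3
        before = set(model.reactions) | set(model.metabolites)
        with pytest.raises(CollisionError, match="bof1"):
            assemble_bof(spec, top, pools, model)
        assert set(model.reactions) | set(model.metabolites) == before

    def test_two_tags_coexist(self, cfg3, tmp_path):
        model = make_toy_model(cfg3)
        path = make_composition(cfg3, model, tmp_path / "c.xlsx")
        sheets = composition.load_workbook(path)
        for tag in ("v1", "v2"):
            spec = composition.build_spec(sheets, tag, "c", model)
            build_bof(model, spec)
        tagged = [r for r in model.reactions if r.endswith("_v1") or r.endswith("_v2")]
        assert len(tagged) == 12

    def test_set_objective_flag(self, cfg3, tmp_path):
        model = make_toy_model(cfg3)
        path = make_composition(cfg3, model, tmp_path / "c.xlsx")
        spec = composition.build_spec(composition.load_workbook(path), "obj", "c", model)
        build_bof(model, spec, set_objective=True)
        assert model.objective == "BIOMASS_obj"

    def test_compartment_suffix_option(self, cfg3, tmp_path):
        model = make_toy_model(cfg3)
        path = make_composition(cfg3, model, tmp_path / "c.xlsx")
        spec = composition.build_spec(composition.load_workbook(path), "bg", "c", model)
        build_bof(model, spec, compartment_suffix=True)
        assert "BIOMASS_bg_c" in model.metabolites
        assert "BIOMASS_bg" in model.reactions

    def test_formulas_asserted_but_missing_is_error(self, tmp_path):
        model = tiny_model({"x_c": (None, None)})
        spec = BofSpec(
            top=PseudoReactionSpec("BIOMASS", 1, [entry("x_c", 1.0, "mmol_per_gDW")]),
            pools={},
            tag="t",
            compartment="c",
            sheet_order=["BIOMASS"],
        )
        with pytest.raises(SpecError, match="formula"):
            build_bof(model, spec, formulas_available=True)


class TestRemove:
    def _snapshot(self, model):
        return {
            "mets": set(model.metabolites),
            "rxns": {r.id: (tuple(sorted(r.stoichiometry.items())), r.bounds)
                     for r in model.reactions.values()},
        }

    def test_add_then_remove_is_identity(self, cfg3, tmp_path):
        model = make_toy_model(cfg3)
        path = make_composition(cfg3, model, tmp_path / "c.xlsx")
        spec = composition.build_spec(composition.load_workbook(path), "t1", "c", model)
        before = self._snapshot(model)
        build_bof(model, spec)
        assert self._snapshot(model) != before
        remove_bof(model, "t1")
        assert self._snapshot(model) == before

    def test_unknown_tag(self, toy3):
        with pytest.raises(NotFoundError):
            remove_bof(toy3, "nope")

    def test_other_tag_survives(self, cfg3, tmp_path):
        model = make_toy_model(cfg3)
        path = make_composition(cfg3, model, tmp_path / "c.xlsx")
        sheets = composition.load_workbook(path)
        for tag in ("a", "b"):
            build_bof(model, composition.build_spec(sheets, tag, "c", model))
        remove_bof(model, "a")
        assert [r for r in model.reactions if r.endswith("_a")] == []
        assert len([r for r in model.reactions if r.endswith("_b")]) == 6

    def test_objective_unset_with_warning(self, cfg3, tmp_path, caplog):
        model = make_toy_model(cfg3)
        path = make_composition(cfg3, model, tmp_path / "c.xlsx")
        spec = composition.build_spec(composition.load_workbook(path), "t", "c", model)
        build_bof(model, spec, set_objective=True)
        with caplog.at_level("WARNING"):
            remove_bof(model, "t")
        assert model.objective is None
        assert "objective" in caplog.text


class TestFlatten:
    def test_hand_chain_multiplication(self):
        # DNA pool: MW 500 by construction is awkward with real formulas, so
        # verify the chain rule itself: coefficient * fraction
        model = tiny_model(DNTP_MODEL)
        dna = PseudoReactionSpec(
            "DNA", 2, [entry(f"d{i}_c", 0.25, "mol_per_mol") for i in range(1, 5)]
        )
        pool = resolve_pool(dna, {}, model)
        top_spec = PseudoReactionSpec("BIOMASS", 1, [entry("DNA", 0.04, "g_per_gDW")])
        spec = BofSpec(top=top_spec, pools={"DNA": dna}, tag="t", compartment="c",
                       sheet_order=["BIOMASS", "DNA"])
        top = resolve_top(top_spec, {"DNA": pool}, model)
        flat = flatten_bof(spec, top, {"DNA": pool})
        expected = 1.0 * 1000.0 / pool.pool_molar_mass * 0.25  # mass fraction is 1.0
        for i in range(1, 5):
            assert flat[f"d{i}_c"] == pytest.approx(expected, rel=1e-12)

    def test_single_level_equals_top(self):
        model = tiny_model(DNTP_MODEL)
        top_spec = PseudoReactionSpec(
            "BIOMASS",
            1,
            [entry("a_c", 0.4, "g_per_gDW"), entry("b_c", 0.5, "g_per_gDW")],
            [MaintenanceEntry("d1_c", -3.0, MaintenanceUnit.MMOL_PER_GDW)],
        )
        spec = BofSpec(top=top_spec, pools={}, tag="t", compartment="c", sheet_order=["BIOMASS"])
        top = resolve_top(top_spec, {}, model)
        flat = flatten_bof(spec, top, {})
        assert flat["a_c"] == pytest.approx(top.coefficients["a_c"], rel=1e-15)
        assert flat["b_c"] == pytest.approx(top.coefficients["b_c"], rel=1e-15)
        assert flat["d1_c"] == pytest.approx(3.0)  # consumed -> positive consumption

    def test_hierarchical_equals_hand_converted_single_level(self, built3):
        """Core oracle: flatten the 3-level build and compare against a
        single-level dataset whose coefficients were derived independently
        (plain arithmetic on the raw sheet values, no builder code)."""
        model, spec, top, pools, _ = built3
        flat = flatten_bof(spec, top, pools)

        # independent re-derivation ---------------------------------------
        def mw_of(mid):
            return molar_mass(model.metabolites[mid].formula)

        def pool_info(name):
            """(mole fraction map over model metabolites, pool molar mass)"""
            pspec = spec.pools[name]
            moles = {}
            for e in pspec.entries:
                if e.metabolite_id in spec.pools:
                    sub, sub_mw = pool_info(e.metabolite_id)
                    amount = e.value / sub_mw if e.unit.is_mass else e.value
                    moles[e.metabolite_id] = (amount, sub, sub_mw)
                else:
                    amount = e.value / mw_of(e.metabolite_id) if e.unit.is_mass else e.value
                    moles[e.metabolite_id] = (amount, None, mw_of(e.metabolite_id))
            total = sum(a for a, _, _ in moles.values())
            fractions = {}
            mw = 0.0
            for mid, (amount, sub, sub_mw) in moles.items():
                frac = amount / total
                mw += frac * sub_mw
                if sub is None:
                    fractions[mid] = fractions.get(mid, 0.0) + frac
                else:
                    for smid, sfrac in sub.items():
                        fractions[smid] = fractions.get(smid, 0.0) + frac * sfrac
            # maintenance of this sheet and of subpools is checked separately
            return fractions, mw

        masses = {}
        infos = {}
        for e in spec.top.entries:
            if e.metabolite_id in spec.pools:
                fractions, mw = pool_info(e.metabolite_id)
                infos[e.metabolite_id] = (fractions, mw)
            else:
                fractions, mw = {e.metabolite_id: 1.0}, mw_of(e.metabolite_id)
                infos[e.metabolite_id] = (fractions, mw)
            assert e.unit is Unit.G_PER_GDW  # fixture top sheet unit
            masses[e.metabolite_id] = e.value
        total_mass = sum(masses.values())
        expected = {}
        for cid, mass in masses.items():
            fractions, mw = infos[cid]
            coeff = (mass / total_mass) * 1000.0 / mw
            for mid, frac in fractions.items():
                expected[mid] = expected.get(mid, 0.0) + coeff * frac

        for mid, value in expected.items():
            assert flat[mid] == pytest.approx(value, rel=1e-9), mid

    def test_flatten_matches_single_level_pipeline(self, built3, tmp_path):
        """Feed the flattened coefficients back in as a single-level sheet in
        mmol_per_gDW and check the pipeline reproduces them (closure)."""
        model, spec, top, pools, _ = built3
        flat = flatten_bof(spec, top, pools)
        consumed = {m: v for m, v in flat.items() if v > 0}
        produced = {m: -v for m, v in flat.items() if v < 0}
        top_spec = PseudoReactionSpec(
            "BIOMASS",
            1,
            [CompositionEntry(m, v, Unit.MMOL_PER_GDW) for m, v in consumed.items()],
        )
        single = BofSpec(top=top_spec, pools={}, tag="s", compartment="c",
                         sheet_order=["BIOMASS"])
        top_single = resolve_top(top_spec, {}, model)
        flat_single = flatten_bof(single, top_single, {})
        # net produced species (maintenance byproducts) carry mass out of the
        # hierarchical build, so the single-level normalization constant
        # differs; coefficient *ratios* must nevertheless match exactly
        assert produced  # fixture includes maintenance byproducts
        ref = next(iter(consumed))
        for mid in consumed:
            assert flat_single[mid] / flat_single[ref] == pytest.approx(
                consumed[mid] / consumed[ref], rel=1e-9
            )


class TestMassClosure:
    def test_net_mass_is_one_gram(self, built3):
        model, spec, top, pools, _ = built3
        report = validate.balance_check(model, "bof1")
        assert report.biomass_mass_g == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 11])
    @pytest.mark.parametrize("levels", [1, 2, 3])
    def test_mass_closure_randomized(self, tmp_path, seed, levels):
        cfg = FixtureConfig(levels=levels, seed=seed)
        model = make_toy_model(cfg)
        path = make_composition(cfg, model, tmp_path / f"c{levels}_{seed}.xlsx")
        spec = composition.build_spec(composition.load_workbook(path), "t", "c", model)
        build_bof(model, spec)
        report = validate.balance_check(model, "t")
        assert report.all_balanced
        assert report.biomass_mass_g == pytest.approx(1.0, rel=1e-6)


class TestWorkbookLevelInvariance:
    def test_unit_invariance_full_pipeline(self, tmp_path):
        """g vs mg vs %DW on the top sheet: identical coefficients."""
        coeff_sets = []
        for unit in (Unit.G_PER_GDW, Unit.MG_PER_GDW, Unit.PERCENT_DW_MASS):
            cfg = FixtureConfig(levels=3, seed=13, units={"BIOMASS": unit})
            model = make_toy_model(cfg)
            path = make_composition(cfg, model, tmp_path / f"c_{unit.value}.xlsx")
            spec = composition.build_spec(composition.load_workbook(path), "t", "c", model)
            top, pools = resolve_all(spec, model)
            coeff_sets.append(top.coefficients)
        ref = coeff_sets[0]
        for other in coeff_sets[1:]:
            assert set(other) == set(ref)
            for mid in ref:
                assert other[mid] == pytest.approx(ref[mid], rel=1e-9)

    def test_scale_invariance_full_pipeline(self, tmp_path):
        results = []
        for total in (0.97, 6.79):  # x7
            cfg = FixtureConfig(levels=2, seed=21, total_mass=total)
            model = make_toy_model(cfg)
            path = make_composition(cfg, model, tmp_path / f"c_{total}.xlsx")
            spec = composition.build_spec(composition.load_workbook(path), "t", "c", model)
            top, _ = resolve_all(spec, model)
            results.append(top)
        for mid in results[0].coefficients:
            assert results[1].coefficients[mid] == pytest.approx(
                results[0].coefficients[mid], rel=1e-9
            )
        assert results[1].scale_factor == pytest.approx(results[0].scale_factor / 7, rel=1e-9)

    def test_zero_row_does_not_change_downstream(self, tmp_path):
        import openpyxl

        cfg = FixtureConfig(levels=2, seed=2)
        model = make_toy_model(cfg)
        path = make_composition(cfg, model, tmp_path / "c.xlsx")
        spec_ref = composition.build_spec(composition.load_workbook(path), "t", "c", model)
        top_ref, _ = resolve_all(spec_ref, model)
        # plant a zero-valued extra row on the DNA sheet
        wb = openpyxl.load_workbook(path)
        ws = wb["DNA"]
        unit = ws.cell(row=2, column=4).value
        ws.append(["aa1_c", "AA1", 0.0, unit])
        path2 = tmp_path / "c0.xlsx"
        wb.save(path2)
        spec_zero = composition.build_spec(composition.load_workbook(path2), "t", "c", model)
        top_zero, _ = resolve_all(spec_zero, model)
        for mid in top_ref.coefficients:
            assert top_zero.coefficients[mid] == pytest.approx(
                top_ref.coefficients[mid], rel=1e-12
            )


class TestReport:
    def test_every_species_once_per_reaction(self, built3):
        _, _, _, _, report = built3
        seen = set()
        for row in report.rows:
            key = (row.reaction_id, row.species_id)
            assert key not in seen
            seen.add(key)

    def test_scale_factor_recorded(self, built3):
        _, _, top, _, report = built3
        assert report.scale_factor == top.scale_factor

    def test_tsv_and_xlsx_outputs(self, built3, tmp_path):
        *_, report = built3
        report.to_tsv(tmp_path / "r.tsv")
        report.to_xlsx(tmp_path / "r.xlsx")
        text = (tmp_path / "r.tsv").read_text()
        assert "scale_factor" in text
        import openpyxl

        wb = openpyxl.load_workbook(tmp_path / "r.xlsx")
        assert "SUMMARY" in wb.sheetnames
        assert "BIOMASS_bof1" in wb.sheetnames
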