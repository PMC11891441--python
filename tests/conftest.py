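import cobra
import pytest

from bofkit import composition, builder
from bofkit.fixtures import FixtureConfig, make_composition, make_toy_model
from bofkit.gem_io import ModelHandle


def tiny_model(mets: dict[str, tuple[str, int | None]]) -> ModelHandle:
    """Hand-built one-compartment model: id -> (formula, charge)."""
    model = cobra.Model("tiny")
    model.compartments = {"c": "cytosol"}
    objs = []
    for mid, (formula, charge) in mets.items():
        met = cobra.Metabolite(mid, formula=formula, compartment="c", name=mid)
        if charge is not None:
            met.charge = charge
        objs.append(met)
    model.add_metabolites(objs)
    rxn = cobra.Reaction("DUMMY")
    rxn.bounds = (0, 1000)
    model.add_reactions([rxn])
    rxn.add_metabolites({objs[0]: -1})
    return ModelHandle(model)


@pytest.fixture
def cfg3():
    return FixtureConfig(levels=3, seed=7, make_feasible=True)


@pytest.fixture
def toy3(cfg3):
    return make_toy_model(cfg3)


@pytest.fixture
def workbook3(cfg3, toy3, tmp_path):
    return make_composition(cfg3, toy3, tmp_path / "comp.xlsx")


@pytest.fixture
def spec3(workbook3, toy3):
    sheets = composition.load_workbook(workbook3)
    return composition.build_spec(sheets, "bof1", "c", toy3)


@pytest.fixture
def built3(spec3, toy3):
    """Three-level fixture after BOF insertion: (model, spec, top, pools, report)."""
    top, pools = builder.resolve_all(spec3, toy3)
    report = builder.assemble_bof(spec3, top, pools, toy3)
    return toy3, spec3, top, pools, report
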