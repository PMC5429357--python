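import numpy as np
import pytest

import dtni
from dtni.kinetics import (KineticModel, Reaction, UnsupportedRateLaw,
                           load_sbml_model)

SBML_HEADER = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="m">
    <listOfCompartments><compartment id="cell" size="1"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialConcentration="2.0"/>
      <species id="B" compartment="cell" initialConcentration="0.0"/>
    </listOfSpecies>
    <listOfReactions>
"""
SBML_FOOTER = """    </listOfReactions>
  </model>
</sbml>
"""

MASS_ACTION_RXN = """      <reaction id="conv" reversible="false">
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>k1</ci><ci>A</ci></apply>
          </math>
          <listOfParameters><parameter id="k1" value="0.1"/></listOfParameters>
        </kineticLaw>
      </reaction>
"""

HILL_RXN = """      <reaction id="hill" reversible="false">
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><divide/>
              <apply><times/><ci>V</ci><ci>A</ci></apply>
              <apply><plus/><ci>K</ci><ci>A</ci></apply>
            </apply>
          </math>
          <listOfParameters>
            <parameter id="V" value="1.0"/><parameter id="K" value="0.5"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
"""

REVERSIBLE_RXN = """      <reaction id="rev" reversible="true">
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B"/></listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><minus/>
              <apply><times/><ci>kf</ci><ci>A</ci></apply>
              <apply><times/><ci>kr</ci><ci>B</ci></apply>
            </apply>
          </math>
          <listOfParameters>
            <parameter id="kf" value="0.4"/><parameter id="kr" value="0.2"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
"""


class TestSbmlLoading:
    def test_mass_action_model_loads(self, tmp_path):
        path = tmp_path / "mini.xml"
        path.write_text(SBML_HEADER + MASS_ACTION_RXN + SBML_FOOTER)
        model = load_sbml_model(path)
        assert model.species == {"A": 2.0, "B": 0.0}
        assert len(model.reactions) == 1
        rxn = model.reactions[0]
        assert rxn.reactants == [("A", 1)]
        assert rxn.products == [("B", 1)]
        assert rxn.rate_constant == pytest.approx(0.1)

    def test_hill_law_rejected_naming_reaction(self, tmp_path):
        path = tmp_path / "hill.xml"
        path.write_text(SBML_HEADER + HILL_RXN + SBML_FOOTER)
        with pytest.raises(UnsupportedRateLaw, match="hill"):
            load_sbml_model(path)

    def test_reversible_law_split_into_two_reactions(self, tmp_path):
        path = tmp_path / "rev.xml"
        path.write_text(SBML_HEADER + REVERSIBLE_RXN + SBML_FOOTER)
        model = load_sbml_model(path)
        assert len(model.reactions) == 2
        fwd, back = model.reactions
        assert fwd.rate_constant == pytest.approx(0.4)
        assert back.rate_constant == pytest.approx(0.2)
        assert back.reactants == [("B", 1)]

    def test_unparseable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("this is not sbml")
        with pytest.raises(ValueError):
            load_sbml_model(path)


class TestDrugAugmentation:
    def test_empty_spec_is_identity(self, nfkb_model):
        base = dtni.ikb_nfkb_module()
        out = dtni.add_drug_reactions(base, [])
        assert out.species == base.species
        assert len(out.reactions) == len(base.reactions)

    def test_binding_spec_bookkeeping(self):
        base = dtni.ikb_nfkb_module()
        out = dtni.add_drug_reactions(base, [("drugX", "IKK", 1.0, "inactivation")])
        assert len(out.species) == len(base.species) + 1
        assert len(out.reactions) == len(base.reactions) + 1
        assert "drugX" in out.compound_species
        assert out.species["drugX"] == 0.0

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            dtni.add_drug_reactions(dtni.ikb_nfkb_module(),
                                    [("d", "NOPE", 1.0, "induction")])

    def test_zero_dose_trajectories_match_unaugmented_model(self):
        base = dtni.ikb_nfkb_module()
        aug = dtni.add_drug_reactions(base, dtni.default_drug_spec())
        times = np.array([2.0, 8.0, 24.0])
        y_base = base.simulate(times)
        y_aug = aug.simulate(times, {c: 0.0 for c in aug.compound_species})
        gene_idx = [list(aug.species).index(g) for g in aug.gene_species]
        assert np.allclose(y_aug[gene_idx], y_base, atol=1e-8)


class TestSimulateDataset:
    def test_inert_compound_gives_zero_ratios(self):
        model = dtni.ikb_nfkb_module()
        model.species["placebo"] = 0.0
        model.compound_species.append("placebo")
        tensor = dtni.simulate_dataset(model, noise=dtni.NoiseModel(0.0, 2))
        assert np.allclose(tensor.values, 0.0, atol=1e-7)

    def test_default_design(self, nfkb_model):
        tensor = dtni.simulate_dataset(nfkb_model,
                                       noise=dtni.NoiseModel(0.0, 2, 0))
        assert np.array_equal(tensor.times, [2.0, 8.0, 24.0])
        assert tensor.n_doses == 3
        assert tensor.compounds == nfkb_model.compound_species
        # drug species are not observables
        assert not set(tensor.genes) & set(nfkb_model.compound_species)

    def test_zero_sigma_replicates_identical(self, nfkb_tensor, nfkb_model):
        tensor = dtni.simulate_dataset(nfkb_model,
                                       noise=dtni.NoiseModel(0.0, 2, 0))
        assert np.array_equal(tensor.values[..., 0], tensor.values[..., 1])

    def test_mass_conservation_of_total_nfkb(self):
        """NFkB is only shuttled between free, nuclear and complexed forms;
        its total is conserved along any trajectory."""
        model = dtni.ikb_nfkb_module()
        y = model.simulate(np.linspace(0.5, 24, 10))
        names = list(model.species)
        total = sum(y[names.index(s)] for s in ("NFkB", "NFkBn", "NFkB_IkB"))
        assert np.allclose(total, total[0], rtol=1e-6)

    def test_validation_of_model_structure(self):
        with pytest.raises(ValueError, match="undeclared"):
            KineticModel(species={"A": 1.0},
                         reactions=[Reaction("r", [("B", 1)], [], 1.0)])
        with pytest.raises(ValueError, match="rate constant"):
            Reaction("r", [("A", 1)], [], 0.0)
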