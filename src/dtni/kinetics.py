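"""Mass-action kinetic models: SBML loading, drug-reaction augmentation,
stiff simulation, and the dose-time benchmark dataset generator.

The benchmark idea: simulate a mechanistic signalling module (treated at
several doses of one or more drug species, plus a drug-free control),
form log2 ratios treated/control per species and time point, add
replicate noise, and feed the result to network inference.  The module's
reaction structure then provides the gold-standard network to score
against.

Only mass-action rate laws are supported (rate = k * product of reactant
concentrations, times any modifier concentrations); models with other
kinetics are rejected explicitly.  A hand-built IkB-NF-kB-like module
(:func:`ikb_nfkb_module`) ships as the default benchmark; it is a
synthetic stand-in capturing the canonical negative-feedback structure
of NF-kB signalling (IKK-triggered IkB degradation, nuclear
translocation, NF-kB-induced IkB and A20 resynthesis, A20 inhibition of
IKK), not a transcription of any published model.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .data import ExpressionTensor
from .simulate import TG_GATES_TIMES

__all__ = [
    "Reaction",
    "KineticModel",
    "UnsupportedRateLaw",
    "load_sbml_model",
    "add_drug_reactions",
    "simulate_dataset",
    "ikb_nfkb_module",
    "default_drug_spec",
]

RATIO_FLOOR = 1e-12


class UnsupportedRateLaw(ValueError):
    """Raised for SBML reactions whose kinetics are not mass action."""


@dataclass
class Reaction:
    """One irreversible mass-action reaction.

    ``rate = rate_constant * prod(reactants ** stoich) * prod(modifiers)``.
    An empty reactant list is zeroth-order synthesis.
    """

    id: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    rate_constant: float
    modifiers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValueError(f"reaction {self.id}: rate constant must be > 0")


@dataclass
class KineticModel:
    """Species with initial concentrations plus mass-action reactions.

    ``compound_species`` are drug species whose initial concentration is
    the administered dose; setting them all to zero defines the control
    condition.  ``constant_species`` are held fixed during integration
    (SBML boundary/constant species).
    """

    species: dict[str, float]
    reactions: list[Reaction]
    compound_species: list[str] = field(default_factory=list)
    constant_species: set[str] = field(default_factory=set)
    name: str = "kinetic model"

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            for sp, _ in rxn.reactants + rxn.products:
                if sp not in self.species:
                    raise ValueError(f"reaction {rxn.id} references undeclared species {sp!r}")
            for sp in rxn.modifiers:
                if sp not in self.species:
                    raise ValueError(f"reaction {rxn.id} references undeclared modifier {sp!r}")
        for sp, conc in self.species.items():
            if conc < 0:
                raise ValueError(f"species {sp!r} has negative initial concentration")

    @property
    def gene_species(self) -> list[str]:
        """Observable (non-drug) species, in declaration order."""
        drugs = set(self.compound_species)
        return [s for s in self.species if s not in drugs]

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.species)}
        dy = np.zeros_like(y)
        for rxn in self.reactions:
            rate = rxn.rate_constant
            for sp, m in rxn.reactants:
                rate *= y[idx[sp]] ** m
            for sp in rxn.modifiers:
                rate *= y[idx[sp]]
            for sp, m in rxn.reactants:
                dy[idx[sp]] -= m * rate
            for sp, m in rxn.products:
                dy[idx[sp]] += m * rate
        for sp in self.constant_species:
            dy[idx[sp]] = 0.0
        return dy

    def initial_state(self, dose_overrides: dict[str, float] | None = None) -> np.ndarray:
        state = dict(self.species)
        for sp, dose in (dose_overrides or {}).items():
            if sp not in state:
                raise KeyError(sp)
            state[sp] = dose
        return np.array(list(state.values()), dtype=float)

    def simulate(self, times, dose_overrides: dict[str, float] | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
        """Integrate the mass-action ODEs (stiff implicit solver) and
        return concentrations of all species at the requested times,
        shape (n_species, T)."""
        times = np.asarray(times, dtype=float)
        y0 = self.initial_state(dose_overrides)
        sol = solve_ivp(self.rhs, (0.0, float(times[-1])), y0, method="LSODA",
                        t_eval=times, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration of {self.name!r} failed: {sol.message}")
        return sol.y


# ---------------------------------------------------------------------------
# SBML loading (mass-action only)
# ---------------------------------------------------------------------------

def _mass_action_factors(node, reaction_id):
    """Flatten a kinetic-law AST into (names, numbers); reject anything
    that is not a plain product (sums, quotients, functions, powers)."""
    import libsbml

    t = node.getType()
    if t == libsbml.AST_TIMES:
        names, numbers = [], []
        for i in range(node.getNumChildren()):
            sub_names, sub_numbers = _mass_action_factors(node.getChild(i), reaction_id)
            names += sub_names
            numbers += sub_numbers
        return names, numbers
    if t == libsbml.AST_NAME:
        return [node.getName()], []
    if t in (libsbml.AST_INTEGER, libsbml.AST_REAL, libsbml.AST_REAL_E, libsbml.AST_RATIONAL):
        return [], [node.getValue()]
    raise UnsupportedRateLaw(
        f"reaction {reaction_id!r}: kinetic law is not mass action "
        f"(unsupported operation node of type {node.getType()})"
    )


def load_sbml_model(path) -> KineticModel:
    """Load an SBML Level 2/3 model with mass-action kinetic laws.

    Every kinetic law must be a plain product of parameters, compartment
    sizes and the reaction's reactant/modifier species; reversible laws
    written as ``forward - backward`` (each a plain product) are split
    into two irreversible reactions.  Anything else (Hill terms,
    Michaelis-Menten quotients, ...) raises :class:`UnsupportedRateLaw`
    naming the reaction.
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ValueError(f"unparseable SBML {path!r}: {err.getMessage()}")
    sbml = doc.getModel()
    if sbml is None:
        raise ValueError(f"unparseable SBML {path!r}: no model element")

    species: dict[str, float] = {}
    constant: set[str] = set()
    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        conc = sp.getInitialConcentration()
        if np.isnan(conc):
            conc = sp.getInitialAmount()
        species[sp.getId()] = 0.0 if np.isnan(conc) else float(conc)
        if sp.getBoundaryCondition() or sp.getConstant():
            constant.add(sp.getId())

    global_params = {sbml.getParameter(i).getId(): sbml.getParameter(i).getValue()
                     for i in range(sbml.getNumParameters())}
    compartments = {sbml.getCompartment(i).getId():
                    (sbml.getCompartment(i).getSize()
                     if not np.isnan(sbml.getCompartment(i).getSize()) else 1.0)
                    for i in range(sbml.getNumCompartments())}

    reactions: list[Reaction] = []
    for i in range(sbml.getNumReactions()):
        rxn = sbml.getReaction(i)
        rid = rxn.getId()
        law = rxn.getKineticLaw()
        if law is None or law.getMath() is None:
            raise UnsupportedRateLaw(f"reaction {rid!r} has no kinetic law")
        local = {law.getParameter(j).getId(): law.getParameter(j).getValue()
                 for j in range(law.getNumParameters())}

        reactants = [(rxn.getReactant(j).getSpecies(),
                      int(rxn.getReactant(j).getStoichiometry()))
                     for j in range(rxn.getNumReactants())]
        products = [(rxn.getProduct(j).getSpecies(),
                     int(rxn.getProduct(j).getStoichiometry()))
                    for j in range(rxn.getNumProducts())]
        modifiers = [rxn.getModifier(j).getSpecies()
                     for j in range(rxn.getNumModifiers())]

        import libsbml as _ls
        math = law.getMath()
        terms = []
        if math.getType() == _ls.AST_MINUS and math.getNumChildren() == 2:
            terms.append((math.getChild(0), reactants, products))
            terms.append((math.getChild(1), products, reactants))  # backward
        else:
            terms.append((math, reactants, products))

        for suffix, (node, r_side, p_side) in zip(("", "_rev"), terms):
            names, numbers = _mass_action_factors(node, rid)
            k = float(np.prod(numbers)) if numbers else 1.0
            species_factors = []
            for name in names:
                if name in local:
                    k *= local[name]
                elif name in global_params:
                    k *= global_params[name]
                elif name in compartments:
                    k *= compartments[name]
                elif name in species:
                    species_factors.append(name)
                else:
                    raise UnsupportedRateLaw(
                        f"reaction {rid!r}: unknown symbol {name!r} in kinetic law")
            expected: list[str] = []
            for sp, m in r_side:
                expected += [sp] * m
            expected += modifiers
            if sorted(species_factors) != sorted(expected):
                raise UnsupportedRateLaw(
                    f"reaction {rid!r}: kinetic law species {sorted(species_factors)} "
                    f"do not match mass action over reactants/modifiers {sorted(expected)}")
            if k <= 0:
                continue  # zero-rate direction contributes nothing
            reactions.append(Reaction(rid + suffix, list(r_side), list(p_side),
                                      k, list(modifiers)))

    return KineticModel(species=species, reactions=reactions,
                        constant_species=constant,
                        name=sbml.getName() or sbml.getId() or str(path))


# ---------------------------------------------------------------------------
# drug augmentation
# ---------------------------------------------------------------------------

def add_drug_reactions(model: KineticModel, drug_spec) -> KineticModel:
    """Add drug species and their mass-action actions on the pathway.

    ``drug_spec`` is an iterable of ``(drug, target, rate_constant, mode)``
    with mode ``"inactivation"`` (drug + target -> drug: the drug
    catalytically removes its target, e.g. binding-and-degradation) or
    ``"induction"`` (drug -> drug + target: the drug catalyses synthesis
    of its target).  Drug species start at concentration 0 (the dose is
    set per simulation) and are registered as compound species.
    """
    out = copy.deepcopy(model)
    for drug, target, rate, mode in drug_spec:
        if target not in out.species:
            raise ValueError(f"drug {drug!r} targets unknown species {target!r}")
        if drug not in out.species:
            out.species[drug] = 0.0
        if drug not in out.compound_species:
            out.compound_species.append(drug)
        if mode == "inactivation":
            rxn = Reaction(f"{drug}_inactivates_{target}",
                           [(drug, 1), (target, 1)], [(drug, 1)], float(rate))
        elif mode == "induction":
            rxn = Reaction(f"{drug}_induces_{target}",
                           [(drug, 1)], [(drug, 1), (target, 1)], float(rate))
        else:
            raise ValueError(f"unknown drug mode {mode!r}")
        out.reactions.append(rxn)
    return out


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def simulate_dataset(model: KineticModel, times=None, doses=None,
                     noise=None, compounds=None,
                     rtol: float = 1e-8, atol: float = 1e-10) -> ExpressionTensor:
    """Simulate a dose-time log2-ratio dataset from a kinetic model.

    One compound (drug species) is dosed at a time; each compound's
    treated trajectories at every dose are compared against the shared
    drug-free control (all compound concentrations zero) at the same
    time points.  Multiplicative log-normal noise (see
    :class:`~dtni.simulate.NoiseModel`) is applied independently to the
    treated and control channel of each replicate BEFORE ratio formation.
    Species whose control concentration falls to zero are floored at
    1e-12 with a warning.
    """
    from .simulate import NoiseModel

    times = TG_GATES_TIMES if times is None else np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    doses = np.asarray([0.01, 0.05, 0.25]) if doses is None else np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    noise = noise or NoiseModel()
    compounds = list(compounds) if compounds is not None else list(model.compound_species)
    if not compounds:
        raise ValueError("model has no compound species to dose")

    genes = model.gene_species
    gene_idx = [list(model.species).index(g) for g in genes]

    zero_doses = {c: 0.0 for c in model.compound_species}
    control = model.simulate(times, zero_doses, rtol=rtol, atol=atol)[gene_idx]

    n, T, D, C = len(genes), len(times), len(doses), len(compounds)
    treated = np.empty((n, T, D, C))
    for ci, compound in enumerate(compounds):
        for di, dose in enumerate(doses):
            overrides = dict(zero_doses)
            overrides[compound] = float(dose)
            treated[:, :, di, ci] = model.simulate(times, overrides,
                                                   rtol=rtol, atol=atol)[gene_idx]

    if np.any(control < RATIO_FLOOR) or np.any(treated < RATIO_FLOOR):
        warnings.warn("concentrations at/below the ratio floor 1e-12 were clipped")
    control = np.maximum(control, RATIO_FLOOR)
    treated = np.maximum(treated, RATIO_FLOOR)

    rng = np.random.default_rng(noise.seed)
    R = noise.replicates
    values = np.empty((n, T, D, C, R))
    log_ratio = np.log2(treated / control[:, :, None, None])
    for r in range(R):
        if noise.sigma > 0:
            eps_t = rng.normal(0.0, noise.sigma, size=log_ratio.shape)
            eps_c = rng.normal(0.0, noise.sigma, size=log_ratio.shape)
            values[..., r] = log_ratio + eps_t - eps_c
        else:
            values[..., r] = log_ratio

    doses2d = np.repeat(doses[None, :], C, axis=0)
    return ExpressionTensor(list(genes), times, doses2d, compounds, values)


# ---------------------------------------------------------------------------
# synthetic benchmark module
# ---------------------------------------------------------------------------

def ikb_nfkb_module() -> KineticModel:
    """Synthetic IkB-NF-kB-like signalling module (mass action).

    A hand-built stand-in benchmark, NOT a transcription of any published
    model: it reproduces the canonical negative-feedback architecture of
    NF-kB signalling — cytoplasmic sequestration of NF-kB by IkB,
    IKK-catalysed IkB degradation, nuclear translocation of freed NF-kB,
    NF-kB-driven resynthesis of IkB and of the IKK inhibitor A20, and an
    NF-kB target transcript as readout.  Rates are per hour, tuned so the
    module responds on the 2-24 h window of the in vitro design.
    """
    # initial concentrations = the module's drug-free steady state, so the
    # control condition is stationary and log2 ratios isolate the response
    species = {
        "NFkB_IkB": 1.8336,
        "NFkB": 0.0978,
        "NFkBn": 0.1686,
        "IkB": 0.2319,
        "IkB_mRNA": 0.2698,
        "A20": 0.3513,
        "A20_mRNA": 0.1686,
        "IKK": 0.0399,
        "Target_mRNA": 0.3513,
    }
    # rates per hour, giving relaxation on the 2-24 h scale of the design
    r = Reaction
    reactions = [
        r("complex_formation", [("NFkB", 1), ("IkB", 1)], [("NFkB_IkB", 1)], 1.5),
        r("ikk_degrades_ikb", [("NFkB_IkB", 1), ("IKK", 1)], [("NFkB", 1), ("IKK", 1)], 1.0),
        r("nuclear_import", [("NFkB", 1)], [("NFkBn", 1)], 0.4),
        r("ikb_export", [("NFkBn", 1), ("IkB", 1)], [("NFkB_IkB", 1)], 1.0),
        r("ikb_transcription", [("NFkBn", 1)], [("NFkBn", 1), ("IkB_mRNA", 1)], 0.4),
        r("ikb_translation", [("IkB_mRNA", 1)], [("IkB_mRNA", 1), ("IkB", 1)], 0.4),
        r("ikb_mrna_decay", [("IkB_mRNA", 1)], [], 0.25),
        r("ikb_decay", [("IkB", 1)], [], 0.15),
        r("a20_transcription", [("NFkBn", 1)], [("NFkBn", 1), ("A20_mRNA", 1)], 0.25),
        r("a20_translation", [("A20_mRNA", 1)], [("A20_mRNA", 1), ("A20", 1)], 0.25),
        r("a20_mrna_decay", [("A20_mRNA", 1)], [], 0.25),
        r("a20_decay", [("A20", 1)], [], 0.12),
        r("a20_inhibits_ikk", [("A20", 1), ("IKK", 1)], [("A20", 1)], 1.2),
        r("ikk_synthesis", [], [("IKK", 1)], 0.02),
        r("ikk_decay", [("IKK", 1)], [], 0.08),
        r("target_transcription", [("NFkBn", 1)], [("NFkBn", 1), ("Target_mRNA", 1)], 0.25),
        r("target_mrna_decay", [("Target_mRNA", 1)], [], 0.12),
    ]
    return KineticModel(species=species, reactions=reactions,
                        name="synthetic IkB-NF-kB-like module")


def default_drug_spec() -> list[tuple[str, str, float, str]]:
    """Default drug actions on the synthetic module: four drugs entering
    the pathway at different points (a synthetic stand-in for a measured
    drug-reaction table)."""
    return [
        ("drug_ikk_act", "IKK", 1.0, "induction"),
        ("drug_ikb_deg", "IkB", 2.0, "inactivation"),
        ("drug_nfkb_ind", "NFkB", 0.5, "induction"),
        ("drug_a20_deg", "A20", 2.0, "inactivation"),
    ]
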