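"""End-to-end simulation benchmarks: simulate -> infer -> evaluate.

Reproduces the standard simulation-study designs for dose-time network
inference: comparing the dose-time method against its time-only
baseline, and sweeping the number of time points, doses, compounds,
the noise level and the replicate count to map their influence on
recovery of a known network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .evaluation import (classify_edges, edge_confidence, gold_standard_from_model,
                         roc_auroc)
from .kinetics import add_drug_reactions, default_drug_spec, ikb_nfkb_module, simulate_dataset
from .model import DTNI, TSNI
from .significance import loocv_consensus
from .simulate import (NoiseModel, add_noise, make_linear_grn, simulate_linear,
                       TG_GATES_DOSES, TG_GATES_TIMES)
from .data import ExpressionTensor
from .evaluation import GoldStandard

__all__ = ["BenchmarkConfig", "run_benchmark", "sweep",
           "design_times", "design_doses"]

KINETIC_DOSE_SCALE = 0.01  # kinetic module doses in units where 1:5:25 -> 0.01..0.25


def design_times(n_times: int) -> np.ndarray:
    """Sampling times in hours: the in vitro template (2, 8, 24) for
    three points, otherwise geometric spacing over the same window."""
    if n_times == 3:
        return TG_GATES_TIMES.copy()
    return np.geomspace(2.0, 24.0, n_times)


def design_doses(n_doses: int) -> np.ndarray:
    """Dose design: ratio 1:5:25 for three levels, otherwise geometric
    over the same 25-fold range."""
    if n_doses == 3:
        return TG_GATES_DOSES.copy()
    return np.geomspace(1.0, 25.0, n_doses)


@dataclass
class BenchmarkConfig:
    """One benchmark condition (shared across its seeds)."""

    generator: str = "kinetic"        # "linear" or "kinetic"
    n_genes: int = 10                 # linear generator only
    edge_density: float = 0.15        # linear generator only
    n_times: int = 3
    n_doses: int = 3
    n_compounds: int = 1
    replicates: int = 2
    sigma: float = 0.05
    n_perm: int = 200
    alpha: float = 0.05
    k: int | str = "auto"
    seeds: list[int] = field(default_factory=lambda: list(range(20)))
    method: str = "both"              # "dtni", "tsni" or "both"
    loocv: bool = False

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seeds must be non-empty")
        for name in ("n_genes", "n_times", "n_doses", "n_compounds",
                     "replicates", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.generator not in ("linear", "kinetic"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.method not in ("dtni", "tsni", "both"):
            raise ValueError(f"unknown method {self.method!r}")


# cache of noiseless kinetic log2-ratio tensors, keyed by design
_KINETIC_CACHE: dict[tuple, tuple[np.ndarray, "ExpressionTensor"]] = {}


def _kinetic_clean(config: BenchmarkConfig):
    spec = default_drug_spec()
    if config.n_compounds > len(spec):
        raise ValueError(
            f"kinetic benchmark supports at most {len(spec)} compounds")
    key = (config.n_times, config.n_doses, config.n_compounds)
    if key not in _KINETIC_CACHE:
        model = add_drug_reactions(ikb_nfkb_module(), spec[: config.n_compounds])
        tensor = simulate_dataset(
            model,
            times=design_times(config.n_times),
            doses=design_doses(config.n_doses) * KINETIC_DOSE_SCALE,
            noise=NoiseModel(sigma=0.0, replicates=1),
        )
        gold = gold_standard_from_model(model).restrict(tensor.genes)
        _KINETIC_CACHE[key] = (tensor, gold)
    return _KINETIC_CACHE[key]


def _dataset_for_seed(config: BenchmarkConfig, seed: int
                      ) -> tuple[ExpressionTensor, GoldStandard]:
    noise = NoiseModel(sigma=config.sigma, replicates=config.replicates, seed=seed)
    if config.generator == "kinetic":
        clean, gold = _kinetic_clean(config)
        values = add_noise(clean.values[..., 0], noise)
        tensor = ExpressionTensor(list(clean.genes), clean.times.copy(),
                                  clean.doses.copy(), list(clean.compounds), values)
        return tensor, gold
    # linear generator: a fresh ground truth per seed
    rng = np.random.default_rng(seed)
    A, gold_idx = make_linear_grn(config.n_genes, config.edge_density, seed)
    b = np.zeros((config.n_genes, config.n_compounds))
    for c in range(config.n_compounds):
        targets = rng.choice(config.n_genes, size=max(1, config.n_genes // 5),
                             replace=False)
        b[targets, c] = rng.uniform(0.5, 1.5, size=targets.size)
    times = design_times(config.n_times)
    doses = design_doses(config.n_doses)
    clean = simulate_linear(A, b, times, doses)
    values = add_noise(clean, noise)
    genes = [f"g{i+1}" for i in range(config.n_genes)]
    compounds = [f"cpd{c+1}" for c in range(config.n_compounds)]
    doses2d = np.repeat(doses[None, :], config.n_compounds, axis=0)
    tensor = ExpressionTensor(genes, times, doses2d, compounds, values)
    gold = GoldStandard(genes, {(genes[j], genes[i]) for j, i in gold_idx})
    return tensor, gold


def _evaluate_fit(result, gold, alpha):
    scores = edge_confidence(result.p_values, result.A, result.genes)
    _, auroc = roc_auroc(scores, gold)
    counts = classify_edges(result.network(alpha), gold)
    counts.auroc = auroc
    return counts


def run_benchmark(config: BenchmarkConfig) -> dict:
    """Run simulate -> infer -> evaluate for every seed of a config.

    Returns a machine-readable report: the config, one row per
    (seed, method) with the confusion counts and metrics, and per-method
    aggregate mean/sd of geometric mean, AUROC and PPV.  Deterministic
    given the config.
    """
    methods = ["dtni", "tsni"] if config.method == "both" else [config.method]
    rows = []
    for seed in config.seeds:
        tensor, gold = _dataset_for_seed(config, seed)
        for method in methods:
            cls = DTNI if method == "dtni" else TSNI
            res = cls(tensor, k=config.k).fit(
                n_perm=config.n_perm, seed=seed, alpha=config.alpha)
            counts = _evaluate_fit(res, gold, config.alpha)
            row = {"seed": seed, "method": method, **counts.as_dict()}
            if config.loocv and len(tensor.compounds) >= 2 and method == "dtni":
                consensus = loocv_consensus(tensor, alpha=config.alpha,
                                            n_perm=config.n_perm, seed=seed)
                row["ppv_loocv"] = classify_edges(consensus, gold).ppv
                row["n_edges_loocv"] = len(consensus)
            rows.append(row)

    aggregate = {}
    for method in methods:
        sub = [r for r in rows if r["method"] == method]
        agg = {}
        for metric in ("geometric_mean", "auroc", "ppv", "sensitivity",
                       "specificity", "ppv_loocv"):
            vals = [r[metric] for r in sub if metric in r]
            if vals:
                agg[f"mean_{metric}"] = float(np.mean(vals))
                agg[f"sd_{metric}"] = float(np.std(vals))
        aggregate[method] = agg
    return {"config": asdict(config), "rows": rows, "aggregate": aggregate}


def sweep(config: BenchmarkConfig, axis: str, values) -> list[dict]:
    """Vary one design axis (n_times, n_doses, n_compounds, sigma or
    replicates), re-running the benchmark at each value.

    Returns one aggregate row per axis value, suitable for plotting
    recovery metrics against the axis.
    """
    allowed = {"n_times", "n_doses", "n_compounds", "sigma", "replicates"}
    if axis not in allowed:
        raise ValueError(f"axis must be one of {sorted(allowed)}")
    values = list(values)
    if values != sorted(values):
        raise ValueError("sweep values must be ascending")
    out = []
    for value in values:
        cfg = BenchmarkConfig(**{**asdict(config), axis: value})
        report = run_benchmark(cfg)
        for method, agg in report["aggregate"].items():
            out.append({axis: value, "method": method, **agg})
    return out


def write_report(report, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
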