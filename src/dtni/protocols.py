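"""Standard evaluation protocol: the simulation studies that validate the
method end-to-end.

Each study builds its data from the package's own generators, runs the
inference, and returns plain dictionaries of measured quantities.  The
studies are deterministic given their seed.  Problem sizes are desk
scale: networks of 5-9 genes, 20 Monte Carlo seeds per condition, and
100-200 permutations per test (the add-one p-value floor is then 1/101
resp. 1/201, ample for thresholding at 0.05).
"""

from __future__ import annotations

import numpy as np

from .benchmark import BenchmarkConfig, run_benchmark, sweep
from .data import ExpressionTensor
from .evaluation import (GoldStandard, edge_confidence, gold_standard_from_model,
                         roc_auroc)
from .kinetics import add_drug_reactions, default_drug_spec, ikb_nfkb_module
from .model import DTNI, TSNI
from .simulate import NoiseModel, make_linear_grn, simulate_linear_dataset

__all__ = [
    "oracle_recovery_study",
    "null_calibration_study",
    "method_comparison_study",
    "trend_studies",
    "loocv_study",
    "gold_standard_summary",
]


def _seed_base(seed: int) -> int:
    return int(seed) % 100_000


def oracle_recovery_study(seed: int = 0, n_runs: int = 4) -> dict:
    """Exact-recovery check on noiseless linear-ODE data.

    Ground truths of 5-8 genes are excited by a per-gene perturbation
    panel (one compound per gene — the classic identifiability design;
    a single input excites too few independent directions for full-rank
    recovery), sampled densely in time, and fitted time-block-only at
    full-rank reduction.  Reports the worst relative Frobenius error of
    the recovered interaction matrix and the worst AUROC of edge
    recovery ranked by |strength|.
    """
    base = _seed_base(seed)
    errors, aurocs = [], []
    for i in range(n_runs):
        n = 5 + i % 4
        A, gold = make_linear_grn(n, 0.2, base + i)
        tensor = simulate_linear_dataset(
            A, np.eye(n), times=np.linspace(0.5, 24.0, 24),
            doses=[1.0, 5.0, 25.0], noise=NoiseModel(0.0, 1))
        res = TSNI(tensor, smoothing=None, n_time_grid=48,
                   k="full").fit(permute=False)
        errors.append(float(np.linalg.norm(res.A - A) / np.linalg.norm(A)))
        genes = tensor.genes
        gs = GoldStandard(genes, {(genes[j], genes[i_]) for j, i_ in gold})
        scores = edge_confidence(np.ones_like(res.A), res.A, genes)
        aurocs.append(roc_auroc(scores, gs)[1])
    return {
        "max_frobenius_error": max(errors),
        "min_auroc": min(aurocs),
        "n_runs": n_runs,
    }


def null_calibration_study(seed: int = 0, n_datasets: int = 8,
                           n_genes: int = 12, n_perm: int = 200) -> dict:
    """Type-I error of the permutation test under the global null.

    Pure-noise tensors (no interactions, no perturbation response) on the
    standard 3 x 3 x 2-replicate design; every off-diagonal edge
    p-value is collected (n_datasets * n(n-1) tests) and the fraction at
    or below 0.05 plus the Kolmogorov-Smirnov distance from uniformity
    are reported.
    """
    from scipy.stats import kstest

    base = _seed_base(seed)
    ps = []
    for i in range(n_datasets):
        rng = np.random.default_rng(base + 100 + i)
        values = rng.normal(0.0, 0.2, size=(n_genes, 3, 3, 1, 2))
        tensor = ExpressionTensor([f"g{k}" for k in range(n_genes)],
                                  [2.0, 8.0, 24.0], [[1.0, 5.0, 25.0]],
                                  ["cpd1"], values)
        res = DTNI(tensor).fit(n_perm=n_perm, seed=base + i)
        ps.append(res.p_values[~np.eye(n_genes, dtype=bool)])
    ps = np.concatenate(ps)
    return {
        "type1_error_rate": float(np.mean(ps <= 0.05)),
        "ks_statistic": float(kstest(ps, "uniform").statistic),
        "mean_p": float(ps.mean()),
        "n_tests": int(ps.size),
    }


def method_comparison_study(seed: int = 0, n_seeds: int = 20,
                            n_perm: int = 200) -> dict:
    """Dose-time versus time-only inference on the kinetic benchmark.

    The in vitro anchor design — 3 time points (2/8/24 h), 3 doses at
    ratio 1:5:25, 2 replicates, moderate noise — with the four-compound
    panel pooled, scored by AUROC of p-value-ranked edges over seeds.
    """
    base = _seed_base(seed)
    cfg = BenchmarkConfig(generator="kinetic", n_compounds=4, sigma=0.05,
                          n_perm=n_perm, seeds=[base + i for i in range(n_seeds)],
                          method="both")
    report = run_benchmark(cfg)
    d = {r["seed"]: r["auroc"] for r in report["rows"] if r["method"] == "dtni"}
    t = {r["seed"]: r["auroc"] for r in report["rows"] if r["method"] == "tsni"}
    diffs = [d[s] - t[s] for s in sorted(d)]
    dtni_mean = float(np.mean(list(d.values())))
    tsni_mean = float(np.mean(list(t.values())))
    return {
        "dtni_mean_auroc": dtni_mean,
        "tsni_mean_auroc": tsni_mean,
        "auroc_advantage": float(np.mean(diffs)),
        "relative_advantage_pct": 100.0 * (dtni_mean - tsni_mean) / tsni_mean,
        "wins": int(sum(x > 0 for x in diffs)),
        "n_seeds": n_seeds,
    }


def trend_studies(seed: int = 0, n_seeds: int = 20, n_perm: int = 100) -> dict:
    """Design-axis sweeps mirroring the simulation-study figures.

    Each axis is swept where its effect expresses: time resolution and
    compound count at moderate noise; dose count at higher noise (the
    extra dose levels act as replication, which pays off when noise is
    the limiting factor); the noise and replicate axes on the 6-time
    design, where there is performance to lose.  Geometric-mean score is
    the metric for the design-size axes, AUROC for noise and replicates.
    """
    base = _seed_base(seed)
    seeds = [base + i for i in range(n_seeds)]
    out = {}

    anchor = BenchmarkConfig(generator="kinetic", n_compounds=4, sigma=0.05,
                             n_perm=n_perm, seeds=seeds, method="dtni")
    out["gmean_by_n_times"] = {
        str(r["n_times"]): r["mean_geometric_mean"]
        for r in sweep(anchor, "n_times", [3, 6])}
    out["auroc_by_n_times"] = {
        str(r["n_times"]): r["mean_auroc"]
        for r in sweep(anchor, "n_times", [3, 6, 12])}
    out["gmean_by_n_compounds"] = {
        str(r["n_compounds"]): r["mean_geometric_mean"]
        for r in sweep(anchor, "n_compounds", [1, 4])}

    noisy = BenchmarkConfig(generator="kinetic", n_compounds=4, sigma=0.2,
                            n_perm=n_perm, seeds=seeds, method="dtni")
    out["gmean_by_n_doses"] = {
        str(r["n_doses"]): r["mean_geometric_mean"]
        for r in sweep(noisy, "n_doses", [3, 6, 12])}

    six = BenchmarkConfig(generator="kinetic", n_times=6, n_compounds=4,
                          sigma=0.05, n_perm=n_perm, seeds=seeds, method="dtni")
    out["auroc_by_sigma"] = {
        str(r["sigma"]): r["mean_auroc"]
        for r in sweep(six, "sigma", [0.0, 0.2, 0.5])}

    six_noisy = BenchmarkConfig(generator="kinetic", n_times=6, n_compounds=4,
                                sigma=0.1, n_perm=n_perm, seeds=seeds,
                                method="dtni")
    out["auroc_by_replicates"] = {
        str(r["replicates"]): r["mean_auroc"]
        for r in sweep(six_noisy, "replicates", [1, 2])}
    return out


def loocv_study(seed: int = 0, n_seeds: int = 10, n_perm: int = 100) -> dict:
    """Leave-one-compound-out consensus versus the full run.

    Four-compound kinetic simulation at 6 time points and moderate
    noise; reports the mean positive predictive value of the full-run
    network and of the LOOCV consensus.
    """
    base = _seed_base(seed)
    cfg = BenchmarkConfig(generator="kinetic", n_times=6, n_compounds=4,
                          sigma=0.05, n_perm=n_perm,
                          seeds=[base + i for i in range(n_seeds)],
                          method="dtni", loocv=True)
    report = run_benchmark(cfg)
    full = [r["ppv"] for r in report["rows"]]
    consensus = [r["ppv_loocv"] for r in report["rows"]]
    return {
        "ppv_full": float(np.mean(full)),
        "ppv_loocv": float(np.mean(consensus)),
        "n_seeds": n_seeds,
    }


def gold_standard_summary() -> dict:
    """Size of the drug-augmented synthetic benchmark module's
    gold-standard network (directed and undirected edge counts)."""
    model = add_drug_reactions(ikb_nfkb_module(), default_drug_spec())
    gold = gold_standard_from_model(model)
    undirected = {frozenset(e) for e in gold.edges}
    return {
        "n_nodes": len(gold.nodes),
        "n_edges_directed": len(gold.edges),
        "n_edges_undirected": len(undirected),
    }
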