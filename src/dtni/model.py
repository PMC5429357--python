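"""Model classes: dose-time (DTNI) and time-only (TSNI) network inference.

Usage follows the fit/results idiom of statistical modelling packages::

    res = DTNI(tensor).fit(n_perm=1000, seed=42)
    res.summary()          # table of significant interactions
    net = res.network(alpha=0.05)

`DTNI` couples time-derivative and dose-derivative ODE blocks with one
shared interaction matrix; `TSNI` is the time-only special case (the
same pipeline with the dose block switched off).  Multi-compound tensors
are pooled into a single system with one shared network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data import ExpressionTensor, validate_tensor
from .inference import (LinearOdeModel, assemble_system, estimate_interactions,
                        reduce_dimension)
from .network import InferredNetwork
from .significance import permutation_test, threshold_network

__all__ = ["DTNI", "TSNI", "DTNIResults", "run_dtni", "run_tsni"]


class DTNI:
    """Dose-Time Network Identification model.

    Parameters
    ----------
    tensor : ExpressionTensor
        Log2-ratio expression over genes x times x doses x compounds x
        replicates (controls already consumed).  Needs T >= 2 times and,
        for the dose equations, D >= 3 dose levels.
    dose_equations : bool
        Include the dose-derivative block (True for DTNI; the
        :class:`TSNI` subclass fixes it to False).
    n_time_grid, n_dose_grid : int
        Interpolation grid sizes (20 time points, 10 dose points by
        default; performance saturates well below dense grids).
    smoothing : None | "gcv" | float
        Spline smoothing policy (see the smoothing module).
    dose_scale : {"log10", "linear"}
    perturbation : {"step", "transient"}
        Compound input u_c: a constant step of magnitude d, or a
        transient d*exp(-t/tau).
    k : int or "auto"
        SVD reduction dimension; "auto" uses the numerical rank.
    average_replicates : bool
        Average replicates instead of stacking them as independent rows.
    """

    include_dose_equations = True

    def __init__(self, tensor: ExpressionTensor, *, n_time_grid: int = 20,
                 n_dose_grid: int = 10, smoothing="gcv", dose_scale: str = "log10",
                 perturbation: str = "step", tau: float = 8.0, k="auto",
                 average_replicates: bool = False, dose_equations: bool | None = None):
        validate_tensor(tensor).raise_if_invalid()
        if tensor.n_times < 2:
            raise ValueError("need at least 2 time points")
        self.tensor = tensor
        self.options = dict(
            include_dose_equations=(self.include_dose_equations
                                    if dose_equations is None else dose_equations),
            n_time_grid=n_time_grid, n_dose_grid=n_dose_grid, smoothing=smoothing,
            dose_scale=dose_scale, perturbation=perturbation, tau=tau,
            average_replicates=average_replicates,
        )
        self.k = k

    def fit(self, *, n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
            permute: bool = True) -> "DTNIResults":
        """Assemble, reduce, estimate and (optionally) test significance.

        Deterministic given ``seed``; ``permute=False`` skips the
        permutation test (all p-values set to 1)."""
        system = assemble_system(self.tensor, **self.options)
        reduced = reduce_dimension(system, self.k)
        model = estimate_interactions(reduced)
        if permute:
            p_values = permutation_test(system, model, n_perm=n_perm, seed=seed)
        else:
            p_values = np.ones_like(model.A)
        run_log = dict(
            method="dtni" if self.options["include_dose_equations"] else "tsni",
            n_genes=len(system.genes), compounds=system.compounds,
            k_requested=self.k, k_used=reduced.k,
            n_rows=system.n_rows, scale_factors=system.scale_factors,
            n_perm=n_perm if permute else 0, seed=seed, alpha=alpha,
            **{
                key: val for key, val in self.options.items()
            },
        )
        return DTNIResults(model=model, p_values=p_values, alpha=alpha,
                           run_log=run_log)


class TSNI(DTNI):
    """Time-only network inference: the dose-derivative block is omitted,
    so only dx/dt equations (still dose-indexed through the perturbation
    input) constrain the interaction matrix."""

    include_dose_equations = False


@dataclass
class DTNIResults:
    """Results of a DTNI/TSNI fit.

    Attributes
    ----------
    model : LinearOdeModel
        Interaction matrix A, perturbation coefficients b and h, fitted
        values and residuals.
    p_values : ndarray (n x n)
        Residual-permutation p-values, ``p_values[i, j]`` for j -> i.
    """

    model: LinearOdeModel
    p_values: np.ndarray
    alpha: float
    run_log: dict

    @property
    def genes(self) -> list[str]:
        return self.model.genes

    @property
    def A(self) -> np.ndarray:
        return self.model.A

    def interactions(self) -> pd.DataFrame:
        """All off-diagonal interactions as a tidy frame sorted by
        p-value ascending then |strength| descending."""
        n = len(self.genes)
        rows = []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                s = float(self.A[i, j])
                rows.append((self.genes[j], self.genes[i], s,
                             "activation" if s > 0 else "inhibition",
                             float(self.p_values[i, j])))
        frame = pd.DataFrame(rows, columns=["source", "target", "strength",
                                            "sign", "p_value"])
        return frame.sort_values(
            ["p_value", "strength", "source", "target"],
            key=lambda col: -col.abs() if col.name == "strength" else col,
        ).reset_index(drop=True)

    def network(self, alpha: float | None = None, adjust: bool = False) -> InferredNetwork:
        """Significant-edge network at level alpha (default: the fit's)."""
        return threshold_network(self.model, self.p_values,
                                 self.alpha if alpha is None else alpha,
                                 adjust=adjust)

    def summary(self, alpha: float | None = None) -> str:
        alpha = self.alpha if alpha is None else alpha
        net = self.network(alpha)
        lines = [
            f"{self.run_log['method'].upper()} results",
            "=" * 46,
            f"genes: {len(self.genes)}   compounds: {len(self.model.compounds)}",
            f"regression rows: {self.run_log['n_rows']}   reduced dim k: {self.run_log['k_used']}",
            f"permutations: {self.run_log['n_perm']}   seed: {self.run_log['seed']}",
            f"significant interactions at alpha={alpha:g}: {len(net)}",
            "-" * 46,
        ]
        width = max([6] + [len(n) for n in self.genes]) + 2
        lines.append(f"{'source':<{width}}{'target':<{width}}"
                     f"{'strength':>10}  {'sign':<11}{'p':>8}")
        for e in net.sorted_edges():
            lines.append(f"{e.source:<{width}}{e.target:<{width}}"
                         f"{e.strength:>10.4f}  {e.sign:<11}{e.p_value:>8.4f}")
        return "\n".join(lines)

    def save_run_log(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)


def run_dtni(tensor: ExpressionTensor, *, n_perm: int = 1000, seed: int = 0,
             alpha: float = 0.05, **options) -> DTNIResults:
    """Functional entry point: full dose-time inference on a tensor."""
    return DTNI(tensor, **options).fit(n_perm=n_perm, seed=seed, alpha=alpha)


def run_tsni(tensor: ExpressionTensor, *, n_perm: int = 1000, seed: int = 0,
             alpha: float = 0.05, **options) -> DTNIResults:
    """Functional entry point: time-only inference on a tensor."""
    return TSNI(tensor, **options).fit(n_perm=n_perm, seed=seed, alpha=alpha)
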