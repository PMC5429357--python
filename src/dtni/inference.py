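"""Dose-time ODE regression: system assembly, dimension reduction and
interaction estimation.

The estimand is a linear ODE description of a gene regulatory network.
For ``n`` genes, the time equations state that the rate of change of gene
``i`` is a linear combination of the expression of all genes plus a
compound-specific perturbation input::

    dx_i/dt (t, d, c) = sum_j a_ij x_j(t, d, c) + b_i^c u_c(d, t)

The dose equations additionally describe how expression evolves with
(log-)dose at a fixed exposure time, assuming dependence on the
expression of the other genes and on the time of exposure::

    dx_i/d(log10 d) (t, d, c) = sum_j a_ij x_j(t, d, c) + h_i^c t

Both blocks share ONE interaction matrix A and are estimated jointly by
stacking their regression rows (the time-only system is the classic
time-series special case).  Because transcriptomics has more genes than
informative measurements, the gene-state predictor block is reduced by
SVD before estimation and the reduced-space coefficients are
back-transformed, which yields the minimum-norm least-squares solution at
full rank and a unique, identifiable estimate below it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionTensor

__all__ = [
    "RegressionSystem",
    "ReducedSystem",
    "LinearOdeModel",
    "assemble_system",
    "reduce_dimension",
    "estimate_interactions",
]

logger = logging.getLogger(__name__)

TIME_EQ = "time_eq"
DOSE_EQ = "dose_eq"


def step_input(dose: float, t: np.ndarray) -> np.ndarray:
    """Constant-in-time perturbation of magnitude equal to the dose."""
    return np.full_like(np.asarray(t, dtype=float), float(dose))


def transient_input(dose: float, t: np.ndarray, tau: float) -> np.ndarray:
    """Exponentially decaying perturbation d * exp(-t / tau)."""
    return float(dose) * np.exp(-np.asarray(t, dtype=float) / float(tau))


@dataclass
class RegressionSystem:
    """Stacked dose-time regression system.

    ``X`` has one column per gene (tensor gene order) followed by one
    perturbation-input column per compound (time equations) and, when dose
    equations are included, one exposure-time column per compound (dose
    equations).  ``Y`` holds the matching derivative responses, one column
    per target gene.  Rows are standardized per block: every row of a
    block (responses and predictors alike) is divided by the block's
    root-mean-square response and by the square root of its row count,
    so that dose-derivative rows — different units, and a row count that
    grows with the number of sampled time points — do not dominate the
    joint objective.
    """

    genes: list[str]
    compounds: list[str]
    X: np.ndarray
    Y: np.ndarray
    block_labels: np.ndarray
    course_ids: np.ndarray
    scale_factors: dict[str, float]
    has_dose_block: bool
    tensor: "ExpressionTensor | None" = None
    options: dict | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def gene_block(self) -> np.ndarray:
        return self.X[:, : self.n_genes]


@dataclass
class ReducedSystem:
    """SVD-reduced system: gene-state predictors projected onto the top-k
    right singular directions; perturbation columns pass through
    unreduced."""

    system: RegressionSystem
    k: int
    V_k: np.ndarray          # n x k right singular vectors
    design: np.ndarray       # rows x (k + n_pert)
    singular_values: np.ndarray


@dataclass
class LinearOdeModel:
    """Fitted linear ODE model: interaction matrix and perturbation
    coefficients, with fit diagnostics.

    ``A[i, j]`` is the effect of gene j on the derivative of gene i; the
    diagonal is self-degradation and is never reported as an edge.  ``b``
    (compounds x genes) are the perturbation-input coefficients of the
    time equations and ``h`` (compounds x genes) the exposure-time
    coefficients of the dose equations (all-zero when the dose block is
    absent).
    """

    genes: list[str]
    compounds: list[str]
    A: np.ndarray
    b: np.ndarray
    h: np.ndarray
    fitted_values: np.ndarray
    residuals: np.ndarray
    reduced: ReducedSystem
    coef: np.ndarray  # reduced-space coefficients, (k + n_pert) x n

    @property
    def system(self) -> RegressionSystem:
        return self.reduced.system


def _courses_time(tensor, n_grid, smoothing):
    """Yield (compound, dose, replicate, grid, values (m x n), derivs)."""
    from .smoothing import smooth_course

    for c in range(len(tensor.compounds)):
        for d in range(tensor.n_doses):
            for r in range(tensor.n_replicates):
                Y = tensor.values[:, :, d, c, r].T       # T x n
                grid, vals, ders = smooth_course(tensor.times, Y, n_grid, smoothing)
                yield c, d, r, grid, vals, ders


def _courses_dose(tensor, n_grid, scale, smoothing):
    from .smoothing import smooth_course

    for c in range(len(tensor.compounds)):
        if scale == "log10":
            x = np.log10(tensor.doses[c])
        elif scale == "linear":
            x = tensor.doses[c]
        else:
            raise ValueError(f"unknown dose scale {scale!r}")
        for t in range(tensor.n_times):
            for r in range(tensor.n_replicates):
                Y = tensor.values[:, t, :, c, r].T       # D x n
                grid, vals, ders = smooth_course(x, Y, n_grid, smoothing)
                yield c, t, r, grid, vals, ders


def assemble_system(
    tensor: ExpressionTensor,
    *,
    include_dose_equations: bool = True,
    n_time_grid: int = 20,
    n_dose_grid: int = 10,
    smoothing="gcv",
    dose_scale: str = "log10",
    perturbation: str = "step",
    tau: float = 8.0,
    average_replicates: bool = False,
) -> RegressionSystem:
    """Build the stacked dose-time regression system from a tensor.

    Replicates are stacked as independent rows by default (preserving
    degrees of freedom for the permutation test); ``average_replicates``
    collapses them first.  With ``include_dose_equations=False`` the
    output is the time-only (classic) system.
    """
    if average_replicates:
        tensor = tensor.average_replicates()
    if include_dose_equations and tensor.n_doses < 3:
        raise ValueError(
            f"dose equations need >= 3 dose levels, got {tensor.n_doses}; "
            "run with include_dose_equations=False for a time-only fit"
        )
    n = tensor.n_genes
    C = len(tensor.compounds)
    n_pert_u = C
    n_pert_t = C if include_dose_equations else 0
    p = n + n_pert_u + n_pert_t

    X_rows, Y_rows, labels, course_ids = [], [], [], []
    course = 0

    # time-equation block: one course per (compound, dose, replicate)
    for c, d, r, grid, vals, ders in _courses_time(tensor, n_time_grid, smoothing):
        m = grid.size
        X = np.zeros((m, p))
        X[:, :n] = vals
        dose = tensor.doses[c, d]
        if perturbation == "step":
            X[:, n + c] = step_input(dose, grid)
        elif perturbation == "transient":
            X[:, n + c] = transient_input(dose, grid, tau)
        else:
            raise ValueError(f"unknown perturbation {perturbation!r}")
        X_rows.append(X)
        Y_rows.append(ders)
        labels.append(np.full(m, TIME_EQ))
        course_ids.append(np.full(m, course))
        course += 1

    # dose-equation block: one course per (compound, time, replicate)
    if include_dose_equations:
        for c, t, r, grid, vals, ders in _courses_dose(tensor, n_dose_grid, dose_scale, smoothing):
            m = grid.size
            X = np.zeros((m, p))
            X[:, :n] = vals
            X[:, n + C + c] = tensor.times[t]
            X_rows.append(X)
            Y_rows.append(ders)
            labels.append(np.full(m, DOSE_EQ))
            course_ids.append(np.full(m, course))
            course += 1

    X = np.vstack(X_rows)
    Y = np.vstack(Y_rows)
    labels = np.concatenate(labels)
    course_ids = np.concatenate(course_ids)

    # per-block standardization: divide each block's rows by its RMS
    # response (units differ between d/dt and d/dlog-dose equations) and
    # by the square root of its row count, so every equation family
    # contributes equal total weight to the joint objective regardless
    # of how many rows the design expands it into
    scale_factors = {}
    for block in (TIME_EQ, DOSE_EQ) if include_dose_equations else (TIME_EQ,):
        rows = labels == block
        rms = float(np.sqrt(np.mean(Y[rows] ** 2)))
        if rms <= 1e-12 or not math.isfinite(rms):  # numerically zero block
            rms = 1.0
        scale = rms * math.sqrt(float(rows.sum()))
        if block == DOSE_EQ:
            scale /= math.sqrt(DOSE_BLOCK_WEIGHT)
        scale_factors[block] = scale
        X[rows] /= scale
        Y[rows] /= scale

    return RegressionSystem(
        genes=list(tensor.genes),
        compounds=list(tensor.compounds),
        X=X,
        Y=Y,
        block_labels=labels,
        course_ids=course_ids,
        scale_factors=scale_factors,
        has_dose_block=include_dose_equations,
        tensor=tensor,
        options=dict(
            include_dose_equations=include_dose_equations,
            n_time_grid=n_time_grid, n_dose_grid=n_dose_grid,
            smoothing=smoothing, dose_scale=dose_scale,
            perturbation=perturbation, tau=tau,
            average_replicates=False,  # tensor above is already averaged if requested
        ),
    )


AUTO_ENERGY = 0.999  # explained-variance cut for the automatic k policy

# The time equations are the generative dynamical model; the dose
# equations are an auxiliary phenomenological constraint whose
# derivatives rest on very few dose levels.  The dose block therefore
# enters the joint objective at half the total weight of the time block.
DOSE_BLOCK_WEIGHT = 0.5


def reduce_dimension(system: RegressionSystem, k="auto") -> ReducedSystem:
    """Project the gene-state predictor block onto its top-k right
    singular directions.

    ``k="auto"`` keeps the smallest k whose singular directions explain
    at least 99% of the gene-state block's variance — expression
    trajectories of co-regulated genes are strongly collinear, and
    near-null singular directions turn into huge mutually cancelling
    coefficient pairs if kept.  ``k="full"`` keeps the numerical rank,
    at which the downstream estimate coincides with the direct
    minimum-norm least-squares solution.  Integer requests above the
    rank are clamped with a warning rather than raised.
    """
    G = system.gene_block()
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    tol = s.max(initial=0.0) * max(G.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if k == "auto":
        energy = np.cumsum(s ** 2) / max(np.sum(s ** 2), np.finfo(float).tiny)
        k_eff = min(int(np.searchsorted(energy, AUTO_ENERGY) + 1), rank)
    elif k == "full":
        k_eff = rank
    else:
        k_eff = int(k)
        if k_eff < 1:
            raise ValueError("k must be >= 1")
        if k_eff > rank:
            logger.warning("requested k=%d exceeds rank %d; clamping", k_eff, rank)
            k_eff = rank
    V_k = Vt[:k_eff].T
    design = np.hstack([G @ V_k, system.X[:, system.n_genes:]])
    return ReducedSystem(system=system, k=k_eff, V_k=V_k, design=design,
                         singular_values=s)


def estimate_interactions(reduced: ReducedSystem) -> LinearOdeModel:
    """Ordinary least squares in the reduced space, one response column
    per target gene, then back-transformation of the gene coefficients to
    the full interaction matrix A.  Fitted values and residuals are
    reported for every original (unreduced) stacked row."""
    system = reduced.system
    n = system.n_genes
    C = len(system.compounds)
    if np.allclose(reduced.design, 0.0):
        logger.warning("degenerate all-zero predictors; returning zero model")
        coef = np.zeros((reduced.design.shape[1], n))
    else:
        coef, *_ = np.linalg.lstsq(reduced.design, system.Y, rcond=None)
    alpha = coef[: reduced.k]                      # k x n (columns = targets)
    A = (reduced.V_k @ alpha).T                    # n x n, rows = targets
    b = coef[reduced.k: reduced.k + C]             # C x n (compound x target)
    if system.has_dose_block:
        h = coef[reduced.k + C: reduced.k + 2 * C]  # C x n
    else:
        h = np.zeros((C, n))
    fitted = reduced.design @ coef
    residuals = system.Y - fitted
    return LinearOdeModel(
        genes=list(system.genes),
        compounds=list(system.compounds),
        A=A,
        b=np.asarray(b),
        h=np.asarray(h),
        fitted_values=fitted,
        residuals=residuals,
        reduced=reduced,
        coef=coef,
    )
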