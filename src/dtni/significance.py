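"""Permutation-of-residuals significance testing and LOOCV consensus.

Measurements over time and dose are mutually dependent, so classical
permutation of the raw data is invalid.  Residuals around a signal
estimate, however, are (approximately) exchangeable.  The test works at
the *data* level:

1. estimate the systematic signal.  With replicates (the usual case)
   the replicate mean is a model-free signal estimate whose residuals
   are pure measurement noise at any design density; without replicates
   the signal is reconstructed from the fitted ODE model (matrix
   exponential of the estimated system, amplitude-calibrated);
2. form pseudo-data: transplant whole residual tuples between sample
   cells (time, dose, compound), shuffling replicate labels within each
   tuple, plus — in the replicate scheme — an independent Gaussian
   top-up at variance sigma^2/R, because the replicate mean absorbs 1/R
   of the noise variance and the null spread must match the sampling
   spread;
3. re-run the entire inference pipeline — interpolation, system
   assembly, dimension reduction (at the fitted k), estimation — on
   each pseudo-dataset.

Re-running the whole pipeline matters: the regression's predictors are
themselves built from the noisy data, so a test that permutes only the
derivative-level residuals while holding the predictors fixed badly
understates the null variability of the coefficients.

Because the pseudo-data retain the signal estimate, the re-estimated
coefficients a*_ij fluctuate around a stable centre; their deviations
from that centre are draws from the coefficient's null distribution
(the centring standard in residual-permutation tests of regression
coefficients, estimated here as the permutation mean).  The p-value of
interaction (j -> i) is the add-one-corrected fraction of permutations
with |a*_ij - mean(a*_ij)| >= |a_ij|.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import ExpressionTensor
from .inference import (LinearOdeModel, RegressionSystem, assemble_system,
                        estimate_interactions, reduce_dimension)
from .network import Edge, InferredNetwork

__all__ = ["permutation_test", "threshold_network", "loocv_consensus", "bh_adjust"]

logger = logging.getLogger(__name__)


STABILITY_MARGIN = 0.01  # per hour; fitted A is shifted to at least this decay


def reconstruct_data(system: RegressionSystem, model: LinearOdeModel) -> np.ndarray:
    """Expression data implied by the fitted ODE model.

    Integrates dx/dt = A x + b_c u_c(d) from x(0) = 0 for every dose and
    compound (matrix exponential, exact for the constant-input case) and
    reads the solution off at the sample times.  The reconstruction must
    come from the global ODE structure, not from course-specific fitted
    curves: a course-wise reconstruction would track each course's own
    noise and leave residuals too small for a calibrated test.

    Two safeguards keep the reconstruction honest:

    * a least-squares A can be (spuriously) unstable; if its spectral
      abscissa exceeds -STABILITY_MARGIN, the diagonal is shifted so all
      modes decay — the reconstruction is a signal estimate, and growing
      modes would let it diverge from data it is supposed to summarize;
    * the reconstruction is amplitude-calibrated per gene (least-squares
      projection coefficient of the data on the reconstruction, clipped
      to [0, 1]) — a least-squares estimate of A need not be a good
      simulator, and when the model carries no signal the calibration
      shrinks the reconstruction toward zero, making the pseudo-data
      plain permuted data.

    Returns an array shaped like ``tensor.values`` (n, T, D, C, R).
    """
    from .simulate import _solve_constant_input, _solve_transient_input

    tensor = system.tensor
    opts = system.options or {}
    perturbation = opts.get("perturbation", "step")
    tau = opts.get("tau", 8.0)
    n, T, D, C, R = tensor.values.shape

    A = model.A
    abscissa = float(np.max(np.linalg.eigvals(A).real))
    if abscissa > -STABILITY_MARGIN:
        A = A - (abscissa + STABILITY_MARGIN) * np.eye(n)

    out = np.empty((n, T, D, C))
    for c in range(C):
        for d in range(D):
            forcing = model.b[c] * tensor.doses[c, d]
            if perturbation == "step":
                x = _solve_constant_input(A, forcing, tensor.times)
            elif perturbation == "transient":
                x = _solve_transient_input(A, forcing, tau, tensor.times)
            else:
                raise ValueError(f"unknown perturbation {perturbation!r}")
            out[:, :, d, c] = x.T

    obs = tensor.values.reshape(n, -1)
    rec = np.repeat(out[..., None], R, axis=-1).reshape(n, -1)
    denom = np.einsum("ij,ij->i", rec, rec)
    beta = np.where(denom > 0,
                    np.einsum("ij,ij->i", obs, rec) / np.maximum(denom, 1e-300),
                    0.0)
    beta = np.clip(beta, 0.0, 1.0)
    out = out * beta[:, None, None, None]
    return np.repeat(out[..., None], R, axis=-1)


def permutation_test(
    system: RegressionSystem,
    model: LinearOdeModel,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Data-level residual-permutation p-values for every entry of A.

    Parameters
    ----------
    system : RegressionSystem
        The system the model was fitted on (carries the tensor and the
        assembly options used, so each permutation can re-run the exact
        same pipeline).
    model : LinearOdeModel
        The fitted model.
    n_perm : int
        Number of permutations; the smallest attainable p-value is
        ``1 / (n_perm + 1)``.
    seed : int
        Master seed; the test is fully deterministic given it.

    Returns
    -------
    ndarray, shape (n, n)
        ``p[i, j]`` for interaction j -> i, each in ``[1/(n_perm+1), 1]``.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if system.tensor is None or system.options is None:
        raise ValueError("system does not carry its tensor/options; "
                         "assemble it with assemble_system")
    tensor = system.tensor
    opts = dict(system.options)

    # Signal estimate whose residuals are exchangeable noise.  With
    # replicates the replicate mean is a model-free signal estimate and
    # its residuals are pure measurement noise at any design density;
    # without replicates fall back to the fitted-ODE reconstruction.
    n, T, D, C, R = tensor.values.shape
    rng = np.random.default_rng(seed)
    a_obs = np.abs(model.A)
    k = model.reduced.k
    draws = np.empty((n_perm,) + model.A.shape)

    # Signal estimate and noise model.  The residual resampling must put
    # back the noise variance the signal estimate absorbed, so that the
    # null spread of the re-estimated coefficients matches their
    # sampling spread: the absorbed fraction is 1/R for the replicate
    # mean and df/T for a smoother with df effective degrees of freedom.
    if R >= 2:
        signal = np.repeat(tensor.values.mean(axis=4, keepdims=True), R, axis=4)
        dev = tensor.values - signal
        var_g = R / (R - 1.0) * np.mean(dev.reshape(n, -1) ** 2, axis=1)
        topup_var = var_g / R
    elif T >= 5:
        signal, absorbed = _smoothed_signal(tensor)
        dev = tensor.values - signal
        denom = max(1.0 - absorbed, 0.1)
        var_g = np.mean(dev.reshape(n, -1) ** 2, axis=1) / denom
        topup_var = var_g * absorbed
    else:
        # too few points for a noise estimate from smoothing: fall back
        # to residuals about the fitted-ODE reconstruction
        signal = reconstruct_data(system, model)
        dev = tensor.values - signal
        var_g = np.zeros(n)
        topup_var = var_g

    topup_sd = np.sqrt(topup_var)[:, None, None, None, None]
    tuples = dev.reshape(n, -1, R)
    n_cells = tuples.shape[1]
    for b in range(n_perm):
        # transplant whole residual tuples between sample cells,
        # shuffling replicate labels within each tuple, plus the
        # independent Gaussian top-up
        perm = rng.permutation(n_cells)
        colperm = rng.permuted(np.tile(np.arange(R), (n_cells, 1)), axis=1)
        dev_star = tuples[:, perm][:, np.arange(n_cells)[:, None], colperm]
        pseudo_values = signal + dev_star.reshape(tensor.values.shape)
        if np.any(topup_var > 0):
            pseudo_values = pseudo_values + rng.normal(
                size=tensor.values.shape) * topup_sd
        draws[b] = _refit(tensor, pseudo_values, opts, k)

    center = draws.mean(axis=0)
    counts = np.sum(np.abs(draws - center) >= a_obs, axis=0)
    return (1.0 + counts) / (n_perm + 1.0)


def _smoothed_signal(tensor: ExpressionTensor) -> tuple[np.ndarray, float]:
    """Signal estimate for unreplicated data: GCV smoothing spline along
    every time course, evaluated at the sample points.  Returns the
    signal array and the average absorbed noise fraction (smoother
    degrees of freedom over points per course)."""
    from .smoothing import LAMBDA_GRID, _sample_smoother, select_lambda

    n, T, D, C, R = tensor.values.shape
    x = tuple(tensor.times)
    stacked = tensor.values.transpose(1, 0, 2, 3, 4).reshape(T, -1)
    lam = select_lambda(np.asarray(x), stacked)
    if lam is None:
        raise ValueError("time course too short to smooth")
    S, df = _sample_smoother(x, lam)
    signal = np.einsum("ut,gtdcr->gudcr", S, tensor.values)
    return signal, df / T


def _refit(tensor: ExpressionTensor, pseudo_values: np.ndarray, opts: dict,
           k: int) -> np.ndarray:
    """Re-run the full pipeline (assembly, reduction, estimation) on a
    pseudo-dataset and return the re-estimated interaction matrix."""
    pseudo = ExpressionTensor(list(tensor.genes), tensor.times.copy(),
                              tensor.doses.copy(), list(tensor.compounds),
                              pseudo_values)
    sys_star = assemble_system(pseudo, **opts)
    red_star = reduce_dimension(sys_star, k)
    return estimate_interactions(red_star).A


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment of a flat array of p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def threshold_network(
    model: LinearOdeModel,
    p_values: np.ndarray,
    alpha: float = 0.05,
    adjust: bool = False,
) -> InferredNetwork:
    """Keep off-diagonal interactions with p <= alpha as network edges.

    The diagonal of A is self-degradation, never an edge.  ``adjust``
    applies Benjamini-Hochberg across the off-diagonal p-values first
    (the default thresholds raw permutation p-values).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    n = len(model.genes)
    p = np.asarray(p_values, dtype=float).copy()
    off = ~np.eye(n, dtype=bool)
    if adjust:
        p[off] = bh_adjust(p[off])
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and p[i, j] <= alpha:
                edges.append(Edge(model.genes[j], model.genes[i],
                                  float(model.A[i, j]), float(p[i, j])))
    return InferredNetwork(list(model.genes), edges)


def loocv_consensus(tensor, *, alpha: float = 0.05, n_perm: int = 1000,
                    seed: int = 0, method: str = "dtni", **options) -> InferredNetwork:
    """Leave-one-compound-out consensus network.

    The method runs on the full multi-compound tensor and on each of the
    C reduced tensors obtained by leaving one compound out; an edge is
    retained only if it is significant (p <= alpha) in the full run AND
    in every reduced run.  Strengths and p-values of the consensus edges
    are those of the full run, so the consensus is always a subset of the
    full-run network.
    """
    from .model import DTNI, TSNI

    if len(tensor.compounds) < 2:
        raise ValueError("LOOCV needs at least 2 compounds")
    cls = {"dtni": DTNI, "tsni": TSNI}[method]
    full = cls(tensor, **options).fit(n_perm=n_perm, seed=seed, alpha=alpha)
    keep = full.network(alpha).edge_set()
    for compound in tensor.compounds:
        reduced = cls(tensor.drop_compound(compound), **options).fit(
            n_perm=n_perm, seed=seed, alpha=alpha)
        keep &= reduced.network(alpha).edge_set()
    full_net = full.network(alpha)
    edges = [e for e in full_net.edges if (e.source, e.target) in keep]
    return InferredNetwork(full_net.nodes, edges)
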