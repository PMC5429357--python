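"""Core data containers and expression-table IO.

The central container is :class:`ExpressionTensor`: log2-ratio expression
values laid out on a complete (gene, time, dose, compound, replicate) grid.
Dose 0 samples are controls; they are consumed when log2 ratios are formed
and never appear inside a tensor.

Expression tables on disk are genes x samples TSV files whose column
headers encode the sample key as ``<compound>|<dose>|<time>|<replicate>``
(doses in the file's native units, times in hours).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleKey",
    "ExpressionTensor",
    "ValidationReport",
    "compute_log2_ratios",
    "validate_tensor",
    "read_expression_table",
    "write_expression_table",
]


class PairingError(ValueError):
    """A treated sample has no matching time/replicate control."""


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one array/sample: compound, dose, time and replicate.

    ``dose == 0`` marks a time-matched control.
    """

    compound: str
    dose: float
    time: float
    replicate: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.time <= 0:
            raise ValueError(f"time must be > 0 hours, got {self.time}")
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")

    @property
    def is_control(self) -> bool:
        return self.dose == 0

    def to_header(self) -> str:
        return f"{self.compound}|{self.dose:g}|{self.time:g}|{self.replicate}"

    @classmethod
    def from_header(cls, column: str) -> "SampleKey":
        parts = column.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"malformed sample column {column!r}: expected "
                "'compound|dose|time|replicate'"
            )
        compound, dose, time, rep = parts
        try:
            return cls(compound, float(dose), float(time), int(rep))
        except ValueError as exc:
            raise ValueError(f"malformed sample column {column!r}: {exc}") from exc


@dataclass
class ExpressionTensor:
    """Log2-ratio expression on a complete gene x time x dose x compound x
    replicate grid.

    Attributes
    ----------
    genes : list of str
        Unique gene identifiers, in fixed order (length ``n``).
    times : ndarray, shape (T,)
        Strictly increasing exposure times in hours.
    doses : ndarray, shape (C, D)
        Per-compound strictly increasing positive doses.  Dose levels are
        aligned by rank (low/mid/high), not by value, so each compound may
        use its own concentration scale.
    compounds : list of str
    values : ndarray, shape (n, T, D, C, R)
        Log2 ratios treated/control.
    """

    genes: list[str]
    times: np.ndarray
    doses: np.ndarray
    compounds: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.doses = np.atleast_2d(np.asarray(self.doses, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        n, T, D, C, R = self.expected_shape()
        if self.values.shape != (n, T, D, C, R):
            raise ValueError(
                f"values shape {self.values.shape} does not match coordinates "
                f"{(n, T, D, C, R)}"
            )
        if len(set(self.genes)) != n:
            raise ValueError("gene identifiers must be unique")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.doses <= 0):
            raise ValueError("tensor doses must be strictly positive (controls are consumed upstream)")
        if np.any(np.diff(self.doses, axis=1) <= 0):
            raise ValueError("doses must be strictly increasing per compound")

    def expected_shape(self) -> tuple[int, int, int, int, int]:
        n = len(self.genes)
        T = self.times.shape[0]
        C, D = self.doses.shape
        if len(self.compounds) != C:
            raise ValueError("doses rows must match number of compounds")
        R = self.values.shape[-1] if self.values.ndim == 5 else 1
        return n, T, D, C, R

    # -- basic structural properties -------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_doses(self) -> int:
        return self.doses.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[4]

    # -- derived tensors --------------------------------------------------
    def drop_compound(self, compound: str) -> "ExpressionTensor":
        """Return the tensor with one compound removed (for leave-one-out)."""
        if compound not in self.compounds:
            raise KeyError(compound)
        keep = [i for i, c in enumerate(self.compounds) if c != compound]
        if not keep:
            raise ValueError("cannot drop the only compound")
        return ExpressionTensor(
            genes=list(self.genes),
            times=self.times.copy(),
            doses=self.doses[keep],
            compounds=[self.compounds[i] for i in keep],
            values=self.values[:, :, :, keep, :].copy(),
        )

    def average_replicates(self) -> "ExpressionTensor":
        return ExpressionTensor(
            genes=list(self.genes),
            times=self.times.copy(),
            doses=self.doses.copy(),
            compounds=list(self.compounds),
            values=self.values.mean(axis=4, keepdims=True),
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionTensor":
        idx = [self.genes.index(g) for g in genes]
        return ExpressionTensor(
            genes=list(genes),
            times=self.times.copy(),
            doses=self.doses.copy(),
            compounds=list(self.compounds),
            values=self.values[idx].copy(),
        )


@dataclass
class ValidationReport:
    """Report-only outcome of :func:`validate_tensor`."""

    duplicate_keys: list[tuple] = field(default_factory=list)
    missing_cells: list[tuple] = field(default_factory=list)
    nonfinite_cells: list[tuple] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.duplicate_keys or self.missing_cells or self.nonfinite_cells)

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise ValueError(f"invalid expression tensor: {self}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = []
        if self.duplicate_keys:
            parts.append(f"{len(self.duplicate_keys)} duplicate keys")
        if self.missing_cells:
            parts.append(f"{len(self.missing_cells)} missing cells")
        if self.nonfinite_cells:
            parts.append(f"{len(self.nonfinite_cells)} non-finite values")
        return "; ".join(parts) or "ok"


def validate_tensor(tensor: ExpressionTensor) -> ValidationReport:
    """Check a tensor for non-finite values.

    Duplicates and missing cells cannot survive tensor construction (the
    dense array forces a complete grid), so on an ``ExpressionTensor`` only
    the finiteness check can fire; the sample-level checks run in
    :func:`_tensor_from_samples` during file reading, which routes its
    findings through the same report type.
    """
    report = ValidationReport()
    bad = np.argwhere(~np.isfinite(tensor.values))
    for g, t, d, c, r in bad:
        report.nonfinite_cells.append(
            (tensor.genes[g], tensor.times[t], tensor.doses[c, d], tensor.compounds[c], r + 1)
        )
    return report


# ---------------------------------------------------------------------------
# log2 ratio formation
# ---------------------------------------------------------------------------

def compute_log2_ratios(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    pairing: Mapping[int, int] | None = None,
) -> ExpressionTensor:
    """Form log2(treated/control) ratios with replicate pairing.

    Parameters
    ----------
    treated, control : DataFrame
        Genes x samples intensity tables (strictly positive), columns
        encoded as ``compound|dose|time|replicate``; control columns carry
        dose 0.
    pairing : mapping, optional
        Treated-replicate -> control-replicate map.  Default: identity
        (replicate 1 pairs with control replicate 1, etc.).  Replicates are
        never cross-paired or averaged.
    """
    pairing = dict(pairing or {})
    if (treated.values <= 0).any() or (control.values <= 0).any():
        raise ValueError("intensities must be strictly positive to form log2 ratios")
    if list(treated.index) != list(control.index):
        raise ValueError("treated and control tables must share the same gene index")

    controls: dict[tuple[str, float, int], pd.Series] = {}
    for col in control.columns:
        key = SampleKey.from_header(str(col))
        if not key.is_control:
            raise ValueError(f"control table contains non-control column {col!r}")
        controls[(key.compound, key.time, key.replicate)] = control[col]

    records: dict[SampleKey, np.ndarray] = {}
    for col in treated.columns:
        key = SampleKey.from_header(str(col))
        if key.is_control:
            raise ValueError(f"treated table contains a dose-0 column {col!r}")
        ctrl_rep = pairing.get(key.replicate, key.replicate)
        ctrl = controls.get((key.compound, key.time, ctrl_rep))
        if ctrl is None:
            raise PairingError(
                f"treated sample {col!r} has no control at time {key.time:g} h, "
                f"replicate {ctrl_rep}"
            )
        if key in records:
            raise ValueError(f"duplicate treated sample {col!r}")
        records[key] = np.log2(treated[col].to_numpy() / ctrl.to_numpy())

    return _tensor_from_samples(list(treated.index), list(records.items()))


def _tensor_from_samples(
    genes: Sequence[str],
    records: Iterable[tuple[SampleKey, np.ndarray]] | Mapping[SampleKey, np.ndarray],
) -> ExpressionTensor:
    """Assemble a dense tensor from per-sample vectors; missing grid cells
    or duplicate keys are hard errors (the inference math assumes a
    complete grid and no imputation is performed)."""
    if isinstance(records, Mapping):
        records = list(records.items())
    else:
        records = list(records)
    keys = [k for k, _ in records]
    compounds = sorted({k.compound for k in keys})
    times = np.array(sorted({k.time for k in keys}))
    report = ValidationReport()

    dose_levels: dict[str, np.ndarray] = {}
    for c in compounds:
        dose_levels[c] = np.array(sorted({k.dose for k in keys if k.compound == c}))
    D = {len(v) for v in dose_levels.values()}
    if len(D) != 1:
        raise ValueError(f"compounds have unequal dose-level counts: { {c: len(v) for c, v in dose_levels.items()} }")
    D = D.pop()
    reps = sorted({k.replicate for k in keys})
    if reps != list(range(1, len(reps) + 1)):
        raise ValueError(f"replicate indices must be 1..R, got {reps}")
    R = len(reps)

    n = len(genes)
    values = np.full((n, len(times), D, len(compounds), R), np.nan)
    seen: set[SampleKey] = set()
    for key, vec in records:
        if key in seen:
            report.duplicate_keys.append(key)
            continue
        seen.add(key)
        t = int(np.searchsorted(times, key.time))
        d = int(np.searchsorted(dose_levels[key.compound], key.dose))
        c = compounds.index(key.compound)
        values[:, t, d, c, key.replicate - 1] = vec

    missing = np.argwhere(np.all(np.isnan(values), axis=0))
    for t, d, c, r in missing:
        report.missing_cells.append(
            (times[t], dose_levels[compounds[c]][d], compounds[c], r + 1)
        )
    report.raise_if_invalid()

    doses = np.stack([dose_levels[c] for c in compounds])
    return ExpressionTensor(list(genes), times, doses, compounds, values)


# ---------------------------------------------------------------------------
# expression table IO
# ---------------------------------------------------------------------------

def write_expression_table(tensor: ExpressionTensor, path) -> None:
    """Write a tensor as a genes x samples TSV with encoded sample headers."""
    cols: dict[str, np.ndarray] = {}
    for c, compound in enumerate(tensor.compounds):
        for d in range(tensor.n_doses):
            for t in range(tensor.n_times):
                for r in range(tensor.n_replicates):
                    key = SampleKey(compound, tensor.doses[c, d], tensor.times[t], r + 1)
                    cols[key.to_header()] = tensor.values[:, t, d, c, r]
    frame = pd.DataFrame(cols, index=pd.Index(tensor.genes, name="gene"))
    frame.to_csv(path, sep="\t")


def read_expression_table(path) -> ExpressionTensor:
    """Read a genes x samples TSV into an :class:`ExpressionTensor`.

    Raises a parse error naming the offending column on malformed headers;
    missing grid cells and duplicate keys are hard errors.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    records = []
    for i, col in enumerate(frame.columns):
        key = SampleKey.from_header(str(col))
        records.append((key, frame.iloc[:, i].to_numpy(dtype=float)))
    tensor = _tensor_from_samples(list(frame.index.astype(str)), records)
    validate_tensor(tensor).raise_if_invalid()
    return tensor
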