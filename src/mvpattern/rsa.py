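"""Representational similarity analysis across (condition, run) items.

The neural RSM holds Pearson correlations between every pair of per-run
condition patterns. Binary model RSMs encode a similarity hypothesis (the
self condition resembles one partner condition) over the subset of
conditions relevant to that hypothesis; all other conditions are dropped
from the item set so that their similarities cannot influence the fit.

A validity mask excludes, for every model:

* the diagonal,
* every pair of items from the same run (within-run similarities are
  inflated by run-shared physiological noise),
* every pair of items of the same condition (same-condition similarities
  reflect reliability, not the hypothesis).

Fit between neural and model RSM is Kendall's tau-a, the rank correlation
with the all-pairs denominator, which is the appropriate statistic when the
model contains ties (a binary model is almost all ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PatternDataset
from .patterns import ROIMask, extract_roi

#: Conditions entering each model, in item order. The first entry is the
#: self condition, the second its hypothesized partner.
MODEL_CONDITIONS = {
    "self_other": ("self", "other", "semantic"),
    "self_introspection": ("self", "introspection", "semantic", "categorization"),
    "self_memory": ("self", "memory", "semantic", "knowledge"),
}


@dataclass
class NeuralRSM:
    items: tuple[tuple[str, int], ...]  # (condition, run)
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.items)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (n, n):
            raise ValueError("RSM shape does not match item count")

    def submatrix(self, items) -> np.ndarray:
        """Reorder/select the correlation matrix for the given items."""
        pos = {it: i for i, it in enumerate(self.items)}
        try:
            idx = [pos[it] for it in items]
        except KeyError as e:
            raise KeyError(f"item {e.args[0]} not in neural RSM") from None
        return self.values[np.ix_(idx, idx)]


@dataclass
class ModelRSM:
    items: tuple[tuple[str, int], ...]
    model_values: np.ndarray  # binary: 1 similar, 0 dissimilar
    valid: np.ndarray  # binary: cells entering the fit
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.items)
        for mat in (self.model_values, self.valid):
            if mat.shape != (n, n):
                raise ValueError("model RSM shape does not match item count")
        if not np.array_equal(self.model_values, self.model_values.T):
            raise ValueError("model_values must be symmetric")
        if not np.array_equal(self.valid, self.valid.T):
            raise ValueError("valid mask must be symmetric")

    @property
    def n_valid_cells(self) -> int:
        """Number of unordered valid cells (upper triangle)."""
        return int(np.triu(self.valid, k=1).sum())


def default_items(condition_labels, n_runs: int) -> tuple[tuple[str, int], ...]:
    """Item ordering: conditions in declared order, runs ascending within."""
    return tuple((c, r) for c in condition_labels for r in range(n_runs))


def build_neural_rsm(
    dataset: PatternDataset,
    items=None,
    roi: ROIMask | None = None,
) -> NeuralRSM:
    """Pearson-correlation RSM over (condition, run) item patterns."""
    if roi is not None:
        dataset = extract_roi(dataset, roi)
    if items is None:
        items = default_items(dataset.conditions, len(dataset.runs))
    items = tuple((c, r) for c, r in items)
    mat = np.stack([dataset.get(r, c) for c, r in items])
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 voxels to correlate patterns")
    sds = mat.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = [items[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance pattern(s) for items {bad}")
    return NeuralRSM(items=items, values=np.corrcoef(mat))


def build_model_rsm(
    model: str,
    n_runs: int,
    condition_labels=None,
) -> ModelRSM:
    """Binary model RSM plus validity mask for one similarity hypothesis.

    ``condition_labels``, if given, maps the canonical roles to this
    dataset's labels in the order of ``MODEL_CONDITIONS[model]``.
    """
    if model not in MODEL_CONDITIONS:
        raise KeyError(
            f"unknown model {model!r}; available: {sorted(MODEL_CONDITIONS)}"
        )
    canonical = MODEL_CONDITIONS[model]
    labels = tuple(condition_labels) if condition_labels else canonical
    if len(labels) != len(canonical):
        raise ValueError(
            f"model {model!r} needs {len(canonical)} condition labels, got {len(labels)}"
        )
    self_label, partner_label = labels[0], labels[1]
    items = default_items(labels, n_runs)
    n = len(items)
    conds = np.array([c for c, _ in items])
    runs = np.array([r for _, r in items])
    same_run = runs[:, None] == runs[None, :]
    same_cond = conds[:, None] == conds[None, :]
    valid = ~same_run & ~same_cond
    np.fill_diagonal(valid, False)
    pair = (conds[:, None] == self_label) & (conds[None, :] == partner_label)
    model_values = ((pair | pair.T) & valid).astype(int)
    return ModelRSM(
        items=items, model_values=model_values, valid=valid.astype(int), name=model
    )


def _valid_cell_values(neural: NeuralRSM, model: ModelRSM):
    sub = neural.submatrix(model.items)
    iu, ju = np.triu_indices(len(model.items), k=1)
    keep = model.valid[iu, ju] > 0
    return sub[iu[keep], ju[keep]], model.model_values[iu[keep], ju[keep]]


def kendall_tau_a(neural: NeuralRSM, model: ModelRSM) -> float:
    """Kendall's tau-a between neural and model values on the valid cells.

    tau_a = (concordant - discordant) / (n(n-1)/2) over all unordered pairs
    of valid cells; tied pairs add nothing to the numerator but keep full
    weight in the denominator. Computed by explicit pair enumeration (valid
    cell counts are at most a few hundred).
    """
    x, y = _valid_cell_values(neural, model)
    n = len(x)
    if n < 2:
        raise ValueError(f"need >= 2 valid cells for tau-a, got {n}")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    num = float(np.sum(sx[iu] * sy[iu]))
    return num / (n * (n - 1) / 2)
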