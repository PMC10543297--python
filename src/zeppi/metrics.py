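"""Interfacial coevolution and conservation metrics.

For a pair of paired-MSA columns (a, b) — one from each protein — three
base measures are computed over the 21-state alphabet (20 amino acids +
gap as the 21st state), all in nats:

* mutual information  MI(a,b) = sum_xy p(x,y) ln p(x,y) / (p(x) p(y))
* conservation        Con(a,b) = 1 - S(a,b) / (2 ln 21), S = joint entropy
* direct information  DI(a,b) from the mean-field DCA model (see `dca`)

The average product correction removes the rank-one background of a
metric matrix M over the interface positions of both proteins:
APC(a,b) = <M(a,.)> <M(.,b)> / <M(.,.)>, corrected value M - APC.

A candidate interface is summarised by twelve numbers: for each base
metric, the mean and the maximum ("top") over its contacts, in raw and
APC-corrected form.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import N_STATES
from .errors import UnscoreableModelError
from .dca import fit_mean_field_dca, DcaModel
from .msa import PairedMSA

LN21 = np.log(N_STATES)

METRIC_KEYS = [
    f"{m}_{agg}_{form}"
    for m in ("mi", "con", "dca")
    for agg in ("mean", "top")
    for form in ("raw", "apc")
]


@dataclass
class ColumnPairStats:
    """Empirical 21-state marginals and joint of two columns."""

    p_x: np.ndarray
    p_y: np.ndarray
    p_xy: np.ndarray
    n_effective: int


def column_pair_stats(
    paired_msa: PairedMSA, pos_a: int, pos_b: int
) -> ColumnPairStats:
    """Unweighted frequency counts of a column pair (gap = state 21)."""
    m = paired_msa.matrix
    xa = m[:, pos_a].astype(np.intp)
    xb = m[:, pos_b].astype(np.intp)
    n = len(xa)
    joint = np.bincount(
        xa * N_STATES + xb, minlength=N_STATES * N_STATES
    ).reshape(N_STATES, N_STATES) / n
    return ColumnPairStats(
        p_x=joint.sum(axis=1),
        p_y=joint.sum(axis=0),
        p_xy=joint,
        n_effective=n,
    )


def _mi_from_joint(joint: np.ndarray) -> float:
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / denom[nz])))


def _joint_entropy(joint: np.ndarray) -> float:
    nz = joint > 0
    return float(-np.sum(joint[nz] * np.log(joint[nz])))


def mutual_information(stats: ColumnPairStats) -> float:
    """MI in nats; zero-probability cells contribute 0; MI >= 0."""
    return _mi_from_joint(stats.p_xy)


def conservation(stats: ColumnPairStats) -> float:
    """1 - joint entropy normalised by its 21x21 maximum (2 ln 21)."""
    return 1.0 - _joint_entropy(stats.p_xy) / (2.0 * LN21)


def apc_correct(metric_matrix: np.ndarray) -> np.ndarray:
    """Subtract the average-product background from a metric matrix.

    The averages run over the interfacial positions of both proteins
    (the matrix axes). NaN entries (e.g. non-convergent DI pairs) are
    ignored in the averages and stay NaN in the output. A zero grand
    mean makes the correction vanish.
    """
    m = np.asarray(metric_matrix, dtype=float)
    grand = np.nanmean(m)
    if not np.isfinite(grand) or grand == 0.0:
        return m.copy()
    row = np.nanmean(m, axis=1, keepdims=True)  # <m(a, .)>
    col = np.nanmean(m, axis=0, keepdims=True)  # <m(., b)>
    return m - row * col / grand


def mi_con_matrices(
    paired_msa: PairedMSA, cols1: list[int], cols2: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """MI and Con for every column pair in cols1 x cols2."""
    m = paired_msa.matrix
    n = m.shape[0]
    a = m[:, cols1].astype(np.intp)
    b = m[:, cols2].astype(np.intp)
    mi = np.empty((len(cols1), len(cols2)))
    con = np.empty_like(mi)
    for i in range(len(cols1)):
        base = a[:, i] * N_STATES
        for j in range(len(cols2)):
            joint = np.bincount(
                base + b[:, j], minlength=N_STATES * N_STATES
            ).reshape(N_STATES, N_STATES) / n
            mi[i, j] = _mi_from_joint(joint)
            con[i, j] = 1.0 - _joint_entropy(joint) / (2.0 * LN21)
    return mi, con


@dataclass
class MetricPanel:
    """The twelve-metric summary of one candidate interface.

    ``values`` maps each of the 12 keys (``{mi,con,dca}_{mean,top}_{raw,apc}``)
    to a float, or ``None`` when DCA is disabled. ``per_contact`` keeps
    the per-contact vectors for diagnostics.
    """

    values: dict[str, float | None]
    per_contact: dict[str, np.ndarray] = field(default_factory=dict)
    n_contacts: int = 0
    degenerate: bool = False

    def to_row(self, model_id: str = "") -> pd.DataFrame:
        row = {"model_id": model_id}
        row.update(self.values)
        return pd.DataFrame([row])


def _aggregate(vec: np.ndarray) -> tuple[float, float]:
    vals = vec[np.isfinite(vec)]
    if len(vals) == 0:
        return float("nan"), float("nan")
    return float(vals.mean()), float(vals.max())


def metric_panel(
    paired_msa: PairedMSA,
    contact_cols: list[tuple[int, int]],
    iface1_cols: list[int] | None = None,
    iface2_cols: list[int] | None = None,
    use_dca: bool = False,
    dca_lambda: float = 0.5,
    dca_model: DcaModel | None = None,
) -> MetricPanel:
    """Compute the 12-metric panel for one set of interface contacts.

    ``contact_cols`` are paired-MSA column index pairs (protein-1 column,
    protein-2 column) of the scored contacts; the APC background is
    estimated over the full iface1 x iface2 matrix. DCA entries are None
    unless ``use_dca``.
    """
    if not contact_cols:
        raise UnscoreableModelError("unscoreable model: zero scoreable contacts")
    if iface1_cols is None:
        iface1_cols = sorted({a for a, _ in contact_cols})
    if iface2_cols is None:
        iface2_cols = sorted({b for _, b in contact_cols})
    i1 = {c: i for i, c in enumerate(iface1_cols)}
    i2 = {c: i for i, c in enumerate(iface2_cols)}
    rows = np.array([i1[a] for a, _ in contact_cols])
    cols = np.array([i2[b] for _, b in contact_cols])

    mi, con = mi_con_matrices(paired_msa, iface1_cols, iface2_cols)
    matrices: dict[str, np.ndarray | None] = {
        "mi_raw": mi,
        "mi_apc": apc_correct(mi),
        "con_raw": con,
        "con_apc": apc_correct(con),
        "dca_raw": None,
        "dca_apc": None,
    }
    if use_dca:
        model = dca_model or fit_mean_field_dca(
            paired_msa.matrix, iface1_cols + iface2_cols, lam=dca_lambda
        )
        di = model.di_matrix(iface1_cols, iface2_cols)
        matrices["dca_raw"] = di
        matrices["dca_apc"] = apc_correct(di)

    values: dict[str, float | None] = {}
    per_contact: dict[str, np.ndarray] = {}
    for m in ("mi", "con", "dca"):
        for form in ("raw", "apc"):
            mat = matrices[f"{m}_{form}"]
            if mat is None:
                values[f"{m}_mean_{form}"] = None
                values[f"{m}_top_{form}"] = None
                continue
            vec = mat[rows, cols]
            per_contact[f"{m}_{form}"] = vec
            mean, top = _aggregate(vec)
            values[f"{m}_mean_{form}"] = mean
            values[f"{m}_top_{form}"] = top

    return MetricPanel(
        values=values,
        per_contact=per_contact,
        n_contacts=len(contact_cols),
        degenerate=(len(iface1_cols) == 1 and len(iface2_cols) == 1),
    )
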