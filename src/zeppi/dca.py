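"""Mean-field direct coupling analysis over a small set of columns.

A maximum-entropy (Potts) model with pairwise couplings is approximated
by inverting the pseudocounted connected-correlation matrix of the
selected columns (mean-field/naive approximation). The gap is the 21st
state and serves as the reference state, so the inversion runs in the
20-dimensional reduced representation per position. Direct information
between two positions is the KL divergence between the two-site "direct"
distribution — couplings e_ij plus single-site fields fitted so its
marginals reproduce the pseudocounted frequencies — and the product of
those marginals.

Only interface plus sampled surface columns are ever fitted, keeping the
inversion small regardless of protein length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import N_STATES
from .errors import DegenerateInputError

_REDUCED = N_STATES - 1  # gap is the reference state


@dataclass
class DcaModel:
    """Fitted couplings and frequencies for a set of columns."""

    positions: list[int]
    couplings: np.ndarray  # (P, P, 21, 21); zero-padded gap row/col
    freqs: np.ndarray      # (P, 21) pseudocounted single-site marginals
    lam: float
    mu_tol: float = 1e-4
    mu_max_iter: int = 500
    _index: dict[int, int] = field(default_factory=dict, repr=False)
    _di_cache: dict[tuple[int, int], float] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._index = {p: i for i, p in enumerate(self.positions)}

    def direct_probability(
        self, pos_a: int, pos_b: int
    ) -> np.ndarray | None:
        """Two-site direct distribution P_dir(x, y); None if the field
        fit does not converge."""
        i, j = self._index[pos_a], self._index[pos_b]
        w = np.exp(self.couplings[i, j])
        fi, fj = self.freqs[i], self.freqs[j]
        mu1 = np.full(N_STATES, 1.0 / N_STATES)
        mu2 = np.full(N_STATES, 1.0 / N_STATES)
        for _ in range(self.mu_max_iter):
            new1 = fi / (w @ mu2)
            new1 /= new1.sum()
            new2 = fj / (w.T @ new1)
            new2 /= new2.sum()
            delta = max(
                np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max()
            )
            mu1, mu2 = new1, new2
            if delta < 1e-12:  # fixed point reached
                break
        p = w * np.outer(mu1, mu2)
        p /= p.sum()
        # the direct distribution must reproduce the single-site marginals
        if (
            np.abs(p.sum(axis=1) - fi).max() > self.mu_tol
            or np.abs(p.sum(axis=0) - fj).max() > self.mu_tol
        ):
            return None
        return p

    def direct_information(self, pos_a: int, pos_b: int) -> float:
        """DI(a,b) in nats; NaN when the two-site fit fails."""
        if pos_a not in self._index or pos_b not in self._index:
            raise KeyError(f"pair ({pos_a}, {pos_b}) not in DCA model")
        key = (pos_a, pos_b)
        if key in self._di_cache:
            return self._di_cache[key]
        p = self.direct_probability(pos_a, pos_b)
        if p is None:
            warnings.warn(
                f"two-site field fit did not converge for pair {key}; "
                "DI reported as missing",
                stacklevel=2,
            )
            di = float("nan")
        else:
            i, j = self._index[pos_a], self._index[pos_b]
            ref = np.outer(self.freqs[i], self.freqs[j])
            nz = p > 0
            di = float(np.sum(p[nz] * np.log(p[nz] / ref[nz])))
        self._di_cache[key] = di
        return di

    def di_matrix(self, cols1: list[int], cols2: list[int]) -> np.ndarray:
        out = np.empty((len(cols1), len(cols2)))
        for i, a in enumerate(cols1):
            for j, b in enumerate(cols2):
                out[i, j] = (
                    0.0 if a == b else self.direct_information(a, b)
                )
        return out


def _frequencies(
    x: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudocounted single and pair frequencies (unweighted counts)."""
    n, p = x.shape
    onehot = np.zeros((n, p, N_STATES))
    rows = np.arange(n)[:, None]
    cols = np.arange(p)[None, :]
    onehot[rows, cols, x] = 1.0
    f1_emp = onehot.mean(axis=0)  # (P, 21)
    f2_emp = np.einsum("nix,njy->ijxy", onehot, onehot) / n
    f1 = lam / N_STATES + (1.0 - lam) * f1_emp
    f2 = lam / N_STATES**2 + (1.0 - lam) * f2_emp
    # same-site blocks: joint of a column with itself is its diagonal
    for i in range(p):
        f2[i, i] = np.diag(f1[i])
    return f1, f2


def fit_mean_field_dca(
    matrix: np.ndarray,
    positions: list[int] | None = None,
    lam: float = 0.5,
) -> DcaModel:
    """Fit the mean-field Potts couplings over the given columns.

    ``matrix`` is an (N, C) uint8 state matrix (states 0..20, gap = 20);
    ``positions`` selects columns (default: all). ``lam`` is the
    pseudocount weight in (0, 1), default 0.5 as in standard mfDCA. A
    singular correlation matrix triggers a pseudocount increase with a
    warning.
    """
    if positions is None:
        positions = list(range(matrix.shape[1]))
    if len(positions) < 2:
        raise DegenerateInputError("DCA needs at least two positions")
    if not 0.0 < lam < 1.0:
        raise ValueError("pseudocount weight must be in (0, 1)")
    x = matrix[:, positions].astype(np.intp)
    p = len(positions)

    current_lam = lam
    while True:
        f1, f2 = _frequencies(x, current_lam)
        r = _REDUCED
        c = (
            f2[:, :, :r, :r]
            - f1[:, None, :r, None] * f1[None, :, None, :r]
        )
        c = c.transpose(0, 2, 1, 3).reshape(p * r, p * r)
        try:
            inv = np.linalg.inv(c)
            break
        except np.linalg.LinAlgError:
            if current_lam >= 0.9:
                raise
            current_lam = min(0.9, current_lam + 0.2)
            warnings.warn(
                "singular correlation matrix; pseudocount increased to "
                f"{current_lam}",
                stacklevel=2,
            )

    e = -inv.reshape(p, r, p, r).transpose(0, 2, 1, 3)
    couplings = np.zeros((p, p, N_STATES, N_STATES))
    couplings[:, :, :r, :r] = e
    # no self-coupling in the two-site direct model
    for i in range(p):
        couplings[i, i] = 0.0
    return DcaModel(
        positions=list(positions),
        couplings=couplings,
        freqs=f1,
        lam=current_lam,
    )
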