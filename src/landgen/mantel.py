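"""Mantel statistics and reciprocal causal modeling (RCM).

The Mantel correlation is the Pearson correlation of the upper-triangle
entries of two labeled distance matrices; its permutation null relabels the
rows and columns of one matrix simultaneously.  The partial Mantel statistic
(Smouse-Long-Sokal) correlates the residuals of the genetic and focal
vectors after ordinary least squares on the control vector, permuting the
genetic (response) matrix.

RCM compares competing hypothesis matrices (isolation by distance /
resistance / environment) through differences of reciprocal partial Mantel
correlations: the relative support of focal H_i against alternative H_j is
r(G, H_i | H_j) - r(G, H_j | H_i).  A hypothesis whose support column is all
positive and whose row is all negative beats every alternative in both
directions and is *fully supported*; the mirror image is *rejected*;
anything else is *partial*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = [
    "MantelResult",
    "RCMResult",
    "Verdict",
    "mantel",
    "partial_mantel",
    "ReciprocalCausalModel",
    "rcm_matrix",
    "evaluate_support",
]


class Verdict(str, enum.Enum):
    FULLY_SUPPORTED = "fully_supported"
    REJECTED = "rejected"
    PARTIAL = "partial"


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str = "greater"
    seed: int | None = None

    def __repr__(self) -> str:
        return f"MantelResult(r={self.r:.4f}, p={self.p:.4g}, n_perm={self.n_perm})"


def _aligned_vectors(*mats: DistanceMatrix) -> tuple[list[str], list[np.ndarray]]:
    labels = mats[0].labels
    n = len(labels)
    if n < 4:
        raise ValueError("need >= 4 sites for a Mantel test")
    vecs = []
    for m in mats:
        if m.labels != labels:
            if set(m.labels) != set(labels):
                raise ValueError("distance matrices carry different labels")
            m = m.reorder(labels)
        v = m.to_vector()
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances cannot enter a Mantel test")
        if np.allclose(v, v[0]):
            raise ValueError("constant off-diagonal matrix has zero variance")
        vecs.append(v)
    return list(labels), vecs


def _perm_vectors(values: np.ndarray, perms: np.ndarray,
                  iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Upper-triangle vectors of ``values`` under each row/column relabeling."""
    return values[perms[:, iu[0]], perms[:, iu[1]]]


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def mantel(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 9999,
           seed: int | None = None, tail: str = "greater") -> MantelResult:
    """Mantel correlation of A and B with a one-sided permutation test.

    ``p = (#{permuted r >= observed} + 1) / (n_perm + 1)`` where each
    permutation relabels the rows and columns of B simultaneously.
    """
    labels, (va, vb) = _aligned_vectors(A, B)
    r = float(np.dot(_standardize(va), _standardize(vb)))
    n = len(labels)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    iu = np.triu_indices(n, k=1)
    Bv = B.reorder(labels).values if B.labels != labels else B.values
    perm_vecs = _perm_vectors(Bv, perms, iu)
    perm_r = _standardize(perm_vecs) @ _standardize(va)
    if tail == "greater":
        k = int(np.sum(perm_r >= r))
    elif tail == "two-sided":
        k = int(np.sum(np.abs(perm_r) >= abs(r)))
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    return MantelResult(r=r, p=(k + 1) / (n_perm + 1), n_perm=n_perm,
                        tail=tail, seed=seed)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals of y (possibly (k, m)) on [1, x]."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, np.atleast_2d(y).T, rcond=None)
    res = np.atleast_2d(y) - (X @ coef).T
    return res[0] if y.ndim == 1 else res


def partial_mantel(G: DistanceMatrix, A: DistanceMatrix, B: DistanceMatrix,
                   n_perm: int = 9999, seed: int | None = None,
                   tail: str = "greater") -> MantelResult:
    """Partial Mantel correlation r(G, A | B) with response permutation.

    G and A are each regressed (OLS, with intercept) on B over upper-triangle
    entries and the residuals correlated; the permutation relabels G's rows
    and columns, re-residualizing each permuted G on B.
    """
    labels, (vg, va, vb) = _aligned_vectors(G, A, B)
    ra = _residualize(va, vb)
    if np.allclose(ra, 0.0, atol=1e-12):
        raise ValueError("A is collinear with B off-diagonal; partial r undefined")
    rg = _residualize(vg, vb)
    if np.allclose(rg, 0.0, atol=1e-12):
        raise ValueError("G is collinear with B off-diagonal; partial r undefined")
    r = float(np.dot(_standardize(rg), _standardize(ra)))
    n = len(labels)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    iu = np.triu_indices(n, k=1)
    Gv = G.reorder(labels).values if G.labels != labels else G.values
    perm_vecs = _perm_vectors(Gv, perms, iu)
    perm_res = _residualize(perm_vecs, vb)
    perm_r = _standardize(perm_res) @ _standardize(ra)
    if tail == "greater":
        k = int(np.sum(perm_r >= r))
    elif tail == "two-sided":
        k = int(np.sum(np.abs(perm_r) >= abs(r)))
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    return MantelResult(r=r, p=(k + 1) / (n_perm + 1), n_perm=n_perm,
                        tail=tail, seed=seed)


# ---------------------------------------------------------------------------
# Reciprocal causal modeling
# ---------------------------------------------------------------------------

@dataclass
class RCMResult:
    """Fitted reciprocal-causal-modeling comparison.

    ``partial_r[i, j]`` (i != j) is r(G, H_i | H_j); the diagonal carries the
    simple Mantel r(G, H_i).  ``support`` follows the winner-positive-column
    orientation: entry (row i, column j) is
    r(G, H_j | H_i) - r(G, H_i | H_j), so a fully supported hypothesis shows
    an all-positive column and an all-negative row.  ``p_values`` aligns with
    ``partial_r``.
    """

    hypotheses: list[str]
    partial_r: np.ndarray
    support: np.ndarray
    p_values: np.ndarray
    verdicts: dict[str, Verdict]
    n_perm: int
    seed: int | None = None

    def support_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.support, index=self.hypotheses,
                            columns=self.hypotheses)

    def correlation_frame(self, stars: bool = True) -> pd.DataFrame:
        """Mantel/partial-Mantel correlation panel with significance markers.

        ``**`` marks p < 0.002 and ``*`` p < 0.01 (permutation p-values).
        """
        out = pd.DataFrame(index=self.hypotheses, columns=self.hypotheses,
                           dtype=object)
        for i, hi in enumerate(self.hypotheses):
            for j, hj in enumerate(self.hypotheses):
                r, p = self.partial_r[i, j], self.p_values[i, j]
                cell = f"{r:.2f}"
                if stars:
                    if p < 0.002:
                        cell += "**"
                    elif p < 0.01:
                        cell += "*"
                out.iloc[i, j] = cell
        return out

    def summary(self) -> str:
        lines = ["Reciprocal causal modeling", "=" * 40,
                 f"permutations per test: {self.n_perm}", "",
                 "(A) relative support (row vs column; winner = positive column)",
                 self.support_frame().round(3).to_string(), "",
                 "(B) Mantel / partial Mantel correlations (** p<0.002, * p<0.01)",
                 self.correlation_frame().to_string(), "", "verdicts:"]
        for h, v in self.verdicts.items():
            lines.append(f"  {h}: {v.value}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "hypotheses": self.hypotheses,
            "partial_r": self.partial_r.tolist(),
            "support": self.support.tolist(),
            "p_values": self.p_values.tolist(),
            "verdicts": {h: v.value for h, v in self.verdicts.items()},
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def evaluate_support(support: np.ndarray, hypotheses: list[str]
                     ) -> dict[str, Verdict]:
    """Verdict per hypothesis from the oriented support matrix.

    Fully supported: its column all positive and its row all negative (zeros
    break full support); rejected is the mirror image; anything else partial.
    """
    support = np.asarray(support, dtype=float)
    out: dict[str, Verdict] = {}
    k = len(hypotheses)
    for i, h in enumerate(hypotheses):
        col = np.delete(support[:, i], i)
        row = np.delete(support[i, :], i)
        if k > 1 and np.all(col > 0) and np.all(row < 0):
            out[h] = Verdict.FULLY_SUPPORTED
        elif k > 1 and np.all(col < 0) and np.all(row > 0):
            out[h] = Verdict.REJECTED
        else:
            out[h] = Verdict.PARTIAL
    return out


class ReciprocalCausalModel:
    """Model object comparing hypothesis distance matrices against G.

    Parameters
    ----------
    G
        Genetic distance matrix (typically linearized FST).
    hypotheses
        Ordered mapping label -> predictor :class:`DistanceMatrix`, e.g.
        ``{"IBD": ..., "IBR": ..., "IBE-tmin": ...}``.
    """

    def __init__(self, G: DistanceMatrix, hypotheses: Mapping[str, DistanceMatrix]):
        if len(hypotheses) < 2:
            raise ValueError("need >= 2 hypotheses to compare")
        self.G = G
        self.hypotheses = dict(hypotheses)
        self.labels = list(hypotheses)

    def fit(self, n_perm: int = 9999, seed: int | None = None,
            compute_p: bool = True) -> RCMResult:
        """Run all reciprocal partial Mantel tests and assemble the result.

        ``compute_p=False`` skips permutation p-values (zeros reported), which
        is useful in large simulation studies where only the support matrix
        and verdicts are needed.
        """
        k = len(self.labels)
        partial_r = np.zeros((k, k))
        p_values = np.ones((k, k))
        n_eff = n_perm if compute_p else 0
        rng = np.random.default_rng(seed)
        for i, hi in enumerate(self.labels):
            sub = int(rng.integers(2 ** 31)) if seed is not None else None
            if compute_p:
                res = mantel(self.G, self.hypotheses[hi], n_perm=n_perm, seed=sub)
            else:
                res = _fast_r(self.G, self.hypotheses[hi])
            partial_r[i, i], p_values[i, i] = res.r, res.p
            for j, hj in enumerate(self.labels):
                if i == j:
                    continue
                sub = int(rng.integers(2 ** 31)) if seed is not None else None
                if compute_p:
                    res = partial_mantel(self.G, self.hypotheses[hi],
                                         self.hypotheses[hj], n_perm=n_perm,
                                         seed=sub)
                else:
                    res = _fast_partial_r(self.G, self.hypotheses[hi],
                                          self.hypotheses[hj])
                partial_r[i, j], p_values[i, j] = res.r, res.p
        support = partial_r.T - partial_r       # entry (i, j): support of H_j over H_i
        verdicts = evaluate_support(support, self.labels)
        return RCMResult(hypotheses=self.labels, partial_r=partial_r,
                         support=support, p_values=p_values, verdicts=verdicts,
                         n_perm=n_eff, seed=seed)


def _fast_r(A: DistanceMatrix, B: DistanceMatrix) -> MantelResult:
    _, (va, vb) = _aligned_vectors(A, B)
    return MantelResult(float(np.dot(_standardize(va), _standardize(vb))),
                        p=1.0, n_perm=0)


def _fast_partial_r(G: DistanceMatrix, A: DistanceMatrix, B: DistanceMatrix
                    ) -> MantelResult:
    _, (vg, va, vb) = _aligned_vectors(G, A, B)
    ra = _residualize(va, vb)
    if np.allclose(ra, 0.0, atol=1e-12):
        raise ValueError("A is collinear with B off-diagonal; partial r undefined")
    rg = _residualize(vg, vb)
    return MantelResult(float(np.dot(_standardize(rg), _standardize(ra))),
                        p=1.0, n_perm=0)


def rcm_matrix(G: DistanceMatrix, hypotheses: Mapping[str, DistanceMatrix],
               n_perm: int = 9999, seed: int | None = None,
               compute_p: bool = True) -> RCMResult:
    """Functional wrapper: fit a :class:`ReciprocalCausalModel`."""
    return ReciprocalCausalModel(G, hypotheses).fit(n_perm=n_perm, seed=seed,
                                                    compute_p=compute_p)
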