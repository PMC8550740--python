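"""Pairwise nucleotide divergence: p-distance, percent identity, Tajima-Nei.

All three operate on positionally aligned, equal-length sequences with
pairwise deletion: any site at which either sequence carries a gap or a
non-ACGT symbol is excluded from that pair's comparison only.

The Tajima-Nei (1984) distance corrects the observed proportion of differing
sites p for unequal base composition:

    d = -b * ln(1 - p / b),   b = (1 - sum_i q_i^2 + p^2 / h) / 2,
    h = sum_{i<j} x_ij^2 / (2 q_i q_j)

where q_i are the four average nucleotide frequencies of the pooled pair and
x_ij the frequencies of the six unordered mismatch types. With equal
composition and all mismatch types equally frequent, b -> 3/4 and d reduces
to the Jukes-Cantor form -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

_BASES = "ACGT"
_PAIRS = list(combinations(range(4), 2))  # six unordered base pairs


class UndefinedDistanceError(ValueError):
    """No comparable sites remain after pairwise deletion."""


class SaturationError(ValueError):
    """p >= b: the model-corrected distance is undefined (saturated pair)."""

    def __init__(self, p: float, b: float):
        super().__init__(f"Tajima-Nei saturation: p={p:.6f} >= b={b:.6f}")
        self.p = p
        self.b = b


@dataclass
class TajimaNeiComponents:
    """Intermediate quantities of the Tajima-Nei distance, for audit."""

    p: float
    q: np.ndarray  # 4 average base frequencies of the pooled pair
    x: np.ndarray  # 4x4 symmetric matrix of pair frequencies (off-diag only)
    h: float
    b: float
    d: float
    n_sites_used: int


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str
    n_sites_used: np.ndarray


def _comparable(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return [(x, y) for x, y in zip(a, b) if x in _BASES and y in _BASES]


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing sites under pairwise deletion.

    Returns (p, n_sites_used). Raises UndefinedDistanceError if no site
    is comparable.
    """
    sites = _comparable(a, b)
    if not sites:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    diffs = sum(1 for x, y in sites if x != y)
    return diffs / len(sites), len(sites)


def percent_identity(a: str, b: str) -> float:
    """100 * (1 - p), the identity convention used in divergence tables."""
    p, _ = p_distance(a, b)
    return 100.0 * (1.0 - p)


def tajima_nei(a: str, b: str) -> TajimaNeiComponents:
    """Tajima-Nei model-corrected distance between two aligned sequences."""
    sites = _comparable(a, b)
    n = len(sites)
    if n == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")

    # average base frequencies over the pooled pair
    counts = np.zeros(4)
    x = np.zeros((4, 4))
    diffs = 0
    idx = {base: i for i, base in enumerate(_BASES)}
    for ca, cb in sites:
        ia, ib = idx[ca], idx[cb]
        counts[ia] += 1
        counts[ib] += 1
        if ia != ib:
            diffs += 1
            lo, hi = min(ia, ib), max(ia, ib)
            x[lo, hi] += 1
    q = counts / (2 * n)
    x /= n
    p = diffs / n

    if p == 0.0:
        return TajimaNeiComponents(p=0.0, q=q, x=x, h=0.0, b=0.0, d=0.0, n_sites_used=n)

    h = 0.0
    for i, j in _PAIRS:
        if x[i, j] > 0:
            h += x[i, j] ** 2 / (2.0 * q[i] * q[j])
    b = 0.5 * (1.0 - float(np.sum(q**2)) + p**2 / h)
    if p >= b:
        raise SaturationError(p, b)
    d = -b * math.log(1.0 - p / b)
    return TajimaNeiComponents(p=p, q=q, x=x, h=h, b=b, d=d, n_sites_used=n)


_METRICS = ("p_distance", "percent_identity", "tajima_nei")


def distance_matrix(seqs: list[str], labels: list[str] | None = None,
                    metric: str = "p_distance") -> DistanceMatrix:
    """All-pairs distance matrix over equal-length aligned sequences."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if labels is None:
        labels = [f"seq{i}" for i in range(len(seqs))]
    if len(labels) != len(seqs):
        raise ValueError("labels/seqs length mismatch")
    n = len(seqs)
    values = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    if metric == "percent_identity":
        np.fill_diagonal(values, 100.0)
    for i in range(n):
        used[i, i] = sum(1 for c in seqs[i] if c in _BASES)
        for j in range(i + 1, n):
            try:
                if metric == "p_distance":
                    v, m = p_distance(seqs[i], seqs[j])
                elif metric == "percent_identity":
                    p, m = p_distance(seqs[i], seqs[j])
                    v = 100.0 * (1.0 - p)
                else:
                    comp = tajima_nei(seqs[i], seqs[j])
                    v, m = comp.d, comp.n_sites_used
            except (UndefinedDistanceError, SaturationError) as exc:
                raise type(exc)(
                    f"pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = v
            used[i, j] = used[j, i] = m
    return DistanceMatrix(labels=list(labels), values=values, metric=metric, n_sites_used=used)


def write_matrix_tsv(matrix: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
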