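"""Correlated-mutation scoring of core-position pairs.

Two scorers are provided, both producing a symmetric matrix of scores in
[0, 1] over core positions:

``sca``
    A perturbation-style statistical coupling score.  For a pair of
    columns (i, j), restricted to sequences non-gapped at both: for each
    residue *a* observed at i with count ``n_a >= min_subset``, the
    conditional residue distribution at j given *a* is compared with the
    marginal distribution at j by total-variation distance,
    ``d_a = 0.5 * sum_b |f_{j|a}(b) - f_j(b)|``.  The directed score is
    the count-weighted mean of ``d_a`` over qualifying residues, and the
    reported score is the mean of the two directions.  A column with a
    single residue perturbs nothing, so conserved columns score 0.

``nmi``
    Mutual information (base 2) of the joint residue distribution,
    normalised by the smaller of the two column entropies.  1 exactly
    when the columns determine each other; 0 for a conserved column.

Gap handling is pairwise-complete: sequences gapped (or 'X') at either
column of a pair are dropped for that pair only.  Pairs with fewer than
``min_pairs`` complete sequences are flagged undefined (NaN), never
coerced to 0.  No small-sample bias correction is applied to the mutual
information; its bias is roughly ``(|A|-1)(|B|-1) / (2 n ln 2)`` bits for
alphabet sizes |A|, |B| and n sequences, negligible at the alignment
sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyCoreError, InsufficientPairsError
from .msa import GAP_CODE, CorePositions, Msa

METHODS = ("sca", "nmi")


@dataclass
class CmaConfig:
    """Scoring configuration.

    min_pairs : minimum number of sequences non-gapped at both columns
        for a pair score to be defined (default 20).
    min_subset : minimum count of a residue at the perturbing column for
        it to contribute to the sca score (default 5).
    subset_ids : optional sequence-id subset to score on.
    """

    method: str = "sca"
    min_pairs: int = 20
    min_subset: int = 5
    subset_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")
        if self.min_subset < 1:
            raise ValueError("min_subset must be >= 1")


@dataclass
class CmaMatrix:
    """Symmetric pairwise score matrix over core positions.

    ``scores[i, j]`` is indexed by core-position *rank* (0-based into
    ``positions``); undefined pairs and the diagonal are NaN.
    ``low_support`` flags sca pairs where no residue met ``min_subset``.
    """

    positions: tuple[int, ...]
    scores: np.ndarray
    n_pairs: np.ndarray
    method: str
    n_sequences: int
    low_support: set[tuple[int, int]] = field(default_factory=set)

    def score(self, i: int, j: int) -> float:
        """Score between core positions i and j (position numbers)."""
        a, b = self.positions.index(i), self.positions.index(j)
        return float(self.scores[a, b])

    def defined_scores(self) -> np.ndarray:
        """All defined off-diagonal scores (upper triangle, 1-D)."""
        iu = np.triu_indices(len(self.positions), k=1)
        vals = self.scores[iu]
        return vals[~np.isnan(vals)]

    def to_edgelist(self) -> pd.DataFrame:
        """Long-format table: pos_i, pos_j (i < j), score, n_pairs, method."""
        rows = []
        k = len(self.positions)
        for a in range(k):
            for b in range(a + 1, k):
                s = self.scores[a, b]
                if np.isnan(s):
                    continue
                rows.append(
                    (
                        self.positions[a],
                        self.positions[b],
                        float(s),
                        int(self.n_pairs[a, b]),
                        self.method,
                    )
                )
        return pd.DataFrame(
            rows, columns=["pos_i", "pos_j", "score", "n_pairs", "method"]
        )

    def write_tsv(self, path) -> None:
        self.to_edgelist().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_matrix_tsv(path) -> CmaMatrix:
    """Rebuild a :class:`CmaMatrix` from its edge-list TSV."""
    df = pd.read_csv(path, sep="\t")
    positions = tuple(sorted(set(df.pos_i) | set(df.pos_j)))
    rank = {p: r for r, p in enumerate(positions)}
    k = len(positions)
    scores = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    for row in df.itertuples():
        a, b = rank[row.pos_i], rank[row.pos_j]
        scores[a, b] = scores[b, a] = row.score
        n_pairs[a, b] = n_pairs[b, a] = row.n_pairs
    method = str(df.method.iloc[0]) if len(df) else "sca"
    return CmaMatrix(positions, scores, n_pairs, method, n_sequences=0)


# -- scoring kernels (operate on a 20x20 joint count table) ---------------


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _nmi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    pij = joint / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    hi, hj = _entropy_bits(pi), _entropy_bits(pj)
    hmin = min(hi, hj)
    if hmin == 0.0:
        return 0.0
    nz = pij > 0
    mi = float((pij[nz] * np.log2(pij[nz] / np.outer(pi, pj)[nz])).sum())
    # clip tiny negative rounding and >1 rounding
    return float(min(max(mi / hmin, 0.0), 1.0))


def _sca_directed(joint: np.ndarray, min_subset: int) -> float | None:
    """Directed perturbation score rows -> columns; None if no row qualifies."""
    n_a = joint.sum(axis=1)
    f_j = joint.sum(axis=0) / joint.sum()
    qual = n_a >= min_subset
    if not qual.any():
        return None
    cond = joint[qual] / n_a[qual, None]
    d = 0.5 * np.abs(cond - f_j).sum(axis=1)
    w = n_a[qual] / n_a[qual].sum()
    return float(w @ d)


def _sca_from_joint(joint: np.ndarray, min_subset: int) -> tuple[float, bool]:
    """Symmetrised sca score and a low-support flag."""
    d_ij = _sca_directed(joint, min_subset)
    d_ji = _sca_directed(joint.T, min_subset)
    if d_ij is None and d_ji is None:
        return 0.0, True
    if d_ij is None:
        d_ij = d_ji
    if d_ji is None:
        d_ji = d_ij
    return float(min(0.5 * (d_ij + d_ji), 1.0)), False


def _joint_counts(xi: np.ndarray, xj: np.ndarray) -> tuple[np.ndarray, int]:
    mask = (xi != GAP_CODE) & (xj != GAP_CODE)
    n = int(mask.sum())
    if n == 0:
        return np.zeros((20, 20)), 0
    joint = np.bincount(
        xi[mask].astype(np.intp) * 20 + xj[mask], minlength=400
    ).reshape(20, 20).astype(float)
    return joint, n


# -- public pairwise operations ------------------------------------------


def _pair_columns(
    msa: Msa, core: CorePositions, i: int, j: int, subset_ids=None
) -> tuple[np.ndarray, np.ndarray]:
    if i == j:
        raise ValueError("pair requires two distinct core positions")
    enc = msa.encoded() if subset_ids is None else msa.subset(subset_ids).encoded()
    return enc[:, core.column_of(i) - 1], enc[:, core.column_of(j) - 1]


def nmi_score(
    msa: Msa,
    core: CorePositions,
    i: int,
    j: int,
    min_pairs: int = 20,
    subset_ids=None,
) -> float:
    """Normalised mutual information between core positions i and j."""
    xi, xj = _pair_columns(msa, core, i, j, subset_ids)
    joint, n = _joint_counts(xi, xj)
    if n < min_pairs:
        raise InsufficientPairsError(
            f"positions {i},{j}: {n} complete pairs < min_pairs={min_pairs}"
        )
    return _nmi_from_joint(joint)


def sca_score(
    msa: Msa,
    core: CorePositions,
    i: int,
    j: int,
    min_pairs: int = 20,
    min_subset: int = 5,
    subset_ids=None,
) -> float:
    """Perturbation-style statistical coupling score between i and j."""
    xi, xj = _pair_columns(msa, core, i, j, subset_ids)
    joint, n = _joint_counts(xi, xj)
    if n < min_pairs:
        raise InsufficientPairsError(
            f"positions {i},{j}: {n} complete pairs < min_pairs={min_pairs}"
        )
    score, _ = _sca_from_joint(joint, min_subset)
    return score


def compute_cma_matrix(
    msa: Msa, core: CorePositions, config: CmaConfig | None = None
) -> CmaMatrix:
    """Score all unordered core-position pairs with the configured method."""
    config = config or CmaConfig()
    if len(core) < 2:
        raise EmptyCoreError("need at least 2 core positions for pairwise scores")
    target = msa if config.subset_ids is None else msa.subset(config.subset_ids)
    enc = target.encoded()
    cols = np.asarray(core.columns, dtype=np.intp) - 1
    X = np.ascontiguousarray(enc[:, cols])
    k = len(core)
    scores = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    low_support: set[tuple[int, int]] = set()
    positions = tuple(core.numbers)
    for a, b in combinations(range(k), 2):
        joint, n = _joint_counts(X[:, a], X[:, b])
        n_pairs[a, b] = n_pairs[b, a] = n
        if n < config.min_pairs:
            continue
        if config.method == "nmi":
            s = _nmi_from_joint(joint)
        else:
            s, low = _sca_from_joint(joint, config.min_subset)
            if low:
                low_support.add((positions[a], positions[b]))
        scores[a, b] = scores[b, a] = s
    return CmaMatrix(
        positions, scores, n_pairs, config.method, target.n_sequences, low_support
    )
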