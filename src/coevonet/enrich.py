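"""Keyword enrichment on co-evolution networks.

The enrichment score of a keyword on a network is

    Escore = (Kn / Kt) * (Nt / Nn)

with Nn the number of positions in the network, Nt the total number of
core positions, Kn the number of network positions annotated with the
keyword and Kt the total number of annotated positions.  It is the
keyword density inside the network relative to the whole alignment; 1
means no enrichment, and under random placement of Kt annotated
positions its expectation is exactly 1 (Kn is hypergeometric).

An undefined score (no position annotated, or an empty network) is kept
distinct from a genuine 0 throughout.  Significance is estimated by a
permutation test over random position sets of the same size as the
network, with add-one smoothing:
``p = (1 + #{escore_perm >= escore_obs}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cma import CmaMatrix
from .litmine import AnnotationTable
from .network import build_network

#: Default cutoff sweep, 0.50 .. 0.95 in steps of 0.05.
DEFAULT_CUTOFFS = tuple(round(0.50 + 0.05 * k, 2) for k in range(10))

STATUS_OK = "ok"
STATUS_EMPTY_NETWORK = "empty-network"
STATUS_UNDEFINED_KEYWORD = "undefined-keyword"


@dataclass(frozen=True)
class EnrichmentResult:
    """Escore of one keyword on one network."""

    keyword: str
    cutoff: float | None
    k_n: int
    k_t: int
    n_n: int
    n_t: int
    escore: float | None
    status: str = STATUS_OK
    p_value: float | None = None


@dataclass
class EnrichmentCurve:
    """Escore of one keyword across a strictly increasing cutoff grid."""

    keyword: str
    results: list[EnrichmentResult]

    def __post_init__(self) -> None:
        cuts = [r.cutoff for r in self.results]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "keyword": r.keyword,
                    "cutoff": r.cutoff,
                    "Kn": r.k_n,
                    "Kt": r.k_t,
                    "Nn": r.n_n,
                    "Nt": r.n_t,
                    "escore": r.escore,
                    "status": r.status,
                    "p_value": r.p_value,
                }
                for r in self.results
            ]
        )


def escore(
    network_positions: Iterable[int],
    keyword_positions: Iterable[int],
    total_positions: Iterable[int],
    keyword: str = "",
    cutoff: float | None = None,
) -> EnrichmentResult:
    """Enrichment of a keyword position set on a network position set."""
    net = set(network_positions)
    kw = set(keyword_positions)
    tot = set(total_positions)
    if not net <= tot or not kw <= tot:
        raise ValueError("network and keyword positions must be within the total set")
    n_n, n_t = len(net), len(tot)
    k_t = len(kw)
    k_n = len(net & kw)
    if n_n == 0:
        return EnrichmentResult(
            keyword, cutoff, 0, k_t, 0, n_t, None, STATUS_EMPTY_NETWORK
        )
    if k_t == 0:
        return EnrichmentResult(
            keyword, cutoff, 0, 0, n_n, n_t, None, STATUS_UNDEFINED_KEYWORD
        )
    value = (k_n / k_t) * (n_t / n_n)
    return EnrichmentResult(keyword, cutoff, k_n, k_t, n_n, n_t, value)


def enrichment_curve(
    matrix: CmaMatrix,
    annotations: AnnotationTable,
    keyword: str,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> EnrichmentCurve:
    """Escore of one keyword across a cutoff sweep.

    The network position set at each cutoff is the union of all
    component nodes (per-component scores are available through
    :func:`escore` directly).
    """
    total = set(matrix.positions)
    kw_positions = annotations.positions_for(keyword) & total
    results = []
    for cutoff in cutoffs:
        net = build_network(matrix, cutoff)
        results.append(
            escore(net.nodes, kw_positions, total, keyword=keyword, cutoff=cutoff)
        )
    return EnrichmentCurve(keyword, results)


def permutation_pvalue(
    matrix: CmaMatrix,
    annotations: AnnotationTable,
    keyword: str,
    cutoff: float,
    n_perm: int = 999,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation significance of a keyword's Escore at one cutoff.

    Random position sets of the network's size are drawn from all core
    positions; the p-value is the add-one-smoothed fraction with Escore
    at least as large as observed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    total = tuple(matrix.positions)
    kw_positions = annotations.positions_for(keyword) & set(total)
    net = build_network(matrix, cutoff)
    observed = escore(net.nodes, kw_positions, total, keyword=keyword, cutoff=cutoff)
    if observed.status != STATUS_OK:
        return observed
    rng = np.random.default_rng(seed)
    n_n = observed.n_n
    arr = np.array(total)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(arr, size=n_n, replace=False)
        k_n = len(set(draw.tolist()) & kw_positions)
        es = (k_n / observed.k_t) * (observed.n_t / n_n)
        if es >= observed.escore - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return EnrichmentResult(
        keyword, cutoff, observed.k_n, observed.k_t, observed.n_n,
        observed.n_t, observed.escore, STATUS_OK, p
    )
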