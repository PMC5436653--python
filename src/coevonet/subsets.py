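"""Sub-alignments and network-robustness scans.

Two kinds of sub-alignment are supported: residue-conditioned subsets
(all sequences carrying a given residue at a given core position — the
position becomes conserved in the subset and drops out of its networks,
revealing the next layer of co-evolution) and random subsets for testing
how many sequences a reliable network needs.  Core positions are *not*
re-derived for subsets, so position numbers stay comparable between the
full alignment and every subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cma import CmaConfig, compute_cma_matrix
from .errors import EmptySubsetError
from .msa import AA_INDEX, CorePositions, Msa
from .network import build_network, f_measure

#: Below this many sequences a subset network is considered unreliable.
MIN_SEQUENCES_WARNING = 50


@dataclass(frozen=True)
class SubsetSpec:
    """Specification of a sub-alignment selection."""

    kind: str  # conditioned | random
    position: int | None = None
    residue: str | None = None
    fraction: float | None = None
    replicates: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "conditioned":
            if self.residue not in AA_INDEX:
                raise ValueError(f"residue must be one of the 20 amino acids")
        elif self.kind == "random":
            if not (self.fraction and 0 < self.fraction <= 1):
                raise ValueError("fraction must be in (0, 1]")
        else:
            raise ValueError("kind must be 'conditioned' or 'random'")


def subset_by_residue(
    msa: Msa,
    core: CorePositions,
    number: int,
    residue: str,
    min_sequences: int = MIN_SEQUENCES_WARNING,
) -> Msa:
    """Sequences carrying ``residue`` at core position ``number``.

    Columns are unchanged, so position numbers remain valid.  Raises
    :class:`EmptySubsetError` when no sequence qualifies; warns when the
    subset is smaller than ``min_sequences``.
    """
    if residue not in AA_INDEX:
        raise ValueError(f"{residue!r} is not a standard amino acid")
    col = core.column_of(number)
    keep = [sid for sid, row in zip(msa.ids, msa.rows) if row[col - 1] == residue]
    if not keep:
        raise EmptySubsetError(
            f"no sequence has {residue} at core position {number}"
        )
    if len(keep) < min_sequences:
        warnings.warn(
            f"conditioned subset has only {len(keep)} sequences "
            f"(< {min_sequences}); its networks may be unreliable",
            stacklevel=2,
        )
    return msa.subset(keep)


def random_subsets(
    msa: Msa,
    fractions: Sequence[float],
    replicates: int,
    seed: int = 0,
) -> list[tuple[float, int, Msa]]:
    """Uniform without-replacement row subsets, one per (fraction, replicate).

    Subset size is ``round(fraction * N)`` with a floor of 2; fractions
    whose size would fall below 2 are skipped with a warning.  Sampling
    is reproducible per (seed, fraction, replicate index); a fraction of
    1.0 returns the full alignment with row order preserved.
    """
    out = []
    for fraction in fractions:
        if not 0 < fraction <= 1:
            raise ValueError("fractions must be in (0, 1]")
        size = round(fraction * msa.n_sequences)
        if size < 2:
            warnings.warn(
                f"fraction {fraction} yields {size} < 2 sequences; skipped",
                stacklevel=2,
            )
            continue
        for rep in range(replicates):
            if fraction == 1.0:
                out.append((fraction, rep, msa))
                continue
            rng = np.random.default_rng([seed, int(round(fraction * 10**6)), rep])
            idx = np.sort(rng.choice(msa.n_sequences, size=size, replace=False))
            out.append((fraction, rep, msa.subset([msa.ids[i] for i in idx])))
    return out


def robustness_scan(
    msa: Msa,
    core: CorePositions,
    cma_config: CmaConfig,
    cutoff: float,
    fractions: Sequence[float],
    replicates: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Network stability under random subsampling.

    For each subset, pairwise scores and the network are recomputed at
    the *same* cutoff as the full alignment and the F-measure of the
    subset's node set against the full-alignment node set is recorded.
    Returns (per-replicate table, per-fraction mean/sd summary).
    """
    full_matrix = compute_cma_matrix(msa, core, cma_config)
    full_nodes = build_network(full_matrix, cutoff).nodes
    if not full_nodes:
        raise ValueError(
            f"full-alignment network is empty at cutoff {cutoff}; nothing to scan"
        )
    rows = []
    for fraction, rep, sub in random_subsets(msa, fractions, replicates, seed):
        sub_matrix = compute_cma_matrix(sub, core, cma_config)
        sub_nodes = build_network(sub_matrix, cutoff).nodes
        cmp = f_measure(sub_nodes, full_nodes)
        rows.append(
            (fraction, rep, sub.n_sequences, cmp.precision, cmp.recall, cmp.f_measure)
        )
    report = pd.DataFrame(
        rows,
        columns=["fraction", "replicate", "n_sequences", "precision", "recall",
                 "f_measure"],
    )
    summary = (
        report.groupby("fraction")["f_measure"]
        .agg(mean_f="mean", sd_f="std", n="count")
        .reset_index()
    )
    return report, summary
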