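"""Synthetic protein super-family generator with planted co-evolution.

Emulates the statistical structure that drives correlated-mutation
signals in real super-families: sequences fall into functional
subgroups, and at a planted set of "network" positions each subgroup has
its own consensus residue which members carry with high probability
(``p_cons``).  Across the family those positions therefore co-vary as a
group — the signal the pairwise scorers are meant to detect — while
background positions draw independently from per-column residue
profiles.  Two levels are supported: level-1 networks keyed on the
top-level subgroup, and level-2 networks keyed on an independent nested
subgroup label, which only become the dominant network once a level-1
position is conditioned to a single residue (the layered behaviour seen
when sub-alignments of a super-family are analysed).

A companion corpus generator writes synthetic article texts mentioning
mutations (with wild-type letters that actually match the emitted
sequences) at planted positions together with each network's keyword, so
the text-mining pipeline can be validated end to end against a known
annotation table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .litmine import build_annotation_table, one_to_three
from .msa import AMINO_ACIDS, CorePositions, Msa, map_3d_to_residue

_NOISE_KEYWORDS = ("stability", "buffer", "expression", "crystallization")


@dataclass(frozen=True)
class PlantedNetwork:
    """A planted set of co-evolving positions tagged with a keyword.

    ``level`` 1 couples the positions to the top-level subgroup; level 2
    couples them to the nested subgroup label.
    """

    positions: tuple[int, ...]
    keyword: str
    level: int = 1


@dataclass
class SimConfig:
    """Study conditions for one synthetic super-family.

    Defaults emulate a large, diverse super-family: 5000 sequences over
    8 equal subgroups, 150 core positions, one planted 12-position
    network carried with probability 0.9, 5% random gaps, and residue
    profiles drawn from a symmetric Dirichlet (concentration 0.5) for
    realistic column heterogeneity.
    """

    n_sequences: int = 5000
    n_positions: int = 150
    group_weights: tuple[float, ...] = (0.125,) * 8
    subgroup_weights: tuple[float, ...] | None = None
    networks: tuple[PlantedNetwork, ...] = (
        PlantedNetwork(tuple(range(5, 138, 12)), "enantioselectivity"),
    )
    p_cons: float = 0.9
    gap_rate: float = 0.05
    dirichlet_conc: float = 0.5
    n_variable_columns: int = 0
    variable_gap_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_cons <= 1:
            raise ValueError("p_cons must be in [0, 1]")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")
        if abs(sum(self.group_weights) - 1) > 1e-9:
            raise ValueError("group weights must sum to 1")
        if self.subgroup_weights is not None and abs(sum(self.subgroup_weights) - 1) > 1e-9:
            raise ValueError("subgroup weights must sum to 1")
        if len(self.group_weights) > 20:
            raise ValueError("at most 20 subgroups (distinct consensus residues)")
        seen: set[int] = set()
        for net in self.networks:
            if not set(net.positions) <= set(range(1, self.n_positions + 1)):
                raise ValueError(f"network positions out of range: {net.positions}")
            if seen & set(net.positions):
                raise ValueError("planted position sets must be disjoint")
            if net.level == 2 and self.subgroup_weights is None:
                raise ValueError("level-2 networks require subgroup_weights")
            seen |= set(net.positions)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated family."""

    config: SimConfig
    groups: np.ndarray
    subgroups: np.ndarray | None
    consensus: dict[int, np.ndarray]  # position -> consensus aa index per (sub)group
    network_positions: dict[str, tuple[int, ...]]  # keyword -> positions
    levels: dict[str, int] = field(default_factory=dict)

    def positions_for_level(self, level: int) -> set[int]:
        return {
            p
            for kw, positions in self.network_positions.items()
            if self.levels.get(kw, 1) == level
            for p in positions
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": self.groups.tolist(),
                "subgroups": None if self.subgroups is None else self.subgroups.tolist(),
                "consensus": {str(k): v.tolist() for k, v in self.consensus.items()},
                "network_positions": {
                    kw: list(p) for kw, p in self.network_positions.items()
                },
                "levels": self.levels,
            },
            indent=1,
        )


def simulate_family(config: SimConfig) -> tuple[Msa, SimTruth]:
    """Draw a synthetic aligned family; deterministic given the seed.

    Core columns are generated first (planted + background), then
    ``n_variable_columns`` high-gap columns are spliced in at random
    places to mimic structurally variable regions, which a gap-fraction
    core derivation excludes again — planted positions are stated in
    core numbering, which survives the round trip.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_sequences, config.n_positions
    n_groups = len(config.group_weights)
    groups = rng.choice(n_groups, size=n, p=np.asarray(config.group_weights))
    subgroups = None
    if config.subgroup_weights is not None:
        subgroups = rng.choice(
            len(config.subgroup_weights), size=n, p=np.asarray(config.subgroup_weights)
        )

    # background: per-column Dirichlet profiles
    profiles = rng.dirichlet([config.dirichlet_conc] * 20, size=k)
    X = np.empty((n, k), dtype=np.int8)
    u = rng.random((n, k))
    cum = profiles.cumsum(axis=1)
    for col in range(k):
        X[:, col] = np.searchsorted(cum[col], u[:, col], side="right")
    np.clip(X, 0, 19, out=X)

    # planted networks: per-(sub)group consensus, distinct across groups
    consensus: dict[int, np.ndarray] = {}
    network_positions: dict[str, tuple[int, ...]] = {}
    levels: dict[str, int] = {}
    for net in config.networks:
        labels = groups if net.level == 1 else subgroups
        n_labels = n_groups if net.level == 1 else len(config.subgroup_weights)
        network_positions[net.keyword] = net.positions
        levels[net.keyword] = net.level
        for pos in net.positions:
            cons = rng.choice(20, size=n_labels, replace=False)
            consensus[pos] = cons
            col = pos - 1
            carrier = rng.random(n) < config.p_cons
            vals = cons[labels]
            # non-carriers: uniform over the other 19 residues
            other = (vals + rng.integers(1, 20, size=n)) % 20
            X[:, col] = np.where(carrier, vals, other)

    # gaps
    gap_mask = rng.random((n, k)) < config.gap_rate
    X[gap_mask] = 20

    # splice in high-gap variable columns
    total_cols = k + config.n_variable_columns
    if config.n_variable_columns:
        var_slots = set(
            rng.choice(total_cols, size=config.n_variable_columns, replace=False).tolist()
        )
        full = np.empty((n, total_cols), dtype=np.int8)
        core_iter = iter(range(k))
        for col in range(total_cols):
            if col in var_slots:
                profile = rng.dirichlet([config.dirichlet_conc] * 20)
                vals = rng.choice(20, size=n, p=profile)
                gaps = rng.random(n) < config.variable_gap_frac
                full[:, col] = np.where(gaps, 20, vals)
            else:
                full[:, col] = X[:, next(core_iter)]
        X = full

    alphabet = np.frombuffer((AMINO_ACIDS + "-").encode(), dtype=np.uint8)
    rows = [bytes(alphabet[row]).decode() for row in X]
    width = len(str(n))
    ids = [f"seq{i:0{width}d}" for i in range(1, n + 1)]
    msa = Msa(ids, rows)
    truth = SimTruth(config, groups, subgroups, consensus, network_positions, levels)
    return msa, truth


_SENTENCE_TEMPLATES = (
    "The {compact} mutation strongly affected {kw} of the enzyme.",
    "Variant {three} showed a clear change in {kw} in our assays.",
    "{wt3}{pos} was mutated to {mut3}, which altered {kw} markedly.",
)


def simulate_corpus(
    msa: Msa,
    core: CorePositions,
    truth: SimTruth,
    articles_per_position: int = 2,
    keyword_noise: float = 0.0,
    include_planted: bool = True,
    n_mut: int = 2,
    seed: int = 0,
):
    """Synthetic article texts mentioning mutations at planted positions.

    Each planted position is mentioned together with its network's
    keyword in ``articles_per_position`` distinct articles (each article
    is "about" one alignment sequence, recorded in the returned
    mapping).  ``keyword_noise`` adds, per planted sentence, that many
    noise sentences on average, each pairing a random core position with
    a random neutral keyword in a single article.

    Returns ``(articles, article_seq, expected_table)`` where
    ``articles`` maps article id to text, ``article_seq`` maps article
    id to the sequence it describes, and ``expected_table`` is the
    annotation table the mining pipeline should reproduce (built from
    the generated records with the same ``n_mut`` filter).
    """
    rng = np.random.default_rng(seed)
    articles: dict[str, list[str]] = {}
    article_seq: dict[str, str] = {}
    records: list[tuple[int, str, str]] = []
    counter = 0

    def new_article() -> str:
        nonlocal counter
        counter += 1
        return f"PMID{counter:05d}"

    def pick_sequence(pos: int) -> tuple[str, int, str] | None:
        col = core.column_of(pos)
        for _ in range(50):
            sid = msa.ids[int(rng.integers(msa.n_sequences))]
            mapped = map_3d_to_residue(msa, core, sid, pos)
            if mapped is not None:
                return sid, mapped[0], mapped[1]
        return None

    def add_sentence(pos: int, keyword: str, article_id: str, sid_info) -> None:
        sid, res_num, wt = sid_info
        mut = AMINO_ACIDS[(AMINO_ACIDS.index(wt) + 1 + int(rng.integers(19))) % 20]
        template = _SENTENCE_TEMPLATES[int(rng.integers(len(_SENTENCE_TEMPLATES)))]
        sentence = template.format(
            compact=f"{wt}{res_num}{mut}",
            three=f"{one_to_three(wt)}{res_num}{one_to_three(mut)}",
            wt3=one_to_three(wt),
            mut3=one_to_three(mut),
            pos=res_num,
            kw=keyword.replace(" AND ", " and "),
        )
        articles.setdefault(article_id, []).append(sentence)
        article_seq[article_id] = sid
        records.append((pos, keyword, article_id))

    n_planted_sentences = 0
    if include_planted:
        for keyword, positions in sorted(truth.network_positions.items()):
            for pos in positions:
                for _ in range(articles_per_position):
                    info = pick_sequence(pos)
                    if info is None:
                        continue
                    aid = new_article()
                    add_sentence(pos, keyword, aid, info)
                    n_planted_sentences += 1

    n_noise = rng.poisson(keyword_noise * max(n_planted_sentences, 1))
    for _ in range(n_noise):
        pos = int(rng.choice(np.arange(1, len(core) + 1)))
        info = pick_sequence(pos)
        if info is None:
            continue
        keyword = _NOISE_KEYWORDS[int(rng.integers(len(_NOISE_KEYWORDS)))]
        add_sentence(pos, keyword, new_article(), info)

    texts = {aid: " ".join(sentences) for aid, sentences in articles.items()}
    expected = build_annotation_table(records, n_mut=n_mut)
    return texts, article_seq, expected


def write_run(
    out_dir, msa: Msa, truth: SimTruth, articles: Mapping[str, str] | None = None,
    article_seq: Mapping[str, str] | None = None, expected=None
) -> None:
    """Write a simulated run (FASTA, truth JSON, articles, expected table)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    msa.write_fasta(out / "alignment.fasta")
    (out / "truth.json").write_text(truth.to_json())
    if articles:
        adir = out / "articles"
        adir.mkdir(exist_ok=True)
        for aid, text in articles.items():
            (adir / f"{aid}.txt").write_text(text + "\n")
        if article_seq:
            with open(out / "article_seq.tsv", "w") as fh:
                fh.write("article_id\tseq_id\n")
                for aid in sorted(article_seq):
                    fh.write(f"{aid}\t{article_seq[aid]}\n")
    if expected is not None:
        expected.write_tsv(out / "expected_annotations.tsv")
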