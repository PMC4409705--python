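"""Null-model interaction sets.

Four controls are provided, each destroying co-regulation signal in a
different, complementary way while keeping some aspect of the real data
fixed:

* :func:`sample_random_pairs` — random protein pairs drawn from the
  analysis universe, excluding every real (and homodimeric) interaction.
  The baseline "no relationship" control; its degree structure is
  binomial-like, unlike real interactomes.
* :func:`shuffle_interactome` — a uniformly random permutation of node
  labels over the real network. Topology (edge count, exact degree
  multiset, components) is preserved; which protein sits at which node is
  randomised. This controls for the scale-free character of biological
  networks that random pairs lack.
* :func:`shuffle_operons` — permutes the gene-to-operon assignment while
  preserving every operon's size, then expands the false operons to pairs.
* :func:`hub_matched_controls` — for each hub, as many random partners as
  it has analyzable real neighbours, so hub-level sample sizes are matched
  exactly.

All operations take an explicit integer seed and are deterministic given
it; seeds are recorded in each set's ``source_note``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .interactions import GroupTable, InteractionSet, Pair, expand_group_pairs
from .params import ParamsTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingConfig:
    """Configuration for random-pair sampling.

    Attributes
    ----------
    universe
        Proteins eligible as endpoints (those with known translational
        parameters).
    excluded
        Real interactions that a random pair must not reproduce.
    target_count
        Number of distinct random pairs to produce (default 3000).
    seed
        Seed for the pseudo-random generator.
    """

    universe: frozenset[str]
    excluded: InteractionSet = field(
        default_factory=lambda: InteractionSet("excluded", frozenset())
    )
    target_count: int = 3000
    seed: int = 0

    def feasible_count(self) -> int:
        n = len(self.universe)
        total = n * (n - 1) // 2
        excluded_inside = sum(
            1 for a, b in self.excluded.pairs if a in self.universe and b in self.universe
        )
        return total - excluded_inside


def sample_random_pairs(config: SamplingConfig) -> InteractionSet:
    """Draw ``target_count`` distinct random heterodimeric pairs.

    Pairs are drawn with replacement from the universe; draws that are
    homodimeric, excluded, or already collected are rejected, and drawing
    repeats until the target count of distinct pairs accumulates. When the
    target exceeds half of the feasible pairs, the feasible set is
    enumerated and sampled without replacement instead (still uniform, and
    guaranteed to terminate); the switch depends only on the configuration,
    so determinism per seed is preserved.
    """
    if config.target_count < 1:
        raise ValueError("target_count must be positive")
    feasible = config.feasible_count()
    if config.target_count > feasible:
        raise ValueError(
            f"target_count {config.target_count} infeasible: at most {feasible} "
            f"pairs available given the universe and exclusions"
        )
    rng = np.random.default_rng(config.seed)
    universe = sorted(config.universe)
    n = len(universe)
    excluded = config.excluded.pairs

    chosen: set[Pair] = set()
    if config.target_count > feasible // 2:
        all_pairs = [
            p
            for p in itertools.combinations(universe, 2)
            if p not in excluded
        ]
        idx = rng.choice(len(all_pairs), size=config.target_count, replace=False)
        chosen = {all_pairs[i] for i in sorted(idx)}
    else:
        while len(chosen) < config.target_count:
            need = config.target_count - len(chosen)
            ii = rng.integers(0, n, size=2 * need + 8)
            jj = rng.integers(0, n, size=2 * need + 8)
            for i, j in zip(ii, jj):
                if i == j:
                    continue
                a, b = universe[i], universe[j]
                pair = (a, b) if a < b else (b, a)
                if pair in excluded or pair in chosen:
                    continue
                chosen.add(pair)
                if len(chosen) == config.target_count:
                    break
    return InteractionSet(
        label="random",
        pairs=frozenset(chosen),
        source_note=f"{config.target_count} random pairs, seed={config.seed}",
    )


def shuffle_interactome(edges: InteractionSet, seed: int) -> InteractionSet:
    """Permute node labels of a network uniformly at random.

    The returned set has exactly the input's edge count and degree multiset
    (the permutation is a graph isomorphism onto relabelled nodes); only
    protein identity is randomised, which severs any relation between a
    node's translational parameters and its neighbourhood.
    """
    if not edges.pairs:
        raise ValueError("cannot shuffle an empty interaction set")
    nodes = sorted(edges.proteins)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(nodes))
    relabel = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    pairs = frozenset(
        (na, nb) if na < nb else (nb, na)
        for na, nb in ((relabel[a], relabel[b]) for a, b in edges.pairs)
    )
    return InteractionSet(
        label="shuffled",
        pairs=pairs,
        source_note=f"label-shuffled {edges.label}, seed={seed}",
    )


def shuffle_operons(groups: GroupTable, seed: int) -> InteractionSet:
    """Shuffle gene-to-operon assignment and expand the false operons.

    Group sizes are preserved exactly: the pooled membership list is
    permuted and re-sliced into groups of the original sizes, then all
    member pairs are extracted from each false operon.
    """
    if len(groups) == 0:
        raise ValueError("cannot shuffle an empty group table")
    gids = sorted(groups.groups)
    pool = [m for gid in gids for m in groups.groups[gid]]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    shuffled_pool = [pool[i] for i in perm]
    false_groups: dict[str, tuple[str, ...]] = {}
    offset = 0
    for gid in gids:
        k = len(groups.groups[gid])
        members = shuffled_pool[offset : offset + k]
        offset += k
        # a gene drawn twice into one false operon (possible when it sits in
        # several real operons) is collapsed; sizes are preserved as multisets
        # of assignments, pair expansion needs unique members
        false_groups[gid] = tuple(dict.fromkeys(members))
    false_table = GroupTable(groups=false_groups)
    out = expand_group_pairs(false_table, label="shuffled")
    return InteractionSet(
        label="shuffled",
        pairs=out.pairs,
        source_note=f"operon-shuffled, seed={seed}",
    )


def hub_matched_controls(
    hubs: list[str],
    network: InteractionSet,
    table: ParamsTable,
    parameter: str = "R",
    seed: int = 0,
) -> InteractionSet:
    """Degree-matched random partner sets for a list of hubs.

    For each hub carrying ``parameter``, draw — without replacement, from
    the universe of proteins carrying ``parameter`` — exactly as many random
    partners as the hub has analyzable real neighbours in ``network``. Hubs
    absent from the network, or with no analyzable neighbours, contribute
    nothing. The hub's true partners are *not* excluded from the candidate
    universe; collisions with real edges are logged.
    """
    universe = sorted(table.genes_with(parameter))
    universe_set = set(universe)
    adjacency: dict[str, set[str]] = {}
    for a, b in network.pairs:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    rng = np.random.default_rng(seed)
    pairs: set[Pair] = set()
    collisions = 0
    for hub in sorted(set(hubs)):
        if hub not in universe_set:
            continue
        neighbors = adjacency.get(hub, set())
        n = sum(1 for v in neighbors if v in universe_set)
        if n == 0:
            continue
        candidates = [g for g in universe if g != hub]
        if len(candidates) < n:
            raise ValueError(
                f"hub {hub!r} needs {n} partners but only {len(candidates)} candidates exist"
            )
        idx = rng.choice(len(candidates), size=n, replace=False)
        for i in idx:
            partner = candidates[i]
            pair = (hub, partner) if hub < partner else (partner, hub)
            if pair in network.pairs:
                collisions += 1
            pairs.add(pair)
    if collisions:
        logger.info("hub controls: %d sampled pair(s) coincide with real edges", collisions)
    return InteractionSet(
        label="hub-control",
        pairs=frozenset(pairs),
        source_note=f"{len(pairs)} degree-matched control pairs, seed={seed}",
    )
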