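"""Window-based gene-set co-enrichment on an importance-sorted gene list.

Given per-gene contribution scores, the genes scoring in the top
(100 - p)% form the universe (p in {50, 70, 90}); the universe is sorted by
score, the window size is W = floor(N / 10), and for each gene set the
*anchor* is the member appearing earliest in the sorted list.  The set's
co-enrichment fraction is the share of its other members lying within +/- W
positions of the anchor.  The same statistic on randomly permuted orderings
of the universe gives a null; the permutation p-value is
(1 + #{permutation mean >= observed mean}) / (R + 1).

Gene sets are read from / written to GMT files (one set per line:
name <tab> description <tab> member...), filtered to >= 30 members present
in the scored universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 30
WINDOW_DIVISOR = 10
PERCENTILES = (50, 70, 90)


@dataclass
class GeneSetCollection:
    sets: dict  # name -> list of member genes
    min_size_applied: bool = False

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets)

    def to_gmt(self, path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, description, *members]) + "\n")

    def filtered(self, universe, min_size: int = MIN_SET_SIZE) -> "GeneSetCollection":
        """Keep sets with >= min_size members inside the scored universe."""
        uni = set(universe)
        kept = {
            name: [g for g in members if g in uni]
            for name, members in self.sets.items()
        }
        kept = {n: m for n, m in kept.items() if len(m) >= min_size}
        return GeneSetCollection(kept, min_size_applied=True)


@dataclass
class CoenrichmentReport:
    percentile: float
    n_input_genes: int
    window_size: int
    set_fractions: dict  # set name -> fraction on the sorted list
    random_fractions: dict  # set name -> mean fraction over permutations
    mean_sorted_fraction: float
    mean_random_fraction: float
    p_value: float
    n_permutations: int
    anchors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "n_input_genes": self.n_input_genes,
            "window_size": self.window_size,
            "set_fractions": {k: float(v) for k, v in self.set_fractions.items()},
            "random_fractions": {k: float(v) for k, v in self.random_fractions.items()},
            "mean_sorted_fraction": float(self.mean_sorted_fraction),
            "mean_random_fraction": float(self.mean_random_fraction),
            "p_value": float(self.p_value),
            "n_permutations": self.n_permutations,
            "anchors": self.anchors,
        }


def select_percentile(scores, names, percentile: float) -> list[str]:
    """Genes scoring at or above the given percentile, sorted by rank.

    Rank-based: the top floor(n * (1 - p/100)) genes by score, descending,
    ties broken by name.  From 13 960 genes the 50th/70th/90th percentiles
    select 6980, 4188 and 1396 genes.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    names = list(names)
    k = int(np.floor(len(names) * (100 - percentile) / 100 + 1e-9))
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return [names[i] for i in order[:k]]


def window_size(n_genes: int) -> int:
    """W = floor(N / 10) (698, 418, 139 for N = 6980, 4188, 1396)."""
    return n_genes // WINDOW_DIVISOR


def window_fraction(ordered_genes, set_members, W: int) -> float | None:
    """Fraction of a set's members within +/- W of its anchor in the ordered list.

    The anchor is the member appearing earliest; it is excluded from the
    denominator.  Returns None (and logs) when fewer than 2 members are in
    the list.
    """
    pos = {g: i for i, g in enumerate(ordered_genes)}
    member_pos = sorted(pos[g] for g in set_members if g in pos)
    if len(member_pos) < 2:
        logger.info("set skipped: fewer than 2 members in universe")
        return None
    anchor = member_pos[0]
    near = sum(1 for p in member_pos[1:] if abs(p - anchor) <= W)
    return near / (len(member_pos) - 1)


def _pooled_fraction(ordered, sets: dict, W: int) -> float:
    """Pool near-anchor counts across sets instead of averaging fractions."""
    pos = {g: i for i, g in enumerate(ordered)}
    near = total = 0
    for members in sets.values():
        mp = sorted(pos[g] for g in members if g in pos)
        if len(mp) < 2:
            continue
        near += sum(1 for p in mp[1:] if abs(p - mp[0]) <= W)
        total += len(mp) - 1
    return near / total if total else np.nan


def coenrichment_test(
    scores,
    names,
    collection: GeneSetCollection,
    percentile: float,
    R: int = 100,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
    pooled: bool = False,
) -> CoenrichmentReport:
    """Sorted-list co-enrichment versus a permutation null.

    The universe is the percentile-selected gene list (already
    score-sorted); each permutation reshuffles the same universe and
    re-applies the identical anchor/window statistic.  ``pooled=True``
    pools member counts across sets rather than averaging per-set
    fractions (the per-set mean is the default summary).
    """
    universe = select_percentile(scores, names, percentile)
    coll = collection if collection.min_size_applied else collection.filtered(
        universe, min_size
    )
    coll = coll.filtered(universe, min_size)
    if not coll.sets:
        raise ValueError("no gene set has enough members in the selected universe")
    N = len(universe)
    W = window_size(N)

    set_fracs, anchors = {}, {}
    pos = {g: i for i, g in enumerate(universe)}
    for name, members in coll.sets.items():
        frac = window_fraction(universe, members, W)
        if frac is None:
            continue
        set_fracs[name] = frac
        anchors[name] = universe[min(pos[g] for g in members if g in pos)]
    if pooled:
        observed = _pooled_fraction(universe, coll.sets, W)
    else:
        observed = float(np.mean(list(set_fracs.values())))

    rng = np.random.default_rng(seed)
    uni_arr = np.array(universe, dtype=object)
    perm_means = np.empty(R)
    rand_sums = {name: 0.0 for name in set_fracs}
    for r in range(R):
        perm = list(uni_arr[rng.permutation(N)])
        fracs = []
        for name in set_fracs:
            f = window_fraction(perm, coll.sets[name], W)
            fracs.append(f)
            rand_sums[name] += f
        perm_means[r] = (
            _pooled_fraction(perm, coll.sets, W) if pooled else np.mean(fracs)
        )
    p_value = (1 + int((perm_means >= observed).sum())) / (R + 1)

    return CoenrichmentReport(
        percentile=percentile,
        n_input_genes=N,
        window_size=W,
        set_fractions=set_fracs,
        random_fractions={n: s / R for n, s in rand_sums.items()},
        mean_sorted_fraction=observed,
        mean_random_fraction=float(perm_means.mean()),
        p_value=p_value,
        n_permutations=R,
        anchors=anchors,
    )
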