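"""Maximal dependence decomposition of aligned fragments into motif subgroups.

A chi-square statistic over a 5x5 contingency table of amino-acid property
groups measures the dependence between every pair of window positions.  The
fragment set is recursively split on the position whose summed pairwise
dependence is largest (provided at least one pairing exceeds the chi-square
threshold), into fragments that carry the dominant property group at that
position and the rest, until subgroups fall below the maximum cluster size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sequence_io import AA20, PAD, Fragment

GROUP_NAMES = ("polar", "acidic", "basic", "hydrophobic", "aromatic")

#: Default 5-way property grouping of the 20 standard residues.
DEFAULT_GROUPS: dict[str, str] = {
    **{aa: "polar" for aa in "GSTCQN"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "hydrophobic" for aa in "AVLIMP"},
    **{aa: "aromatic" for aa in "FWY"},
}


@dataclass(frozen=True)
class AAGroupScheme:
    """Mapping of the 20 standard residues onto 5 property groups."""

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    group_names: tuple[str, ...] = GROUP_NAMES

    def __post_init__(self) -> None:
        if len(self.group_names) != 5:
            raise ValueError("exactly 5 property groups are required")
        missing = set(AA20) - set(self.mapping)
        if missing:
            raise ValueError(f"residues not mapped to a group: {sorted(missing)}")
        bad = set(self.mapping.values()) - set(self.group_names)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")

    def group_index(self, aa: str) -> int | None:
        """0-4 for a standard residue, None for 'X'."""
        group = self.mapping.get(aa)
        return None if group is None else self.group_names.index(group)

    def residues_of(self, group: str) -> frozenset[str]:
        return frozenset(aa for aa, g in self.mapping.items() if g == group)


DEFAULT_SCHEME = AAGroupScheme()


@dataclass
class MDDConfig:
    chi2_threshold: float = 34.3
    max_cluster_size: int = 205
    min_subgroup_size: int = 2
    n: int = 10

    def __post_init__(self) -> None:
        if self.chi2_threshold <= 0:
            raise ValueError("chi2_threshold must be > 0")
        if not self.max_cluster_size >= self.min_subgroup_size >= 1:
            raise ValueError("need max_cluster_size >= min_subgroup_size >= 1")


@dataclass(frozen=True)
class ContingencyTable:
    """5x5 property-group counts for a window position pair."""

    counts: np.ndarray
    offset_i: int
    offset_j: int

    def __post_init__(self) -> None:
        if self.counts.shape != (5, 5):
            raise ValueError("contingency table must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _group_matrix(fragments: Sequence[Fragment], scheme: AAGroupScheme) -> np.ndarray:
    """|fragments| x (2n+1) matrix of group indices; -1 marks 'X'."""
    if not fragments:
        return np.zeros((0, 0), dtype=np.int8)
    lut = np.full(91, -1, dtype=np.int8)
    for aa in AA20:
        lut[ord(aa)] = scheme.group_index(aa)
    rows = [lut[np.frombuffer(f.residues.encode(), dtype=np.uint8)] for f in fragments]
    return np.vstack(rows)


def build_contingency(
    fragments: Sequence[Fragment],
    offset_i: int,
    offset_j: int,
    scheme: AAGroupScheme = DEFAULT_SCHEME,
) -> ContingencyTable:
    """Count property-group co-occurrences at two window offsets.

    The site offset 0 is always the centered cysteine and is not a valid
    test position; fragments with 'X' at either offset are skipped.
    """
    if offset_i == offset_j:
        raise ValueError("offsets must differ")
    if not fragments:
        raise ValueError("empty fragment set")
    n = fragments[0].n
    for off in (offset_i, offset_j):
        if off == 0 or not -n <= off <= n:
            raise ValueError(f"offset {off} invalid for half-width {n} (0 excluded)")
    counts = np.zeros((5, 5), dtype=np.int64)
    for f in fragments:
        gi = scheme.group_index(f.residue_at(offset_i))
        gj = scheme.group_index(f.residue_at(offset_j))
        if gi is not None and gj is not None:
            counts[gi, gj] += 1
    return ContingencyTable(counts, offset_i, offset_j)


def _chi2_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        raise ValueError("chi-square undefined for an empty table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    mask = expected > 0
    return float(((counts[mask] - expected[mask]) ** 2 / expected[mask]).sum())


def chi_square(table: ContingencyTable) -> float:
    """Pearson chi-square of the 5x5 table; zero-expectation cells
    contribute 0."""
    return _chi2_from_counts(np.asarray(table.counts, dtype=float))


def _group_scores(counts: np.ndarray) -> np.ndarray:
    """Per-group dependence scores used to pick the split group.

    For each row group the table is collapsed to 2x5 (group vs rest) and
    the chi-square of the collapsed table taken; this measures how much of
    the dependence is explained by presence/absence of that group alone and
    is robust to groups with very different background frequencies.
    """
    total = counts.sum()
    scores = np.zeros(counts.shape[0])
    if total <= 0:
        return scores
    for m in range(counts.shape[0]):
        rest = counts.sum(axis=0) - counts[m]
        collapsed = np.vstack([counts[m], rest])
        scores[m] = _chi2_from_counts(collapsed)
    return scores


def _pair_tables(groups: np.ndarray, n: int) -> dict[tuple[int, int], np.ndarray]:
    """5x5 count tables for every ordered offset pair (i, j), i != j, 0
    excluded; rows with 'X' at either offset are dropped per pair."""
    offsets = [o for o in range(-n, n + 1) if o != 0]
    tables: dict[tuple[int, int], np.ndarray] = {}
    for a in range(len(offsets)):
        for b in range(a + 1, len(offsets)):
            oi, oj = offsets[a], offsets[b]
            ci = groups[:, n + oi]
            cj = groups[:, n + oj]
            valid = (ci >= 0) & (cj >= 0)
            flat = np.bincount(ci[valid] * 5 + cj[valid], minlength=25)
            t = flat.reshape(5, 5).astype(float)
            tables[(oi, oj)] = t
            tables[(oj, oi)] = t.T
    return tables


def select_split(
    fragments: Sequence[Fragment],
    scheme: AAGroupScheme = DEFAULT_SCHEME,
    config: MDDConfig | None = None,
) -> tuple[int, str] | None:
    """Choose the (offset, property group) of maximal positional dependence.

    For each candidate offset i the dependence score is D(i) = sum over
    j != i of chi2(i, j); an offset is eligible only if some pairing
    exceeds ``config.chi2_threshold``.  Among eligible offsets the one with
    maximal D wins (ties: smaller |offset|, then the negative one).  The
    split group is the one whose presence/absence at that offset explains
    the most dependence (largest group-vs-rest collapsed chi-square summed
    over the offset's pairings).  Returns None when nothing is eligible or
    the set is smaller than ``min_subgroup_size``.
    """
    config = config or MDDConfig(n=fragments[0].n if fragments else 10)
    if len(fragments) < config.min_subgroup_size:
        return None
    n = fragments[0].n
    groups = _group_matrix(fragments, scheme)
    tables = _pair_tables(groups, n)
    offsets = [o for o in range(-n, n + 1) if o != 0]

    best: tuple[float, int, int] | None = None  # (-D, |offset|, sign-rank)
    best_offset: int | None = None
    for oi in offsets:
        chis = {}
        for oj in offsets:
            if oj == oi:
                continue
            t = tables[(oi, oj)]
            if t.sum() <= 0:
                continue
            chis[oj] = _chi2_from_counts(t)
        if not chis or max(chis.values()) <= config.chi2_threshold:
            continue
        d_score = sum(chis.values())
        key = (-d_score, abs(oi), 0 if oi < 0 else 1)
        if best is None or key < best:
            best = key
            best_offset = oi
    if best_offset is None:
        return None

    scores = np.zeros(5)
    for oj in offsets:
        if oj == best_offset:
            continue
        t = tables[(best_offset, oj)]
        if t.sum() > 0:
            scores += _group_scores(t)
    group = scheme.group_names[int(np.argmax(scores))]
    return best_offset, group


# ---------------------------------------------------------------------------
# Recursive decomposition tree
# ---------------------------------------------------------------------------


@dataclass
class MDDNode:
    """Leaf (subgroup id + members) or internal split node."""

    members: list[Fragment] = field(default_factory=list)
    size: int = 0
    subgroup_id: str | None = None
    split_offset: int | None = None
    split_group: str | None = None
    match_child: "MDDNode | None" = None
    rest_child: "MDDNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_offset is None


@dataclass
class MDDTree:
    root: MDDNode
    config: MDDConfig
    scheme: AAGroupScheme = DEFAULT_SCHEME

    def leaves(self) -> list[MDDNode]:
        out: list[MDDNode] = []

        def walk(node: MDDNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.match_child)
                walk(node.rest_child)

        walk(self.root)
        return out

    def splits(self) -> list[tuple[int, str]]:
        out: list[tuple[int, str]] = []

        def walk(node: MDDNode) -> None:
            if not node.is_leaf:
                out.append((node.split_offset, node.split_group))
                walk(node.match_child)
                walk(node.rest_child)

        walk(self.root)
        return out


def mdd_cluster(
    fragments: Sequence[Fragment],
    scheme: AAGroupScheme = DEFAULT_SCHEME,
    config: MDDConfig | None = None,
) -> MDDTree:
    """Recursively partition *fragments* into motif subgroups.

    A node smaller than ``max_cluster_size``, or one where no position pair
    passes the dependence threshold, becomes a leaf.  Otherwise the set is
    split into fragments carrying the selected group at the selected offset
    and the rest.  Leaf ids are assigned depth-first, match branch first,
    as "Palm1", "Palm2", ...
    """
    if not fragments:
        raise ValueError("cannot cluster an empty fragment set")
    config = config or MDDConfig(n=fragments[0].n)

    def build(members: list[Fragment]) -> MDDNode:
        node = MDDNode(members=members, size=len(members))
        if len(members) < config.max_cluster_size:
            return node
        choice = select_split(members, scheme, config)
        if choice is None:
            return node
        offset, group = choice
        residues = scheme.residues_of(group)
        match = [f for f in members if f.residue_at(offset) in residues]
        rest = [f for f in members if f.residue_at(offset) not in residues]
        if not match or not rest:
            return node
        node.split_offset = offset
        node.split_group = group
        node.match_child = build(match)
        node.rest_child = build(rest)
        node.members = []
        return node

    tree = MDDTree(build(list(fragments)), config, scheme)
    for k, leaf in enumerate(tree.leaves(), start=1):
        leaf.subgroup_id = f"Palm{k}"
    return tree


def assign_subgroup(fragment: Fragment, tree: MDDTree) -> str:
    """Route a fragment down the tree to its motif subgroup id.

    At each split the match child is taken iff the residue at the split
    offset belongs to the split group; 'X' routes to the rest child.
    """
    node = tree.root
    while not node.is_leaf:
        residues = tree.scheme.residues_of(node.split_group)
        aa = fragment.residue_at(node.split_offset)
        node = node.match_child if aa in residues else node.rest_child
    return node.subgroup_id


def tree_to_dict(tree: MDDTree) -> dict:
    def encode(node: MDDNode) -> dict:
        if node.is_leaf:
            return {"leaf": node.subgroup_id, "size": node.size}
        return {
            "split_offset": node.split_offset,
            "split_group": node.split_group,
            "size": node.size,
            "match": encode(node.match_child),
            "rest": encode(node.rest_child),
        }

    return {
        "root": encode(tree.root),
        "config": {
            "chi2_threshold": tree.config.chi2_threshold,
            "max_cluster_size": tree.config.max_cluster_size,
            "min_subgroup_size": tree.config.min_subgroup_size,
            "n": tree.config.n,
        },
        "groups": {aa: g for aa, g in tree.scheme.mapping.items()},
    }


def tree_from_dict(data: dict) -> MDDTree:
    """Rebuild a routable tree (structure only, no member fragments)."""

    def decode(obj: dict) -> MDDNode:
        if "leaf" in obj:
            return MDDNode(size=obj["size"], subgroup_id=obj["leaf"])
        return MDDNode(
            size=obj["size"],
            split_offset=obj["split_offset"],
            split_group=obj["split_group"],
            match_child=decode(obj["match"]),
            rest_child=decode(obj["rest"]),
        )

    scheme = AAGroupScheme(mapping=dict(data["groups"]))
    return MDDTree(decode(data["root"]), MDDConfig(**data["config"]), scheme)


def write_tree(tree: MDDTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=2)


def read_tree(path: str | Path) -> MDDTree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Composition analysis
# ---------------------------------------------------------------------------


def position_frequency_matrix(fragments: Sequence[Fragment]):
    """Symbol-frequency matrix per window offset (shared with the PWM
    builder)."""
    from .features import build_pwm

    return build_pwm(fragments)


def composition_enrichment(
    pos_fragments: Sequence[Fragment],
    neg_fragments: Sequence[Fragment],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-(offset, residue) enrichment of positives over negatives.

    A two-sided two-proportion z-test compares occurrence frequencies at
    every non-center offset; rows with p < alpha are flagged "enriched"
    (positive frequency higher) or "depleted".  Returns a DataFrame with
    columns offset, residue, pos_freq, neg_freq, z, pvalue, direction.
    """
    if not pos_fragments or not neg_fragments:
        raise ValueError("both fragment sets must be non-empty")
    n = pos_fragments[0].n
    if neg_fragments[0].n != n:
        raise ValueError("fragment sets have different window sizes")
    n1, n2 = len(pos_fragments), len(neg_fragments)
    rows = []
    for offset in range(-n, n + 1):
        if offset == 0:
            continue
        for aa in AA20:
            k1 = sum(f.residue_at(offset) == aa for f in pos_fragments)
            k2 = sum(f.residue_at(offset) == aa for f in neg_fragments)
            p1, p2 = k1 / n1, k2 / n2
            pooled = (k1 + k2) / (n1 + n2)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            z = 0.0 if se == 0 else (p1 - p2) / se
            pvalue = 2 * norm.sf(abs(z))
            if pvalue < alpha:
                direction = "enriched" if p1 > p2 else "depleted"
            else:
                direction = "ns"
            rows.append((offset, aa, p1, p2, z, pvalue, direction))
    return pd.DataFrame(
        rows, columns=["offset", "residue", "pos_freq", "neg_freq", "z", "pvalue", "direction"]
    )
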