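"""Seeded generator of cysteine-centered fragment datasets with planted
property-group motifs.

Negatives are i.i.d. draws from a background composition with the center
forced to 'C'.  Each positive is assigned one rule-set by mixture weight;
every rule in the set then, with its own probability, overwrites the
residue at its offset with a uniform draw from the rule's residue set.
Positional dependence between offsets therefore arises from the latent
rule-set assignment: offsets enriched within the same rule-set (or enriched
in one rule-set and background in another) co-vary across the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mdd import DEFAULT_SCHEME, AAGroupScheme
from .sequence_io import AA20, NEGATIVE, POSITIVE, Fragment, FragmentDataset


@dataclass(frozen=True)
class MotifRule:
    """Planted enrichment: at *offset*, with *probability*, a positive
    fragment carries a residue drawn uniformly from the group or residue
    set."""

    offset: int
    group_or_residues: str | frozenset[str]
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("rule offset 0 is the centered cysteine")
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("probability must be in (0, 1]")

    def residues(self, scheme: AAGroupScheme = DEFAULT_SCHEME) -> tuple[str, ...]:
        if isinstance(self.group_or_residues, str) and (
            self.group_or_residues in scheme.group_names
        ):
            return tuple(sorted(scheme.residues_of(self.group_or_residues)))
        return tuple(sorted(set(self.group_or_residues)))


@dataclass
class SyntheticConfig:
    n: int = 10
    n_pos: int = 600
    n_neg: int = 4800
    background: dict[str, float] = field(
        default_factory=lambda: {aa: 1.0 / 20.0 for aa in AA20}
    )
    #: list of (rule list, mixture weight); each positive gets one rule-set
    rules: list[tuple[list[MotifRule], float]] = field(default_factory=list)
    seed: int = 0
    scheme: AAGroupScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be >= 0")
        if self.rules:
            total = sum(w for _, w in self.rules)
            if not np.isclose(total, 1.0):
                raise ValueError(f"rule-set weights must sum to 1, got {total}")
        for rules, _ in self.rules:
            for r in rules:
                if abs(r.offset) > self.n:
                    raise ValueError(f"rule offset {r.offset} outside +/-{self.n}")


def _background_arrays(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(config.background.keys()))
    probs = np.array(list(config.background.values()), dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("degenerate background composition")
    return letters, probs / probs.sum()


def generate(config: SyntheticConfig) -> FragmentDataset:
    """Draw a seeded synthetic :class:`FragmentDataset`."""
    rng = np.random.default_rng(config.seed)
    letters, probs = _background_arrays(config)
    w = 2 * config.n + 1
    center = config.n
    fragments: list[Fragment] = []

    weights = np.array([wt for _, wt in config.rules], dtype=float)
    for i in range(config.n_pos):
        residues = rng.choice(letters, size=w, p=probs)
        residues[center] = "C"
        if config.rules:
            which = rng.choice(len(config.rules), p=weights)
            for rule in config.rules[which][0]:
                if rng.random() < rule.probability:
                    pool = rule.residues(config.scheme)
                    residues[center + rule.offset] = pool[rng.integers(len(pool))]
        fragments.append(Fragment(f"pos{i}", 1000 + i, "".join(residues), POSITIVE))

    for i in range(config.n_neg):
        residues = rng.choice(letters, size=w, p=probs)
        residues[center] = "C"
        fragments.append(Fragment(f"neg{i}", 1000 + i, "".join(residues), NEGATIVE))

    return FragmentDataset(fragments, n=config.n)


def default_palm_config(seed: int = 0) -> SyntheticConfig:
    """Four equal-weight motif classes over a uniform background, focused
    at offsets +10, +4, -1 and +1, each focal position planted with
    probability 0.9; 600 positives, 4800 negatives (1:8).

    Each class also enriches its group at three support offsets with a
    weaker probability, so the class's positions co-vary across the
    mixture — the pairwise dependence that the chi-square decomposition
    detects.  A class confined to one position would leave all position
    pairs independent and be invisible to the test.  All four classes use
    groups with low background frequency (basic, aromatic, acidic); a
    high-background group such as polar makes the match branch absorb
    about half of every node and collapses the tree below four leaves.
    """
    rules = [
        ([MotifRule(10, "basic", 0.9), MotifRule(9, "basic", 0.65),
          MotifRule(8, "basic", 0.65), MotifRule(7, "basic", 0.65)], 0.25),
        ([MotifRule(4, "basic", 0.9), MotifRule(5, "basic", 0.65),
          MotifRule(6, "basic", 0.65), MotifRule(3, "basic", 0.65)], 0.25),
        ([MotifRule(-1, "aromatic", 0.9), MotifRule(-2, "aromatic", 0.65),
          MotifRule(-3, "aromatic", 0.65), MotifRule(-4, "aromatic", 0.65)], 0.25),
        ([MotifRule(1, "acidic", 0.9), MotifRule(2, "acidic", 0.65),
          MotifRule(-5, "acidic", 0.65), MotifRule(-6, "acidic", 0.65)], 0.25),
    ]
    return SyntheticConfig(n=10, n_pos=600, n_neg=4800, rules=rules, seed=seed)


def focal_offsets(config: SyntheticConfig) -> list[int]:
    """The first (focal) rule offset of every non-empty rule-set."""
    return [rules[0].offset for rules, _ in config.rules if rules]


def planted_offsets(config: SyntheticConfig) -> set[int]:
    """All offsets carrying planted enrichment in any rule-set."""
    return {r.offset for rules, _ in config.rules for r in rules}


def single_motif_config(
    seed: int = 0,
    offset: int = 4,
    group: str = "basic",
    probability: float = 0.9,
    n_pos: int = 400,
    n_neg: int = 0,
    carrier_weight: float = 0.5,
    satellite_probability: float = 0.55,
    satellite_count: int = 8,
) -> SyntheticConfig:
    """One planted property-group motif in a carrier subpopulation.

    A fraction ``carrier_weight`` of positives carries the focal group at
    the focal offset with the given probability.  Pairwise positional
    dependence only exists when at least two positions co-vary across the
    carrier/non-carrier mixture, so carriers additionally show the group at
    several high-|offset| satellite positions with a weaker probability;
    the focal offset then dominates every dependence score while remaining
    the single strong motif position.
    """
    candidates = [
        o
        for o in sorted(range(-10, 11), key=lambda o: (-abs(o), o < 0))
        if o not in (0, offset)
    ]
    rules = [MotifRule(offset, group, probability)] + [
        MotifRule(o, group, satellite_probability)
        for o in candidates[:satellite_count]
    ]
    mixture = [(rules, carrier_weight)]
    if carrier_weight < 1.0:
        mixture.append(([], 1.0 - carrier_weight))
    return SyntheticConfig(n=10, n_pos=n_pos, n_neg=n_neg, rules=mixture, seed=seed)
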