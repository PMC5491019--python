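"""Sequence and site I/O: FASTA reading, window-fragment extraction,
negative-site derivation and fragment-level deduplication.

Fragments are (2n+1)-mer peptide windows centered on a candidate cysteine,
with 'X' padding where the window runs past a protein terminus.  Positions
are 1-based in all I/O; window offsets run -n..+n with 0 at the site.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

#: The 20 standard amino-acid one-letter codes, alphabetical.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Padding / unknown-residue symbol.
PAD = "X"
#: Full fragment alphabet (20 standard letters + 'X').
SYMBOLS21 = AA20 + PAD

_AA20_SET = frozenset(AA20)

POSITIVE = "positive"
NEGATIVE = "negative"


def sanitize_sequence(raw: str) -> str:
    """Uppercase *raw* and map every non-standard letter (B, Z, J, U, O,
    '*', ...) to 'X'."""
    up = raw.upper()
    return "".join(c if c in _AA20_SET else PAD for c in up)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    protein_id: str
    position: int  # 1-based
    label: str = POSITIVE

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class Fragment:
    """A (2n+1)-mer window centered at ``site_position`` of a protein."""

    protein_id: str
    site_position: int  # 1-based
    residues: str
    label: str

    def __post_init__(self) -> None:
        if len(self.residues) % 2 != 1:
            raise ValueError("fragment length must be odd (2n+1)")
        bad = set(self.residues) - set(SYMBOLS21)
        if bad:
            raise ValueError(f"fragment contains non-alphabet symbols {bad}")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def n(self) -> int:
        return len(self.residues) // 2

    @property
    def center(self) -> str:
        return self.residues[self.n]

    def residue_at(self, offset: int) -> str:
        """Residue at window offset in -n..+n (0 = site)."""
        if not -self.n <= offset <= self.n:
            raise IndexError(f"offset {offset} outside window +/-{self.n}")
        return self.residues[self.n + offset]

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.site_position)


@dataclass
class FragmentDataset:
    fragments: list[Fragment] = field(default_factory=list)
    n: int = 10

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for f in self.fragments:
            if f.n != self.n:
                raise ValueError(
                    f"fragment {f.key} has half-width {f.n}, dataset expects {self.n}"
                )
            if f.key in seen:
                raise ValueError(f"duplicate fragment site {f.key}")
            seen.add(f.key)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    @property
    def positives(self) -> list[Fragment]:
        return [f for f in self.fragments if f.is_positive]

    @property
    def negatives(self) -> list[Fragment]:
        return [f for f in self.fragments if not f.is_positive]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and non-standard letters mapped to 'X'.
    Raises ``ValueError`` on an empty file or duplicate ids.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read a site TSV: ``protein_id<TAB>position[<TAB>label]``.

    Lines starting with '#' are skipped; a missing label defaults to
    positive.
    """
    sites: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            pid, pos = parts[0], parts[1]
            label = parts[2] if len(parts) > 2 and parts[2] else POSITIVE
            try:
                position = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {pos!r}") from exc
            sites.append(SiteAnnotation(pid, position, label))
    return sites


def write_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")


def extract_fragment(
    protein: ProteinRecord,
    position: int,
    n: int,
    label: str = POSITIVE,
    strict_center: bool = True,
) -> Fragment:
    """Extract the (2n+1)-mer window centered at the 1-based *position*.

    Out-of-range flanks are padded with 'X'.  With ``strict_center`` the
    centered residue must be 'C'.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"position {position} out of range for protein {protein.id!r} "
            f"(length {len(seq)})"
        )
    if strict_center and seq[position - 1] != "C":
        raise ValueError(
            f"site {protein.id}:{position} is {seq[position - 1]!r}, expected 'C'"
        )
    i = position - 1
    left = seq[max(0, i - n) : i]
    right = seq[i + 1 : i + 1 + n]
    residues = PAD * (n - len(left)) + left + seq[i] + right + PAD * (n - len(right))
    return Fragment(protein.id, position, residues, label)


def build_dataset(
    proteins: Sequence[ProteinRecord],
    positive_annotations: Sequence[SiteAnnotation],
    n: int = 10,
    strict_center: bool = True,
) -> FragmentDataset:
    """Build positive fragments from annotated sites and negative fragments
    from every other cysteine of the annotated proteins."""
    by_id = {p.id: p for p in proteins}
    if len(by_id) != len(proteins):
        raise ValueError("duplicate protein ids")
    positives_by_protein: dict[str, set[int]] = {}
    for ann in positive_annotations:
        if ann.protein_id not in by_id:
            raise ValueError(f"annotation references unknown protein {ann.protein_id!r}")
        positives_by_protein.setdefault(ann.protein_id, set()).add(ann.position)

    fragments: list[Fragment] = []
    for pid, pos_sites in positives_by_protein.items():
        protein = by_id[pid]
        for pos in sorted(pos_sites):
            fragments.append(
                extract_fragment(protein, pos, n, POSITIVE, strict_center=strict_center)
            )
        for i, aa in enumerate(protein.sequence, start=1):
            if aa == "C" and i not in pos_sites:
                fragments.append(extract_fragment(protein, i, n, NEGATIVE))
    return FragmentDataset(fragments, n=n)


def fragment_identity(a: Fragment, b: Fragment) -> float:
    """Fraction of matching window positions ('X' matches only 'X')."""
    if len(a.residues) != len(b.residues):
        raise ValueError("fragments have different window sizes")
    matches = sum(x == y for x, y in zip(a.residues, b.residues))
    return matches / len(a.residues)


def _greedy_cluster(fragments: list[Fragment], threshold: float) -> list[Fragment]:
    """Greedy single-linkage representative selection at identity >= threshold,
    keeping the first member (input order) of each cluster."""
    reps: list[Fragment] = []
    for frag in fragments:
        if not any(fragment_identity(frag, rep) >= threshold for rep in reps):
            reps.append(frag)
    return reps


def deduplicate(
    dataset: FragmentDataset,
    identity_threshold: float = 1.0,
    cdhit_order: bool = False,
) -> FragmentDataset:
    """Remove cross-set duplicates and cluster homologous fragments.

    First, any negative fragment whose residues equal those of some positive
    fragment is dropped (the positive is always kept).  Then each label
    class is greedily clustered at ``identity_threshold`` and only cluster
    representatives are retained.  With ``cdhit_order`` fragments are
    pre-sorted lexicographically by residues (a stand-in for CD-HIT's
    length-then-lexicographic convention; windows all share one length)
    before the greedy pass; otherwise input order decides representatives.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    positive_residues = {f.residues for f in dataset.positives}
    positives = list(dataset.positives)
    negatives = [f for f in dataset.negatives if f.residues not in positive_residues]
    if cdhit_order:
        positives = sorted(positives, key=lambda f: f.residues)
        negatives = sorted(negatives, key=lambda f: f.residues)
    kept = _greedy_cluster(positives, identity_threshold) + _greedy_cluster(
        negatives, identity_threshold
    )
    order = {f.key: i for i, f in enumerate(dataset.fragments)}
    kept.sort(key=lambda f: order[f.key])
    return FragmentDataset(kept, n=dataset.n)


def write_fragments(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Export fragments as ``protein_id<TAB>position<TAB>fragment<TAB>label``."""
    with open(path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for f in fragments:
            writer.writerow([f.protein_id, f.site_position, f.residues, f.label])


def read_fragments(path: str | Path) -> FragmentDataset:
    """Read the fragment TSV written by :func:`write_fragments`."""
    fragments: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            pid, pos, residues, label = parts
            fragments.append(Fragment(pid, int(pos), residues, label))
    if not fragments:
        raise ValueError(f"no fragments found in {path}")
    return FragmentDataset(fragments, n=fragments[0].n)
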