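"""Numeric feature encodings for cysteine-centered fragments.

Schemes
-------
``binary``    one-hot over the 20 standard residues per window position,
              (2n+1) x 20 values; 'X' encodes as an all-zero block.
``aac``       relative frequencies of the 21 symbols in the window.
``aapc``      relative frequencies of ordered adjacent symbol pairs, 21x21.
``blosum62``  the BLOSUM62 substitution-score row of the observed residue
              per position; 'X' encodes as zeros.
``pwm``       per-position relative-frequency lookup in a position weight
              matrix built from positive fragments, length 2n+1.
``pssm``      the window profile rows grouped by residue type into a 20x20
              matrix, divided by the window length and squashed through the
              logistic function, flattened to 400 values.
``asa``       per-position accessible-surface-area percentages scaled to
              [0, 1]; padding and missing residues are 0.

Feature matrices are min-max scaled to [-1, +1] with a scaler fitted on
training data only (constant columns map to 0; unseen out-of-range values
are clipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_io import AA20, PAD, SYMBOLS21, Fragment

_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS21)}
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 rows for the 20 standard residues, columns in AA20 order.
BLOSUM62_ROWS = np.array(
    [[float(_BLOSUM62[a][b]) for b in AA20] for a in AA20], dtype=float
)


def _offsets(n: int) -> list[int]:
    return list(range(-n, n + 1))


# ---------------------------------------------------------------------------
# Single-fragment encoders
# ---------------------------------------------------------------------------


def encode_binary(fragment: Fragment) -> np.ndarray:
    """One-hot (2n+1) x 20 encoding; 'X' gives an all-zero block."""
    w = len(fragment.residues)
    out = np.zeros((w, 20), dtype=float)
    for i, aa in enumerate(fragment.residues):
        j = _AA_INDEX.get(aa)
        if j is not None:
            out[i, j] = 1.0
    return out.ravel()

def encode_aac(fragment: Fragment) -> np.ndarray:
    """Relative frequencies of the 21 symbols over the window (sums to 1)."""
    counts = np.zeros(21, dtype=float)
    for aa in fragment.residues:
        counts[_SYM_INDEX[aa]] += 1.0
    return counts / len(fragment.residues)

def encode_aapc(fragment: Fragment) -> np.ndarray:
    """Relative frequencies of ordered adjacent symbol pairs, 441 values
    (sums to 1 over the 2n adjacent pairs)."""
    counts = np.zeros((21, 21), dtype=float)
    res = fragment.residues
    for a, b in zip(res, res[1:]):
        counts[_SYM_INDEX[a], _SYM_INDEX[b]] += 1.0
    return counts.ravel() / (len(res) - 1)

def encode_blosum62(fragment: Fragment) -> np.ndarray:
    """Per-position BLOSUM62 substitution-score rows, (2n+1) x 20; 'X'
    positions are zero rows."""
    w = len(fragment.residues)
    out = np.zeros((w, 20), dtype=float)
    for i, aa in enumerate(fragment.residues):
        j = _AA_INDEX.get(aa)
        if j is not None:
            out[i] = BLOSUM62_ROWS[j]
    return out.ravel()


# ---------------------------------------------------------------------------
# Position weight matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PWMatrix:
    """Relative frequency of each of the 21 symbols at each window offset.

    ``entries`` has shape (21, 2n+1); rows follow :data:`SYMBOLS21`,
    columns follow offsets -n..+n.  Every column sums to 1.
    """

    entries: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.entries.shape != (21, 2 * self.n + 1):
            raise ValueError("PWM shape must be (21, 2n+1)")

    def frequency(self, symbol: str, offset: int) -> float:
        return float(self.entries[_SYM_INDEX[symbol], self.n + offset])


def build_pwm(fragments: Sequence[Fragment]) -> PWMatrix:
    """Position weight matrix of symbol frequencies over *fragments*."""
    if not fragments:
        raise ValueError("cannot build a PWM from an empty fragment set")
    n = fragments[0].n
    counts = np.zeros((21, 2 * n + 1), dtype=float)
    for f in fragments:
        if f.n != n:
            raise ValueError("fragments have mixed window sizes")
        for i, aa in enumerate(f.residues):
            counts[_SYM_INDEX[aa], i] += 1.0
    return PWMatrix(counts / len(fragments), n)


def encode_pwm(fragment: Fragment, pwm: PWMatrix) -> np.ndarray:
    """Per-position PWM frequency of the observed residue, length 2n+1."""
    if fragment.n != pwm.n:
        raise ValueError("fragment and PWM have different window sizes")
    return np.array(
        [pwm.frequency(fragment.residue_at(o), o) for o in _offsets(pwm.n)]
    )


def write_pwm(pwm: PWMatrix, path: str | Path) -> None:
    """Export as TSV, one row per symbol, columns labeled by offset."""
    with open(path, "w") as fh:
        header = "\t".join(str(o) for o in _offsets(pwm.n))
        fh.write(f"symbol\t{header}\n")
        for i, sym in enumerate(SYMBOLS21):
            row = "\t".join(f"{v:.10g}" for v in pwm.entries[i])
            fh.write(f"{sym}\t{row}\n")


# ---------------------------------------------------------------------------
# PSSM profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSSMProfile:
    """Per-window-position scores for the 20 standard residues.

    ``scores`` has shape (2n+1, 20); rows follow offsets -n..+n, columns
    follow :data:`AA20`.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        rows, cols = self.scores.shape
        if cols != 20 or rows % 2 != 1:
            raise ValueError("PSSM profile must be (2n+1) x 20")

    @property
    def n(self) -> int:
        return self.scores.shape[0] // 2


def build_internal_pssm(
    fragments: Sequence[Fragment], pseudocount: float = 0.05
) -> PSSMProfile:
    """Log-odds profile of the fragment set against a uniform background.

    score(offset, aa) = log2((freq + pc) / (1/20 + pc)) where freq is the
    relative frequency of *aa* among non-'X' residues at the offset.
    """
    if not fragments:
        raise ValueError("cannot build a profile from an empty fragment set")
    n = fragments[0].n
    counts = np.zeros((2 * n + 1, 20), dtype=float)
    for f in fragments:
        if f.n != n:
            raise ValueError("fragments have mixed window sizes")
        for i, aa in enumerate(f.residues):
            j = _AA_INDEX.get(aa)
            if j is not None:
                counts[i, j] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    freq = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return PSSMProfile(np.log2((freq + pseudocount) / (1.0 / 20.0 + pseudocount)))


def load_pssm(path: str | Path, n: int | None = None) -> PSSMProfile:
    """Parse the ASCII PSSM dialect written by PSI-BLAST.

    Expects data lines of the form ``<pos> <aa> <20 scores> ...``; the
    first 20 numeric columns after the residue letter are taken as the
    log-odds block.  If *n* is given, the central 2n+1 rows are kept.
    """
    rows: list[list[float]] = []
    aa_order: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if aa_order is None and len(parts) >= 20 and all(
                p in _AA_INDEX for p in parts[:20]
            ):
                aa_order = parts[:20]
                continue
            if parts[0].isdigit() and len(parts) >= 22 and parts[1] in _AA_INDEX:
                try:
                    rows.append([float(v) for v in parts[2:22]])
                except ValueError as exc:
                    raise ValueError(f"malformed PSSM line: {line!r}") from exc
    if not rows:
        raise ValueError(f"no PSSM score rows found in {path}")
    if aa_order is None:
        aa_order = list(AA20)
    scores = np.array(rows, dtype=float)
    # reorder columns into AA20 (alphabetical) order
    perm = [aa_order.index(a) for a in AA20]
    scores = scores[:, perm]
    if n is not None:
        w = 2 * n + 1
        if scores.shape[0] < w:
            raise ValueError(
                f"profile has {scores.shape[0]} rows, window needs {w}"
            )
        start = (scores.shape[0] - w) // 2
        scores = scores[start : start + w]
    if scores.shape[0] % 2 == 0:
        raise ValueError("profile row count must be odd (2n+1); pass n to window it")
    return PSSMProfile(scores)


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write the profile in the ASCII dialect accepted by :func:`load_pssm`."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("          " + "   ".join(AA20) + "\n")
        for i, row in enumerate(profile.scores, start=1):
            cells = " ".join(f"{v:7.3f}" for v in row)
            fh.write(f"{i:5d} C  {cells}  0.00 0.00\n")


def encode_pssm(fragment: Fragment, profile: PSSMProfile) -> np.ndarray:
    """Residue-type aggregated, logistic-squashed profile encoding.

    Profile rows are binned by the fragment's residue at each offset ('X'
    rows are discarded), each bin summed into one of 20 rows (alphabetical
    residue order), every element divided by the window length 2n+1, and
    squashed with 1/(1+e^-x).  Flattened to 400 values.
    """
    if fragment.n != profile.n:
        raise ValueError("fragment and profile have different window sizes")
    w = len(fragment.residues)
    binned = np.zeros((20, 20), dtype=float)
    for i, aa in enumerate(fragment.residues):
        j = _AA_INDEX.get(aa)
        if j is not None:
            binned[j] += profile.scores[i]
    binned /= w
    return (1.0 / (1.0 + np.exp(-binned))).ravel()


# ---------------------------------------------------------------------------
# ASA
# ---------------------------------------------------------------------------


def read_asa_table(path: str | Path) -> dict[tuple[str, int], float]:
    """Read a TSV of per-residue ASA percentages:
    ``protein_id<TAB>position<TAB>asa_percent``."""
    table: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            table[(parts[0], int(parts[1]))] = float(parts[2])
    return table


def encode_asa(
    fragment: Fragment, asa_table: Mapping[tuple[str, int], float]
) -> np.ndarray:
    """Per-position ASA percent / 100 clipped to [0, 1]; padding and
    residues missing from the table are 0."""
    n = fragment.n
    out = np.zeros(2 * n + 1, dtype=float)
    for k, offset in enumerate(_offsets(n)):
        if fragment.residue_at(offset) == PAD:
            continue
        value = asa_table.get((fragment.protein_id, fragment.site_position + offset))
        if value is not None:
            out[k] = min(max(value / 100.0, 0.0), 1.0)
    return out


# ---------------------------------------------------------------------------
# Scaling, hybrid concatenation and the fit/transform encoder
# ---------------------------------------------------------------------------


def concat(*vectors: np.ndarray) -> np.ndarray:
    """Concatenate per-scheme vectors of one fragment into a hybrid vector."""
    return np.concatenate([np.asarray(v, dtype=float) for v in vectors])


@dataclass
class FeatureScaler:
    """Column-wise min-max scaling of a training matrix to [-1, +1].

    Constant columns map to 0; at transform time out-of-range values are
    clipped to [-1, +1].
    """

    minimum: np.ndarray | None = None
    maximum: np.ndarray | None = None

    def fit(self, matrix: np.ndarray) -> "FeatureScaler":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] == 0:
            raise ValueError("scaler needs a non-empty 2-D training matrix")
        self.minimum = matrix.min(axis=0)
        self.maximum = matrix.max(axis=0)
        return self

    def _check(self) -> tuple[np.ndarray, np.ndarray]:
        if self.minimum is None or self.maximum is None:
            raise RuntimeError("scaler has not been fitted")
        return self.minimum, self.maximum

    def transform(self, matrix: np.ndarray, clip: bool = True) -> np.ndarray:
        lo, hi = self._check()
        matrix = np.asarray(matrix, dtype=float)
        span = hi - lo
        constant = span == 0
        safe = np.where(constant, 1.0, span)
        out = 2.0 * (matrix - lo) / safe - 1.0
        out[:, constant] = 0.0
        if clip:
            np.clip(out, -1.0, 1.0, out=out)
        return out

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        lo, hi = self._check()
        matrix = np.asarray(matrix, dtype=float)
        span = hi - lo
        constant = span == 0
        out = (matrix + 1.0) / 2.0 * np.where(constant, 0.0, span) + lo
        out[:, constant] = lo[constant]
        return out


def fit_scaler(matrix: np.ndarray) -> FeatureScaler:
    return FeatureScaler().fit(matrix)


def apply_scaler(scaler: FeatureScaler, matrix: np.ndarray) -> np.ndarray:
    return scaler.transform(matrix)


#: Registry fixing hybrid concatenation order and dimensions (for n=10).
SCHEME_ORDER = ("aac", "aapc", "binary", "blosum62", "pwm", "pssm", "asa")


def scheme_dimension(scheme: str, n: int) -> int:
    w = 2 * n + 1
    return {
        "binary": w * 20,
        "aac": 21,
        "aapc": 441,
        "blosum62": w * 20,
        "pwm": w,
        "pssm": 400,
        "asa": w,
    }[scheme]


@dataclass
class FragmentEncoder:
    """Fit/transform wrapper turning fragments into scaled hybrid matrices.

    ``schemes`` are applied in registry order regardless of the order given.
    PWM and PSSM components are fitted on the positive training fragments;
    the [-1, +1] scaler on the full training matrix.
    """

    schemes: tuple[str, ...] = ("aac", "pssm")
    pseudocount: float = 0.05
    asa_table: Mapping[tuple[str, int], float] | None = None
    pwm: PWMatrix | None = None
    pssm: PSSMProfile | None = None
    scaler: FeatureScaler | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.schemes) - set(SCHEME_ORDER)
        if unknown:
            raise ValueError(f"unknown feature schemes {sorted(unknown)}")
        self.schemes = tuple(s for s in SCHEME_ORDER if s in self.schemes)

    def fit(
        self, fragments: Sequence[Fragment], labels: Sequence[int] | None = None
    ) -> "FragmentEncoder":
        if not fragments:
            raise ValueError("cannot fit encoder on an empty fragment set")
        self.n = fragments[0].n
        if labels is None:
            reference = list(fragments)
        else:
            reference = [f for f, y in zip(fragments, labels) if y == 1]
            if not reference:
                reference = list(fragments)
        if "pwm" in self.schemes:
            self.pwm = build_pwm(reference)
        if "pssm" in self.schemes and self.pssm is None:
            self.pssm = build_internal_pssm(reference, self.pseudocount)
        self.scaler = FeatureScaler().fit(self.encode(fragments))
        return self

    def encode(self, fragments: Sequence[Fragment]) -> np.ndarray:
        """Raw (unscaled) hybrid feature matrix."""
        rows = []
        for f in fragments:
            parts = []
            for scheme in self.schemes:
                if scheme == "binary":
                    parts.append(encode_binary(f))
                elif scheme == "aac":
                    parts.append(encode_aac(f))
                elif scheme == "aapc":
                    parts.append(encode_aapc(f))
                elif scheme == "blosum62":
                    parts.append(encode_blosum62(f))
                elif scheme == "pwm":
                    assert self.pwm is not None, "encoder not fitted (pwm)"
                    parts.append(encode_pwm(f, self.pwm))
                elif scheme == "pssm":
                    assert self.pssm is not None, "encoder not fitted (pssm)"
                    parts.append(encode_pssm(f, self.pssm))
                elif scheme == "asa":
                    parts.append(encode_asa(f, self.asa_table or {}))
            rows.append(concat(*parts))
        return np.vstack(rows)

    def transform(self, fragments: Sequence[Fragment]) -> np.ndarray:
        if self.scaler is None:
            raise RuntimeError("encoder has not been fitted")
        return self.scaler.transform(self.encode(fragments))
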