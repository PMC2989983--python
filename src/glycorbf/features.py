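"""Fragment encodings and the F-score feature statistic.

Two feature blocks are produced for a (2n+1)-mer window:

* a BLOSUM62 block: each position contributes the 21-long embedding of its
  residue — the residue's row of the BLOSUM62 substitution matrix, min-max
  normalized to [0, 1] over the whole 20x20 matrix, with a 21st slot reserved
  for the terminal symbol (0 for amino acids, 1 for the terminal symbol whose
  other 20 slots are 0);
* a binary SAAP block: one bit per significant amino-acid pair, set when the
  window carries the anchor residue at the anchor position and any partner-set
  residue at the partner position.

The F-score of a feature is the ratio of between-class to within-class
variation,

    F = [(m+ - m)^2 + (m- - m)^2] / (s+^2 + s-^2),

with m the grand mean, m+/m- the class means and s+^2/s-^2 the unbiased
within-class sample variances.  It is invariant under swapping the class
labels and under affine rescaling of the feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_io import (
    ALPHABET,
    AMINO_ACIDS,
    TERMINAL,
    POSITIVE,
    SiteFragment,
)

#: Columns per window position: 20 amino-acid embedding slots + 1 terminal slot.
SYMBOLS_PER_POSITION = 21


def _build_encoding_table() -> dict[str, np.ndarray]:
    """Per-symbol 21-long embeddings from the normalized BLOSUM62 matrix."""
    blosum = substitution_matrices.load("BLOSUM62")
    raw = np.array(
        [[blosum[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
    )
    lo, hi = raw.min(), raw.max()  # -4 and 11 for the half-bit BLOSUM62
    norm = (raw - lo) / (hi - lo)
    table: dict[str, np.ndarray] = {}
    for i, aa in enumerate(AMINO_ACIDS):
        row = np.zeros(SYMBOLS_PER_POSITION)
        row[:20] = norm[i]
        table[aa] = row
    term = np.zeros(SYMBOLS_PER_POSITION)
    term[20] = 1.0
    table[TERMINAL] = term
    return table


_ENCODING = _build_encoding_table()


def encode_blosum62(fragment: SiteFragment | str) -> np.ndarray:
    """Encode a window as the concatenation of per-position embeddings.

    A (2n+1)-mer yields a vector of length (2n+1) x 21; for the deployed
    29-mer that is 609.
    """
    window = fragment.window if isinstance(fragment, SiteFragment) else fragment
    try:
        rows = [_ENCODING[ch] for ch in window]
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} outside the 21-symbol alphabet")
    return np.concatenate(rows)


def fscore(values_pos: Sequence[float], values_neg: Sequence[float]) -> float:
    """F-score of one feature given its values in each class.

    Requires at least two samples per class (unbiased variances).  When both
    within-class variances vanish the statistic is 0 if the class means agree
    and +inf otherwise.
    """
    xp = np.asarray(values_pos, dtype=float)
    xn = np.asarray(values_neg, dtype=float)
    if xp.size < 2 or xn.size < 2:
        raise ValueError("each class needs at least 2 samples for the F-score")
    mp, mn = xp.mean(), xn.mean()
    m = (xp.sum() + xn.sum()) / (xp.size + xn.size)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = xp.var(ddof=1) + xn.var(ddof=1)
    if den == 0.0:
        return math.inf if num > 0.0 else 0.0
    return float(num / den)


def binary_fscore_from_counts(
    c_pos: np.ndarray | float,
    n_pos: int,
    c_neg: np.ndarray | float,
    n_neg: int,
) -> np.ndarray | float:
    """F-score of 0/1 indicator features from per-class success counts.

    Algebraically identical to :func:`fscore` on the expanded 0/1 samples
    (the unbiased variance of c ones among n is c(n-c)/(n(n-1))); vectorized
    over arrays of counts.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("each class needs at least 2 samples for the F-score")
    cp = np.asarray(c_pos, dtype=float)
    cn = np.asarray(c_neg, dtype=float)
    mp = cp / n_pos
    mn = cn / n_neg
    m = (cp + cn) / (n_pos + n_neg)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = cp * (n_pos - cp) / (n_pos * (n_pos - 1.0)) + cn * (n_neg - cn) / (
        n_neg * (n_neg - 1.0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0),
                       np.where(num > 0.0, np.inf, 0.0))
    if np.isscalar(c_pos) or out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class FScoreValue:
    feature_id: str
    fscore: float


def _window_matrix(fragments: Sequence[SiteFragment]) -> tuple[np.ndarray, np.ndarray, int]:
    """Character matrix (fragments x positions), positive mask, and n."""
    if not fragments:
        raise ValueError("no fragments")
    n = fragments[0].n
    if any(f.n != n for f in fragments):
        raise ValueError("fragments mix window sizes")
    mat = np.array([list(f.window) for f in fragments], dtype="<U1")
    pos_mask = np.array([f.label == POSITIVE for f in fragments], dtype=bool)
    return mat, pos_mask, n


def positional_residue_fscores(
    fragments: Sequence[SiteFragment],
) -> dict[tuple[int, str], FScoreValue]:
    """F-score of every (relative position, residue) indicator feature.

    For each flank position p != 0 and each of the 20 amino acids a, scores
    the binary feature "window carries a at p" over positives vs negatives.
    """
    mat, pos_mask, n = _window_matrix(fragments)
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    out: dict[tuple[int, str], FScoreValue] = {}
    for aa in AMINO_ACIDS:
        ind = mat == aa
        c_pos = ind[pos_mask].sum(axis=0)
        c_neg = ind[~pos_mask].sum(axis=0)
        scores = binary_fscore_from_counts(c_pos, n_pos, c_neg, n_neg)
        for col in range(2 * n + 1):
            p = col - n
            if p == 0:
                continue
            out[(p, aa)] = FScoreValue(f"{p:+d}{aa}", float(scores[col]))
    return out


def per_position_max_fscores(
    fragments: Sequence[SiteFragment],
) -> dict[int, tuple[str, float]]:
    """Best residue indicator per flank position: position -> (residue, F)."""
    per_residue = positional_residue_fscores(fragments)
    best: dict[int, tuple[str, float]] = {}
    for (p, aa), val in sorted(per_residue.items()):
        if p not in best or val.fscore > best[p][1]:
            best[p] = (aa, val.fscore)
    return best


def encode_saaps(fragment: SiteFragment | str, saap_list: Sequence) -> np.ndarray:
    """Binary SAAP block: bit j set iff the window matches pair j.

    A pair matches when the anchor residue sits at the anchor position and a
    partner-set residue sits at the partner position (positions relative to
    the center, which is position 0 and may not be referenced).
    """
    window = fragment.window if isinstance(fragment, SiteFragment) else fragment
    n = (len(window) - 1) // 2
    bits = np.zeros(len(saap_list))
    for j, saap in enumerate(saap_list):
        for pos in (saap.anchor_pos, saap.partner_pos):
            if pos == 0 or not -n <= pos <= n:
                raise ValueError(
                    f"SAAP position {pos:+d} invalid for a window with n={n}"
                )
        if (
            window[saap.anchor_pos + n] == saap.anchor_res
            and window[saap.partner_pos + n] in saap.partner_set
        ):
            bits[j] = 1.0
    return bits


def encode_fragment(fragment: SiteFragment, saap_list: Sequence = ()) -> np.ndarray:
    """Full feature vector: BLOSUM62 block followed by the SAAP block."""
    base = encode_blosum62(fragment)
    if not saap_list:
        return base
    return np.concatenate([base, encode_saaps(fragment, saap_list)])


def property_fscore(
    fragments: Sequence[SiteFragment],
    property_table: Mapping[str, float],
) -> dict[int, float]:
    """Positional F-scores of one physicochemical property.

    ``property_table`` maps each of the 20 amino acids to one real value
    (an AAindex-style scale); the terminal symbol contributes 0.  For each
    relative position the property value of the residue there is the feature.
    """
    missing = [aa for aa in AMINO_ACIDS if aa not in property_table]
    if missing:
        raise ValueError(f"property table missing amino acids: {missing}")
    lookup = {aa: float(property_table[aa]) for aa in AMINO_ACIDS}
    lookup[TERMINAL] = 0.0
    mat, pos_mask, n = _window_matrix(fragments)
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("both classes must be present")
    values = np.vectorize(lookup.__getitem__, otypes=[float])(mat)
    out: dict[int, float] = {}
    for col in range(2 * n + 1):
        out[col - n] = fscore(values[pos_mask, col], values[~pos_mask, col])
    return out


_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"  # the flat-file I-line residue order


def read_aaindex(path: str | Path) -> dict[str, dict[str, float]]:
    """Parse AAindex1 flat-file entries into accession -> {residue: value}.

    Only the H (accession) and I (values) records are used; 'NA' values make
    an entry unusable and it is skipped.
    """
    tables: dict[str, dict[str, float]] = {}
    accession = None
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            if line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("I ") and accession:
                vals: list[str] = []
                vals += next(lines).split()
                vals += next(lines).split()
                if len(vals) != 20:
                    raise ValueError(
                        f"{path}: entry {accession}: expected 20 values, "
                        f"got {len(vals)}"
                    )
                if "NA" in vals:
                    accession = None
                    continue
                tables[accession] = {
                    aa: float(v) for aa, v in zip(_AAINDEX_ORDER, vals)
                }
                accession = None
    return tables


def read_property_tsv(path: str | Path) -> dict[str, float]:
    """Read a plain two-column residue<TAB>value property table."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected residue<TAB>value")
            table[fields[0]] = float(fields[1])
    return table
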