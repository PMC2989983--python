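"""Discovery of significant amino-acid pairs (SAAPs) around candidate sites.

The procedure, run independently per (center residue, TM/non-TM) stratum:

1. score every (flank position, residue) indicator with the F-score and take
   the position with the largest score as the anchor position;
2. the most frequent amino acids among positives at the anchor position become
   anchor residues; every (anchor residue, partner position, partner residue)
   combination whose partner residue is sufficiently frequent among positives
   yields a candidate pair, scored by the F-score of its binary indicator;
   two partner residues at one position may merge into an "or" partner set
   when the merged indicator strictly outscores both singletons;
3. candidates are ranked by descending F-score and added to the feature
   vector one at a time (forward selection); the prefix that maximizes the
   cross-validated balanced accuracy is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .features import (
    binary_fscore_from_counts,
    per_position_max_fscores,
    _window_matrix,
)
from .sequence_io import AMINO_ACIDS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SAAP:
    """A significant amino-acid pair: anchor plus partner-set constraint.

    Positions are relative to the candidate site (position 0, never used);
    the partner set holds one or two residues ("+9E or +9T" style).
    """

    anchor_pos: int
    anchor_res: str
    partner_pos: int
    partner_set: tuple[str, ...]
    fscore: float

    def __post_init__(self) -> None:
        if self.anchor_pos == 0 or self.partner_pos == 0:
            raise ValueError("SAAP positions may not reference the site itself")
        if self.partner_pos == self.anchor_pos:
            raise ValueError("partner position must differ from the anchor position")
        if not 1 <= len(self.partner_set) <= 2:
            raise ValueError("partner set must hold 1 or 2 residues")
        if len(set(self.partner_set)) != len(self.partner_set):
            raise ValueError("partner set holds duplicate residues")

    def describe(self) -> str:
        partner = " or ".join(f"{self.partner_pos:+d}{r}" for r in self.partner_set)
        return f"({self.anchor_pos:+d}{self.anchor_res}, {partner})"


@dataclass
class AnchorChoice:
    position: int
    residues: list[str]
    position_fscores: dict[int, tuple[str, float]] = field(default_factory=dict)


def select_anchor(fragments: Sequence, k_anchor: int = 3) -> AnchorChoice:
    """Pick the anchor position (max positional F-score) and anchor residues.

    Ties at the maximum resolve to the smaller absolute position, then the
    negative side, and are logged.  Anchor residues are those most frequent
    among positives at the chosen position (top ``k_anchor``, frequency ties
    broken alphabetically).
    """
    best = per_position_max_fscores(fragments)
    top = max(v[1] for v in best.values())
    tied = sorted((p for p, v in best.items() if v[1] == top), key=lambda p: (abs(p), p))
    if len(tied) > 1:
        logger.info(
            "anchor F-score tie at positions %s; choosing %+d", tied, tied[0]
        )
    anchor_pos = tied[0]

    mat, pos_mask, n = _window_matrix(fragments)
    col = mat[pos_mask, anchor_pos + n]
    counts = {aa: int((col == aa).sum()) for aa in AMINO_ACIDS}
    ranked = sorted(counts, key=lambda aa: (-counts[aa], aa))
    residues = [aa for aa in ranked if counts[aa] > 0][:k_anchor]
    return AnchorChoice(anchor_pos, residues, best)


def enumerate_pairs(
    fragments: Sequence,
    anchor: AnchorChoice,
    f_min: float = 0.10,
) -> list[SAAP]:
    """All candidate SAAPs for the anchor, ranked by descending F-score.

    For each anchor residue and each other flank position, partner residues
    with positive-class frequency >= ``f_min`` at that position produce
    singleton-partner pairs; the best two-residue merge at a position is added
    when it strictly outscores both of its singletons.
    """
    mat, pos_mask, n = _window_matrix(fragments)
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())
    pos_rows = mat[pos_mask]
    neg_rows = mat[~pos_mask]

    candidates: list[SAAP] = []
    for anchor_res in anchor.residues:
        anchor_col = anchor.position + n
        a_pos = pos_rows[:, anchor_col] == anchor_res
        a_neg = neg_rows[:, anchor_col] == anchor_res
        for p in range(-n, n + 1):
            if p in (0, anchor.position):
                continue
            col = p + n
            freqs = {
                aa: (pos_rows[:, col] == aa).mean() for aa in AMINO_ACIDS
            }
            frequent = [aa for aa in AMINO_ACIDS if freqs[aa] >= f_min]
            singles: dict[str, float] = {}
            for aa in frequent:
                cp = int((a_pos & (pos_rows[:, col] == aa)).sum())
                cn = int((a_neg & (neg_rows[:, col] == aa)).sum())
                singles[aa] = float(binary_fscore_from_counts(cp, n_pos, cn, n_neg))
                candidates.append(SAAP(anchor.position, anchor_res, p, (aa,), singles[aa]))
            best_merge = None
            for r1, r2 in combinations(frequent, 2):
                cp = int((a_pos & np.isin(pos_rows[:, col], (r1, r2))).sum())
                cn = int((a_neg & np.isin(neg_rows[:, col], (r1, r2))).sum())
                score = float(binary_fscore_from_counts(cp, n_pos, cn, n_neg))
                if score > singles[r1] and score > singles[r2]:
                    if best_merge is None or score > best_merge.fscore:
                        best_merge = SAAP(
                            anchor.position, anchor_res, p, (r1, r2), score
                        )
            if best_merge is not None:
                candidates.append(best_merge)
    candidates.sort(
        key=lambda s: (-s.fscore, abs(s.partner_pos), s.partner_pos,
                       s.anchor_res, s.partner_set)
    )
    return candidates


def saap_indicator_counts(fragments: Sequence, saap: SAAP) -> tuple[int, int, int, int]:
    """Per-class match counts of one SAAP's indicator: (c+, n+, c-, n-)."""
    mat, pos_mask, n = _window_matrix(fragments)
    hits = (mat[:, saap.anchor_pos + n] == saap.anchor_res) & np.isin(
        mat[:, saap.partner_pos + n], saap.partner_set
    )
    return (
        int(hits[pos_mask].sum()),
        int(pos_mask.sum()),
        int(hits[~pos_mask].sum()),
        int((~pos_mask).sum()),
    )


@dataclass
class SelectionResult:
    """Forward-selection outcome: chosen prefix and the full selection curve."""

    selected: list[SAAP]
    curve: list[tuple[int, float]]  # (prefix length, CV balanced accuracy)

    @property
    def best_bacc(self) -> float:
        best_len = len(self.selected)
        return next(b for k, b in self.curve if k == best_len)


def rank_and_select(
    candidate_saaps: Sequence[SAAP],
    fragments: Sequence,
    model_trainer: Callable[[Sequence, Sequence[SAAP]], float],
    max_pairs: int = 20,
) -> SelectionResult:
    """Forward selection over F-score-ranked pairs by cross-validated BAcc.

    ``model_trainer(fragments, saap_prefix)`` must return the pooled
    cross-validated balanced accuracy of a model using the BLOSUM62 block plus
    the given pairs.  The prefix (possibly empty: BLOSUM62-only model) with
    maximal BAcc wins; ties go to the shorter prefix.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    ranked = sorted(candidate_saaps, key=lambda s: -s.fscore)[:max_pairs]
    curve: list[tuple[int, float]] = []
    for k in range(len(ranked) + 1):
        bacc = model_trainer(fragments, ranked[:k])
        curve.append((k, bacc))
        logger.debug("forward selection: %d pairs -> BAcc %.4f", k, bacc)
    best_k = max(range(len(curve)), key=lambda k: (curve[k][1], -k))
    return SelectionResult(selected=list(ranked[:best_k]), curve=curve)


def write_saap_table(
    saaps: Sequence[SAAP], center_residue: str, protein_class: str, path
) -> None:
    """Serialize SAAPs as TSV (layout mirrors the published pair tables)."""
    with open(path, "w") as fh:
        fh.write(
            "#center_residue\tprotein_class\tanchor_pos\tanchor_res"
            "\tpartner_pos\tpartner_set\tfscore\n"
        )
        for s in saaps:
            fh.write(
                f"{center_residue}\t{protein_class}\t{s.anchor_pos:+d}\t{s.anchor_res}"
                f"\t{s.partner_pos:+d}\t{','.join(s.partner_set)}\t{s.fscore:.6g}\n"
            )


def read_saap_table(path) -> list[tuple[str, str, SAAP]]:
    """Read a SAAP TSV back as (center_residue, protein_class, SAAP) rows."""
    rows: list[tuple[str, str, SAAP]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields")
            center, cls, a_pos, a_res, p_pos, p_set, score = fields
            rows.append(
                (
                    center,
                    cls,
                    SAAP(
                        int(a_pos),
                        a_res,
                        int(p_pos),
                        tuple(p_set.split(",")),
                        float(score),
                    ),
                )
            )
    return rows
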