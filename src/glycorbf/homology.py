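"""Homology reduction of site-fragment sets.

Two proteins with more than 30% pairwise identity are treated as homologous.
Among homologous proteins, site fragments whose (2n+1)-mer windows are 100%
identical and centered on equivalently placed sites collapse to a single
representative; positional equivalence of the re-aligned fragments is read as
byte-identical window strings.  The reduction is applied separately to
positive and negative fragments.

Identity is computed from a Smith-Waterman local alignment with BLOSUM62
scores and BLAST-style affine gaps (open 11, extend 1: a gap of length g
costs 11 + g), as matches / alignment columns x 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .sequence_io import POSITIVE, TERMINAL, TERMINAL_TEXT, SiteFragment


@dataclass(frozen=True)
class IdentityResult:
    """Percent identity over the columns of the best local alignment."""

    percent_identity: float
    aligned_length: int


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: a length-g gap costs 11 + g, so the first gapped
    # column scores -12 and each further one -1.
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> IdentityResult:
    """Percent identity between two protein sequences (local alignment).

    When no local alignment has a positive score the identity is 0 over an
    empty alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a = seq_a.replace(TERMINAL, TERMINAL_TEXT)
    b = seq_b.replace(TERMINAL, TERMINAL_TEXT)
    if _ALIGNER.score(a, b) <= 0:
        return IdentityResult(0.0, 0)
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return IdentityResult(0.0, 0)
    return IdentityResult(100.0 * counts.identities / columns, int(columns))


@dataclass(frozen=True)
class DedupRecord:
    """One removal: which fragment was kept for which discarded one."""

    kept_protein: str
    kept_position: int
    dropped_protein: str
    dropped_position: int
    reason: str


def dedup_fragments(
    fragments: Sequence[SiteFragment],
    protein_sequences: Mapping[str, str],
    protein_identity_threshold: float = 30.0,
) -> tuple[list[SiteFragment], list[DedupRecord]]:
    """Collapse redundant fragments between homologous proteins.

    A fragment is dropped when an already-kept fragment of the same class has
    a byte-identical window and comes from the same protein or from a protein
    exceeding the identity threshold.  Within a redundancy group the fragment
    with the lexicographically smallest (protein id, position) is retained, so
    the operation is deterministic and idempotent.  Positive and negative
    fragments are reduced independently.

    Returns the kept fragments (input order preserved) and a removal report.
    """
    if fragments and len({f.n for f in fragments}) > 1:
        raise ValueError("fragments mix window sizes")

    identity_cache: dict[tuple[str, str], float] = {}

    def homologous(pid_a: str, pid_b: str) -> bool:
        if pid_a == pid_b:
            return True
        key = (min(pid_a, pid_b), max(pid_a, pid_b))
        if key not in identity_cache:
            identity_cache[key] = pairwise_identity(
                protein_sequences[pid_a], protein_sequences[pid_b]
            ).percent_identity
        return identity_cache[key] > protein_identity_threshold

    dropped: set[int] = set()
    report: list[DedupRecord] = []
    for label_class in ({POSITIVE}, set()):
        # group this class's fragments by identical window string
        groups: dict[str, list[int]] = {}
        for idx, frag in enumerate(fragments):
            in_class = (frag.label == POSITIVE) == bool(label_class)
            if in_class:
                groups.setdefault(frag.window, []).append(idx)
        for indices in groups.values():
            if len(indices) < 2:
                continue
            order = sorted(
                indices, key=lambda i: (fragments[i].protein_id, fragments[i].position)
            )
            kept: list[int] = []
            for idx in order:
                frag = fragments[idx]
                match = next(
                    (
                        k
                        for k in kept
                        if homologous(fragments[k].protein_id, frag.protein_id)
                    ),
                    None,
                )
                if match is None:
                    kept.append(idx)
                else:
                    dropped.add(idx)
                    keeper = fragments[match]
                    report.append(
                        DedupRecord(
                            keeper.protein_id,
                            keeper.position,
                            frag.protein_id,
                            frag.position,
                            "identical window in homologous protein",
                        )
                    )
    kept_fragments = [f for i, f in enumerate(fragments) if i not in dropped]
    return kept_fragments, report


def write_dedup_report(report: Sequence[DedupRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#kept_id\tkept_position\tdropped_id\tdropped_position\treason\n")
        for rec in report:
            fh.write(
                f"{rec.kept_protein}\t{rec.kept_position}\t{rec.dropped_protein}"
                f"\t{rec.dropped_position}\t{rec.reason}\n"
            )
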