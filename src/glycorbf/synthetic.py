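"""Synthetic glycoprotein datasets with controllable pair-motif signal.

The generator emulates the structure of an O-glycosylation training corpus:
protein sequences drawn from a background residue distribution (serine and
threonine enriched so candidate sites exist), a configurable fraction of
transmembrane proteins carrying alternating extracellular / transmembrane /
cytoplasmic segments, and positive sites placed on S/T residues outside TM
segments (glycosyltransferases cannot reach residues buried in the membrane,
so real positive sets show none there).  Around each positive site, implanted
amino-acid pairs rewrite flank residues with a configurable penetrance,
creating the enrichment signal that pair discovery is expected to recover.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pipeline_eval import SitePrediction
from .sequence_io import (
    AMINO_ACIDS,
    NEGATIVE,
    POSITIVE,
    ProteinRecord,
    SiteAnnotation,
    TopologySegment,
)


@dataclass(frozen=True)
class ImplantSpec:
    """One pair motif to implant around positive sites.

    ``partner_pos`` may be None for an anchor-only (single residue) implant.
    With probability ``penetrance`` a positive site's flank is rewritten to
    carry the anchor residue (and, if present, one partner-set residue).
    """

    anchor_pos: int
    anchor_res: str
    partner_pos: int | None = None
    partner_set: tuple[str, ...] = ()
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.anchor_pos == 0 or self.partner_pos == 0:
            raise ValueError("implants may not overwrite the site itself")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        if self.partner_pos is not None and not self.partner_set:
            raise ValueError("a partner position requires a partner set")

    @property
    def offsets(self) -> tuple[int, ...]:
        if self.partner_pos is None:
            return (self.anchor_pos,)
        return (self.anchor_pos, self.partner_pos)


def default_background() -> dict[str, float]:
    """Uniform background with serine/threonine enriched to 10% each."""
    freqs = {aa: 0.8 / 18 for aa in AMINO_ACIDS}
    freqs["S"] = 0.10
    freqs["T"] = 0.10
    return freqs


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 60
    length_range: tuple[int, int] = (80, 300)
    fraction_tm: float = 0.3
    positive_rate: float = 0.05
    implanted_saaps: Sequence[ImplantSpec] = ()
    background_frequencies: dict[str, float] | None = None
    tm_segment_length_range: tuple[int, int] = (15, 25)
    seed: int = 0
    #: optional exact totals; when set they override positive_rate
    n_positive_sites: int | None = None
    n_negative_sites: int | None = None

    def __post_init__(self) -> None:
        freqs = self.background_frequencies or default_background()
        if set(freqs) != set(AMINO_ACIDS):
            raise ValueError("background frequencies must cover the 20 amino acids")
        total = sum(freqs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"background frequencies sum to {total}, expected 1")
        if any(v < 0 for v in freqs.values()):
            raise ValueError("background frequencies must be nonnegative")
        if not 0.0 <= self.fraction_tm <= 1.0:
            raise ValueError("fraction_tm must lie in [0, 1]")
        if not 0.0 <= self.positive_rate <= 1.0:
            raise ValueError("positive_rate must lie in [0, 1]")
        self.background_frequencies = freqs


def _make_topology(
    rng: np.random.Generator, length: int, seg_len_range: tuple[int, int]
) -> list[TopologySegment]:
    """Alternating E/TM/C segments covering the whole protein."""
    lo, hi = seg_len_range
    n_tm = int(rng.integers(1, 4))
    # place TM helices with at least `gap` residues between and around them
    gap = 12
    placed: list[tuple[int, int]] = []
    cursor = 1 + gap
    for _ in range(n_tm):
        seg_len = int(rng.integers(lo, hi + 1))
        if cursor + seg_len + gap > length:
            break
        start = cursor + int(rng.integers(0, max(1, (length - cursor - seg_len - gap) // max(1, n_tm))))
        placed.append((start, start + seg_len - 1))
        cursor = start + seg_len + gap
    if not placed:  # protein too short for a helix: single TM at the middle
        seg_len = min(lo, max(1, length // 3))
        start = max(1, (length - seg_len) // 2)
        placed = [(start, start + seg_len - 1)]
    segments: list[TopologySegment] = []
    side = "E"
    pos = 1
    for start, end in placed:
        if start > pos:
            segments.append(TopologySegment(side, pos, start - 1))
        segments.append(TopologySegment("TM", start, end))
        side = "C" if side == "E" else "E"
        pos = end + 1
    if pos <= length:
        segments.append(TopologySegment(side, pos, length))
    return segments


def generate(
    config: SimConfig,
) -> tuple[list[ProteinRecord], list[SiteAnnotation], dict[str, list[TopologySegment]]]:
    """Generate proteins, site annotations, and topology from a config.

    Positive sites are S/T positions outside TM segments with enough room for
    all implant offsets; each implant rewrites the flank with its penetrance.
    Every remaining S/T is a negative candidate (optionally subsampled to an
    exact total).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    freqs = config.background_frequencies
    aas = np.array(list(AMINO_ACIDS))
    probs = np.array([freqs[a] for a in AMINO_ACIDS])
    offsets = [off for spec in config.implanted_saaps for off in spec.offsets]
    max_off = max(offsets, default=0)
    min_off = min(offsets, default=0)

    sequences: dict[str, list[str]] = {}
    topology: dict[str, list[TopologySegment]] = {}
    eligible: list[tuple[str, int]] = []
    for i in range(config.n_proteins):
        pid = f"SYN{i + 1:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = list(aas[rng.choice(len(aas), size=length, p=probs)])
        sequences[pid] = seq
        is_tm = rng.random() < config.fraction_tm
        segments = (
            _make_topology(rng, length, config.tm_segment_length_range)
            if is_tm
            else []
        )
        topology[pid] = segments
        for pos in range(1, length + 1):
            if seq[pos - 1] not in ("S", "T"):
                continue
            if any(seg.label == "TM" and pos in seg for seg in segments):
                continue
            if pos + min_off < 1 or pos + max_off > length:
                continue
            eligible.append((pid, pos))

    if config.n_positive_sites is not None:
        if config.n_positive_sites > len(eligible):
            raise ValueError(
                f"requested {config.n_positive_sites} positive sites but only "
                f"{len(eligible)} eligible positions exist"
            )
        chosen = rng.choice(len(eligible), size=config.n_positive_sites, replace=False)
        positive_set = {eligible[i] for i in chosen}
    else:
        mask = rng.random(len(eligible)) < config.positive_rate
        positive_set = {site for site, hit in zip(eligible, mask) if hit}

    # implant pair motifs around the chosen positives
    centers_by_protein: dict[str, set[int]] = {}
    for pid, pos in positive_set:
        centers_by_protein.setdefault(pid, set()).add(pos)
    for pid, pos in sorted(positive_set):
        seq = sequences[pid]
        centers = centers_by_protein[pid]
        for spec in config.implanted_saaps:
            if rng.random() >= spec.penetrance:
                continue
            writes = [(spec.anchor_pos, spec.anchor_res)]
            if spec.partner_pos is not None:
                partner = spec.partner_set[int(rng.integers(len(spec.partner_set)))]
                writes.append((spec.partner_pos, partner))
            for off, res in writes:
                target = pos + off
                if 1 <= target <= len(seq) and target not in centers:
                    seq[target - 1] = res

    records: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    negatives: list[SiteAnnotation] = []
    for pid in sorted(sequences):
        seq = "".join(sequences[pid])
        records.append(ProteinRecord(id=pid, sequence=seq, topology=topology[pid]))
        centers = centers_by_protein.get(pid, set())
        for pos, ch in enumerate(seq, start=1):
            if ch not in ("S", "T"):
                continue
            if pos in centers:
                annotations.append(SiteAnnotation(pid, pos, ch, POSITIVE))
            else:
                negatives.append(SiteAnnotation(pid, pos, ch, NEGATIVE))

    if config.n_negative_sites is not None:
        if config.n_negative_sites > len(negatives):
            raise ValueError(
                f"requested {config.n_negative_sites} negative sites but only "
                f"{len(negatives)} exist"
            )
        chosen = rng.choice(len(negatives), size=config.n_negative_sites, replace=False)
        negatives = [negatives[i] for i in sorted(chosen)]
    annotations.extend(negatives)
    annotations.sort(key=lambda s: (s.protein_id, s.position))
    return records, annotations, topology


def reference_confusion_fixture() -> tuple[list[SitePrediction], dict[str, list[TopologySegment]]]:
    """A deterministic TM-protein prediction set with a known confusion matrix.

    2652 labeled candidate sites whose decisions give confusion counts
    (tp, fp, tn, fn) = (132, 462, 1988, 70) before topology filtering, with
    exactly 145 of the false positives inside TM segments and every true
    positive outside them — so the TM veto removes exactly those 145 false
    positives (a 31.4% reduction) and nothing else.

    The fixture is synthetic: site coordinates and scores are constructed
    directly, not produced by a trained model.
    """
    # categories: (count, true label, decision, needs TM slot)
    categories = [
        (132, POSITIVE, POSITIVE, False),  # TP, extracellular
        (70, POSITIVE, NEGATIVE, False),  # FN, extracellular
        (145, NEGATIVE, POSITIVE, True),  # FP inside TM segments
        (317, NEGATIVE, POSITIVE, False),  # FP, extracellular
        (1988, NEGATIVE, NEGATIVE, False),  # TN, extracellular
    ]
    n_tm_sites = sum(c for c, _, _, tm in categories if tm)
    n_e_sites = sum(c for c, _, _, tm in categories if not tm)

    # proteins of length 340 with one 20-residue TM helix at 161..180
    topology: dict[str, list[TopologySegment]] = {}
    tm_slots: list[tuple[str, int]] = []
    e_slots: list[tuple[str, int]] = []
    protein_len, tm_start, tm_end = 340, 161, 180
    i = 0
    while len(tm_slots) < n_tm_sites or len(e_slots) < n_e_sites:
        i += 1
        pid = f"FIX{i:04d}"
        topology[pid] = [
            TopologySegment("E", 1, tm_start - 1),
            TopologySegment("TM", tm_start, tm_end),
            TopologySegment("C", tm_end + 1, protein_len),
        ]
        tm_slots += [(pid, p) for p in range(tm_start, tm_end + 1)]
        e_slots += [(pid, p) for p in range(1, tm_start)]

    predictions: list[SitePrediction] = []
    tm_iter = iter(tm_slots)
    e_iter = iter(e_slots)
    residues = "ST"
    k = 0
    for count, truth, decision, in_tm in categories:
        for _ in range(count):
            pid, pos = next(tm_iter) if in_tm else next(e_iter)
            margin = 1.0 if decision == POSITIVE else -1.0
            predictions.append(
                SitePrediction(
                    protein_id=pid,
                    position=pos,
                    residue=residues[k % 2],
                    protein_class="TM",
                    score_pos=0.5 + margin / 2,
                    score_neg=0.5 - margin / 2,
                    decision=decision,
                    topology_label="TM" if in_tm else "E",
                    true_label=truth,
                )
            )
            k += 1
    return predictions, topology


def topology_distribution_fixture() -> tuple[list[SiteAnnotation], dict[str, list[TopologySegment]]]:
    """Positive sites distributed over topology labels as in a TM-protein corpus.

    202 synthetic positive sites on one segmented protein: 177 extracellular,
    22 lumenal, 1 nucleoplasmic, 2 uncovered (Unknown), none cytoplasmic or
    transmembrane — giving an 87.6% extracellular share.
    """
    pid = "FIXT3"
    topology = {
        pid: [
            TopologySegment("E", 1, 177),
            TopologySegment("L", 178, 199),
            TopologySegment("N", 200, 200),
            TopologySegment("TM", 201, 220),
            TopologySegment("C", 221, 240),
        ]
    }
    positions = list(range(1, 178)) + list(range(178, 200)) + [200] + [245, 246]
    sites = [SiteAnnotation(pid, pos, "S", POSITIVE) for pos in positions]
    return sites, topology
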