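"""Sequences, site annotations, membrane topology, and site-centered windows.

Protein sequences are read from FASTA; site annotations and membrane-topology
segments from plain tab-separated files.  All coordinates are 1-based inclusive
(the UniProt feature convention); relative window positions run -n..+n with the
candidate serine/threonine at 0.

The working alphabet has 21 symbols: the 20 standard amino acids plus a
dedicated terminal symbol (rendered ``X`` in text output) that pads windows
hanging over a sequence end and absorbs non-standard residue codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in BLOSUM62 row order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Terminal / unknown symbol: 21st alphabet character, written as 'X' in files.
TERMINAL = "⊥"
TERMINAL_TEXT = "X"

ALPHABET = AMINO_ACIDS + TERMINAL

#: Non-standard residue codes mapped onto the terminal/unknown symbol.
NON_STANDARD = frozenset("BZJOUX*")

TOPOLOGY_LABELS = ("L", "N", "E", "C", "TM", "S", "Unknown")

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class TopologySegment:
    """A labeled interval of a protein's membrane topology (1-based inclusive)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in TOPOLOGY_LABELS:
            raise ValueError(
                f"unknown topology label {self.label!r}; allowed: {TOPOLOGY_LABELS}"
            )
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad segment coordinates {self.start}..{self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class ProteinRecord:
    """A protein sequence with optional membrane-topology segments."""

    id: str
    sequence: str
    topology: list[TopologySegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: characters outside the 21-symbol "
                f"alphabet: {sorted(bad)}"
            )

    @property
    def is_tm(self) -> bool:
        """True if the protein has at least one transmembrane segment."""
        return any(seg.label == "TM" for seg in self.topology)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """One candidate S/T site with its experimental label."""

    protein_id: str
    position: int  # 1-based
    residue: str  # 'S' or 'T'
    label: str  # POSITIVE or NEGATIVE


@dataclass(frozen=True)
class SiteFragment:
    """A (2n+1)-residue window over the 21-symbol alphabet centered on a site."""

    protein_id: str
    position: int
    center: str
    window: str
    label: str

    @property
    def n(self) -> int:
        return (len(self.window) - 1) // 2

    def __post_init__(self) -> None:
        if len(self.window) % 2 != 1:
            raise ValueError("window length must be odd (2n+1)")
        if self.window[self.n] != self.center:
            raise ValueError("window center does not match the stated residue")


def _clean_sequence(record_id: str, raw: str) -> str:
    seq = raw.upper()
    mapped = []
    warned: set[str] = set()
    for ch in seq:
        if ch in NON_STANDARD:
            if ch not in warned:
                logger.warning(
                    "protein %s: non-standard residue %r mapped to the "
                    "terminal/unknown symbol",
                    record_id,
                    ch,
                )
                warned.add(ch)
            mapped.append(TERMINAL)
        else:
            mapped.append(ch)
    return "".join(mapped)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased; non-standard residue codes (B, Z, J, O, U, X, *)
    are mapped to the terminal/unknown symbol with a logged warning.  Record ids
    are the first whitespace-delimited header token and must be unique.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA entry with empty header")
        seq = _clean_sequence(rec.id, str(rec.seq))
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence.replace(TERMINAL, TERMINAL_TEXT)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _data_lines(path: str | Path):
    """Yield (line_number, fields) for a TSV, skipping a '#' header and blanks."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_topology(path: str | Path) -> dict[str, list[TopologySegment]]:
    """Read topology segments (id, start, end, label), grouped and validated.

    Segments of one protein are sorted by start; overlapping segments, unknown
    labels and inverted coordinates are rejected with the offending line number.
    """
    grouped: dict[str, list[TopologySegment]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        pid, start_s, end_s, label = fields
        try:
            seg = TopologySegment(label=label, start=int(start_s), end=int(end_s))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        grouped.setdefault(pid, []).append(seg)
    for pid, segs in grouped.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{path}: protein {pid!r}: overlapping segments "
                    f"{a.start}..{a.end} ({a.label}) and {b.start}..{b.end} ({b.label})"
                )
    return grouped


def write_topology(
    topology: Mapping[str, Sequence[TopologySegment]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tstart\tend\tlabel\n")
        for pid in sorted(topology):
            for seg in sorted(topology[pid], key=lambda s: s.start):
                fh.write(f"{pid}\t{seg.start}\t{seg.end}\t{seg.label}\n")


def read_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read site annotations (id, position, residue, label)."""
    sites: list[SiteAnnotation] = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        pid, pos_s, residue, label = fields
        if residue not in ("S", "T"):
            raise ValueError(f"{path}:{lineno}: residue must be S or T, got {residue!r}")
        if label not in (POSITIVE, NEGATIVE):
            raise ValueError(
                f"{path}:{lineno}: label must be {POSITIVE!r} or {NEGATIVE!r}"
            )
        sites.append(SiteAnnotation(pid, int(pos_s), residue, label))
    return sites


def write_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tposition\tresidue\tlabel\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.label}\n")


def attach_topology(
    records: Iterable[ProteinRecord],
    topology: Mapping[str, Sequence[TopologySegment]],
) -> None:
    """Attach topology segments to records in place, checking bounds."""
    for rec in records:
        segs = topology.get(rec.id, [])
        for seg in segs:
            if seg.end > len(rec):
                raise ValueError(
                    f"protein {rec.id!r}: segment {seg.start}..{seg.end} exceeds "
                    f"sequence length {len(rec)}"
                )
        rec.topology = sorted(segs, key=lambda s: s.start)


def label_at(
    segments: Sequence[TopologySegment], position: int, default: str = "Unknown"
) -> str:
    """Topology label of the segment containing ``position`` (or ``default``)."""
    for seg in segments:
        if position in seg:
            return seg.label
    return default


def candidate_sites(
    record: ProteinRecord, positive_positions: Iterable[int] = ()
) -> list[SiteAnnotation]:
    """All S/T positions of a protein as labeled candidate sites.

    Positions listed in ``positive_positions`` are labeled positive; every
    other serine/threonine is a negative candidate.
    """
    positives = set(positive_positions)
    out: list[SiteAnnotation] = []
    for idx, ch in enumerate(record.sequence, start=1):
        if ch in ("S", "T"):
            label = POSITIVE if idx in positives else NEGATIVE
            out.append(SiteAnnotation(record.id, idx, ch, label))
    return out


def extract_window(
    record: ProteinRecord, position: int, n: int, label: str = NEGATIVE
) -> SiteFragment:
    """Extract the (2n+1)-mer window centered on a candidate S/T position.

    Flanks falling outside the sequence are padded with the terminal symbol,
    so terminal characters occur only in maximal prefixes/suffixes.
    """
    if n < 1:
        raise ValueError("window half-width n must be >= 1")
    if not 1 <= position <= len(record):
        raise ValueError(f"position {position} outside protein {record.id!r}")
    center = record.sequence[position - 1]
    if center not in ("S", "T"):
        raise ValueError(
            f"protein {record.id!r} position {position}: center residue is "
            f"{center!r}, expected S or T"
        )
    chars = []
    for off in range(-n, n + 1):
        idx = position + off
        chars.append(record.sequence[idx - 1] if 1 <= idx <= len(record) else TERMINAL)
    return SiteFragment(
        protein_id=record.id,
        position=position,
        center=center,
        window="".join(chars),
        label=label,
    )


def window_to_text(window: str) -> str:
    """Render a window for text output (terminal symbol as 'X')."""
    return window.replace(TERMINAL, TERMINAL_TEXT)


def window_from_text(text: str) -> str:
    """Parse a window from text output ('X' as the terminal symbol)."""
    return text.replace(TERMINAL_TEXT, TERMINAL)


def build_fragments(
    records: Iterable[ProteinRecord],
    sites: Iterable[SiteAnnotation],
    n: int,
) -> list[SiteFragment]:
    """Windows for every annotated site, validated against the sequences."""
    by_id = {rec.id: rec for rec in records}
    fragments = []
    for site in sites:
        rec = by_id.get(site.protein_id)
        if rec is None:
            raise ValueError(f"site references unknown protein {site.protein_id!r}")
        if rec.sequence[site.position - 1] != site.residue:
            raise ValueError(
                f"protein {site.protein_id!r} position {site.position}: sequence "
                f"has {rec.sequence[site.position - 1]!r}, annotation says "
                f"{site.residue!r}"
            )
        fragments.append(extract_window(rec, site.position, n, label=site.label))
    return fragments
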