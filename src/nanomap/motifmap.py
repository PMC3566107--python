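"""In silico two-color label maps computed from DNA sequence.

A :class:`ReferenceMap` holds, per label channel, the sorted positions at which
a nicking-enzyme recognition motif occurs in a sequence (on either strand), plus
the intervals of ambiguous bases (runs of N) that mark scaffold gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Runs of at least this many consecutive N are recorded as scaffold gaps.
N_GAP_MIN = 10


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ChannelSpec:
    """A nicking motif bound to one label color channel."""

    channel_id: int
    motif: str
    display_name: str = ""

    def __post_init__(self):
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        if len(motif) < 4:
            raise ValidationError(f"motif {motif!r} shorter than 4 bases")
        if re.search("[^ACGT]", motif):
            raise ValidationError(f"motif {motif!r} contains non-ACGT characters")
        if int(self.channel_id) < 1:
            raise ValidationError("channel_id must be a positive integer")


DEFAULT_CHANNELS: tuple[ChannelSpec, ChannelSpec] = (
    ChannelSpec(1, "GCTCTTC", "Nt.BspQI"),
    ChannelSpec(2, "CCTCAGC", "Nt.BbvCI"),
)


@dataclass
class ReferenceMap:
    """An in silico label map for one sequence record.

    ``labels`` maps channel_id to a strictly increasing list of 0-based
    integer positions (first base of the motif match). ``gaps`` is a sorted
    list of half-open ``(start, end)`` intervals covering runs of >= 10 N.
    """

    map_id: str
    length_bp: int
    labels: dict[int, list[int]] = field(default_factory=dict)
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.length_bp < 0:
            raise ValidationError(f"{self.map_id}: negative length")
        for ch, pos in self.labels.items():
            for a, b in zip(pos, pos[1:]):
                if b <= a:
                    raise ValidationError(
                        f"{self.map_id}: channel {ch} positions not strictly increasing"
                    )
            if pos and (pos[0] < 0 or pos[-1] >= max(self.length_bp, 1)):
                raise ValidationError(
                    f"{self.map_id}: channel {ch} position outside [0, {self.length_bp})"
                )
        prev_end = -1
        for s, e in self.gaps:
            if not (0 <= s < e <= self.length_bp):
                raise ValidationError(f"{self.map_id}: gap ({s},{e}) out of bounds")
            if s <= prev_end:
                raise ValidationError(f"{self.map_id}: overlapping gap intervals")
            prev_end = e

    @property
    def channels(self) -> list[int]:
        return sorted(self.labels)

    @property
    def total_labels(self) -> int:
        return sum(len(v) for v in self.labels.values())

    def slice(self, start: int, end: int, map_id: str | None = None) -> "ReferenceMap":
        """Sub-map over the half-open interval [start, end), rebased to 0."""
        if not (0 <= start < end <= self.length_bp):
            raise ValidationError(f"slice ({start},{end}) outside map {self.map_id}")
        labels = {
            ch: [p - start for p in pos if start <= p < end]
            for ch, pos in self.labels.items()
        }
        gaps = [
            (max(s, start) - start, min(e, end) - start)
            for s, e in self.gaps
            if s < end and e > start
        ]
        return ReferenceMap(
            map_id=map_id or f"{self.map_id}:{start}-{end}",
            length_bp=end - start,
            labels=labels,
            gaps=gaps,
        )


def find_nick_sites(
    sequence: str,
    channels: tuple[ChannelSpec, ...] = DEFAULT_CHANNELS,
    map_id: str = "map",
) -> ReferenceMap:
    """Locate every motif occurrence on either strand of ``sequence``.

    A label is emitted at the 0-based position of the first base of each
    occurrence of the motif, and of its reverse complement, on the forward
    strand (each nickase recognizes one strand, and labels from both
    orientations are visible). Overlapping occurrences are all reported.
    Runs of >= 10 N are recorded as gap intervals; motifs never match across
    N because the motifs contain only ACGT.
    """
    seq = sequence.upper()
    bad = re.search("[^ACGTN]", seq)
    if bad:
        raise ValidationError(
            f"invalid character {seq[bad.start()]!r} at position {bad.start()}"
        )
    ids = [c.channel_id for c in channels]
    if len(set(ids)) != len(ids):
        raise ValidationError("channel_ids must be unique within a run")

    gaps = [(m.start(), m.end()) for m in re.finditer(f"N{{{N_GAP_MIN},}}", seq)]

    labels: dict[int, list[int]] = {}
    for ch in channels:
        pats = {ch.motif, revcomp(ch.motif)}
        hits: set[int] = set()
        for pat in pats:
            hits.update(m.start() for m in re.finditer(f"(?={pat})", seq))
        labels[ch.channel_id] = sorted(hits)

    return ReferenceMap(map_id=map_id, length_bp=len(seq), labels=labels, gaps=gaps)


def label_density(map_) -> float:
    """Average label spacing in kb per label: length_bp / total labels / 1000.

    Accepts any map object exposing ``length_bp`` plus either ``labels``
    (position lists per channel) or ``peaks`` (consensus peaks per channel).
    """
    total = total_label_count(map_)
    if total < 1:
        raise ValidationError(f"{getattr(map_, 'map_id', 'map')}: density undefined, zero labels")
    return (map_.length_bp / 1000.0) / total


def total_label_count(map_) -> int:
    if hasattr(map_, "peaks"):
        return sum(len(v) for v in map_.peaks.values())
    return sum(len(v) for v in map_.labels.values())
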