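"""Threading a short fold into a long fold: embeddings, conflicts, ranking.

The dual-fold design procedure starts by sliding the short fold's
residue frame along the long fold (a contiguous embedding, no gaps) and
keeping the offsets at which a chosen anchor element pair overlaps.
Each candidate alignment is then scored by counting *catastrophic
interactions*: residue/environment incompatibilities (buried polar
residues, proline inside helices or strands, packing violations) that a
single shared sequence would suffer in one fold context or the other.
Alignments are ranked by conflict count, the quantity the procedure
minimises before any mutation is designed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .fold_model import HELIX, STRAND, FoldTemplate
from .tables import POLAR_RESIDUES, RESIDUE_VOLUME

logger = logging.getLogger(__name__)

# -- configuration defaults ------------------------------------------------

#: Minimum residue overlap between anchor elements (about one helical turn).
ANCHOR_MIN_OVERLAP = 4
#: Summed side-chain volume budget factor for an overpacked core pair.
OVERPACK_FACTOR = 1.25
#: Fraction of the reference volume budget below which a core G/A is underpacked.
UNDERPACK_FRACTION = 0.5
#: Helix positions within this many residues of the element start tolerate proline.
HELIX_FIRST_TURN = 4

#: Ordinal severity per conflict kind (ranking is by count first; these only
#: break ties).
SEVERITY = {
    "buried_polar": 2.0,
    "helix_breaker": 3.0,
    "strand_breaker": 3.0,
    "overpacked_pair": 1.0,
    "underpacked_core": 0.5,
}


# -- domain types ----------------------------------------------------------


@dataclass(frozen=True)
class Embedding:
    """Contiguous mapping of a short fold into a long fold.

    Short-fold residue ``i`` maps to long-fold residue ``i + offset``;
    the embedded window is long positions ``offset+1 .. offset+short_len``
    (1-based, inclusive).  ``correspondences`` records, for every short
    element, the long element it best overlaps: tuples of
    ``(short_label, long_label, overlap_length, kind_match)``.
    """

    offset: int
    short_len: int
    anchor: tuple[str, str]
    correspondences: tuple[tuple[str, str, int, bool], ...] = ()

    @property
    def window(self) -> tuple[int, int]:
        """Long-frame (start, end) of the embedded region, 1-based inclusive."""
        return (self.offset + 1, self.offset + self.short_len)

    def contains(self, long_pos: int) -> bool:
        return self.offset + 1 <= long_pos <= self.offset + self.short_len

    def to_short(self, long_pos: int) -> int:
        return long_pos - self.offset

    def to_long(self, short_pos: int) -> int:
        return short_pos + self.offset

    @property
    def kind_matches(self) -> int:
        return sum(1 for c in self.correspondences if c[3])


@dataclass(frozen=True)
class Conflict:
    """One catastrophic interaction at a long-frame position."""

    long_position: int
    kind: str
    severity: float
    detail: str

    def __post_init__(self):
        if self.severity <= 0:
            raise DomainError("conflict severity must be positive")


@dataclass(frozen=True)
class ConflictReport:
    embedding: Embedding
    conflicts: tuple[Conflict, ...]

    @property
    def total_count(self) -> int:
        return len(self.conflicts)

    @property
    def total_severity(self) -> float:
        return sum(c.severity for c in self.conflicts)


# -- operations ------------------------------------------------------------


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def enumerate_embeddings(
    long: FoldTemplate,
    short: FoldTemplate,
    anchor: tuple[str, str],
    min_overlap: int = ANCHOR_MIN_OVERLAP,
) -> list[Embedding]:
    """All offsets at which the short fold fits inside the long fold with the
    anchor elements overlapping by at least ``min_overlap`` residues.

    ``anchor`` is a ``(short_element_label, long_element_label)`` pair.
    """
    if short.length > long.length:
        raise DomainError(
            f"short fold ({short.length}) longer than long fold ({long.length})"
        )
    try:
        a_short = short.element_by_label(anchor[0])
    except KeyError:
        raise ConfigurationError(f"anchor element {anchor[0]!r} absent from {short.name}") from None
    try:
        a_long = long.element_by_label(anchor[1])
    except KeyError:
        raise ConfigurationError(f"anchor element {anchor[1]!r} absent from {long.name}") from None

    out = []
    for offset in range(long.length - short.length + 1):
        ov = _overlap(a_short.start + offset, a_short.end + offset, a_long.start, a_long.end)
        if ov < min_overlap:
            continue
        corr = []
        for el in short.elements:
            best_label, best_ov, best_kind = "", 0, False
            for lel in long.elements:
                o = _overlap(el.start + offset, el.end + offset, lel.start, lel.end)
                if o > best_ov:
                    best_label, best_ov, best_kind = lel.label, o, lel.kind == el.kind
            corr.append((el.label, best_label, best_ov, best_kind and best_ov > 0))
        out.append(
            Embedding(
                offset=offset,
                short_len=short.length,
                anchor=tuple(anchor),
                correspondences=tuple(corr),
            )
        )
    return out


def _fold_context_conflicts(
    sequence: str,
    template: FoldTemplate,
    context: str,
    to_long,
    ref_sequence: str,
    overpack_factor: float,
    underpack_fraction: float,
) -> list[Conflict]:
    """Conflicts of ``sequence`` (in the template's own frame) against one fold.

    ``to_long`` maps template-frame positions to long-frame positions for
    reporting.  ``sequence`` and ``ref_sequence`` have template length.
    """
    conflicts: list[Conflict] = []
    n = template.length

    # Buried polar + underpacked core (per-position rules).
    for pos in range(1, n + 1):
        aa = sequence[pos - 1]
        if template.burial_of(pos) == "core":
            if aa in POLAR_RESIDUES:
                conflicts.append(
                    Conflict(
                        to_long(pos), "buried_polar", SEVERITY["buried_polar"],
                        f"{aa} buried at core position in {context} fold",
                    )
                )
            if aa in "GA":
                budget = RESIDUE_VOLUME[ref_sequence[pos - 1]] + sum(
                    RESIDUE_VOLUME[ref_sequence[j - 1]] for j in template.partners(pos)
                )
                current = RESIDUE_VOLUME[aa] + sum(
                    RESIDUE_VOLUME[sequence[j - 1]] for j in template.partners(pos)
                )
                if current <= underpack_fraction * budget:
                    conflicts.append(
                        Conflict(
                            to_long(pos), "underpacked_core", SEVERITY["underpacked_core"],
                            f"{aa} leaves core cavity in {context} fold "
                            f"(volume {current:.0f} of budget {budget:.0f})",
                        )
                    )

    # Proline in elements.
    for el in template.elements:
        for pos in range(el.start, el.end + 1):
            if sequence[pos - 1] != "P":
                continue
            if el.kind == HELIX and pos - el.start >= HELIX_FIRST_TURN:
                conflicts.append(
                    Conflict(
                        to_long(pos), "helix_breaker", SEVERITY["helix_breaker"],
                        f"P inside helix {el.label or '?'} in {context} fold",
                    )
                )
            elif el.kind == STRAND:
                conflicts.append(
                    Conflict(
                        to_long(pos), "strand_breaker", SEVERITY["strand_breaker"],
                        f"P inside strand {el.label or '?'} in {context} fold",
                    )
                )

    # Overpacked contacting core pairs.
    for i, j in sorted(template.contacts):
        if template.burial_of(i) == "core" and template.burial_of(j) == "core":
            vol = RESIDUE_VOLUME[sequence[i - 1]] + RESIDUE_VOLUME[sequence[j - 1]]
            budget = RESIDUE_VOLUME[ref_sequence[i - 1]] + RESIDUE_VOLUME[ref_sequence[j - 1]]
            if vol > overpack_factor * budget:
                conflicts.append(
                    Conflict(
                        to_long(i), "overpacked_pair", SEVERITY["overpacked_pair"],
                        f"pair ({to_long(i)},{to_long(j)}) volume {vol:.0f} exceeds "
                        f"budget {overpack_factor:.2f}x{budget:.0f} in {context} fold",
                    )
                )
    return conflicts


def score_conflicts(
    emb: Embedding,
    long: FoldTemplate,
    short: FoldTemplate,
    sequence: str,
    overpack_factor: float = OVERPACK_FACTOR,
    underpack_fraction: float = UNDERPACK_FRACTION,
) -> ConflictReport:
    """Count catastrophic interactions of one long-frame sequence in both folds.

    Every position is evaluated in the long-fold context; positions inside
    the embedded window are additionally evaluated in the short-fold
    context through the offset.  Both templates must carry burial classes.
    """
    if len(sequence) != long.length:
        raise DomainError(f"sequence length {len(sequence)} != long fold length {long.length}")
    conflicts = _fold_context_conflicts(
        sequence, long, "long", lambda p: p, long.ref_sequence,
        overpack_factor, underpack_fraction,
    )
    w0, w1 = emb.window
    short_seq = sequence[w0 - 1 : w1]
    conflicts += _fold_context_conflicts(
        short_seq, short, "short", emb.to_long, short.ref_sequence,
        overpack_factor, underpack_fraction,
    )
    conflicts.sort(key=lambda c: (c.long_position, c.kind, c.detail))
    return ConflictReport(embedding=emb, conflicts=tuple(conflicts))


def rank_key(report: ConflictReport) -> tuple:
    """Sort key for alignment ranking: fewest conflicts, lowest severity,
    most kind-matched element correspondences, smallest offset."""
    return (
        report.total_count,
        report.total_severity,
        -report.embedding.kind_matches,
        report.embedding.offset,
    )


def rank_embeddings(reports: list[ConflictReport]) -> list[ConflictReport]:
    """Deterministic ranking of conflict reports (best alignment first)."""
    if not reports:
        raise DomainError("cannot rank an empty list of conflict reports")
    return sorted(reports, key=rank_key)
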