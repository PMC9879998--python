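"""Coarse-grained fold templates: topology, contact maps, burial classes.

A fold is represented at the resolution the dual-fold design procedure
needs: an ordered list of secondary-structure elements (helices and
strands; loops are the gaps between them), a residue-residue contact map
built from representative side-chain positions, a per-residue burial
class derived from contact counts, and a reference amino acid sequence.
Residue numbering is 1-based and inclusive throughout.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, TopologyFormatError

logger = logging.getLogger(__name__)

# -- configuration defaults ------------------------------------------------

#: Distance cutoff (angstrom) between representative atoms defining a contact.
CONTACT_CUTOFF = 8.0
#: Minimum sequence separation |i - j| for a contact.
MIN_SEQ_SEP = 3

HELIX, STRAND, LOOP = "helix", "strand", "loop"

_CHAR_TO_KIND = {
    "α": HELIX, "a": HELIX, "H": HELIX, "h": HELIX,
    "β": STRAND, "b": STRAND, "E": STRAND, "e": STRAND,
}
_KIND_TO_GREEK = {HELIX: "α", STRAND: "β"}
_KIND_TO_HE = {HELIX: "H", STRAND: "E"}


def parse_topology(topology: str) -> list[str]:
    """Parse a compact topology string into an ordered list of element kinds.

    Both the Greek alphabet (``"βαββαβ"``) and the H/E alphabet
    (``"EHEEHE"``) are accepted, case-insensitively.

    Raises
    ------
    TopologyFormatError
        If a character maps to no element kind; the message names the
        character and its (1-based) position.
    """
    kinds = []
    for pos, ch in enumerate(topology, start=1):
        try:
            kinds.append(_CHAR_TO_KIND[ch])
        except KeyError:
            raise TopologyFormatError(
                f"unknown topology character {ch!r} at position {pos}"
            ) from None
    return kinds


def format_topology(kinds: list[str], alphabet: str = "greek") -> str:
    """Inverse of :func:`parse_topology`. ``alphabet`` is ``greek`` or ``he``."""
    table = _KIND_TO_GREEK if alphabet == "greek" else _KIND_TO_HE
    try:
        return "".join(table[k] for k in kinds)
    except KeyError as exc:
        raise TopologyFormatError(f"cannot format element kind {exc.args[0]!r}") from None


# -- domain types ----------------------------------------------------------


@dataclass(frozen=True)
class SecondaryElement:
    """One helix or strand, spanning residues ``start..end`` (1-based, inclusive)."""

    kind: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.kind not in (HELIX, STRAND, LOOP):
            raise DomainError(f"unknown element kind {self.kind!r}")
        if self.start > self.end:
            raise DomainError(f"element {self.label or self.kind}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class BurialPolicy:
    """Contact-count thresholds mapping contact number to burial class."""

    contact_number_core: int = 6
    contact_number_surface: int = 2

    def __post_init__(self):
        if self.contact_number_surface >= self.contact_number_core:
            raise DomainError("surface threshold must be below core threshold")


@dataclass(frozen=True)
class FoldTemplate:
    """Coarse template for one fold.

    ``contacts`` is a frozenset of sorted ``(i, j)`` residue pairs with
    ``i < j`` and ``j - i >= MIN_SEQ_SEP``.  ``burial`` maps every residue
    to one of ``core``/``boundary``/``surface`` (may be ``None`` before
    classification).  ``ref_sequence`` has length ``length``.
    """

    name: str
    length: int
    elements: tuple[SecondaryElement, ...]
    contacts: frozenset[tuple[int, int]]
    ref_sequence: str
    burial: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(self.ref_sequence) != self.length:
            raise DomainError(
                f"{self.name}: ref_sequence length {len(self.ref_sequence)} != {self.length}"
            )
        prev_end = 0
        for el in self.elements:
            if el.start <= prev_end:
                raise DomainError(f"{self.name}: elements overlap or are out of order at {el.label}")
            if el.end > self.length:
                raise DomainError(f"{self.name}: element {el.label} extends past length {self.length}")
            prev_end = el.end
        for i, j in self.contacts:
            if not (1 <= i < j <= self.length):
                raise DomainError(f"{self.name}: contact ({i},{j}) out of range")
            if j - i < MIN_SEQ_SEP:
                raise DomainError(f"{self.name}: contact ({i},{j}) below minimum sequence separation")
        if self.burial is not None and len(self.burial) != self.length:
            raise DomainError(f"{self.name}: burial classes must cover all residues")

    # -- queries --

    @property
    def topology_string(self) -> str:
        return format_topology([el.kind for el in self.elements])

    def element_at(self, pos: int) -> SecondaryElement | None:
        """Element containing residue ``pos``, or None if it lies in a loop."""
        for el in self.elements:
            if pos in el:
                return el
        return None

    def element_by_label(self, label: str) -> SecondaryElement:
        for el in self.elements:
            if el.label == label:
                return el
        raise KeyError(label)

    def contact_counts(self) -> np.ndarray:
        """Number of contacts per residue, index 0 = residue 1."""
        counts = np.zeros(self.length, dtype=int)
        for i, j in self.contacts:
            counts[i - 1] += 1
            counts[j - 1] += 1
        return counts

    def partners(self, pos: int) -> list[int]:
        """Contact partners of residue ``pos``."""
        out = [j for i, j in self.contacts if i == pos]
        out += [i for i, j in self.contacts if j == pos]
        return sorted(out)

    def burial_of(self, pos: int) -> str:
        if self.burial is None:
            raise DomainError(f"{self.name}: burial classes not assigned")
        return self.burial[pos - 1]

    # -- serialization --

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "length": self.length,
            "elements": [
                {"kind": el.kind, "start": el.start, "end": el.end, "label": el.label}
                for el in self.elements
            ],
            "topology_string": self.topology_string,
            "contacts": sorted([list(p) for p in self.contacts]),
            "burial": list(self.burial) if self.burial is not None else None,
            "ref_sequence": self.ref_sequence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldTemplate":
        return cls(
            name=d["name"],
            length=d["length"],
            elements=tuple(
                SecondaryElement(e["kind"], e["start"], e["end"], e.get("label", ""))
                for e in d["elements"]
            ),
            contacts=frozenset(tuple(p) for p in d["contacts"]),
            ref_sequence=d["ref_sequence"],
            burial=tuple(d["burial"]) if d.get("burial") else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FoldTemplate":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- operations ------------------------------------------------------------


def contacts_from_coordinates(
    coords: dict[int, np.ndarray],
    cutoff: float = CONTACT_CUTOFF,
    min_seq_sep: int = MIN_SEQ_SEP,
) -> frozenset[tuple[int, int]]:
    """Contact set from representative-atom coordinates.

    ``coords`` maps 1-based residue indices to 3-vectors; residues without
    coordinates are simply absent (the PDB reader warns about them).
    ``(i, j)`` with ``i < j`` is a contact iff the distance is at most
    ``cutoff`` and ``j - i >= min_seq_sep``.
    """
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    idx = sorted(coords)
    if not idx:
        return frozenset()
    xyz = np.array([coords[i] for i in idx], dtype=float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    out = set()
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if j - i >= min_seq_sep and dist[a, b] <= cutoff:
                out.add((i, j))
    return frozenset(out)


def classify_burial(template: FoldTemplate, policy: BurialPolicy = BurialPolicy()) -> tuple[str, ...]:
    """Burial class per residue from contact counts.

    ``core`` if the contact count is at least ``policy.contact_number_core``,
    ``surface`` if at most ``policy.contact_number_surface``, else
    ``boundary``.
    """
    counts = template.contact_counts()
    classes = []
    for c in counts:
        if c >= policy.contact_number_core:
            classes.append("core")
        elif c <= policy.contact_number_surface:
            classes.append("surface")
        else:
            classes.append("boundary")
    return tuple(classes)


def with_burial(template: FoldTemplate, policy: BurialPolicy = BurialPolicy()) -> FoldTemplate:
    """Return a copy of ``template`` with burial classes assigned."""
    return replace(template, burial=classify_burial(template, policy))


# -- file readers ----------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Read FASTA records as ``(id, description, sequence)`` tuples."""
    from Bio import SeqIO

    return [(rec.id, rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str, str]]) -> None:
    """Write ``(id, description, sequence)`` tuples as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(seq), id=rid, description=desc if desc != rid else "")
        for rid, desc, seq in records
    ]
    seqio_write(recs, str(path), "fasta")


def read_pdb_coordinates(path, chain: str | None = None) -> tuple[dict[int, np.ndarray], str]:
    """Representative-atom coordinates and sequence from a PDB file.

    Uses C-beta (C-alpha for glycine) from ATOM records of the first
    model; altloc blank or 'A'.  Residues missing both atoms are excluded
    with a warning.  Returns ``(coords, one_letter_sequence)`` with
    residues renumbered sequentially from 1.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(iter(structure))
    if chain is None:
        ch = next(iter(model))
    else:
        ch = model[chain]
    coords: dict[int, np.ndarray] = {}
    seq = []
    idx = 0
    for res in ch:
        if res.id[0] != " ":
            continue
        idx += 1
        seq.append(protein_letters_3to1.get(res.get_resname(), "X"))
        name = "CA" if res.get_resname() == "GLY" else "CB"
        if name not in res:
            warnings.warn(f"residue {idx} ({res.get_resname()}) has no {name} atom; excluded")
            logger.warning("residue %d has no representative atom; excluded from contacts", idx)
            continue
        atom = res[name]
        if atom.is_disordered():
            try:
                atom = atom.disordered_get("A")
            except Exception:
                atom = atom.disordered_get_list()[0]
        coords[idx] = np.asarray(atom.get_coord(), dtype=float)
    return coords, "".join(seq)
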