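"""Joint sequence design for two folds sharing an embedded window.

After an alignment is chosen, the two reference sequences are merged
(the embedded window takes the short fold's sequence) and the remaining
catastrophic interactions are resolved by exhaustive substitution search
over small clusters of spatially coupled positions.  The governing
objective is *conservation*: among assignments that remove the conflicts,
the one changing the fewest residues wins; a coarse dual-fold energy and
then alphabetical order break ties.  Positions outside the window are
then optionally optimised for long-fold stability alone; the embedded
window is never edited after merging, so the short construct is always
exactly the window of the long sequence.

The coarse energy is a deliberately simple pairwise-contact + burial +
secondary-structure-propensity score: it stands behind the same
interface an all-atom scorer would use (see :class:`ExternalScorer`),
and only its orderings matter to the search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Protocol

import numpy as np

from .embedding import ConflictReport, Embedding, score_conflicts
from .errors import DomainError
from .fold_model import FoldTemplate
from .tables import (
    AA_INDEX,
    AMINO_ACIDS,
    burial_term,
    contact_potential,
    ss_propensity,
)

logger = logging.getLogger(__name__)

# -- configuration defaults ------------------------------------------------

#: Substitution alphabet for designed positions: no C (disulfides), no P
#: (backbone breaker), no W/M/H.
CANDIDATE_ALPHABET = "AGSTVLIFYDEKRNQ"
#: Greedy stability sweeps over non-overlap positions.
MAX_SWEEPS = 20
#: Cap on exhaustive cluster assignments before per-position candidate pruning.
MAX_ASSIGNMENTS = 2000
#: Energies compared in tie-breaks after rounding to this many decimals.
ENERGY_DECIMALS = 6


# -- energy model ----------------------------------------------------------


@dataclass(frozen=True)
class EnergyModel:
    """Additive coarse energy: contacts + burial + secondary-structure terms.

    ``contact_potential`` is a symmetric 20x20 array in :data:`AMINO_ACIDS`
    order; ``burial`` maps class name to a 20-vector; ``ss`` maps element
    kind to a 20-vector.  Lower is more favourable everywhere.
    """

    contact: np.ndarray
    burial: dict[str, np.ndarray]
    ss: dict[str, np.ndarray]
    weights: tuple[float, float, float] = (1.0, 1.0, 0.5)

    def __post_init__(self):
        if self.contact.shape != (20, 20) or not np.allclose(self.contact, self.contact.T):
            raise DomainError("contact potential must be a symmetric 20x20 table")
        if any(w < 0 for w in self.weights):
            raise DomainError("energy weights must be non-negative")

    @classmethod
    def default(cls) -> "EnergyModel":
        return cls(contact=contact_potential(), burial=burial_term(), ss=ss_propensity())


class ExternalScorer(Protocol):
    """Adapter interface for an external all-atom scorer.

    Any callable mapping ``(sequence, template) -> float`` (lower =
    better) can replace :func:`coarse_energy` wherever a scorer argument
    is accepted; no binding to a particular program is shipped.
    """

    def __call__(self, sequence: str, template: FoldTemplate) -> float: ...


def _seq_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[c] for c in sequence], dtype=int)
    except KeyError:
        for pos, c in enumerate(sequence, start=1):
            if c not in AA_INDEX:
                raise DomainError(f"nonstandard residue {c!r} at position {pos}") from None
        raise


class EnergyEvaluator:
    """Precomputed fast evaluator of the coarse energy for one template."""

    def __init__(self, template: FoldTemplate, model: EnergyModel):
        self.template = template
        self.model = model
        pairs = sorted(template.contacts)
        self._ci = np.array([i - 1 for i, _ in pairs], dtype=int)
        self._cj = np.array([j - 1 for _, j in pairs], dtype=int)
        if template.burial is None:
            raise DomainError(f"{template.name}: burial classes required for energy evaluation")
        self._bur = np.stack([model.burial[b] for b in template.burial])  # (L, 20)
        ssrows = np.zeros((template.length, 20))
        for el in template.elements:
            if el.kind in model.ss:
                ssrows[el.start - 1 : el.end] = model.ss[el.kind]
        self._ss = ssrows

    def energy(self, sequence: str) -> float:
        s = _seq_indices(sequence)
        w_c, w_b, w_s = self.model.weights
        e_c = self.model.contact[s[self._ci], s[self._cj]].sum() if len(self._ci) else 0.0
        e_b = self._bur[np.arange(len(s)), s].sum()
        e_s = self._ss[np.arange(len(s)), s].sum()
        return float(w_c * e_c + w_b * e_b + w_s * e_s)


def coarse_energy(sequence: str, template: FoldTemplate, model: EnergyModel | None = None) -> float:
    """Coarse fold-compatibility energy of ``sequence`` on ``template``.

    ``w_c * sum contact P[s_i, s_j] + w_b * sum burial B[class_i, s_i]
    + w_s * sum_{i in elements} S[kind_i, s_i]``; deterministic and
    additive over the three terms.  Loop positions contribute no
    secondary-structure term.
    """
    if len(sequence) != template.length:
        raise DomainError(f"sequence length {len(sequence)} != template length {template.length}")
    model = model or EnergyModel.default()
    return EnergyEvaluator(template, model).energy(sequence)


# -- joint design ----------------------------------------------------------


class MutationRecord(NamedTuple):
    position: int
    frm: str
    to: str
    stage: str  # cluster | nonoverlap | variant | tail_graft


class Identity(NamedTuple):
    percent: float
    nearest: int


@dataclass(frozen=True)
class JointDesign:
    """One long-frame sequence serving both folds.

    The embedded window of ``long_sequence`` *is* the short construct;
    ``mutation_log`` replays from ``initial_sequence`` (the merged
    starting point) to ``long_sequence``.
    """

    name: str
    long_sequence: str
    embedding: Embedding
    initial_sequence: str
    mutation_log: tuple[MutationRecord, ...] = ()

    @property
    def short_sequence(self) -> str:
        w0, w1 = self.embedding.window
        return self.long_sequence[w0 - 1 : w1]

    def in_window(self, pos: int) -> bool:
        return self.embedding.contains(pos)

    def replay(self) -> str:
        """Apply the mutation log to the initial sequence (consistency check)."""
        seq = self.initial_sequence
        for rec in self.mutation_log:
            if rec.stage == "tail_graft":
                if seq[rec.position - 1 : rec.position - 1 + len(rec.frm)] != rec.frm:
                    raise DomainError(f"mutation log replay mismatch at graft {rec.position}")
                seq = seq[: rec.position - 1] + rec.to
            else:
                if seq[rec.position - 1] != rec.frm:
                    raise DomainError(
                        f"mutation log replay mismatch at {rec.position}: "
                        f"expected {rec.frm}, found {seq[rec.position - 1]}"
                    )
                seq = seq[: rec.position - 1] + rec.to + seq[rec.position :]
        return seq


def merge_initial(embedding: Embedding, long: FoldTemplate, short: FoldTemplate) -> JointDesign:
    """Thread the short reference sequence into the long one.

    The embedded window takes the short fold's reference sequence; every
    other position keeps the long fold's reference.
    """
    w0, w1 = embedding.window
    if w0 < 1 or w1 > long.length:
        raise DomainError("embedding does not fit inside the long fold")
    seq = long.ref_sequence[: w0 - 1] + short.ref_sequence + long.ref_sequence[w1:]
    return JointDesign(
        name=f"{long.name}+{short.name}",
        long_sequence=seq,
        embedding=embedding,
        initial_sequence=seq,
    )


# -- conflict clustering ---------------------------------------------------


def find_conflict_clusters(
    report: ConflictReport,
    template: FoldTemplate,
    max_cluster: int = 6,
) -> list[tuple[int, ...]]:
    """Group conflict positions into small spatially coupled clusters.

    Clusters are connected components of the contact graph restricted to
    conflict positions plus their contact partners; components larger
    than ``max_cluster`` are split greedily along the sequence, and
    singleton components are padded with their highest-contact-count
    sequence neighbour so a substitution search has at least a pair to
    work with.
    """
    import networkx as nx

    conflict_pos = sorted({c.long_position for c in report.conflicts})
    if not conflict_pos:
        return []
    members = set(conflict_pos)
    for p in conflict_pos:
        members.update(template.partners(p))
    g = nx.Graph()
    g.add_nodes_from(members)
    for i, j in template.contacts:
        if i in members and j in members:
            g.add_edge(i, j)
    counts = template.contact_counts()
    clusters: list[tuple[int, ...]] = []
    for comp in sorted(nx.connected_components(g), key=min):
        pos = sorted(comp)
        if len(pos) == 1:
            p = pos[0]
            neighbors = [q for q in (p - 1, p + 1) if 1 <= q <= template.length]
            neighbors.sort(key=lambda q: (-counts[q - 1], q))
            if neighbors:
                pos = sorted([p, neighbors[0]])
        while len(pos) > max_cluster:
            clusters.append(tuple(pos[:max_cluster]))
            pos = pos[max_cluster:]
        clusters.append(tuple(pos))
    return clusters


# -- cluster resolution ----------------------------------------------------


def _conflicts_within(report: ConflictReport, cluster: set[int]) -> list:
    """Conflicts attributed to cluster positions (pairs count if either
    endpoint lies in the cluster; pair partners are recorded in detail)."""
    out = []
    for c in report.conflicts:
        if c.long_position in cluster:
            out.append(c)
        elif c.kind == "overpacked_pair":
            # detail carries "pair (i,j) ..."
            inside = any(p in cluster for p in _pair_positions(c.detail))
            if inside:
                out.append(c)
    return out


def _pair_positions(detail: str) -> tuple[int, int]:
    frag = detail.split("(", 1)[1].split(")", 1)[0]
    i, j = frag.split(",")
    return int(i), int(j)


def resolve_cluster(
    design: JointDesign,
    cluster: tuple[int, ...],
    long: FoldTemplate,
    short: FoldTemplate,
    model: EnergyModel | None = None,
    candidate_alphabet: str = CANDIDATE_ALPHABET,
    max_assignments: int = MAX_ASSIGNMENTS,
) -> JointDesign:
    """Exhaustively search substitutions over one cluster of positions.

    Feasible assignments leave zero conflicts attributed to the cluster
    under both fold contexts; among them the choice is lexicographic:
    fewest mutations from the current sequence, lowest combined dual
    energy (long + embedded-window short energy, rounded to
    ``ENERGY_DECIMALS``), then alphabetical.  If nothing is feasible the
    minimal-conflict assignment under the same tie-break chain is taken
    and a warning logged.  When the full product of per-position
    candidates exceeds ``max_assignments``, each position's candidate
    list is pruned to the best single substitutions so the product fits.
    """
    if len(cluster) > 6:
        raise DomainError(f"cluster of {len(cluster)} positions exceeds the maximum of 6")
    model = model or EnergyModel.default()
    e_long = EnergyEvaluator(long, model)
    e_short = EnergyEvaluator(short, model)
    cluster = tuple(sorted(cluster))
    cset = set(cluster)
    base = design.long_sequence
    w0, w1 = design.embedding.window

    def assemble(assign: tuple[str, ...]) -> str:
        seq = list(base)
        for p, aa in zip(cluster, assign):
            seq[p - 1] = aa
        return "".join(seq)

    def dual_energy(seq: str) -> float:
        return e_long.energy(seq) + e_short.energy(seq[w0 - 1 : w1])

    def evaluate(assign: tuple[str, ...]) -> tuple:
        seq = assemble(assign)
        rep = score_conflicts(design.embedding, long, short, seq)
        n_conf = len(_conflicts_within(rep, cset))
        n_mut = sum(1 for p, aa in zip(cluster, assign) if aa != base[p - 1])
        return (n_conf, n_mut, round(dual_energy(seq), ENERGY_DECIMALS), assign)

    candidates: list[list[str]] = []
    for p in cluster:
        cur = base[p - 1]
        alts = [cur] + [aa for aa in candidate_alphabet if aa != cur]
        candidates.append(alts)

    total = int(np.prod([len(c) for c in candidates]))
    if total > max_assignments:
        per_pos = max(2, int(max_assignments ** (1.0 / len(cluster))))
        pruned = []
        for k, p in enumerate(cluster):
            scored = []
            for aa in candidates[k]:
                assign = tuple(base[q - 1] if q != p else aa for q in cluster)
                scored.append((evaluate(assign)[:3], aa))
            scored.sort(key=lambda t: (t[0], t[1]))
            keep = [base[p - 1]] + [aa for _, aa in scored if aa != base[p - 1]]
            pruned.append(keep[:per_pos])
        candidates = pruned
        logger.info(
            "cluster %s: pruned candidate sets to %s per position (budget %d)",
            cluster, per_pos, max_assignments,
        )

    best = min(evaluate(a) for a in itertools.product(*candidates))
    n_conf, n_mut, _, assign = best
    if n_conf > 0:
        logger.warning(
            "cluster %s infeasible: best assignment leaves %d conflict(s)", cluster, n_conf
        )
    new_seq = assemble(assign)
    log = list(design.mutation_log)
    for p, aa in zip(cluster, assign):
        if aa != base[p - 1]:
            log.append(MutationRecord(p, base[p - 1], aa, "cluster"))
    return replace(design, long_sequence=new_seq, mutation_log=tuple(log))


# -- non-overlap stability optimisation ------------------------------------


def optimize_nonoverlap(
    design: JointDesign,
    long: FoldTemplate,
    short: FoldTemplate,
    model: EnergyModel | None = None,
    candidate_alphabet: str = CANDIDATE_ALPHABET,
    max_sweeps: int = MAX_SWEEPS,
) -> JointDesign:
    """Greedy long-fold stability sweep over positions outside the window.

    A substitution is accepted iff it strictly lowers the long-fold
    coarse energy and introduces no new conflict (total conflict count
    does not increase).  Sweeps repeat until a full pass accepts nothing
    or ``max_sweeps`` is reached; the embedded window is never touched.
    """
    model = model or EnergyModel.default()
    ev = EnergyEvaluator(long, model)
    seq = design.long_sequence
    log = list(design.mutation_log)
    w0, w1 = design.embedding.window
    positions = [p for p in range(1, long.length + 1) if not (w0 <= p <= w1)]
    base_report = score_conflicts(design.embedding, long, short, seq)
    n_conflicts = base_report.total_count

    for sweep in range(max_sweeps):
        accepted = 0
        for p in positions:
            cur = seq[p - 1]
            cur_e = ev.energy(seq)
            scored = []
            for aa in candidate_alphabet:
                if aa == cur:
                    continue
                cand = seq[: p - 1] + aa + seq[p:]
                e = ev.energy(cand)
                if e < cur_e - 10 ** -ENERGY_DECIMALS:
                    scored.append((e, aa, cand))
            scored.sort()
            for e, aa, cand in scored:
                rep = score_conflicts(design.embedding, long, short, cand)
                if rep.total_count <= n_conflicts:
                    seq = cand
                    n_conflicts = rep.total_count
                    log.append(MutationRecord(p, cur, aa, "nonoverlap"))
                    accepted += 1
                    break
        logger.info("nonoverlap sweep %d: %d substitutions accepted", sweep + 1, accepted)
        if accepted == 0:
            break
    else:
        logger.info("nonoverlap optimisation stopped at max_sweeps=%d", max_sweeps)
    return replace(design, long_sequence=seq, mutation_log=tuple(log))


# -- variants, truncation, grafting, identity ------------------------------


def apply_variant(
    design: JointDesign,
    mutations: list[tuple[int, str, str]],
    name: str | None = None,
) -> tuple[JointDesign, tuple[bool, ...]]:
    """Apply named point mutations, e.g. ``[(5, "Y", "L")]`` for Y5L.

    Each ``from`` residue must match the current sequence (guards against
    stale coordinates).  Returns the renamed design and, per mutation,
    whether the site lies inside the embedded window (i.e. whether the
    derived short construct changes too).
    """
    seq = design.long_sequence
    log = list(design.mutation_log)
    inside = []
    for pos, frm, to in mutations:
        if not (1 <= pos <= len(seq)):
            raise DomainError(f"mutation position {pos} outside sequence")
        if seq[pos - 1] != frm:
            raise DomainError(
                f"stale mutation {frm}{pos}{to}: current residue is {seq[pos - 1]}"
            )
        seq = seq[: pos - 1] + to + seq[pos:]
        log.append(MutationRecord(pos, frm, to, "variant"))
        inside.append(design.in_window(pos))
    new_name = name or design.name + "".join(f"+{f}{p}{t}" for p, f, t in mutations)
    return (
        replace(design, name=new_name, long_sequence=seq, mutation_log=tuple(log)),
        tuple(inside),
    )


def truncate_to_short(design: JointDesign) -> str:
    """The embedded-window sequence: the short construct, exactly."""
    return design.short_sequence


def graft_cterminal_tail(sequence: str, n_replace: int, tail: str) -> str:
    """Replace the last ``n_replace`` residues with ``tail``.

    This is how inhibitor function is (re)installed on a design: the
    C-terminal residues are swapped for a protease-binding tail.
    """
    if n_replace > len(sequence):
        raise DomainError(f"cannot replace {n_replace} residues of a {len(sequence)}-mer")
    if not tail:
        raise DomainError("tail must be non-empty")
    return sequence[: len(sequence) - n_replace] + tail


def graft_design_tail(design: JointDesign, n_replace: int, tail: str, name: str | None = None) -> JointDesign:
    """C-terminal tail graft on a design; must not reach into the window."""
    seq = design.long_sequence
    _, w1 = design.embedding.window
    if len(seq) - n_replace < w1:
        raise DomainError("tail graft would replace embedded-window residues")
    new_seq = graft_cterminal_tail(seq, n_replace, tail)
    start = len(seq) - n_replace + 1
    rec = MutationRecord(start, seq[start - 1 :], tail, "tail_graft")
    return replace(
        design,
        name=name or design.name + "I",
        long_sequence=new_seq,
        mutation_log=design.mutation_log + (rec,),
    )


def percent_identity(a: str, b: str) -> Identity:
    """Positional identity over an alignment of equal length, as a percentage.

    Returns the raw percentage and its nearest-integer rounding (one
    substitution in 56 residues -> 98.2 -> 98).
    """
    if len(a) != len(b):
        raise DomainError(f"sequence lengths differ ({len(a)} vs {len(b)})")
    if not a:
        raise DomainError("cannot compute identity of empty sequences")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    pct = 100.0 * matches / len(a)
    return Identity(percent=pct, nearest=int(round(pct)))
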