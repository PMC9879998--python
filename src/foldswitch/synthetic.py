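"""Synthetic inputs for every pipeline stage.

The central generator builds *fold pairs with a planted embedding*: a
long fold template, a short fold excised from a window of it, and
reference sequences arranged so that the planted offset scores a chosen
number of catastrophic interactions while every other admissible offset
scores at least a (higher) decoy floor.  Ranking candidate alignments on
such a pair must therefore recover the planted offset at rank 1 — the
module's core guarantee, and what makes the whole design engine testable
without any structure downloads.

Geometry is explicit rather than a random graph: strands are laid out as
a flat sheet, helices packed above it, loops arced away, and the contact
map computed from the resulting coordinates with the standard cutoff —
so burial classes and contacts are geometrically coherent and conflict
planting is interpretable.

Melt and kinetics simulators with realistic defaults (20-100 deg C scan
in 0.5 deg steps; substrate 0.1-10 uM with inhibitor at 0/50/100 nM)
round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assays import (
    INHIBITOR_GRID_NM,
    SUBSTRATE_GRID_UM,
    InhibitionDataset,
    km_apparent,
    mm_rate,
)
from .embedding import (
    ANCHOR_MIN_OVERLAP,
    Embedding,
    enumerate_embeddings,
    score_conflicts,
)
from .errors import DomainError, GenerationError
from .fold_model import (
    HELIX,
    STRAND,
    BurialPolicy,
    FoldTemplate,
    SecondaryElement,
    contacts_from_coordinates,
    with_burial,
)
from .tables import POLAR_RESIDUES
from .thermo import (
    DEFAULT_BASELINES,
    MeltingCurve,
    ThermoState,
    default_melt_grid,
    simulate_melt,
)

logger = logging.getLogger(__name__)

#: Residue pools by burial class for generated reference sequences.
CORE_POOL = "LIVF"
BOUNDARY_POOL = "AVTS"
SURFACE_POOL = "STNEKDQA"
#: Layout attempts before the generator gives up.
MAX_ATTEMPTS = 100


@dataclass(frozen=True)
class ToyFoldSpec:
    """Specification of a planted fold pair.

    ``decoy_conflict_floor`` must exceed ``n_planted_conflicts`` so the
    plant is recoverable by conflict-count ranking.
    """

    long_length: int = 90
    short_length: int = 56
    anchor_kind: str = HELIX
    anchor_length: int = 16
    planted_offset: int = 10
    n_planted_conflicts: int = 3
    decoy_conflict_floor: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.decoy_conflict_floor <= self.n_planted_conflicts:
            raise DomainError("decoy_conflict_floor must exceed n_planted_conflicts")
        if self.short_length > self.long_length:
            raise DomainError("short fold cannot exceed long fold length")
        if not (0 <= self.planted_offset <= self.long_length - self.short_length):
            raise DomainError("planted offset does not fit inside the long fold")
        if self.anchor_kind != HELIX:
            raise DomainError("only helix anchors are generated")
        if not (8 <= self.anchor_length <= 30):
            raise DomainError("anchor length outside generator bounds (8-30)")
        if not (40 <= self.long_length <= 200):
            raise DomainError("long length outside generator bounds (40-200)")


# -- geometric layout ------------------------------------------------------


def _helix_coords(n: int, origin: np.ndarray, direction: int) -> np.ndarray:
    """Ideal alpha-helix: 1.5 A rise, 100 deg per residue, 2.3 A radius."""
    t = np.arange(n)
    ang = np.deg2rad(100.0) * t
    x = origin[0] + direction * 1.5 * t
    y = origin[1] + 2.3 * np.cos(ang)
    z = origin[2] + 2.3 * np.sin(ang)
    return np.column_stack([x, y, z])


def _strand_coords(n: int, origin: np.ndarray, direction: int) -> np.ndarray:
    """Extended strand: 3.4 A rise with a small pleat."""
    t = np.arange(n)
    x = origin[0] + direction * 3.4 * t
    y = np.full(n, origin[1])
    z = origin[2] + 0.6 * (-1.0) ** t
    return np.column_stack([x, y, z])


def _loop_coords(n: int, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Loop residues on an arc bulging away (negative z) from the scaffold."""
    out = np.zeros((n, 3))
    for k in range(n):
        f = (k + 1) / (n + 1)
        p = (1 - f) * start + f * end
        p[2] -= 7.0 * np.sin(np.pi * f)
        out[k] = p
    return out


def _layout_elements(plan: list[tuple[str, int]], loop_lengths: list[int]) -> np.ndarray:
    """Coordinates for a chain of elements separated by loops.

    ``plan`` lists (kind, length) per element; ``loop_lengths`` has one
    entry per gap including the leading and trailing tails.
    """
    n_total = sum(n for _, n in plan) + sum(loop_lengths)
    coords = np.zeros((n_total, 3))
    strand_row = 0
    helix_row = 0
    placed: list[np.ndarray] = []
    idx = loop_lengths[0]
    element_xyz = []
    for e, (kind, n) in enumerate(plan):
        direction = 1 if e % 2 == 0 else -1
        if kind == STRAND:
            origin = np.array([-1.7 * n * direction, 5.0 * strand_row, 0.0])
            xyz = _strand_coords(n, origin, direction)
            strand_row += 1
        else:
            origin = np.array([-0.75 * n * direction, 2.5 + 10.0 * helix_row, 6.5])
            xyz = _helix_coords(n, origin, direction)
            helix_row += 1
        element_xyz.append((idx, xyz))
        idx += n + loop_lengths[e + 1]
    for (start_idx, xyz) in element_xyz:
        coords[start_idx : start_idx + len(xyz)] = xyz
    # Fill loops (and tails) by interpolation between flanking element ends.
    cursor = 0
    for e in range(len(plan) + 1):
        n_loop = loop_lengths[e]
        if n_loop:
            left = element_xyz[e - 1][1][-1] if e > 0 else element_xyz[0][1][0] + [-6, -6, -2]
            right = element_xyz[e][1][0] if e < len(plan) else element_xyz[-1][1][-1] + [6, 6, -2]
            coords[cursor : cursor + n_loop] = _loop_coords(n_loop, np.array(left, float), np.array(right, float))
        cursor += n_loop
        if e < len(plan):
            cursor += plan[e][1]
    return coords


def _build_long_template(spec: ToyFoldSpec, rng: np.random.Generator) -> FoldTemplate:
    """A beta-alpha-beta-beta-alpha-beta long fold with the anchor helix first."""
    a = spec.anchor_length
    plan = [
        (STRAND, 7),
        (HELIX, a),
        (STRAND, 6),
        (STRAND, 6),
        (HELIX, 10),
        (STRAND, 6),
    ]
    n_elem = sum(n for _, n in plan)
    n_loops = spec.long_length - n_elem
    if n_loops < 7 * 2:
        raise GenerationError("long fold too short for the element plan")
    # 7 gaps (leading tail, 5 internal loops, trailing tail); each >= 2.
    cuts = rng.multinomial(n_loops - 14, np.full(7, 1 / 7))
    loop_lengths = [int(2 + c) for c in cuts]
    # The anchor helix must sit fully inside the planted window.
    start_a1 = loop_lengths[0] + plan[0][1] + loop_lengths[1] + 1
    w0, w1 = spec.planted_offset + 1, spec.planted_offset + spec.short_length
    shift = 0
    if start_a1 < w0:
        shift = w0 - start_a1
    if start_a1 + a - 1 + shift > w1:
        raise GenerationError("anchor helix cannot fit inside the planted window")
    loop_lengths[1] += shift
    loop_lengths[2] = max(2, loop_lengths[2] - shift)
    total = sum(n for _, n in plan) + sum(loop_lengths)
    loop_lengths[-1] += spec.long_length - total
    if loop_lengths[-1] < 0:
        raise GenerationError("loop budget exhausted")

    coords = _layout_elements(plan, loop_lengths)
    elements = []
    pos = loop_lengths[0] + 1
    helix_i = strand_i = 0
    for e, (kind, n) in enumerate(plan):
        if kind == HELIX:
            helix_i += 1
            label = f"α{helix_i}"
        else:
            strand_i += 1
            label = f"β{strand_i}"
        elements.append(SecondaryElement(kind, pos, pos + n - 1, label))
        pos += n + loop_lengths[e + 1]
    contacts = contacts_from_coordinates({i + 1: coords[i] for i in range(len(coords))})
    template = FoldTemplate(
        name=f"toyS-{spec.seed}",
        length=spec.long_length,
        elements=tuple(elements),
        contacts=contacts,
        ref_sequence="A" * spec.long_length,
    )
    return with_burial(template)


def _excise_short(long_t: FoldTemplate, spec: ToyFoldSpec) -> FoldTemplate:
    w0, w1 = spec.planted_offset + 1, spec.planted_offset + spec.short_length
    off = spec.planted_offset
    elements = []
    for el in long_t.elements:
        s, e = max(el.start, w0), min(el.end, w1)
        if e - s + 1 >= 3:
            elements.append(SecondaryElement(el.kind, s - off, e - off, el.label))
    contacts = frozenset(
        (i - off, j - off) for i, j in long_t.contacts if w0 <= i and j <= w1 and i >= w0 and j <= w1
    )
    short = FoldTemplate(
        name=f"toyG-{spec.seed}",
        length=spec.short_length,
        elements=tuple(elements),
        contacts=contacts,
        ref_sequence="A" * spec.short_length,
    )
    return with_burial(short)


def _assign_reference_sequences(
    long_t: FoldTemplate, short_t: FoldTemplate, spec: ToyFoldSpec, rng: np.random.Generator
) -> tuple[str, str]:
    """Base sequences with zero conflicts at the planted offset.

    Long-core positions get large hydrophobics; the short reference
    starts as the window of the long one.
    """
    seq = []
    for pos in range(1, long_t.length + 1):
        b = long_t.burial_of(pos)
        pool = CORE_POOL if b == "core" else (BOUNDARY_POOL if b == "boundary" else SURFACE_POOL)
        # Core in the short context must also avoid polar/G/A; pools already do.
        seq.append(pool[rng.integers(len(pool))])
    # A at long-core is never drawn; also keep A away from short-core positions.
    w0 = spec.planted_offset + 1
    for q in range(1, short_t.length + 1):
        if short_t.burial_of(q) == "core":
            p = q + spec.planted_offset
            if seq[p - 1] in "GA":
                seq[p - 1] = CORE_POOL[rng.integers(len(CORE_POOL))]
    long_seq = "".join(seq)
    short_seq = long_seq[w0 - 1 : w0 - 1 + spec.short_length]
    return long_seq, short_seq


def make_fold_pair(spec: ToyFoldSpec) -> tuple[FoldTemplate, FoldTemplate, Embedding]:
    """Generate (long, short, truth) with the guarantees described above.

    Deterministic per ``spec.seed``.  Raises :class:`GenerationError`
    with a hint to loosen parameters if no layout satisfies the spec
    within the attempt budget.
    """
    base_rng = np.random.default_rng(spec.seed)
    last_reason = "no attempt made"
    for attempt in range(MAX_ATTEMPTS):
        rng = np.random.default_rng(base_rng.integers(2**31))
        try:
            pair = _attempt(spec, rng)
        except GenerationError as exc:
            last_reason = str(exc)
            continue
        if pair is not None:
            if attempt:
                logger.info("fold pair generated after %d attempts", attempt + 1)
            return pair
        last_reason = "plant/decoy constraints unsatisfied"
    raise GenerationError(
        f"could not satisfy spec after {MAX_ATTEMPTS} attempts ({last_reason}); "
        "try a lower decoy_conflict_floor, fewer planted conflicts, or a longer anchor"
    )


def _attempt(spec: ToyFoldSpec, rng: np.random.Generator):
    long_t = _build_long_template(spec, rng)
    short_t = _excise_short(long_t, spec)
    anchor_label = f"α1"
    try:
        short_t.element_by_label(anchor_label)
    except KeyError:
        raise GenerationError("anchor helix lost in excision")

    long_seq, short_seq = _assign_reference_sequences(long_t, short_t, spec, rng)
    long_t = FoldTemplate(
        name=long_t.name, length=long_t.length, elements=long_t.elements,
        contacts=long_t.contacts, ref_sequence=long_seq, burial=long_t.burial,
    )
    off = spec.planted_offset
    short_list = list(short_seq)

    def short_template_with(seq: str) -> FoldTemplate:
        return FoldTemplate(
            name=short_t.name, length=short_t.length, elements=short_t.elements,
            contacts=short_t.contacts, ref_sequence=seq, burial=short_t.burial,
        )

    def merged(embedding: Embedding, sseq: str) -> str:
        a, b = embedding.window
        return long_seq[: a - 1] + sseq + long_seq[b:]

    embeddings = enumerate_embeddings(long_t, short_template_with("".join(short_list)),
                                      (anchor_label, anchor_label))
    by_offset = {e.offset: e for e in embeddings}
    if off not in by_offset:
        raise GenerationError("planted offset not admissible under the anchor rule")
    truth = by_offset[off]

    # -- plant exactly n conflicts at the true offset (K at long-core sites) --
    in_short_core = {q for q in range(1, short_t.length + 1) if short_t.burial_of(q) == "core"}
    candidates = []
    for q in range(1, short_t.length + 1):
        p = q + off
        if long_t.burial_of(p) == "core" and short_list[q - 1] not in POLAR_RESIDUES:
            gain = 2 if q in in_short_core else 1
            candidates.append((q, gain))
    rng.shuffle(candidates)
    need = spec.n_planted_conflicts
    for q, gain in sorted(candidates, key=lambda t: t[1]):
        if gain <= need:
            short_list[q - 1] = "K"
            need -= gain
        if need == 0:
            break
    if need:
        raise GenerationError("not enough plantable core sites for the requested conflicts")

    # -- raise every decoy offset to the floor with plant-neutral mines --
    decoys = [e for e in embeddings if e.offset != off]
    st = short_template_with("".join(short_list))
    counts = {
        e.offset: score_conflicts(e, long_t, st, merged(e, "".join(short_list))).total_count
        for e in decoys
    }

    def p_mine_gain(q: int, d: int) -> int:
        el = long_t.element_at(q + d)
        if el is None:
            return 0
        if el.kind == STRAND:
            return 1
        return 1 if (q + d) - el.start >= 4 else 0

    def k_mine_gain(q: int, d: int) -> int:
        return 1 if long_t.burial_of(q + d) == "core" else 0

    mine_candidates = []
    for q in range(1, short_t.length + 1):
        if short_list[q - 1] in POLAR_RESIDUES or short_list[q - 1] == "P":
            continue
        p = q + off
        # P mine: loop in both frames at the plant, so plant count is unchanged.
        if short_t.element_at(q) is None and long_t.element_at(p) is None:
            mine_candidates.append(("P", q))
        # K mine: surface/boundary in both contexts at the plant.
        if q not in in_short_core and long_t.burial_of(p) != "core":
            mine_candidates.append(("K", q))
    rng.shuffle(mine_candidates)

    floor = spec.decoy_conflict_floor
    for _ in range(60):
        deficit = {d: floor - c for d, c in counts.items() if c < floor}
        if not deficit:
            break
        best = None
        for kind, q in mine_candidates:
            if short_list[q - 1] in "PK":
                continue
            gain_fn = p_mine_gain if kind == "P" else k_mine_gain
            gains = {d: gain_fn(q, d) for d in deficit}
            useful = sum(min(g, deficit[d]) for d, g in gains.items())
            if useful and (best is None or useful > best[0]):
                best = (useful, kind, q, gain_fn)
        if best is None:
            return None  # no mine helps the remaining deficits; retry layout
        _, kind, q, gain_fn = best
        short_list[q - 1] = kind
        for d in counts:
            counts[d] += gain_fn(q, d)
    else:
        return None

    # -- final verification from scratch --
    final_short = short_template_with("".join(short_list))
    plant_count = score_conflicts(
        truth, long_t, final_short, merged(truth, "".join(short_list))
    ).total_count
    if plant_count != spec.n_planted_conflicts:
        return None
    for e in decoys:
        c = score_conflicts(e, long_t, final_short, merged(e, "".join(short_list))).total_count
        if c < spec.decoy_conflict_floor:
            return None
    return long_t, final_short, truth


# -- thermodynamic scenario ladders ----------------------------------------


def make_switch_scenario(
    dG_long: float,
    dG_switch: float,
    effects: list[tuple[str, float, float]],
    T_C: float = 25.0,
):
    """Scripted mutation ladder over the linked three-state equilibrium.

    ``effects`` maps mutation names to ``(ddG_long, ddG_switch)`` applied
    cumulatively; returns ``[(name, SwitchEquilibrium), ...]`` starting
    from the unmutated state.
    """
    from .thermo import celsius_to_kelvin, three_state_populations

    T = celsius_to_kelvin(T_C)
    out = [("start", three_state_populations(dG_long, dG_switch, T))]
    g_long, g_switch = dG_long, dG_switch
    for name, ddg_long, ddg_switch in effects:
        g_long += ddg_long
        g_switch += ddg_switch
        out.append((name, three_state_populations(g_long, g_switch, T)))
    return out


# -- kinetics and melt simulators ------------------------------------------


def simulate_inhibition(
    V_max: float,
    K_M_uM: float,
    K_I_nM: float,
    S_grid_uM: tuple[float, ...] = SUBSTRATE_GRID_UM,
    I_grid_nM: tuple[float, ...] = INHIBITOR_GRID_NM,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
    enzyme_nM: float = 1.0,
) -> InhibitionDataset:
    """Competitive-inhibition rate table with multiplicative lognormal noise.

    ``noise_cv`` is the coefficient of variation of the rate noise
    (0 gives exactly on-model rates); deterministic per seed.
    """
    if min(V_max, K_M_uM, K_I_nM) <= 0:
        raise DomainError("kinetic parameters must be positive")
    if noise_cv < 0:
        raise DomainError("noise_cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.zeros((len(I_grid_nM), len(S_grid_uM)))
    for a, I in enumerate(I_grid_nM):
        km_app = km_apparent(K_M_uM, I, K_I_nM)
        rates[a] = mm_rate(np.asarray(S_grid_uM), V_max, km_app)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.normal(-sigma**2 / 2.0, sigma, size=rates.shape)
        rates = rates * np.exp(noise)
    return InhibitionDataset(
        substrate_uM=tuple(S_grid_uM),
        inhibitor_nM=tuple(I_grid_nM),
        rates=rates,
        enzyme_nM=enzyme_nM,
    )


def simulate_melt_preset(
    tm_C: float,
    dHm: float,
    dCp: float = 0.0,
    noise_frac: float = 0.0,
    seed: int | np.random.Generator | None = None,
    baselines: tuple[float, float, float, float] = DEFAULT_BASELINES,
) -> MeltingCurve:
    """A melt on the standard 20-100 deg C scan grid.

    ``noise_frac`` scales Gaussian noise to the curve's signal range
    (e.g. 0.02 for a 2 % noise study).
    """
    grid = default_melt_grid()
    state = ThermoState.from_celsius("sim", tm_C, dHm, dCp)
    clean = simulate_melt(state, baselines, grid, noise_sd=0.0)
    span = float(np.ptp(clean.ellipticity))
    return simulate_melt(state, baselines, grid, noise_sd=noise_frac * span, seed=seed)
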