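"""Cysteine-framework extraction and 4-category classification of
three-finger-fold proteins.

A mature protein's cysteines are mapped onto a canonical 10-slot reference
template by an order-preserving, spacing-distortion-minimizing assignment;
mapped cysteines mark occupied slots, unmapped core cysteines count as
extras, the central (loop II) anchor spacing beyond the reference gives the
loop extension, and residues past the last occupied slot form the C-terminal
tail. A hydrophobic tail of sufficient length is called a membrane-anchoring
domain (anchored vs secreted), replacing external transmembrane predictors
with a transparent Kyte-Doolittle heuristic. Classes: plesiotypic (all 10
ancestral cysteines, no loop extension), short-chain (the derived form that
lost one pair), long-chain (a novel loop-II pair plus an extended loop) and
non-standard (everything else).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .formats import SequenceRecord
from .synthgen import ALL_SLOTS, SHORT_CHAIN_LOST, SLOT_TEMPLATE, CORE_TEMPLATE_LEN

logger = logging.getLogger(__name__)

#: Canonical reference core: the 10-slot cysteine-spacing template as a
#: sequence (X = indifferent filler column). Slot positions follow
#: SLOT_TEMPLATE; the final residue is slot 10, so anything past it is tail.


def canonical_reference_core() -> str:
    core = ["X"] * CORE_TEMPLATE_LEN
    for pos in SLOT_TEMPLATE:
        core[pos] = "C"
    return "".join(core)


REFERENCE_CORE = canonical_reference_core()
_REF_LOOP2 = (SLOT_TEMPLATE[3], SLOT_TEMPLATE[4])   # columns bounding loop II
REF_LOOP2_LEN = _REF_LOOP2[1] - _REF_LOOP2[0] - 1


class CysClassError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds for tail detection and classification (config-exposed)."""

    tail_min_length: int = 12          # L_min, residues
    tail_min_hydropathy: float = 0.5   # H_min, mean Kyte-Doolittle
    loop2_extension_min: int = 4       # E_min, residues
    lost_pair: frozenset = SHORT_CHAIN_LOST
    # signal-peptide heuristic
    cleavage_min: int = 15
    cleavage_max: int = 30
    h_region_min_hydropathy: float = 1.5
    small_residues: str = "AGSCT"      # allowed at -3 and -1


@dataclass(frozen=True)
class MatureProtein:
    id: str
    full_sequence: str
    cleavage_site: int | None
    mature_sequence: str
    flagged: bool = False              # True when no cleavage site was found

    def __post_init__(self) -> None:
        if self.cleavage_site is not None:
            assert self.mature_sequence == self.full_sequence[self.cleavage_site:]


@dataclass(frozen=True)
class CysteineFramework:
    slot_occupancy: tuple               # 10 bools
    slot_positions: dict                # slot (1-based) -> mature index
    extra_cys: tuple                    # mature indices not mapped to slots
    extra_cys_loop2: int                # extras falling inside loop II
    loop2_extension: int
    tail_length: int
    core_end: int                       # mature index one past the core region

    @property
    def n_occupied(self) -> int:
        return sum(self.slot_occupancy)

    @property
    def occupied_slots(self) -> frozenset:
        return frozenset(i + 1 for i, o in enumerate(self.slot_occupancy) if o)


@dataclass(frozen=True)
class ClassCall:
    scaffold_class: str                # plesiotypic | short_chain | long_chain | non_standard
    secretion: str                     # anchored | secreted
    evidence: str


# ---------------------------------------------------------------------------
# Signal peptide
# ---------------------------------------------------------------------------

def mean_hydropathy(seq: str) -> float:
    vals = [KYTE_DOOLITTLE[a] for a in seq if a in KYTE_DOOLITTLE]
    return sum(vals) / len(vals) if vals else 0.0


def cleave_signal_peptide(record: SequenceRecord, annotation: int | None = None,
                          params: ClassifierParams | None = None) -> MatureProtein:
    """Remove the signal peptide.

    With an annotated site, cleave exactly there (annotations always win).
    Otherwise scan candidate sites in [cleavage_min, cleavage_max] and take
    the first satisfying a von Heijne-style rule: small residues at the -3
    and -1 positions and a hydrophobic h-region window upstream. If no site
    qualifies the sequence is returned uncleaved with a warning flag.
    """
    params = params or ClassifierParams()
    seq = record.sequence
    if annotation is not None:
        if annotation >= len(seq):
            raise CysClassError(
                f"{record.id}: cleavage annotation {annotation} beyond length {len(seq)}")
        return MatureProtein(record.id, seq, annotation, seq[annotation:])
    for p in range(params.cleavage_min, min(params.cleavage_max, len(seq) - 10) + 1):
        if seq[p - 1] not in params.small_residues:
            continue
        if seq[p - 3] not in params.small_residues:
            continue
        window = seq[p - 13: p - 5]
        if len(window) == 8 and mean_hydropathy(window) >= params.h_region_min_hydropathy:
            return MatureProtein(record.id, seq, p, seq[p:])
    logger.debug("%s: no signal-peptide cleavage site found", record.id)
    return MatureProtein(record.id, seq, None, seq, flagged=True)


# ---------------------------------------------------------------------------
# Framework mapping
# ---------------------------------------------------------------------------

#: Costs of the slot-assignment program (see map_cysteine_framework).
EXTRA_CYS_COST = 3.0        # a cysteine left unassigned (novel/extra)
SKIPPED_SLOT_COST = 3.0     # a template slot left unoccupied (lost pair)
SPACING_COST = 1.0          # per residue of rigid inter-anchor distortion
ELASTIC_COST = 0.1          # per residue of expansion across an elastic loop
OFFSET_COST = 0.25          # per residue of absolute offset of the first pair
_ASSIGN_BONUS = 1e-6        # tie-break: prefer more, and earlier, assignments
#: Loops that tolerate insertions in the three-finger fold: the central
#: loop II (after slot 4) and loop III (after slot 8). Spacing expansion
#: across these is cheap; the disulfide-knot spacing elsewhere is rigid.
ELASTIC_AFTER_SLOTS = (4, 8)


def _pair_cost(c_span: int, t_span: int, j2: int, j: int) -> float:
    """Distortion cost for consecutive assigned slots j2 < j (0-based)."""
    delta = c_span - t_span
    if delta > 0 and any(j2 <= b - 1 < j for b in ELASTIC_AFTER_SLOTS):
        return ELASTIC_COST * delta
    return SPACING_COST * abs(delta)


def _slot_assignment(cys_positions: list[int], slot_templates: list[int]
                     ) -> dict[int, int]:
    """Order-preserving assignment of cysteine positions to template slots.

    Minimizes total cost: unassigned cysteines and skipped slots pay flat
    costs, consecutive assigned pairs pay per-residue distortion between
    the observed and template inter-anchor spacing (expansion across the
    elastic loops is cheap), and the first assigned pair pays a small
    absolute-offset term that anchors the register at the core N-terminus.
    Returns {slot (1-based) -> cysteine position}.
    """
    m, k = len(cys_positions), len(slot_templates)
    best: dict[tuple[int, int], float] = {}
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    for i in range(m):
        for j in range(k):
            # start here: earlier cysteines extra, earlier slots skipped
            cost = (EXTRA_CYS_COST * i + SKIPPED_SLOT_COST * j
                    + OFFSET_COST * abs(cys_positions[i] - slot_templates[j])
                    - _ASSIGN_BONUS * (m - i))
            prev = None
            for i2 in range(i):
                for j2 in range(j):
                    if (i2, j2) not in best:
                        continue
                    cand = (best[(i2, j2)]
                            + EXTRA_CYS_COST * (i - i2 - 1)
                            + SKIPPED_SLOT_COST * (j - j2 - 1)
                            + _pair_cost(cys_positions[i] - cys_positions[i2],
                                         slot_templates[j] - slot_templates[j2],
                                         j2, j)
                            - _ASSIGN_BONUS * (m - i))
                    if cand < cost - 1e-12:
                        cost, prev = cand, (i2, j2)
            best[(i, j)] = cost
            back[(i, j)] = prev
    # close: remaining cysteines extra, remaining slots skipped
    total_best = EXTRA_CYS_COST * m + SKIPPED_SLOT_COST * k   # assign nothing
    end_state = None
    for (i, j), cost in best.items():
        total = (cost + EXTRA_CYS_COST * (m - i - 1)
                 + SKIPPED_SLOT_COST * (k - j - 1))
        if total < total_best - 1e-12:
            total_best, end_state = total, (i, j)
    assignment: dict[int, int] = {}
    state = end_state
    while state is not None:
        i, j = state
        assignment[j + 1] = cys_positions[i]
        state = back[state]
    return assignment


def map_cysteine_framework(mature: MatureProtein | str,
                           reference: str = REFERENCE_CORE) -> CysteineFramework:
    """Map the mature sequence's cysteines onto the canonical 10-slot
    template and read off occupancy, extras, loop-II extension and tail.

    The mapping is an order-preserving assignment of the observed cysteine
    positions to the template slot positions (distortion-minimizing dynamic
    program; costs documented above). Custom references are supported: slot
    positions are taken from the C residues of `reference`, loop II being
    the region between its 4th and 5th cysteine.
    """
    seq = mature if isinstance(mature, str) else mature.mature_sequence
    if not seq:
        raise CysClassError("empty mature sequence")
    slots = [i for i, a in enumerate(reference) if a == "C"]
    ref_loop2 = (slots[4] - slots[3] - 1) if len(slots) >= 5 else REF_LOOP2_LEN
    cys = [i for i, a in enumerate(seq) if a == "C"]
    assignment = _slot_assignment(cys, slots)

    occupancy = tuple(s in assignment for s in range(1, len(slots) + 1))
    slot_positions = dict(sorted(assignment.items()))

    # core region: slot 10 bounds it when occupied; otherwise extrapolate
    # from the last occupied slot by the template remainder
    n_slots = len(slots)
    if n_slots in assignment:
        core_end = assignment[n_slots] + 1
    elif assignment:
        last = max(assignment)
        core_end = min(len(seq),
                       assignment[last] + (slots[-1] - slots[last - 1]) + 1)
    else:
        core_end = len(seq)
    tail_length = len(seq) - core_end

    # loop II span in mature coordinates
    left, right = assignment.get(4), assignment.get(5)
    if left is not None and right is not None and right > left:
        loop2_span = (left + 1, right)
        loop2_len = right - left - 1
    else:
        loop2_span = (0, 0)
        loop2_len = ref_loop2
    loop2_extension = max(0, loop2_len - ref_loop2)

    mapped = set(assignment.values())
    extras = tuple(i for i in cys if i < core_end and i not in mapped)
    extras_loop2 = sum(1 for i in extras if loop2_span[0] <= i < loop2_span[1])

    return CysteineFramework(
        slot_occupancy=occupancy, slot_positions=slot_positions,
        extra_cys=extras, extra_cys_loop2=extras_loop2,
        loop2_extension=loop2_extension, tail_length=tail_length,
        core_end=core_end)


# ---------------------------------------------------------------------------
# MaD detection and classification
# ---------------------------------------------------------------------------

def detect_mad(framework: CysteineFramework, mature: MatureProtein | str,
               params: ClassifierParams | None = None) -> str:
    """anchored iff the tail is long and hydrophobic enough; else secreted."""
    params = params or ClassifierParams()
    seq = mature if isinstance(mature, str) else mature.mature_sequence
    if framework.tail_length < params.tail_min_length:
        return "secreted"
    tail = seq[len(seq) - framework.tail_length:]
    if mean_hydropathy(tail) >= params.tail_min_hydropathy:
        return "anchored"
    return "secreted"


def classify_scaffold(framework: CysteineFramework, secretion: str,
                      params: ClassifierParams | None = None) -> ClassCall:
    """Apply the 4-category rules in fixed order; total on every input."""
    params = params or ClassifierParams()
    occupied = framework.occupied_slots
    extras = len(framework.extra_cys)
    if occupied == ALL_SLOTS and extras == 0 \
            and framework.loop2_extension < params.loop2_extension_min:
        return ClassCall("plesiotypic", secretion,
                         "all 10 ancestral slots, no extras, no loop extension")
    if occupied == ALL_SLOTS - params.lost_pair and extras == 0:
        return ClassCall("short_chain", secretion,
                         f"8 slots with derived-loss pattern (lost "
                         f"{sorted(params.lost_pair)}), no extras")
    if len(occupied) >= 8 and framework.extra_cys_loop2 == 2 \
            and framework.loop2_extension >= params.loop2_extension_min:
        return ClassCall("long_chain", secretion,
                         "novel loop-II cysteine pair with extended loop")
    return ClassCall("non_standard", secretion, "no category rule matched")


def classify_protein(record: SequenceRecord, annotation: int | None = None,
                     params: ClassifierParams | None = None
                     ) -> tuple[MatureProtein, CysteineFramework, ClassCall]:
    """Convenience pipeline: cleave, map framework, detect MaD, classify."""
    params = params or ClassifierParams()
    mature = cleave_signal_peptide(record, annotation, params)
    framework = map_cysteine_framework(mature)
    secretion = detect_mad(framework, mature, params)
    return mature, framework, classify_scaffold(framework, secretion, params)
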