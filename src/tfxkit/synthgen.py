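"""Synthetic LY6/3FTX protein families and genomic clusters with ground truth.

The generator emulates the statistical structure of a marker-anchored
LY6/3FTX genomic cluster: three-exon genes (exon 1 = signal peptide,
exon 3 = C-terminal segment including any membrane-anchoring tail),
pseudogenes carrying in-frame stops or 1-bp frameshifts, orphan exons with
no chaining partners, four-exon genes whose extra exon is a pseudogenized
duplicate of exon 3 inserted 5' of the functional copy, and protein groups
that differ in cysteine framework (the ancestral 10-cysteine arrangement,
an 8-cysteine derived form, a 10-cysteine form with a novel pair plus a
central-loop extension, and forms fitting none of these) and in the
presence of a hydrophobic C-terminal membrane-anchoring tail.

Every implanted feature carries exactly one truth record; truth coordinates
are 0-based half-open on the forward strand. Outputs are deterministic per
(config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats import AnnotationRecord, SequenceRecord, write_config, write_fasta, write_gff3

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Most frequent human codon per amino acid; fixed so back-translation is
#: reproducible. Any fixed table would do.
CODON_TABLE = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
    "*": "TAA",
}
STOP_CODON = "TAA"

#: Canonical 10-slot cysteine template for a 60-residue mature core
#: (0-based positions; slot 10 is the final core residue). Spacings are
#: modeled on mature three-finger-fold cores of 60-74 residues. Loop II is
#: the region between slots 4 and 5 (reference length 6 residues); extra
#: core length is accommodated in loop III (between slots 8 and 9).
SLOT_TEMPLATE = (2, 8, 14, 22, 29, 35, 41, 47, 54, 59)
CORE_TEMPLATE_LEN = 60
LOOP2_INSERT_AFTER = 25       # loop II interior midpoint
LOOP3_INSERT_AFTER = 50       # loop III interior midpoint
REF_LOOP2_LEN = SLOT_TEMPLATE[4] - SLOT_TEMPLATE[3] - 1  # = 6

#: Number of core residues encoded by exon 3 (the C-terminal segment); the
#: rest of the mature core sits on exon 2 and the signal peptide on exon 1.
EXON3_CORE_RESIDUES = 15

HYDROPHOBIC_H = "ILVFM"       # signal-peptide h-region residues
TAIL_RESIDUES = "AILFV"       # membrane-anchoring tail residues
C_REGION = "SSA"              # signal-peptide c-region (satisfies -3/-1 rule)

ALL_SLOTS = frozenset(range(1, 11))
SHORT_CHAIN_LOST = frozenset({2, 3})   # the pair lost in derived forms


class GeneratorError(ValueError):
    """Raised for invalid generator specifications."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One protein group: cysteine framework, tail, and composition bias."""

    name: str
    n_genes: int
    cys_slots: frozenset = ALL_SLOTS
    extra_cys_in_loop2: int = 0
    loop2_extension: int = 0
    has_mad_tail: bool = False
    signal_start: str = "MKT"
    core_length_range: tuple[int, int] = (60, 74)
    biased_residues: str = "GPA"   # 3 residues holding half the filler mass
    disulfide_complete: bool = True
    is_marker: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise GeneratorError(f"group {self.name}: n_genes < 0")
        if not self.cys_slots <= ALL_SLOTS:
            raise GeneratorError(f"group {self.name}: cys_slots outside 1..10")
        total_cys = len(self.cys_slots) + self.extra_cys_in_loop2
        if self.disulfide_complete and total_cys % 2 != 0:
            raise GeneratorError(
                f"group {self.name}: odd total cysteine count ({total_cys}) "
                "in a disulfide-complete scaffold"
            )
        lo, hi = self.core_length_range
        if not (40 <= lo <= hi <= 120):
            raise GeneratorError(
                f"group {self.name}: core_length_range {self.core_length_range} "
                "outside [40, 120]"
            )
        if lo < CORE_TEMPLATE_LEN:
            raise GeneratorError(
                f"group {self.name}: core_length_range minimum below the "
                f"{CORE_TEMPLATE_LEN}-residue slot template"
            )
        if self.extra_cys_in_loop2 and self.loop2_extension < self.extra_cys_in_loop2 + 2:
            raise GeneratorError(
                f"group {self.name}: loop2_extension too short to host "
                f"{self.extra_cys_in_loop2} extra cysteines"
            )
        if len(self.signal_start) != 3 or not self.signal_start.startswith("M"):
            raise GeneratorError(f"group {self.name}: signal_start must be an M-led tripeptide")

    @property
    def expected_class(self) -> str:
        """Scaffold class this group's noise-free members must receive."""
        if self.cys_slots == ALL_SLOTS and self.extra_cys_in_loop2 == 0 \
                and self.loop2_extension < 4:
            return "plesiotypic"
        if self.cys_slots == ALL_SLOTS - SHORT_CHAIN_LOST \
                and self.extra_cys_in_loop2 == 0:
            return "short_chain"
        if len(self.cys_slots) >= 8 and self.extra_cys_in_loop2 == 2 \
                and self.loop2_extension >= 4:
            return "long_chain"
        return "non_standard"

    @property
    def expected_secretion(self) -> str:
        return "anchored" if self.has_mad_tail else "secreted"


def default_groups(n_per_group: int = 4) -> list[GroupSpec]:
    """The seven study groups: anchored/secreted LY6, pre-3FTX, and the four
    toxin categories (plesiotypic, short-chain, long-chain, non-standard)."""
    return [
        GroupSpec("ly6_anchored", n_per_group, ALL_SLOTS, 0, 0, True, "MKL",
                  biased_residues="KRE"),
        GroupSpec("ly6_secreted", n_per_group, ALL_SLOTS, 0, 0, False, "MNS",
                  biased_residues="DEQ"),
        GroupSpec("pre3ftx", n_per_group, ALL_SLOTS, 0, 0, True, "MKV",
                  biased_residues="NTS"),
        GroupSpec("ftx_plesiotypic", n_per_group, ALL_SLOTS, 0, 0, False, "MKT",
                  biased_residues="GPA"),
        GroupSpec("ftx_short", n_per_group, ALL_SLOTS - SHORT_CHAIN_LOST, 0, 0,
                  False, "MKT", biased_residues="HYW"),
        GroupSpec("ftx_long", n_per_group, ALL_SLOTS - SHORT_CHAIN_LOST, 2, 6,
                  False, "MKT", biased_residues="VIM"),
        GroupSpec("ftx_nonstandard", n_per_group, ALL_SLOTS - frozenset({7}), 0, 0,
                  False, "MKA", biased_residues="FLQ", disulfide_complete=False),
    ]


def marker_group() -> GroupSpec:
    """The single-copy synteny anchor (a TOP1MT-like marker gene)."""
    return GroupSpec("marker_top1mt", 1, frozenset(), 0, 0, False, "MSL",
                     biased_residues="KDG", disulfide_complete=False,
                     is_marker=True)


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinTruth:
    """Ground truth for one generated protein."""

    protein_id: str
    group: str
    orthogroup: str
    sequence: str                 # signal + mature
    cleavage_site: int            # mature starts here
    mature_sequence: str
    tail_length: int
    loop2_extension: int
    cys_slots: frozenset         # occupied canonical slots (1-based)
    extra_cys: int
    scaffold_class: str
    secretion: str
    exon_peptides: tuple[str, str, str]   # E1 (signal), E2, E3 segments

    @property
    def has_mad(self) -> bool:
        return self.tail_length > 0


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one implanted gene / orphan exon set."""

    gene_id: str
    scaffold_id: str
    orthogroup: str
    protein_id: str
    strand: str
    status: str                              # intact | pseudogene | orphan_exon_set
    exons: tuple                             # ((start, end, role), ...) in gene order
    lesion: str = ""

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def roles(self) -> tuple:
        return tuple(r for _, _, r in self.exons)


@dataclass
class ProteinFamily:
    """Generated proteins plus panel (per-group exemplar exon peptides)."""

    records: list = field(default_factory=list)        # SequenceRecord
    truth: list = field(default_factory=list)          # ProteinTruth
    panel: list = field(default_factory=list)          # SequenceRecord, ids group:ROLE
    groups: list = field(default_factory=list)

    def truth_by_id(self) -> dict:
        return {t.protein_id: t for t in self.truth}


@dataclass
class GenomeResult:
    """Scaffolds plus gene-level truth (and updated protein truths)."""

    scaffolds: list = field(default_factory=list)      # SequenceRecord
    genes: list = field(default_factory=list)          # GeneTruth
    proteins: dict = field(default_factory=dict)       # protein_id -> ProteinTruth

    def scaffold_seq(self, scaffold_id: str) -> str:
        for rec in self.scaffolds:
            if rec.id == scaffold_id:
                return rec.sequence
        raise KeyError(scaffold_id)


# ---------------------------------------------------------------------------
# Protein construction
# ---------------------------------------------------------------------------

def _composition_profile(biased: str) -> np.ndarray:
    """Filler-residue distribution: half the mass on 3 group residues."""
    pool = [a for a in AA20 if a != "C"]
    probs = np.full(len(pool), 0.5 / (len(pool) - len(biased)))
    for i, a in enumerate(pool):
        if a in biased:
            probs[i] = 0.5 / len(biased)
    return probs / probs.sum()


def _build_core(spec: GroupSpec, rng: np.random.Generator) -> tuple[str, dict]:
    """Build one mature core from the slot template.

    Returns the core and a layout dict with slot/extra positions (core
    coordinates) and the loop-II extension length.
    """
    pool = [a for a in AA20 if a != "C"]
    probs = _composition_profile(spec.biased_residues)
    template = list(rng.choice(pool, size=CORE_TEMPLATE_LEN, p=probs))
    for slot in range(1, 11):
        pos = SLOT_TEMPLATE[slot - 1]
        template[pos] = "C" if slot in spec.cys_slots else "S"

    ext = spec.loop2_extension
    loop2ins = list(rng.choice(pool, size=ext, p=probs)) if ext else []
    extra_positions_rel: list[int] = []
    if spec.extra_cys_in_loop2:
        # spread the novel cysteines inside the insertion, away from its ends
        idxs = np.linspace(1, ext - 2, spec.extra_cys_in_loop2)
        for k in sorted({int(round(v)) for v in idxs}):
            loop2ins[k] = "C"
            extra_positions_rel.append(k)

    lo, hi = spec.core_length_range
    core_len = int(rng.integers(lo, hi + 1))
    loop3_len = core_len - CORE_TEMPLATE_LEN
    loop3ins = list(rng.choice(pool, size=loop3_len, p=probs))

    core = (template[:LOOP2_INSERT_AFTER + 1] + loop2ins
            + template[LOOP2_INSERT_AFTER + 1:LOOP3_INSERT_AFTER + 1] + loop3ins
            + template[LOOP3_INSERT_AFTER + 1:])

    def shifted(pos: int) -> int:
        out = pos
        if pos > LOOP2_INSERT_AFTER:
            out += ext
        if pos > LOOP3_INSERT_AFTER:
            out += loop3_len
        return out

    layout = {
        "slot_positions": {s: shifted(SLOT_TEMPLATE[s - 1]) for s in spec.cys_slots},
        "extra_positions": [LOOP2_INSERT_AFTER + 1 + k for k in extra_positions_rel],
        "loop2_extension": ext,
    }
    return "".join(core), layout


def _build_signal(spec: GroupSpec, rng: np.random.Generator) -> str:
    h_len = int(rng.integers(12, 19))
    h = "".join(rng.choice(list(HYDROPHOBIC_H), size=h_len))
    return spec.signal_start + h + C_REGION


def _build_tail(rng: np.random.Generator) -> str:
    tail_len = int(rng.integers(14, 21))
    return "".join(rng.choice(list(TAIL_RESIDUES), size=tail_len))


def _mutate(seq: str, immutable: set, rate: float, rng: np.random.Generator,
            alphabets: dict) -> str:
    """Point-substitute at `rate`, respecting per-position alphabets and
    never touching cysteines or immutable positions."""
    out = list(seq)
    for i, aa in enumerate(out):
        if i in immutable or aa == "C":
            continue
        if rng.random() < rate:
            pool = [a for a in alphabets.get(i, AA20) if a not in ("C", aa)]
            out[i] = str(rng.choice(pool))
    return "".join(out)


def _exon_peptides(signal: str, mature: str, tail_length: int) -> tuple[str, str, str]:
    e3_len = EXON3_CORE_RESIDUES + tail_length
    return signal, mature[:-e3_len], mature[-e3_len:]


def generate_protein_family(groups: Sequence[GroupSpec], seed: int,
                            divergence: float = 0.0) -> ProteinFamily:
    """Generate proteins for each group plus a panel of exemplar exon peptides.

    Each group gets one exemplar (built from the slot template with
    group-biased filler); members are point-substituted copies at rate
    `divergence`, with cysteines, the signal tripeptide, and the c-region
    held fixed so the framework ground truth stays exact.
    """
    rng = np.random.default_rng(seed)
    fam = ProteinFamily(groups=list(groups))
    for spec in groups:
        core, layout = _build_core(spec, rng)
        signal = _build_signal(spec, rng)
        tail = _build_tail(rng) if spec.has_mad_tail else ""
        exemplar_mature = core + tail
        exemplar = signal + exemplar_mature

        cleavage = len(signal)
        e1, e2, e3 = _exon_peptides(signal, exemplar_mature, len(tail))
        for role, pep in (("E1", e1), ("E2", e2), ("E3", e3)):
            fam.panel.append(SequenceRecord(
                f"{spec.name}:{role}", pep, f"exemplar {role} peptide"))

        # positions that must not drift under divergence
        immutable = set(range(3)) | set(range(cleavage - 3, cleavage))
        alphabets = {i: HYDROPHOBIC_H for i in range(3, cleavage - 3)}
        for i in range(len(core), len(exemplar_mature)):
            alphabets[cleavage + i] = TAIL_RESIDUES

        for i in range(spec.n_genes):
            seq = _mutate(exemplar, immutable, divergence, rng, alphabets) \
                if divergence > 0 else exemplar
            pid = f"{spec.name}_{i:03d}"
            mature = seq[cleavage:]
            fam.records.append(SequenceRecord(pid, seq, f"group={spec.name}"))
            fam.truth.append(ProteinTruth(
                protein_id=pid, group=spec.name,
                orthogroup=f"og_{spec.name}_{i}",
                sequence=seq, cleavage_site=cleavage, mature_sequence=mature,
                tail_length=len(tail), loop2_extension=layout["loop2_extension"],
                cys_slots=spec.cys_slots, extra_cys=len(layout["extra_positions"]),
                scaffold_class=spec.expected_class,
                secretion=spec.expected_secretion,
                exon_peptides=_exon_peptides(seq[:cleavage], mature, len(tail)),
            ))
    logger.info("generated %d proteins in %d groups (divergence=%.3f)",
                len(fam.records), len(groups), divergence)
    return fam


# ---------------------------------------------------------------------------
# Gene building and pseudogenization
# ---------------------------------------------------------------------------

@dataclass
class GeneBuild:
    """A gene under construction: ordered exon DNA on the coding strand."""

    gene_id: str
    orthogroup: str
    protein_id: str
    exons: list                      # [(role, dna), ...] in gene order
    strand: str = "+"
    status: str = "intact"
    lesion: str = ""


def back_translate(peptide: str) -> str:
    return "".join(CODON_TABLE[aa] for aa in peptide)


def translate_cds(dna: str) -> str:
    return str(Seq(dna[: len(dna) - len(dna) % 3]).translate())


def pseudogenize(gene: GeneBuild, mode: str, seed: int) -> GeneBuild:
    """Introduce exactly one inactivating lesion into a copy of `gene`.

    `stop` replaces one internal codon by TAA; `frameshift` deletes one base.
    Lesions avoid the first and last codon of the chosen exon so exon
    boundaries stay well-posed for downstream detection.
    """
    if mode not in {"stop", "frameshift"}:
        raise GeneratorError(f"unknown pseudogenization mode {mode!r}")
    if not gene.exons:
        raise GeneratorError(f"gene {gene.gene_id} has no exons")
    if gene.status != "intact":
        raise GeneratorError(f"gene {gene.gene_id} is not intact")
    rng = np.random.default_rng(seed)
    candidates = [i for i, (_, dna) in enumerate(gene.exons) if len(dna) >= 9]
    exon_i = int(rng.choice(candidates))
    role, dna = gene.exons[exon_i]
    n_codons = len(dna) // 3
    codon_i = int(rng.integers(1, n_codons - 1))     # never first/last codon
    if mode == "stop":
        dna = dna[:codon_i * 3] + STOP_CODON + dna[codon_i * 3 + 3:]
        lesion = f"stop@{role}:{codon_i}"
    else:
        base_i = codon_i * 3 + int(rng.integers(0, 3))
        dna = dna[:base_i] + dna[base_i + 1:]
        lesion = f"frameshift@{role}:{base_i}"
    exons = list(gene.exons)
    exons[exon_i] = (role, dna)
    return replace_gene(gene, exons=exons, status="pseudogene", lesion=lesion)


def replace_gene(gene: GeneBuild, **kw) -> GeneBuild:
    data = dict(gene_id=gene.gene_id, orthogroup=gene.orthogroup,
                protein_id=gene.protein_id, exons=gene.exons,
                strand=gene.strand, status=gene.status, lesion=gene.lesion)
    data.update(kw)
    return GeneBuild(**data)


def _gene_from_protein(truth: ProteinTruth, gene_id: str) -> GeneBuild:
    e1, e2, e3 = truth.exon_peptides
    return GeneBuild(
        gene_id=gene_id, orthogroup=truth.orthogroup,
        protein_id=truth.protein_id,
        exons=[("E1", back_translate(e1)), ("E2", back_translate(e2)),
               ("E3", back_translate(e3))],
    )


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    """Layout of one synthetic species' LY6/3FTX cluster scaffold."""

    species_id: str
    groups: tuple = ()                       # GroupSpec, marker included
    n_pseudogenes: int = 1
    n_orphan_exon_sets: int = 1
    n_dup3_genes: int = 1
    dup3_truncation_mode: bool = False
    pseudogene_mode: str = "stop"
    intron_length_range: tuple[int, int] = (50, 200)
    intergenic_length_range: tuple[int, int] = (200, 800)
    divergence: float = 0.05
    drop_orthogroups: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pseudogenes, self.n_orphan_exon_sets, self.n_dup3_genes) < 0:
            raise GeneratorError("counts must be >= 0")
        if self.intron_length_range[0] < 20:
            raise GeneratorError("intron minimum below 20 bp")
        markers = sum(g.n_genes for g in self.groups if g.is_marker)
        if markers != 1:
            raise GeneratorError(
                f"config must implant the marker gene exactly once (got {markers})")
        if self.pseudogene_mode not in {"stop", "frameshift"}:
            raise GeneratorError(f"unknown pseudogene_mode {self.pseudogene_mode!r}")


def default_genome_config(species_id: str = "synthspecies", seed: int = 0,
                          n_per_group: int | None = None, **kw) -> GenomeConfig:
    """Default cluster: 10 genes (9 family members across the 7 groups plus
    the marker), 1 pseudogene, 1 dup-exon-3 gene, 1 orphan exon set."""
    counts = [2, 1, 1, 2, 1, 1, 1] if n_per_group is None else [n_per_group] * 7
    groups = [replace(g, n_genes=c) for g, c in zip(default_groups(), counts)]
    groups.append(marker_group())
    return GenomeConfig(species_id=species_id, groups=tuple(groups), seed=seed, **kw)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _intron(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "GT" + _random_dna(rng, length - 4) + "AG"


def generate_genome(config: GenomeConfig, family: ProteinFamily | None = None
                    ) -> GenomeResult:
    """Assemble one scaffold implanting every gene of `family` (or of a
    family generated from the config), plus pseudogenes, dup-exon-3 genes,
    and orphan exons, separated by random intergenic DNA.

    Introns start GT and end AG. The terminal stop codon of each gene lies
    immediately 3' of exon 3 but outside the annotated exon, so splicing and
    translating the truth exons of an intact gene reproduces its protein
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    if family is None:
        family = generate_protein_family(config.groups, seed=config.seed,
                                         divergence=config.divergence)
    truth_by_id = family.truth_by_id()

    builds: list[GeneBuild] = []
    marker_build: GeneBuild | None = None
    for spec in family.groups:
        for i in range(spec.n_genes):
            pt = truth_by_id[f"{spec.name}_{i:03d}"]
            if pt.orthogroup in config.drop_orthogroups:
                continue
            build = _gene_from_protein(pt, f"{config.species_id}_{pt.protein_id}")
            if spec.is_marker:
                marker_build = build
            else:
                builds.append(build)
    assert marker_build is not None

    proteins = dict(truth_by_id)

    # choose which family genes become pseudogenes / dup-exon-3 carriers
    idx = list(range(len(builds)))
    pseudo_idx = sorted(rng.choice(idx, size=min(config.n_pseudogenes, len(idx)),
                                   replace=False).tolist())
    remaining = [i for i in idx if i not in pseudo_idx]
    dup3_idx = sorted(rng.choice(remaining,
                                 size=min(config.n_dup3_genes, len(remaining)),
                                 replace=False).tolist())

    for i in pseudo_idx:
        builds[i] = pseudogenize(builds[i], config.pseudogene_mode,
                                 seed=int(rng.integers(2**31)))
    for i in dup3_idx:
        builds[i] = _add_dup3(builds[i], config, proteins, rng)

    # marker position: flank or middle of the cluster
    pos = int(rng.choice([0, len(builds) // 2, len(builds)]))
    builds.insert(pos, marker_build)

    # orphan exons: stray E2/E3 copies from random non-marker groups
    orphans: list[GeneBuild] = []
    family_groups = [g for g in family.groups if not g.is_marker and g.n_genes > 0]
    for k in range(config.n_orphan_exon_sets):
        spec = family_groups[int(rng.integers(len(family_groups)))]
        pt = truth_by_id[f"{spec.name}_000"]
        role = str(rng.choice(["E2", "E3"]))
        pep = pt.exon_peptides[{"E1": 0, "E2": 1, "E3": 2}[role]]
        orphans.append(GeneBuild(
            gene_id=f"{config.species_id}_orphan{k}",
            orthogroup=f"orphan_{spec.name}_{k}", protein_id=pt.protein_id,
            exons=[(role, back_translate(pep))], status="orphan_exon_set"))
    for orphan in orphans:
        builds.insert(int(rng.integers(len(builds) + 1)), orphan)

    for b in builds:
        b.strand = str(rng.choice(["+", "-"]))

    # lay the cluster onto one scaffold
    scaffold_id = f"{config.species_id}_scaf1"
    lo_ig, hi_ig = config.intergenic_length_range
    lo_in, hi_in = config.intron_length_range
    parts: list[str] = [_random_dna(rng, int(rng.integers(lo_ig, hi_ig + 1)))]
    offset = len(parts[0])
    genes: list[GeneTruth] = []
    for b in builds:
        segment_parts: list[str] = []
        exon_local: list[tuple[int, int, str]] = []   # coords within segment
        cursor = 0
        for j, (role, dna) in enumerate(b.exons):
            if j > 0:
                intron = _intron(rng, lo_in, hi_in)
                segment_parts.append(intron)
                cursor += len(intron)
            segment_parts.append(dna)
            exon_local.append((cursor, cursor + len(dna), role))
            cursor += len(dna)
        if b.status != "orphan_exon_set":
            segment_parts.append(STOP_CODON)
            cursor += 3
        segment = "".join(segment_parts)
        if b.strand == "-":
            segment = str(Seq(segment).reverse_complement())
            exon_local = [(len(segment) - e, len(segment) - s, role)
                          for s, e, role in exon_local]
        exons = tuple((offset + s, offset + e, role) for s, e, role in exon_local)
        genes.append(GeneTruth(
            gene_id=b.gene_id, scaffold_id=scaffold_id, orthogroup=b.orthogroup,
            protein_id=b.protein_id, strand=b.strand, status=b.status,
            exons=exons, lesion=b.lesion))
        parts.append(segment)
        offset += len(segment)
        spacer = _random_dna(rng, int(rng.integers(lo_ig, hi_ig + 1)))
        parts.append(spacer)
        offset += len(spacer)

    scaffold = SequenceRecord(scaffold_id, "".join(parts),
                              f"species={config.species_id}")
    result = GenomeResult(scaffolds=[scaffold], genes=genes, proteins=proteins)
    _check_roundtrip(result)
    logger.info("assembled scaffold %s: %d bp, %d gene records",
                scaffold_id, len(scaffold.sequence), len(genes))
    return result


def _add_dup3(build: GeneBuild, config: GenomeConfig, proteins: dict,
              rng: np.random.Generator) -> GeneBuild:
    """Insert a pseudogenized duplicate of exon 3 5' of the functional copy.

    In truncation mode the mechanism that creates secreted forms is
    emulated: the retained exon 3 ends at a stop inserted before the
    membrane-anchoring tail, so the encoded protein loses the tail, while
    the 5' duplicate keeps the ancestral full-length exon 3 (pseudogenized).
    """
    pt: ProteinTruth = proteins[build.protein_id]
    roles = dict(build.exons)
    e3_dna = roles["E3"]

    if config.dup3_truncation_mode and pt.tail_length > 0:
        core_bp = EXON3_CORE_RESIDUES * 3
        retained = e3_dna[:core_bp]               # tail codons dropped from the exon
        dup_copy = e3_dna                         # ancestral full-length copy
        new_mature = pt.mature_sequence[: len(pt.mature_sequence) - pt.tail_length]
        proteins[build.protein_id] = replace(
            pt,
            sequence=pt.sequence[:pt.cleavage_site] + new_mature,
            mature_sequence=new_mature, tail_length=0, secretion="secreted",
            exon_peptides=(pt.exon_peptides[0], pt.exon_peptides[1],
                           new_mature[-EXON3_CORE_RESIDUES:]),
        )
    else:
        retained = e3_dna
        dup_copy = e3_dna

    # pseudogenize the duplicate exon with an internal stop
    n_codons = len(dup_copy) // 3
    codon_i = int(rng.integers(1, n_codons - 1))
    dup_copy = dup_copy[:codon_i * 3] + STOP_CODON + dup_copy[codon_i * 3 + 3:]

    exons = [("E1", roles["E1"]), ("E2", roles["E2"]),
             ("E3dup", dup_copy), ("E3", retained)]
    return replace_gene(build, exons=exons)


def _check_roundtrip(result: GenomeResult) -> None:
    """Splice-and-translate every intact truth gene; must equal its protein."""
    for g in result.genes:
        if g.status != "intact":
            continue
        protein = spliced_protein(result.scaffold_seq(g.scaffold_id), g)
        expected = result.proteins[g.protein_id].sequence
        assert protein == expected, f"round-trip failure for {g.gene_id}"


def spliced_protein(scaffold_seq: str, gene: GeneTruth) -> str:
    """Translate the concatenated coding exons (E3dup excluded)."""
    chunks = []
    for s, e, role in gene.exons:
        if role == "E3dup":
            continue
        dna = scaffold_seq[s:e]
        if gene.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        chunks.append(dna)
    return translate_cds("".join(chunks))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def genome_annotations(result: GenomeResult) -> list[AnnotationRecord]:
    out: list[AnnotationRecord] = []
    for g in result.genes:
        start = min(s for s, _, _ in g.exons)
        end = max(e for _, e, _ in g.exons)
        out.append(AnnotationRecord(
            g.scaffold_id, "gene", start, end, g.strand,
            {"ID": g.gene_id, "status": g.status, "orthogroup": g.orthogroup}))
        for s, e, role in g.exons:
            out.append(AnnotationRecord(
                g.scaffold_id, "exon", s, e, g.strand,
                {"Parent": g.gene_id, "role": role, "status": g.status,
                 "orthogroup": g.orthogroup}))
    return out


def protein_truth_table(family_or_result) -> pd.DataFrame:
    truths = (family_or_result.truth if isinstance(family_or_result, ProteinFamily)
              else list(family_or_result.proteins.values()))
    rows = [{
        "protein_id": t.protein_id, "group": t.group, "orthogroup": t.orthogroup,
        "cleavage_site": t.cleavage_site, "tail_length": t.tail_length,
        "loop2_extension": t.loop2_extension,
        "cys_slots": ",".join(map(str, sorted(t.cys_slots))),
        "extra_cys": t.extra_cys, "scaffold_class": t.scaffold_class,
        "secretion": t.secretion, "mature_sequence": t.mature_sequence,
    } for t in truths]
    return pd.DataFrame(rows)


def write_genome_outputs(result: GenomeResult, family: ProteinFamily,
                         config: GenomeConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.scaffolds, outdir / "scaffolds.fasta")
    write_fasta(family.records, outdir / "proteins.fasta")
    write_fasta(family.panel, outdir / "exon_panel.fasta")
    write_gff3(genome_annotations(result), outdir / "truth.gff3")
    protein_truth_table(result).to_csv(outdir / "protein_truth.tsv",
                                       sep="\t", index=False)
    gene_rows = [{
        "gene_id": g.gene_id, "scaffold_id": g.scaffold_id,
        "orthogroup": g.orthogroup, "strand": g.strand, "status": g.status,
        "n_exons": g.n_exons, "roles": ",".join(g.roles), "lesion": g.lesion,
    } for g in result.genes]
    pd.DataFrame(gene_rows).to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    write_config({
        "species_id": config.species_id, "seed": config.seed,
        "n_pseudogenes": config.n_pseudogenes,
        "n_orphan_exon_sets": config.n_orphan_exon_sets,
        "n_dup3_genes": config.n_dup3_genes,
        "dup3_truncation_mode": config.dup3_truncation_mode,
        "pseudogene_mode": config.pseudogene_mode,
        "divergence": config.divergence,
        "groups": ";".join(f"{g.name}:{g.n_genes}" for g in config.groups),
    }, outdir / "generator_config.txt")
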