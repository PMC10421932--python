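"""Exon-homology gene finding on genomic scaffolds.

The search mirrors a translated-BLAST workflow done algorithmically: each
scaffold is translated in six frames, exon peptide queries from a reference
panel are locally aligned (Smith-Waterman, affine gaps, BLOSUM62) against
every frame, hits passing score/identity/coverage thresholds are chained
into gene models by a dynamic program that enforces exon order, strand
consistency, intron-length bounds and GT..AG splice motifs, and each model's
status (intact / pseudogene / orphan exon set) is called from its spliced
translation. A marker-anchored synteny map supports cross-species order
comparison (shared orthogroups, Kendall tau).

Because close homologs differ from panel queries by substitutions rather
than indels, the aligned region of each hit is extrapolated to the full
query span, which recovers exact exon boundaries even when terminal
residues mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.stats import kendalltau

from .formats import SequenceRecord

logger = logging.getLogger(__name__)


class GeneFindError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    """Thresholds for the translated homology search and chaining.

    BLAST-style e-value cutoffs do not port to raw Smith-Waterman scores, so
    filtering uses a per-column normalized score plus identity and query
    coverage; all are config-exposed.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_normalized_score: float = 1.0
    min_identity: float = 0.5
    min_query_coverage: float = 0.75
    max_intron_bp: int = 10_000
    min_intron_bp: int = 20
    require_splice_motifs: bool = True
    #: per-bp penalty on intron span in the chaining DP; keeps assembly
    #: local (true introns at this scale cost a few points, while chaining
    #: to an exon copy one gene over costs more than any exon scores) and
    #: makes tie-breaking deterministic
    intron_penalty_per_bp: float = 0.1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise GeneFindError("gap penalties must be positive")
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_query_coverage <= 1):
            raise GeneFindError("identity/coverage thresholds must be in [0,1]")


def _load_matrix(name: str):
    """Substitution matrix with X scoring 0 against everything."""
    m = substitution_matrices.load(name).copy()
    alphabet = m.alphabet
    if "X" in alphabet:
        xi = alphabet.index("X")
        for j in range(len(alphabet)):
            m[xi, j] = 0.0
            m[j, xi] = 0.0
    return m


def _make_aligner(params: SearchParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _load_matrix(params.matrix_name)
    # affine convention: a gap of length k costs open + (k-1) * extend
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """One translation frame with its peptide->scaffold coordinate map."""

    strand: str              # '+' or '-'
    offset: int              # 0, 1, 2
    peptide: str
    scaffold_len: int

    def scaffold_interval(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """Forward-strand scaffold interval for peptide span [pep_start, pep_end)."""
        nt_start = self.offset + 3 * pep_start
        nt_end = self.offset + 3 * pep_end
        if self.strand == "+":
            return nt_start, nt_end
        return self.scaffold_len - nt_end, self.scaffold_len - nt_start


def sixframe_translate(scaffold: SequenceRecord) -> list[Frame]:
    """Translate all six frames; N translates to X; stops appear as '*'."""
    seq = scaffold.sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise GeneFindError(
            f"scaffold {scaffold.id} contains non-DNA characters: {sorted(bad)}")
    frames = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            frames.append(Frame(strand, off, pep, len(seq)))
    return frames


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    score: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    identity: float
    aligned_columns: int


def _alignment_stats(alignment) -> tuple[float, int]:
    """(identity over aligned columns, number of aligned columns incl. gaps)."""
    matches = 0
    columns = 0
    qa, ta = alignment[0], alignment[1]
    for q, t in zip(qa, ta):
        columns += 1
        if q == t and q != "-":
            matches += 1
    return (matches / columns if columns else 0.0), columns


def local_align_protein(query: str, target: str,
                        params: SearchParams | None = None) -> LocalAlignment:
    """Best Smith-Waterman local alignment of two peptides.

    Ties are broken toward the smallest end coordinates (the first optimal
    alignment in Biopython's deterministic enumeration order).
    """
    params = params or SearchParams()
    if not query or not target:
        raise GeneFindError("empty sequence passed to local alignment")
    aligner = _make_aligner(params, "local")
    alignments = aligner.align(query, target)
    try:
        best = alignments[0]
    except IndexError:
        # no positive-scoring local alignment exists
        return LocalAlignment(0.0, (0, 0), (0, 0), 0.0, 0)
    identity, columns = _alignment_stats(best)
    q_int = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])) \
        if len(best.aligned[0]) else (0, 0)
    t_int = (int(best.aligned[1][0][0]), int(best.aligned[1][-1][1])) \
        if len(best.aligned[1]) else (0, 0)
    return LocalAlignment(float(best.score), q_int, t_int, identity, columns)


# ---------------------------------------------------------------------------
# Exon hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonHit:
    query_exon_id: str
    scaffold_id: str
    strand: str
    frame: int
    interval: tuple[int, int]        # forward-strand, full-query extrapolated
    raw_score: float
    identity: float
    normalized_score: float
    role: str                        # parsed from query id "group:ROLE"

    def __post_init__(self) -> None:
        if self.interval[1] - self.interval[0] < 3:
            raise GeneFindError("hit interval shorter than one codon")


def _query_role(query_id: str) -> str:
    return query_id.rsplit(":", 1)[-1] if ":" in query_id else "E?"


def find_exon_hits(scaffold: SequenceRecord, exon_queries: Sequence[SequenceRecord],
                   params: SearchParams | None = None) -> list[ExonHit]:
    """Search all six frames with every panel query.

    Per (frame, query) the best local alignment is taken, the hit region is
    masked, and the search repeats until scores fall below threshold, so
    multiple gene copies are all recovered. Overlapping hits for the same
    query (and, across queries, for the same exon role) collapse to the
    best-scoring one.
    """
    params = params or SearchParams()
    if not exon_queries:
        raise GeneFindError("empty exon query panel")
    aligner = _make_aligner(params, "local")
    frames = sixframe_translate(scaffold)
    hits: list[ExonHit] = []
    for fr_i, frame in enumerate(frames):
        if not frame.peptide:
            continue
        for q in exon_queries:
            target = frame.peptide
            for _round in range(64):
                alignments = aligner.align(q.sequence, target)
                best = alignments[0]
                if not len(best.aligned[0]):
                    break
                identity, columns = _alignment_stats(best)
                norm = best.score / columns if columns else 0.0
                qs, qe = int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])
                ts, te = int(best.aligned[1][0][0]), int(best.aligned[1][-1][1])
                passes = (norm >= params.min_normalized_score
                          and identity >= params.min_identity
                          and (qe - qs) / len(q.sequence) >= params.min_query_coverage)
                if not passes and identity < params.min_identity:
                    break  # nothing stronger left for this query in this frame
                if passes:
                    # extrapolate to full query span (substitution-only homologs)
                    ext_s = max(0, ts - qs)
                    ext_e = min(len(frame.peptide), te + (len(q.sequence) - qe))
                    interval = frame.scaffold_interval(ext_s, ext_e)
                    hits.append(ExonHit(
                        query_exon_id=q.id, scaffold_id=scaffold.id,
                        strand=frame.strand, frame=frame.offset,
                        interval=interval, raw_score=float(best.score),
                        identity=identity, normalized_score=norm,
                        role=_query_role(q.id)))
                # mask and continue looking for further copies
                target = target[:ts] + "*" * (te - ts) + target[te:]
                if best.score < params.min_normalized_score * max(columns, 1):
                    break
    collapsed = _collapse_overlaps(hits)
    logger.info("scaffold %s: %d raw hits, %d after overlap collapse",
                scaffold.id, len(hits), len(collapsed))
    return collapsed


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _collapse_overlaps(hits: list[ExonHit]) -> list[ExonHit]:
    """Keep the best-scoring hit among overlapping same-role hits.

    Collapsing is strand-blind: a genuine exon also echoes as a weaker hit
    in the antisense frames, and only the best copy should enter chaining.
    """
    order = sorted(hits, key=lambda h: (-h.raw_score, h.interval[0], h.query_exon_id))
    kept: list[ExonHit] = []
    for h in order:
        if any(k.role == h.role and _overlap(k.interval, h.interval) > 0
               for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.interval[0], h.query_exon_id))
    return kept


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A reconstructed gene: ordered exons with roles, status and translation."""

    id: str
    scaffold_id: str
    strand: str
    exons: list                      # [((start, end), role), ...] in gene order
    status: str = ""
    cds: str = ""
    protein: str = ""
    hits: list = field(default_factory=list)

    @property
    def roles(self) -> tuple:
        return tuple(role for _, role in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for (s, _), _ in self.exons),
                max(e for (_, e), _ in self.exons))


_ROLE_RANK = {"E1": 1, "E2": 2, "E3": 3}


def _splice_ok(scaffold_seq: str, up: ExonHit, down: ExonHit) -> bool:
    """GT..AG check for the intron between two gene-order-adjacent hits.

    `up` precedes `down` in gene orientation. On the minus strand the
    coding-strand motifs map to AC / CT on the forward strand.
    """
    if up.strand == "+":
        donor = scaffold_seq[up.interval[1]: up.interval[1] + 2]
        acceptor = scaffold_seq[down.interval[0] - 2: down.interval[0]]
        return donor == "GT" and acceptor == "AG"
    donor = scaffold_seq[up.interval[0] - 2: up.interval[0]]
    acceptor = scaffold_seq[down.interval[1]: down.interval[1] + 2]
    return donor == "AC" and acceptor == "CT"


def _chainable(scaffold_seq: str, up: ExonHit, down: ExonHit,
               params: SearchParams) -> bool:
    if up.strand != down.strand:
        return False
    r1, r2 = _ROLE_RANK.get(up.role, 0), _ROLE_RANK.get(down.role, 0)
    if not (r2 == r1 + 1 or (up.role == "E3" and down.role == "E3")):
        return False
    if up.strand == "+":
        gap = down.interval[0] - up.interval[1]
    else:
        gap = up.interval[0] - down.interval[1]
    if not (params.min_intron_bp - 4 <= gap <= params.max_intron_bp):
        return False
    if params.require_splice_motifs and not _splice_ok(scaffold_seq, up, down):
        return False
    return True


def chain_hits_to_genes(hits: Sequence[ExonHit], scaffold: SequenceRecord,
                        params: SearchParams | None = None) -> list[GeneModel]:
    """Chain hits into gene models maximizing total raw score.

    A dynamic program over gene-orientation-sorted hits finds the best
    chain (same strand, role order E1<E2<E3, one optional extra exon-3 hit,
    intron bounds, splice motifs); the chain's hits are removed and the
    process repeats. A chain with two exon-3 hits labels the 5' copy E3dup.
    Leftover single hits become orphan-exon-set models.
    """
    params = params or SearchParams()
    seq = scaffold.sequence
    remaining = list(hits)
    models: list[GeneModel] = []
    counter = 0
    while True:
        best_chain = _best_chain(remaining, seq, params)
        if best_chain is None or len(best_chain) < 2:
            break
        counter += 1
        models.append(_model_from_chain(best_chain, scaffold, counter))
        used = set(id(h) for h in best_chain)
        remaining = [h for h in remaining if id(h) not in used]
    for h in remaining:
        counter += 1
        models.append(GeneModel(
            id=f"{scaffold.id}_model{counter:03d}", scaffold_id=scaffold.id,
            strand=h.strand, exons=[(h.interval, h.role)],
            status="orphan_exon_set", hits=[h]))
    for m in models:
        _finalize_model(m, seq)
    models.sort(key=lambda m: m.span[0])
    _assert_model_invariants(models, scaffold, params)
    return models


def _best_chain(hits: list[ExonHit], seq: str,
                params: SearchParams) -> list[ExonHit] | None:
    best_score, best = -np.inf, None
    for strand in ("+", "-"):
        sub = [h for h in hits if h.strand == strand]
        sub.sort(key=lambda h: h.interval[0], reverse=(strand == "-"))
        n = len(sub)
        if not n:
            continue
        # dp over (hit, used-dup-flag); E3->E3 transition consumes the flag
        dp = {}
        back = {}
        for i in range(n):
            dp[(i, 0)] = sub[i].raw_score
            back[(i, 0)] = None
        for i in range(n):
            for j in range(i):
                if not _chainable(seq, sub[j], sub[i], params):
                    continue
                dup = 1 if (sub[j].role == "E3" and sub[i].role == "E3") else 0
                if strand == "+":
                    gap = sub[i].interval[0] - sub[j].interval[1]
                else:
                    gap = sub[j].interval[0] - sub[i].interval[1]
                for flag_prev in (0, 1):
                    if (j, flag_prev) not in dp:
                        continue
                    flag = flag_prev + dup
                    if flag > 1:
                        continue
                    cand = (dp[(j, flag_prev)] + sub[i].raw_score
                            - params.intron_penalty_per_bp * gap)
                    if cand > dp.get((i, flag), -np.inf):
                        dp[(i, flag)] = cand
                        back[(i, flag)] = (j, flag_prev)
        for key, score in dp.items():
            chain = []
            k = key
            while k is not None:
                chain.append(sub[k[0]])
                k = back[k]
            chain.reverse()
            if len(chain) >= 2 and score > best_score:
                best_score, best = score, chain
    return best


def _model_from_chain(chain: list[ExonHit], scaffold: SequenceRecord,
                      counter: int) -> GeneModel:
    roles = [h.role for h in chain]
    # two exon-3 hits: the 5'-in-gene-orientation copy is the duplicate
    e3_idx = [i for i, r in enumerate(roles) if r == "E3"]
    if len(e3_idx) == 2:
        roles[e3_idx[0]] = "E3dup"
    return GeneModel(
        id=f"{scaffold.id}_model{counter:03d}", scaffold_id=scaffold.id,
        strand=chain[0].strand,
        exons=[(h.interval, role) for h, role in zip(chain, roles)],
        hits=list(chain))


def _finalize_model(model: GeneModel, scaffold_seq: str) -> None:
    model.status = model.status or ""
    if len(model.exons) == 1 and model.status == "orphan_exon_set":
        (s, e), _ = model.exons[0]
        dna = scaffold_seq[s:e]
        if model.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        model.cds = dna
        model.protein = str(Seq(dna[: len(dna) - len(dna) % 3]).translate())
        return
    status = call_gene_status(model, scaffold_seq)
    model.status = status


def call_gene_status(model: GeneModel, scaffold_seq: str) -> str:
    """intact iff the spliced CDS (E3dup excluded) has no internal stop and
    a length divisible by 3; single unchained exons are orphan exon sets."""
    if not model.exons:
        raise GeneFindError("model has no exons")
    for (s, e), _ in model.exons:
        if s < 0 or e > len(scaffold_seq):
            raise GeneFindError(f"model {model.id}: exon outside scaffold bounds")
    if len(model.exons) == 1:
        return "orphan_exon_set"
    chunks = []
    for (s, e), role in model.exons:
        if role == "E3dup":
            continue
        dna = scaffold_seq[s:e]
        if model.strand == "-":
            dna = str(Seq(dna).reverse_complement())
        chunks.append(dna)
    cds = "".join(chunks)
    model.cds = cds
    if len(cds) % 3 != 0:
        model.protein = ""
        return "pseudogene"
    protein = str(Seq(cds).translate())
    model.protein = protein
    return "pseudogene" if "*" in protein else "intact"


def _assert_model_invariants(models: list[GeneModel], scaffold: SequenceRecord,
                             params: SearchParams) -> None:
    for m in models:
        coords = [iv for iv, _ in m.exons]
        if m.strand == "-":
            coords = coords[::-1]
        for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
            assert e1 <= s2, f"{m.id}: exon order violated"
            assert s2 - e1 <= params.max_intron_bp, f"{m.id}: intron bound violated"
        for (s, e), _ in m.exons:
            assert 0 <= s < e <= len(scaffold.sequence), f"{m.id}: out of bounds"
        dup_idx = [i for i, (_, r) in enumerate(m.exons) if r == "E3dup"]
        assert len(dup_idx) <= 1
        if dup_idx:
            e3_pos = [i for i, (_, r) in enumerate(m.exons) if r == "E3"]
            assert e3_pos and dup_idx[0] < e3_pos[0], f"{m.id}: E3dup not 5' of E3"


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntenyEntry:
    gene_id: str
    orthogroup: str
    position: int          # rank along the scaffold, oriented by the marker
    orientation: int       # +1 same strand as marker, -1 opposite


@dataclass(frozen=True)
class SyntenyMap:
    species_id: str
    scaffold_id: str
    anchor_gene_id: str
    entries: tuple        # SyntenyEntry, ordered


def build_synteny_map(genes: Sequence, marker_orthogroup: str,
                      species_id: str = "") -> SyntenyMap:
    """Marker-anchored gene order for one scaffold.

    `genes` may be truth records or any objects exposing gene_id,
    orthogroup, strand, scaffold_id and a coordinate (exons or span).
    Order and orientation are expressed relative to the marker strand so
    maps are comparable across species regardless of scaffold polarity.
    """
    def start_of(g) -> int:
        if hasattr(g, "exons") and g.exons and isinstance(g.exons[0], tuple) \
                and len(g.exons[0]) == 3:
            return min(s for s, _, _ in g.exons)
        return g.span[0]

    markers = [g for g in genes if g.orthogroup == marker_orthogroup]
    if len(markers) != 1:
        raise GeneFindError(
            f"marker {marker_orthogroup!r} occurs {len(markers)} times; need exactly 1")
    marker = markers[0]
    ordered = sorted(genes, key=start_of)
    if marker.strand == "-":
        ordered = ordered[::-1]
    entries = tuple(
        SyntenyEntry(g.gene_id, g.orthogroup, i,
                     +1 if g.strand == marker.strand else -1)
        for i, g in enumerate(ordered))
    return SyntenyMap(species_id or getattr(marker, "scaffold_id", ""),
                      marker.scaffold_id, marker.gene_id, entries)


def compare_synteny(map_a: SyntenyMap, map_b: SyntenyMap) -> tuple[int, float]:
    """(number of shared orthogroups, Kendall tau of their relative orders)."""
    rank_a = {e.orthogroup: e.position for e in map_a.entries}
    rank_b = {e.orthogroup: e.position for e in map_b.entries}
    shared = sorted(set(rank_a) & set(rank_b))
    if len(shared) < 2:
        return len(shared), float("nan")
    tau = kendalltau([rank_a[o] for o in shared],
                     [rank_b[o] for o in shared]).statistic
    return len(shared), float(tau)


# ---------------------------------------------------------------------------
# Recovery evaluation against generator truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    n_truth_exons: int
    n_exact_exons: int
    n_truth_genes: int
    n_status_correct: int
    n_dup3_truth: int
    n_dup3_flagged: int

    @property
    def exon_recovery(self) -> float:
        return self.n_exact_exons / self.n_truth_exons if self.n_truth_exons else 1.0

    @property
    def status_accuracy(self) -> float:
        return self.n_status_correct / self.n_truth_genes if self.n_truth_genes else 1.0

    @property
    def dup3_recovery(self) -> float:
        return self.n_dup3_flagged / self.n_dup3_truth if self.n_dup3_truth else 1.0


def evaluate_recovery(truth_genes: Sequence, models: Sequence[GeneModel]
                      ) -> RecoveryReport:
    """Compare reconstructed models with generator truth: exact exon
    boundaries, per-gene status, and E3dup flagging of 4-exon genes."""
    model_exons = {(iv, role) for m in models for iv, role in m.exons}
    model_intervals = [iv for m in models for iv, _ in m.exons]

    n_truth_exons = n_exact = 0
    for g in truth_genes:
        for s, e, role in g.exons:
            n_truth_exons += 1
            if ((s, e), role) in model_exons or (s, e) in model_intervals:
                n_exact += 1

    n_status = 0
    n_dup3_truth = n_dup3_flag = 0
    for g in truth_genes:
        span = (min(s for s, _, _ in g.exons), max(e for _, e, _ in g.exons))
        overlapping = [m for m in models if _overlap(m.span, span) > 0]
        match = max(overlapping, key=lambda m: _overlap(m.span, span), default=None)
        if match is not None and match.status == g.status:
            n_status += 1
        if "E3dup" in g.roles:
            n_dup3_truth += 1
            if match is not None and "E3dup" in match.roles:
                dup_i = match.roles.index("E3dup")
                e3_i = match.roles.index("E3")
                if dup_i < e3_i:
                    n_dup3_flag += 1
    return RecoveryReport(n_truth_exons, n_exact, len(truth_genes), n_status,
                          n_dup3_truth, n_dup3_flag)
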