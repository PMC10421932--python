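# Methods

This note documents the models, heuristics and numerical choices behind
tfxkit, and what the synthetic conditions do and do not show about real
genomes.

## Synthetic data model

The generator emulates a marker-anchored LY6/3FTX genomic cluster; its
defaults are the study conditions every test and the acceptance script
run under.

**Protein groups.** Seven groups span the family's diversity: anchored
and secreted LY6, a pre-3FTX-like group (membrane-anchored, signal
starting MK but not MKT), and the four toxin categories — plesiotypic
(ancestral 10-cysteine framework), short-chain (8 cysteines; slots 2–3
lost), long-chain (8 ancestral slots + a novel cysteine pair inside a
6-residue central-loop extension), and non-standard (here: 9 slots,
missing slot 7). Anchored groups end in a hydrophobic tail of 14–20
residues drawn from {A,I,L,F,V} (mean Kyte–Doolittle hydropathy ≥ 1.8).
Mature cores are 60–74 residues, consistent with the 60–74-residue range
typical of the three-finger region; the extra length beyond the
60-residue slot template is placed in loop III.

**Slot template.** The canonical 10 cysteine slots sit at 0-based mature
positions (2, 8, 14, 22, 29, 35, 41, 47, 54, 59) of a 60-residue core;
slot 10 is the final core residue, so everything after it is tail.
Loop II is the region between slots 4 and 5 (reference length 6); loop
III insertions go between slots 8 and 9. The literature gives residue
ranges but no explicit per-slot template, so these spacings are a fixed,
documented idealization.

**Sequences.** Signal peptides are an M-led tripeptide + a hydrophobic
h-region (12–18 residues from {I,L,V,F,M}) + the c-region `SSA`, total
18–24 residues. Filler residues are drawn from a group-specific
composition bias (half the probability mass on three residues per group)
— a stand-in for the sequence divergence that separates real subfamilies
in composition space. Family members are point-substituted copies of a
group exemplar at a configurable rate (default 5%); cysteines, the
signal tripeptide and the c-region never mutate, so framework truth
stays exact.

**Genomes.** Genes are back-translated with a fixed most-frequent-human
codon per amino acid and split into exons at the signal/core and
core/C-terminus boundaries; exon 3 carries the last 15 core residues
plus any tail. Introns (default 50–200 bp) start GT and end AG;
intergenic spacers are 200–800 bp of uniform random DNA. Truth exon
intervals cover coding sequence only — the terminal stop codon sits just
3′ of exon 3 — so splicing and translating the truth exons of an intact
gene reproduces its protein exactly. The marker gene (a TOP1MT-like
single-copy anchor with no cysteines) is implanted exactly once, at a
flank or the middle of the cluster. Pseudogenes get exactly one lesion
(a TAA substitution or a 1-bp deletion), never in the first or last
codon of an exon, so boundary detection stays well-posed; the demo and
acceptance configurations use the stop mode, which keeps exon lengths
intact. Four-exon genes carry a stop-disrupted copy of exon 3 inserted
5′ of the functional copy; in truncation mode the functional exon 3
instead ends at a stop placed before the tail segment, emulating the
duplication-plus-premature-stop route from membrane-anchored to secreted
forms, and the truth protein loses its tail. Orphan exons are lone E2/E3
copies with no chaining partners.

**What this does not model.** Substitution is uniform and rate-fixed; no
phylogenetic correlation, codon bias evolution, indels inside exons,
repeats, or assembly gaps. Passing tests therefore demonstrate
algorithmic correctness under clean homology at ≤15% protein divergence,
not robustness to deep divergence or messy assemblies.

## Gene finding

Scaffolds are translated in all six frames (N → X); exon peptide queries
from a reference panel are aligned to each frame with local
Smith–Waterman (BLOSUM62, gap open 11, extension 1, X scored 0 against
everything). Per (frame, query) the best alignment is taken, masked, and
the search repeated, so multiple gene copies are all found. BLAST-style
e-values do not port to raw Smith–Waterman scores, so hits are filtered
by normalized score (≥ 1.0 per aligned column), identity (≥ 0.5) and
query coverage (≥ 0.75); all are config-exposed. The identity and
coverage defaults were chosen so that a generic 25-residue query finds
nothing in uniform random DNA (the short, low-complexity signal-peptide
and exon-3 queries otherwise produce chance hits) while true hits at 15%
divergence (identity ≈ 0.85) pass with a wide margin. Because close
homologs differ from panel queries by substitutions only, the aligned
region is extrapolated to the full query span, which recovers exact exon
boundaries even when terminal residues mismatch — this assumption fails
for indel-divergent homologs.

Hits overlapping a better same-role hit are collapsed regardless of
strand (a genuine exon also echoes weakly in antisense frames). Chaining
is a dynamic program over gene-orientation-sorted hits maximizing total
alignment score minus 0.1 per intron base pair; transitions require the
same strand, role order E1→E2→E3 (with one optional extra exon-3 hit,
whose 5′ copy is labeled E3dup), intron length within [20, 10000] bp,
and GT..AG splice motifs on the coding strand. The per-bp intron penalty
keeps assembly local — at this genomic scale, chaining to an exon copy
one gene over costs more than any exon scores — and breaks ties
deterministically. Remaining single hits become orphan-exon-set models.
A model is intact iff its spliced CDS (E3dup excluded) has length ≡ 0
mod 3 and a stop-free translation; otherwise pseudogene.

Synteny maps order genes along the scaffold relative to the marker's
strand; two maps are compared by shared orthogroup count and Kendall τ
of the shared genes' relative orders.

## Framework mapping and classification

Signal peptides are removed at the annotated site when given; otherwise
a heuristic scans cleavage positions 15–30 and takes the first with
small residues (A,G,S,C,T) at −3 and −1 and a mean hydropathy ≥ 1.5
over the h-region window [p−13, p−5). Sequences with no qualifying site
are analyzed uncleaved and flagged.

Cysteine slots are mapped by an order-preserving assignment of observed
cysteine positions onto the template slot positions, minimizing: 3.0 per
unassigned cysteine (extra), 3.0 per skipped slot, 1.0 per residue of
spacing distortion between consecutive assigned anchors, 0.25 per
residue of absolute offset of the first pair — except that spacing
*expansion* across the elastic loops (loop II after slot 4, loop III
after slot 8) costs only 0.1 per residue, reflecting that three-finger
loops tolerate insertions while the disulfide-knot spacing is rigid. A
sequence-level Needleman–Wunsch mapping against a concrete reference was
implemented first and abandoned: with vacant lost-pair columns, novel
loop-II cysteines steal slot columns under every gap-penalty setting
tried, and no flat distortion cost separates loop insertions from
register shifts. Ties prefer more, and earlier, assignments. The core
region ends at slot 10's position (extrapolated from the last assigned
slot by the template remainder when slot 10 is empty); unassigned
cysteines before the core end are extras; the loop-II extension is the
assigned slot-4→5 spacing minus the reference 6; the tail is everything
after the core.

MaD detection: anchored iff tail length ≥ 12 (L_min) and mean
Kyte–Doolittle hydropathy of the tail ≥ 0.5 (H_min). Classification
rules, applied in order: (1) all 10 slots, no extras, loop-II extension
< 4 → plesiotypic; (2) exactly the 8 slots left by losing the 2–3 pair,
no extras → short_chain; (3) ≥ 8 slots, exactly 2 extra loop-II
cysteines, extension ≥ 4 → long_chain; (4) otherwise non_standard. The
lost pair (slots 2–3) and E_min = 4 are documented constants exposed in
`ClassifierParams`; the literature identifies the lost bond graphically,
not by number.

## Embedding space and clustering

Features: 20D composition (non-standard residues dropped from numerator
and denominator), 400D normalized 2-mers, a 16D framework descriptor
(10 occupancy flags, extras, loop-II extras, loop-II extension, tail
length, core length, mature length), or imported per-protein vectors
joined by id. Non-composition blocks are z-scored before projection;
composition is left raw. Projection is UMAP with n_neighbors=25,
min_dist=0.5, n_components=3 and a fixed random_state (default 42),
deterministic per seed and input order. Clustering runs on the projected
3D coordinates by default (a feature-space flag exists): k-means
(k-means++/Lloyd, tol 1e-6, max 300 iterations, k=7), DBSCAN (ε=0.55,
minPts=5 counting the point itself; border points join the
lowest-indexed neighbouring cluster), and OPTICS (min_pts=5 — reusing
the DBSCAN value, as the study fixes only ξ — with ξ=0.01 extraction on
a reachability ordering that starts each sweep at the lowest unprocessed
index and advances to the minimum reachability, ties to the lowest
index). DBSCAN and the OPTICS ordering are validated against exhaustive
brute-force oracles for n ≤ 12. Concordance is the adjusted Rand index
with noise (−1) treated as one extra class (configurable by relabeling
before the call). Distances are Euclidean throughout.

The anchored-vs-secreted comparison is made between the pipeline's
MaD calls and truth (the study colored its embedding by per-protein
anchoring predictions rather than clustering for that split); geometric
k=2 clustering splits along group structure, not the MaD axis, and is
not used for this statistic.

## Trees

Neighbor joining follows the classical Saitou–Nei Q-criterion with two
choices the textbook algorithm leaves open: Q ties break toward the
lexicographically lowest label pair, and negative branch lengths are
clamped to 0 with a warning. The final two lineages join along a single
edge so fully resolved trees have internal degree 3. Robinson–Foulds
counts nontrivial bipartitions present in exactly one tree; monophyly is
tested in the unrooted sense (some edge separates exactly the subset).
Bayesian/ML inference is out of scope; published trees are imported as
Newick and compared with these tools.

## Pipeline and problem sizes

One global seed derives per-stage seeds as the first four bytes of
sha256("{seed}:{stage}") mod 2³¹, so stages rerun in isolation
reproduce exactly. The default demo sizes — one ~11 kb scaffold with 10
genes plus 1 orphan exon set, a 203-protein noise-free classification
cohort (29 per group), a 210-protein clustering cohort (30 per group),
200 aligner oracle pairs, 40 density-clustering instances (n ≤ 12), and
50 additive 8-leaf matrices — were chosen to exercise every code path
at the cluster sizes the family actually shows (8–35 genes) while a
full run stays under a minute.

## Known limitations

- Boundary extrapolation assumes substitution-only divergence from the
  query panel; frameshifted pseudogenes are detected but their lesioned
  exon's boundaries are not guaranteed exact.
- The signal-peptide and MaD heuristics are transparent stand-ins for
  learned predictors (SignalP/TMbed-class tools); annotations always
  take precedence and should be supplied for real data.
- The slot-assignment costs are calibrated to three-finger-fold
  geometry; frameworks with radically different spacing would need a
  different template, which `map_cysteine_framework` accepts as an
  argument.
- OPTICS ξ-extraction at ξ=0.01 is highly split-sensitive on diffuse
  clusters; its leaf labels are reported as computed, without smoothing.
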