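# Methods

crpkit re-implements, as a tested pipeline, the computational workflow used to
discover and characterize a family of six-cysteine plant peptides (knottins of
the squash family): counting cysteines from the reduction/alkylation mass
shift, in-silico proteolysis, de novo sequencing from b/y-ion ladders,
cysteine-loop annotation with P1-based functional classification, EMBOSS-style
pairwise similarity, and six-frame translation mining of nucleotide data.
This note records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Mass model

All masses are monoisotopic (reflector-mode MALDI data), hard-coded to five
decimals from the standard residue-mass table and cross-checked against
pyteomics in the test suite. A peptide's neutral mass is strictly additive:
residues + one water + modification deltas − 2 × 1.00783 Da per disulfide;
`[M+H]+` adds one proton. Average masses, charge states above 1+, and isotope
envelopes are deliberately unsupported.

Native peptides of this family are assumed fully oxidized (`n_disulfides =
n_Cys // 2` by default, with an explicit override for free-thiol species).
Reduction and carbamidomethylation therefore shift a peptide by 58.029 Da per
cysteine (1.008 from disulfide opening + 57.021 from the alkyl group); this
per-cysteine quantum is what the peak-pairing stage divides observed shifts
by. The default pairing tolerance is 0.3 Da, covering the ±0.2 Da spread of
the observed shifts; an odd-cysteine peptide (one free thiol) does not follow
the single-quantum model and is out of scope for the counting operation.

Observed intact masses in the source data sit systematically ~0.5 Da below
theory (uncalibrated instrument offset); the pipeline treats printed intact
values as observations inside a 0.7 Da band rather than forcing equality, and
one panel member (the 4084.1 Da peptide) carries a 0.73 Da residual. Fragment-
level masses are far better behaved (≤ 0.06 Da for four of the six printed
fragments, ≤ 0.17 Da for the other two), so fragment matching uses 0.1–0.2 Da
tolerances and a 0.05 Da tolerance for MS/MS ladder gaps.

## Digestion

Cleavage rules are site sets: trypsin after K/R, chymotrypsin after F/Y/W/L,
Glu-C after E. Two deliberate departures from textbook defaults: the trypsin
K/R-P block is OFF (the observed fragments of the sequenced peptide require
cleavage at two K-P junctions; `--no-kp` restores the classical rule), and
chymotrypsin includes Leu but not Met (no Met-boundary fragment was observed).
Complete digestion with `max_missed` missed cleavages enumerates fragments
bounded by consecutive sites; partial digestion is the same with all missed
cleavages allowed, i.e. every site-bounded substring. Fragment masses are
reported for the carbamidomethylated species, the one actually digested.
Fragments below MH 500 are retained but flagged (MALDI low-mass matrix
region).

## De novo sequencing

**Spectrum interpretation** walks a spectrum graph. Every peak is entered in
b-ion space twice: at its own m/z and mirrored through the precursor
(`b = MH + proton − y`), so complementary ions collapse onto shared, doubly
supported junction nodes after clustering (nodes closer than half the
fragment tolerance merge). Directed edges connect nodes whose mass gap
matches a residue; Cys participates as the 160.031 Da carbamidomethylated
pseudo-residue. Paths from the virtual N-terminal node (one proton) to the
virtual C-terminal node (MH − water) spell candidate sequences. Three details
are load-bearing:

* *Antisymmetry*: a path may not use two distinct nodes whose masses sum to
  MH + proton — those are the b- and y-space images of the same ion, and
  without this constraint chimeric paths that hop between the two ladders
  outrank the true read.
* *Composite gaps*: a junction absent from both ion series leaves a
  two-residue gap; such gaps are bridged by residue pairs (both orders
  emitted) and searched by iterative deepening (at most 1, then 2, then 3
  composites per path), because unconstrained composite branching makes the
  path space intractable. Several pair sums collide with single residues
  (G+G = N exactly, G+V ≈ R at 0.011 Da, A+D ≈ W at 0.015 Da), so composite
  and single readings coexist as ranked alternatives.
* *Ranking*: ion coverage (fraction of junctions with an observed node),
  then the number of supporting peaks (doubly supported junctions beat
  mirror-artifact nodes), then summed intensity, then lexicographic order.

Leu/Ile are isobaric and always reported as `J`; Lys/Gln differ by 0.0364 Da,
below any realistic MALDI-TOF/TOF tolerance, so K/Q positions are written `K`
and flagged. Candidates are validated against the precursor mass and the top
20 returned.

**Assembly.** The contract-level assembler places every fragment candidate,
requires overlap agreement at shared positions (with `J` and flagged `K`
acting as L/I and K/Q wildcards), enforces that a fragment's N-terminus
follows a cleavage residue of its own enzyme or opens the peptide, checks the
consensus against the native intact mass (0.7 Da default, the calibration
band), and returns all surviving orderings — order-ambiguous layouts are
flagged, never dropped silently.

For realistic partial digests (tens of redundant, overlapping fragments) the
pipeline entry point `sequence_from_spectra` grows contigs greedily by
maximal consistent overlap instead, with several safeguards shaped by the
failure modes of greedy assembly: spectra are processed in order of
interpretation quality; a spectrum whose candidate variants merge equally
well but disagree (an unresolved transposition) is deferred until other
spectra pin the region down; every uncorroborated merge also branches into
the path where the questionable spectrum is dropped; a contig may never
exceed the intact mass (repeat-induced pileups are mis-merges by
construction); and a contig failing a known amino-acid composition is
repaired, where possible, by a single mass-neutral residue↔pair swap.
Competing contig hypotheses are arbitrated by how well their predicted
complete-digest fragment masses match the observed complete-digest peak
lists, then by how many spectra read consistently with them.

**Isobaric resolution** uses the enzyme-specificity argument: trypsin cleaves
after Lys but not Gln, chymotrypsin after Leu but not Ile, so the
complete-digest fragment-mass set differs between isobaric alternatives.
Assignments of the flagged positions are enumerated jointly (the K/Q and L/I
groups independently — each only moves its own enzyme's sites) and scored
against the observed complete-digest peak lists (+1 per predicted fragment
mass observed within 0.2 Da, −1 per predicted mass absent). A position is
fixed only when every top-scoring assignment agrees; an optional residue
composition (the amino-acid-analysis confirmation step of the original
workflow) constrains the assignment set further. The C-terminal residue never
bounds an internal site and is assigned to the cleaving residue when tied —
the terminal fragment boundary exists either way. Joint set-scoring, rather
than the per-position boundary-peak lookup it generalizes, is what prevents
isobaric single-residue fragments (a lone Leu and a lone Ile fragment both
weigh 132.10 Da) from resolving positions incorrectly; positions the evidence
cannot decide stay flagged, which is a valid outcome — some composition- and
cleavage-preserving rearrangements (e.g. Q-C-K vs K-C-Q around a non-site)
are genuinely indistinguishable by this evidence.

## Annotation and comparison

A sequence decomposes into prefix, inter-cysteine loops, and suffix; the
six-Cys family template is prefix ≤ 5, loops 6/5/3/1/10, suffix ≤ 3, and the
putative disulfide connectivity for six cysteines is the knottin pattern
C1-C4, C2-C5, C3-C6. The functional P1 residue is the second residue of
loop 1 — the offset shared by the characterized squash trypsin inhibitors —
and Arg/Lys there labels a peptide trypsin-inhibitor-like, anything else
antimicrobial-like. The offset is configurable since it is an inference from
the family alignment, not a universal constant.

Pairwise comparison follows the EMBOSS Needle protocol: global alignment,
BLOSUM62, gap open 10 / extend 0.5 under the EMBOSS convention (a gap of
length L costs 10 + 0.5·L), end gaps free. Identity and similarity are
percentages of the alignment length, similarity counting pairs with positive
substitution score. Biopython's `PairwiseAligner` stands behind this
operation; arguments are canonically ordered internally so the result is
exactly symmetric, and the seven printed reference similarities (43.6 down to
20.0 %) reproduce to the printed decimal. Trees are neighbor joining
(scikit-bio) on 1 − identity-fraction distances with negative branch lengths
clamped — a documented stand-in for a maximum-likelihood tree, sufficient for
the two-branch (antimicrobial vs. trypsin-inhibitor) claim at desk scale.
Frequency-logo matrices are plain per-column frequencies over residues+gap;
rendering is left to the caller.

## Mining

Nucleotide input is translated in all six frames (Biopython, stops retained,
N → X), scanned for windows of six cysteines whose spacings satisfy the
template bounds (loop 5, the branch-discriminating loop, defaults to 5–12;
prefix/suffix extension stops at stop codons and further cysteines so every
candidate has exactly six Cys and no stop), then scored against the query
peptides by ungapped local alignment (BLOSUM62). Significance is an ungapped
Karlin–Altschul estimate, E = K·m·n·e^(−λS) with K = 0.13, but λ is solved
for the query's own residue composition (∑ pᵢpⱼe^(λsᵢⱼ) = 1). For a
cysteine-rich query the composition-specific λ is markedly smaller than the
standard-background 0.318 (0.199 for the 39-residue reference query), and
this matters: under the standard constants, about one in a thousand
composition-matched shuffled decoys of the query reaches E ≤ 0.001, while the
corrected λ keeps all such decoys insignificant and leaves true homologs at
E ≤ 10⁻⁹. This is an estimate for thresholding a local search, not a
reproduction of NCBI BLAST statistics (no gapped statistics, no length
corrections, no composition-based score adjustment).

## Assay arithmetic

Molar extinction at 280 nm is 5690·nW + 1280·nY + 120·n_cystine; molar
concentration follows Beer–Lambert. Percent inhibition is
100·(1 − (signal − background)/(negative control − background)), exactly
affine-invariant, clamped to [0, 100] with an explicit flag rather than an
error (activation and noise occur in real plates). No kinetic modelling or
dose–response fitting.

## Synthetic data

Generators are pure functions of their parameters and a seed. Peptides are
drawn on the family template (loops 6/5/3/1/10, prefix 1–5, suffix 1–3,
residues uniform over the 19 non-Cys letters) with the P1 policy selecting
the branch (aromatic/basic/random). MALDI peak lists get Gaussian calibration
jitter (0.05 Da default at the MS1 level), log-normal intensities, and
uniform decoy peaks; MS/MS spectra get complete b/y ladders with 0.01 Da
jitter, 10 % per-ion dropout, and 5 decoys by default. Genomes are uniform
random nucleotide backgrounds with peptides reverse-translated through
uniformly random synonymous codons and planted at disjoint positions on
random strands, with a truth table of coordinates and frames.

What the generator does not emulate — isotope envelopes, adducts, in-source
decay, intensity structure of real ion series, codon bias, intron-containing
precursor genes — bounds what passing tests show: they validate the
arithmetic and the inference logic under the stated noise model, not
instrument-grade robustness.

The full-pipeline property (simulate digests and spectra → interpret →
assemble → resolve → exact recovery of the planted sequence) is exercised on
60 generated peptides per run in the default suite — a size chosen to keep
the suite fast; across two 40/60-peptide seeded batches measured during
development the recovery rate was 98/100, with both failures being the
genuinely indistinguishable rearrangements described above.

## Known limitations

* Cysteine counting assumes fully oxidized, singly protonated species.
* De novo sequencing assumes fixed carbamidomethylation and b/y ions only;
  a/c/x/z ions and multiply charged fragments are not modelled.
* K/Q and L/I calls depend entirely on enzymatic evidence (plus optional
  composition); a C-terminal K/Q is decided by a 0.036 Da mass difference in
  reality, which MALDI-TOF cannot see — the terminal tie-break convention
  assigns the cleaving residue.
* The E-value estimate is not BLAST-calibrated; absolute E-values printed for
  database-scale searches elsewhere are not comparable quantities.
* The NJ tree is a topology-level stand-in; branch support is not computed.
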