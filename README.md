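# crpkit

Discovery and characterization toolkit for plant cysteine-rich peptides
(CRPs): the six-cysteine, three-disulfide knottins of the squash family and
their relatives.

Starting from a crude plant extract, such peptides can be characterized
without any sequence database: alkylating the cysteines shifts each peptide's
MALDI `[M+H]+` by ~58.029 Da per cysteine, so pairing native against
reduced/alkylated peak lists counts the cysteines (Δ348 Da ⇒ six Cys, three
disulfides); partial proteolysis produces overlapping fragments whose b/y-ion
ladders are read de novo; complete digests with trypsin and chymotrypsin
decide the isobaric pairs (Lys/Gln, Leu/Ile) through their cleavage
specificity; and the finished sequences are annotated by cysteine-loop
spacing (CX₆CX₅CX₃CX₁CX₁₀C for this family), classified by the P1 residue of
loop 1 (Arg/Lys ⇒ trypsin-inhibitor-like, Phe ⇒ antimicrobial-like), compared
by EMBOSS-style global alignment, and used as queries to mine six-frame
translated genomes and transcriptomes for homologous precursors.

crpkit implements each of those stages as a library module with a thin CLI,
plus seeded generators that simulate every input class (peak lists, MS/MS
spectra, nucleotide backgrounds with planted precursors) so the whole
pipeline is testable end to end without instrument data.

It is aimed at peptidomics practitioners and bioinformaticians working on
disulfide-rich peptide families — and at anyone who wants a transparent,
fully tested reference implementation of this workflow.

## Worked example

Count cysteines from a native/alkylated peak pair (two-column TSV in, one
pairing out):

```
$ crpkit count-cys --native native.tsv --alkylated alkylated.tsv --tol 0.3
# native_mz	alkylated_mz	delta	n_cys	residual	primary
3734.2000	4082.3000	348.1000	6	-0.0757	1
```

The 348.1 Da shift is within 0.08 Da of six per-cysteine quanta (6 × 58.029):
this 3.7 kDa peptide carries six cysteines, hence three disulfides.

Digest it in silico (trypsin, carbamidomethylated masses, cleavage at K-P
junctions on by default because that is what the MALDI data of this family
shows):

```
$ crpkit digest --fasta citcols.fasta --enzyme trypsin
# parent	fragment	start	end	missed	MH
citcol-2	VCLFVGK	0	7	0	822.4542
citcol-2	PCWSDADCPSGCYCK	7	22	0	1862.6601
citcol-2	PLPLIDAGYCGFL	22	35	0	1435.7290
```

The 822.45 and 1435.73 Da fragments are the ones observed at 822.4 and
1435.7 Da after tryptic digestion of the purified peptide. Annotate the
finished sequences:

```
$ crpkit annotate --fasta citcols.fasta
# name	n_cys	prefix	loops	suffix	P1	label
citcol-2	6	1	6-5-3-1-10	3	F	antimicrobial_like
citcol-8	6	5	6-5-3-1-10	3	F	antimicrobial_like
```

Both match the family template (loops 6/5/3/1/10) and carry Phe at P1 —
antimicrobial-like, consistent with their measured lack of trypsin
inhibition. Compare against a real squash trypsin inhibitor:

```python
>>> from crpkit.annotation import needle_align
>>> r = needle_align("NRVGVCLFVGKPCWSDADCPSGCYCKPLPLIDAGYCGFL",
...                  "QRACPRILKKCRRDSDCPGECICKENGYCG")
>>> print(f"similarity {r.similarity_pct:.1f}%")
similarity 43.6%
```

43.6 % similarity to the *Momordica cochinchinensis* trypsin inhibitor
MCoTI-III — high enough to place both in one structural family, while the
P1 residue (Arg in MCoTI-III, Phe here) separates their functions.

Other subcommands: `denovo` (MGF spectra → consensus sequence), `align`,
`tree` (neighbor-joining newick), `mine` (six-frame CRP mining of nucleotide
FASTA), `assay` (percent-inhibition arithmetic), `simulate` (synthetic
peptides and peak lists). `docs/methods.md` describes the models, defaults
and their rationale.

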