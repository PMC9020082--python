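# coevoscan

Structural characterisation of protein sequence constraints: scoring how
well coevolutionary couplings in a multiple sequence alignment correspond to
3D contacts in a structure, analysing couplings across homomeric and
heteromeric interfaces, and profiling constrained-residue hydrogen-bond
dynamics over molecular-dynamics trajectory frames.

## Who it is for

Researchers with (i) a large gapped alignment of homologous proteins, some
of which have solved structures, and/or (ii) MD trajectory frames of such a
protein. Typical questions: *Which of my structures is in a functionally
relevant conformation? Are the contacts between identical subunits of this
crystal dimer evolutionarily constrained, or a packing artifact? Do two
different subunits of a complex coevolve across their interface? Which
hydrogen bonds involving constrained residues form and break in a
correlated way during a simulation?*

## The statistic

Direct-coupling analysis (DCA) scores every column pair *(i, j)* of an
alignment by the APC-corrected Frobenius norm of its coupling block,
estimated here by mean-field inversion of the redundancy-weighted,
pseudocount-regularised covariance matrix (externally computed scores can
be substituted everywhere via `--scores`).

Ranking all *L* eligible column pairs by coupling score and marking the *D*
pairs that are in 3D contact (minimum all-atom distance ≤ *r*, sequence
separation ≥ *m*) gives a ranked binary list. For every candidate cut point
*X* ending at a contact, the probability of seeing *d(X)* or more contacts
among the top *X* by chance is the hypergeometric tail

    P(X, d) = P[ Hypergeom(L, D, X) ≥ d ] ,

and the reported score is

    S = −log₁₀( min(1, n_tests · min_X P(X, d(X))) )   [dits]

with a Bonferroni factor over the candidate cuts; nats = dits × ln 10. The
same cut-point scan scores heteromeric interfaces (distinguished = cross-
subunit pairs within *r*, default 5 Å), per-frame trajectory conformations
(*simul*), and spatial clusters of pattern residues (*sipris*, where the
ranking is a greedy single-linkage growth order from each seed residue).

For homo-oligomers, ΔS = S(merged) − S(internal), where the merged analysis
lets the shorter of the internal and cross-chain distances define each
pair's contact status. ΔS ≳ 3 indicates that inter-subunit contacts absorb
coupling signal — evidence the interface is evolutionarily constrained.

For heteromers, the two alignments are reduced to one ortholog per species
per side (highest identity against the structure-linked query row, species
matched by `taxid=` labels), concatenated per species, and only
cross-subunit column pairs are scored.

## Worked example

Generate a synthetic homodimer whose five designated cross-interface
residue pairs are in contact, plant the contact pairs at the top of a
coupling table, and rank it:

```
coevoscan fixtures --name dimer --out demo
coevoscan rank --msa demo/aln.fasta --structure demo/dimer.pdb \
    --scores demo/scores.tsv --out demo/out
cat demo/out/rank.tsv
```

```
# coevoscan 0.1.0 | mode=rank | m=5, r=4.0, seed=0
pdbid   chains  S       nats    L       D       X       d       F       dS      degenerate
1TOY    A:B     14.55   33.5    325     8       8       8       0.27    9.82    0
1TOY    A       4.73    10.9    325     3       7       3       0.23            0
```

Reading the rows: the alignment contributes L = 325 ranked column pairs.
Within chain A alone, D = 3 of them are contacts and all three sit in the
top 7 ranks (X = 7, d = 3), giving S = 4.73 dits — the chance probability
of that concentration is about 10⁻⁴·⁷. Merging chain B's cross-interface
distances (row `A:B`) raises the contact count to D = 8, all eight occupy
the top 8 ranks, and S jumps to 14.55 dits. The increment ΔS = 9.82 far
exceeds the interpretive threshold of ~3: the interface contacts carry
coupling signal, so this dimer arrangement behaves like a biologically
constrained interface rather than a packing artifact. F = X/ℓ (here
8/30 = 0.27) says how spread out the optimum cut is relative to the
alignment length.

The other analysis modes follow the same grammar — `hetmer` (two
alignments, two chains), `simul` (per-frame S over a trajectory), `sc2sc` /
`sc2bb` / `sc2sb` / `bb2bb` (hydrogen-bond time series), `dist`
(residue/ligand distances), `correl` (correlated bond switching, ranked by
an exact two-tailed Fisher term — a rank score, not a significance level,
since frames are autocorrelated), `sipris` (pattern-residue clusters) and
`vsi2pml` (PyMOL rendering, solid lines ≤ 10 Å, dashed beyond).

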