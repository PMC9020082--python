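# Methods

This note records the models, numerical choices and design decisions behind
coevoscan, and what the synthetic fixtures do and do not establish.

## Coupling estimation

Couplings are estimated by mean-field DCA. Sequences are down-weighted for
redundancy: the weight of a record is 1/(number of records, itself
included, with ≥ 95% identity over mutually non-gap columns). The 0.95
threshold is the same level at which redundant sequences are conventionally
purged from large alignments, so one threshold serves both purposes; it is
a parameter of `compute_sequence_weights`.

Single and pair frequencies are computed over 21 states (20 amino acids
plus gap; `X` counts as gap) with a uniform pseudocount λ = 0.5 of the
effective counts — the usual mean-field regularisation scale, exposed as a
parameter. The covariance matrix is restricted to the 20 amino-acid states
(gap is the reference state), inverted, and each pair's 20×20 coupling
block is scored by its Frobenius norm in the zero-sum gauge. The average
product correction then subtracts rowmean·colmean/overallmean (off-diagonal
means). A singular covariance at λ = 0 raises with a message directing the
user to a positive pseudocount.

The scorer is injectable everywhere (consensus ranking, heteromer
analysis), so externally computed coupling tables — for example from a
pseudolikelihood or deep-learning method — can replace the built-in
estimator; the rest of the pipeline only consumes the ranking.
Pseudolikelihood maximisation itself is deliberately out of scope.

Consensus ranking draws subsamples *without* replacement within a draw and
restores the full pool between draws, records top-{20,10,5,2} membership
per column pair, and reports percentages. The elevated/reduced test on a
specific residue pair builds a 2×2 table of redundancy-weighted counts
rounded half-up (gapped rows excluded) and reports both one-sided
hypergeometric tails.

## Contacts and hydrogen bonds

Residue–residue distances are minimum all-atom distances (hydrogens
included by default, since the analyses target specific sidechain
interactions in hydrogen-added structures). A contact is a distance ≤ r
(default 4.0 Å; 5.0 Å for heteromeric interfaces) between columns separated
by at least m (default 5). The separation filter is applied to
alignment-column separation, not author residue numbering, because columns
are the ranked objects; it is not applied across chains, where no linear
order exists.

Hydrogen bonds require d(D,A) ≤ 3.5 Å, d(H,A) ≤ 2.5 Å and a D–H–A angle
≥ 120°; all three are parameters. These are standard geometric criteria;
donors and acceptors come from per-residue-type atom tables (backbone N
donates, backbone O accepts; His is both donor and acceptor), hydrogens are
assigned to donors geometrically (within 1.25 Å), and donors without
modeled hydrogens are skipped with a warning. Non-polymer residues (ions,
waters, ligands) participate as generic N/O donors/acceptors in the
residue–heteroatom category only.

## The cut-point statistic

`ica_scan` evaluates the hypergeometric upper tail at each cut ending at a
distinguished element — cuts ending elsewhere are dominated, since the tail
at the same d and larger X is never smaller — and corrects the minimum by a
Bonferroni factor equal to the number of candidate cuts. The correction is
deliberately conservative and is reported (`n_tests`) so users can see it.
Tails are computed in log space, so S-scores remain finite far beyond
float underflow of p itself. Ties between cuts resolve to the smallest X;
because exactly equal rational tails can differ in the last float bit, any
cut within 10⁻⁹ (log10) of the minimum is treated as tied. Degenerate lists
(D = 0 or D = L) raise at the library level and surface as flagged S = 0
rows in pipelines, so a trajectory frame without contacts does not abort a
series.

ΔS is pure bookkeeping — S(merged) recomputed from scratch equals
S(internal) + ΔS — and can be negative. Both runs must rank the same pair
list (equal L) or `delta_s` raises. F = X/ℓ is reported with ℓ = the
alignment column count.

The ordering refinement that places closer interactions higher affects only
report ordering among distinguished elements; the binary statistic is
unchanged by it.

For pattern-residue clusters, each pattern residue seeds a greedy
single-linkage growth ordering (repeatedly append the residue closest to
the grown set, by minimum all-atom distance); the best seed's scan result
receives an additional Bonferroni factor equal to the number of seeds.

## Heteromer pairing

Orthologs are selected per species as the record with the highest
similarity to the structure-linked query row; similarity is the count of
identical residues over columns where both rows are ungapped. The scorer is
injectable (a substitution-matrix scorer can replace it). Score ties break
to the lexicographically smaller id and are flagged, since
ortholog/paralog ambiguity is the known failure mode of best-hit pairing.
Score histograms (20 equal-width bins, fixed-width text) are emitted so a
user can eyeball whether the ortholog scores are unimodal; no normality
test is applied. The paired alignment concatenates A columns before B
columns per species, sorted by taxon id, and only cross-subunit pairs
(i ≤ split < j) are scored.

## Trajectory analyses

An interaction's identity is the unordered residue pair plus its category
(sidechain–sidechain, sidechain–backbone, backbone–backbone,
residue–heteroatom), not specific atom names, so a donor swap between
equivalent atoms (e.g. Arg NH1 vs NH2) counts as the same persisting
interaction. `sc2sb` is the union of the two sidechain categories. An
interaction is *trans* when its partners lie on different chains.

`correl` scores every pair of interactions that switch state at least
`min_switches` times (default 3) by a two-tailed Fisher probability of the
2×2 frame-count table, defined as the total probability of tables (fixed
margins) whose point probability does not exceed the observed table's. The
kernel is computed in exact integer arithmetic, which makes tie handling
exact and the exhaustive small-table validation cheap;
`scipy.stats.fisher_exact` serves as an independent cross-check in the
tests. Because trajectory frames are autocorrelated, the output labels this
quantity a rank score and never a significance level. No smoothing is
applied to the boolean series by default.

`simul` recomputes the contact set from each frame's coordinates and
re-runs the cut-point scan against a fixed coupling table.

## Synthetic fixtures

The generators are pure functions of their arguments including the seed.

*Alignments.* Background columns are i.i.d. uniform over a 6-letter
alphabet — small enough to keep pair-frequency tables well populated at the
default 500 sequences × 40 columns, which stands in for the large (10³–10⁵
sequence) alignments the method targets. A planted pair draws its two
columns from a two-state joint whose match probability is (1+s)/2, so s = 1
is perfect correlation and s = 0 independence.

*Structures.* Chains are ideal α-helices built from internal coordinates
(φ = −57°, ψ = −47°, standard bond geometry), with amide hydrogens and Cβ
atoms; the i→i+4 backbone hydrogen bonds come out at d(O,N) ≈ 3.1 Å and
~165°, inside the detection criteria. Designated contacts are realised by
pseudo-sidechain probe atoms ("XP") extended to a ledge 8 Å off the helix
axis — far enough that probes never graze intervening backbone — ending
3 Å apart; the generator verifies the realised contact map exhaustively
and raises if any non-designated pair (at separations the analyses can
see) falls within 4 Å. Serine positions carry OG/HG atoms for schedulable
hydrogen bonds. Dimers are parallel translated copies 18 Å apart; rings
place k rotated copies with a chosen neighbour-axis chord (default 14.5 Å,
making exactly the two ring neighbours "adjacent" at the r+4 Å criterion).
Probe bond lengths are unphysical by construction; the fixtures exercise
the geometry kernels, not a force field.

*Trajectories.* Frames apply per-residue rigid Gaussian jitter (σ = 0.2 Å)
— rigid per residue so intra-residue geometry (hydrogen attachment) is
never perturbed — and then impose the scheduled donor/acceptor geometry
exactly: bonds scheduled on get a collinear d(D,A) = 2.9 Å arrangement,
bonds scheduled off d(D,A) = 5.5 Å. Imposing the geometry after the jitter
makes the schedule decision noise-proof, so tests can assert exact
reproduction. Consequently the fixtures do not probe the detector's
behaviour near its thresholds under noise; the threshold geometry is
covered by direct unit tests instead.

What passing these fixtures shows: the statistics, bookkeeping and
geometry kernels are correct on inputs with known ground truth. What it
does not show: performance on real alignments (phylogenetic structure,
gaps, paralogy) or real trajectories (correlated motions, solvent), which
have no synthetic counterpart here.

## Problem sizes

The test and acceptance runs use 500×40 alignments (20 seeds), 100-frame
trajectories of ~30-residue helices, 2,000-item calibration batches, and
exhaustive cut-point enumeration to list length 12 — sizes chosen so the
full validation runs in minutes on a single CPU while every check remains
exhaustive or well-powered at its scale.

## Known limitations

- The mean-field estimator is a standard substitute for pseudolikelihood
  optimisation; rankings agree on strong couplings but can differ in the
  tail.
- The Bonferroni correction over cut points is conservative; reported S
  values are lower bounds in that sense.
- Best-hit ortholog pairing cannot distinguish co-orthologs; ambiguous
  taxa are flagged, not resolved.
- The heteromeric and homomeric analyses assume the provided chains are the
  biologically relevant interface; they do not search over interfaces.
- cif output, alignment construction, pattern-residue inference and running
  simulations are out of scope; alignments, structures, trajectories and
  pattern lists are inputs.
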