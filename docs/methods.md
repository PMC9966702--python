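# Methods

`spdca` predicts which peptide stretches of two proteins form the
interface of a transient heterodimer, using only the evolutionary record
of the two protein families, and provides the analysis criteria used to
validate such predictions on simulated coordinates. This note documents
the models, the defaults and why they hold, what the synthetic
validation does and does not demonstrate, and the numerical choices a
maintainer would need to know.

## The coevolutionary model

**Paired alignments.** Orthologs of protein A and protein B are joined
species-by-species into a concatenated alignment (cMSA) of length
L = L_A + L_B. Correlated substitutions *across* the block boundary are
the signal of physical interaction. Before pairing, ortholog sets are
restricted to an identity band relative to a reference sequence
(default 70–90%: near-duplicates carry no divergence information;
distant sequences are unreliable orthologs), and one isoform per species
is kept (the one most identical to the reference, ties to first
occurrence). "Identity" is always the fraction of matching symbols over
mutually ungapped columns; a row sharing no ungapped column with the
reference has undefined identity and is dropped with a warning. The
identity filter operates on aligned rows; unaligned inputs must be
aligned upstream.

**Potts model and pseudo-likelihood fit.** The cMSA is modeled by a
global pairwise (Potts) distribution
P(x) ∝ exp(Σᵢ hᵢ(xᵢ) + Σᵢ<ⱼ Jᵢⱼ(xᵢ,xⱼ)) over a q-state alphabet
(20 amino acids + gap for real data; the gap is a bona fide state).
Fitting maximizes the weighted, L2-regularized pseudo-likelihood — the
product of per-column conditionals, each a multinomial logistic
regression — which is convex and consistent. All L conditionals are
solved jointly by L-BFGS on a sparse one-hot design matrix; the
objective is normalized by the total sequence weight so the gradient
tolerance (1e-5) is independent of alignment depth. The two asymmetric
estimates of each Jᵢⱼ are averaged, then the couplings are shifted to
the zero-sum gauge with field compensation (the joint measure is
unchanged). Defaults: field penalty 0.01, coupling penalty 0.01·(L−1),
sequence reweighting at identity threshold θ = 0.8 (weight 1/n per
cluster of mutually ≥θ-identical rows). These are the conventional
pseudo-likelihood DCA settings; all are exposed. The optimizer is
deterministic; if it stops with a projected gradient above 10× the
tolerance, a `ConvergenceError` carrying iteration diagnostics is
raised rather than returning a silently unconverged model.

A closed-form mean-field fitter (inverse regularized covariance of
one-hot frequencies, pseudocount 0.5) is provided purely as an
independent cross-check; tests require both routes to rank strong
planted couplings identically.

**Coupling scores.** Each pair is summarized by the Frobenius norm of
its zero-sum-gauge coupling block, computed over non-gap states only so
that gap-rich columns cannot dominate interface scores. The average
product correction (APC), S′ᵢⱼ = Sᵢⱼ − S̄ᵢ·S̄ⱼ/S̄ with means taken
excluding the diagonal, removes entropic/phylogenetic background; it is
on by default (negative corrected values are clipped to zero because
the downstream convolution assumes nonnegative scores) and can be
disabled to obtain raw norms. Only the L_A × L_B inter-protein block of
the score matrix enters interface prediction.

## The structure-prior convolution

Real interfaces are contiguous peptides on both partners, so isolated
high scores are more likely false positives than a coherent patch. The
SP-DCA map pools scores over a window:

    Q_ij = Σ_{α=i−l}^{i+l} Σ_{β=j−l}^{j+l} P′_{αβ} · exp(−(a(α−i)² + b(β−j)²))

where P′ is the inter-protein score matrix multiplied column-wise by
per-protein prior masks, `l` is the half-window (interpreted as the
average interacting-peptide length), and `a`, `b` are the normalized
kernel variances along each protein (σ = 1/√(2a) residues). Window
terms beyond the matrix edge contribute zero — proteins are not
periodic, so clipping, not wrap-around. Defaults a = b = 0.001 and
l = 21 are the published settings for full-length GPCRs (~400 residues);
no re-optimization procedure is defined for them, so they are fixed
defaults, not fitted. Q is deliberately not normalized: only the
relative ranking of cells is meaningful. With l = 0 and a = b = 0 the
map reduces to P′ exactly.

**Priors.** Topology segment tables (UniProt style: label, category,
1-based inclusive range) are validated (no overlaps, end ≥ start) with
uncovered stretches auto-labeled "other". The default mask keeps
N-/C-terminal and loop segments and zeroes transmembrane segments,
where high conservation makes coevolutionary signal unreliable. The
prior enters multiplicatively on P before convolution — the most
conservative mechanism consistent with a structure-built kernel — and
an all-ones mask reproduces the bare formula to machine precision.
Real-valued per-column weights (e.g. burial) are accepted wherever a
binary mask is.

**Hot-spots.** Cells strictly above the (1 − f) quantile of Q are
grouped into 8-connected components; each component's bounding
rectangle is reported with its peak and mean score, rectangles closer
than `min_separation` residues on *both* axes are merged, and results
are sorted by peak. A constant map has no distinguishable hot-spot and
yields an empty list with a warning. Defaults f = 0.01 and
min_separation = 10 produce a handful of rectangles on receptor-sized
maps; both are configuration, not science. Rectangles are labeled per
axis by the topology segment covering the majority of their span (ties
to the lower-start segment), giving the conventional "C-Ter/N-Ter"
style labels.

## Physicochemical profiles

Profiles are windowed means (default window 9, must be odd) of
per-residue scale values; windows clip at sequence ends, gaps drop out
of the average, and a window containing only gaps is NaN, so profiles
are well defined on alignment coordinates. Eight canonical scales ship
as replaceable TSV data: Kyte–Doolittle hydrophobicity, Hopp–Woods
hydrophilicity, Grantham polarity, integer side-chain charge at pH 7
(D,E = −1; K,R = +1; His neutral), Charton polarizability, Zamyatnin
residue volume, Chou–Fasman α-helix propensity, and Tien et al.
theoretical maximum SASA. The "secondary-structure similarity" reported
alongside is the helix-propensity profile — a sequence-based proxy
chosen because the interfaces in question are helix-dominated, not a
structure-derived score.

The interface contrast takes the union of hot-spot columns on one axis
(no double counting), computes inside/outside means and a rank-sum
statistic, and estimates a two-sided permutation p-value (default 10⁴
seeded label permutations, add-one rule). Values are snapped at 1e-9
relative precision before ranking so floating-point jitter in windowed
means cannot break ties; a constant profile therefore gives p = 1
exactly. On toy inputs the permutation p agrees with exhaustive subset
enumeration within Monte-Carlo error.

## Synthetic data generator

The generator exists so that coupling inference and the full pipeline
can be validated against a known ground truth. A two-block Potts model
gets i.i.d. N(0, 0.5²) fields and zero couplings except at planted
inter-protein pairs, where J(s,t) = strength·δ_st — identity-favoring
blocks chosen over random ones because they make mutual-information
oracles exactly interpretable. Alignments are drawn by single-site
Gibbs sampling (numba-compiled): one chain, a row recorded every `thin`
sweeps (default 5) after `burn_in` sweeps (default 100). With the
sparse planted couplings the chain mixes in a few sweeps, so recorded
rows are effectively independent; correctness is checked against exact
Boltzmann probabilities on an enumerable 2-column model and against
closed-form single-site marginals. Species ids are synthetic
("sp0001", …).

What the generator does *not* emulate: phylogenetic correlation between
rows (real orthologs are tree-structured; reweighting only partly
compensates), indels/gaps, alignment errors, and conservation gradients
along the sequence. Passing recovery tests therefore demonstrates the
statistical machinery is correct at realistic depth and signal
strength, not that real GPCR interfaces will be recovered at the same
rates.

**Validation studies** (module `spdca.validation`, also run by
`scripts/acceptance.py`): study conditions are 30+30 columns, q = 8,
coupling strength 2.0, M = 2000 sequences.

* *Planted-pair recovery*: 5 isolated planted pairs; precision@5 of the
  inter-protein coupling ranking, averaged over 5 seeds (chance level
  5/900 ≈ 0.006).
* *Hot-spot recovery*: one contiguous 7-residue in-register peptide
  pair; after inference and convolution, the top-1 rectangle's area
  Jaccard with the planted region, over 10 seeds. Two analysis
  parameters are scaled to the 30-residue toy proteins: the kernel
  (a = b = 0.05, l = 5, i.e. σ ≈ 3 residues — the same kernel-width to
  peptide-length ratio the production defaults imply for full-length
  receptors; the production kernel on a 30×30 map would be flat and
  could not localize anything), and the extraction fraction, set to the
  planted-interface areal fraction 49/900 ≈ 0.05 so that predicted and
  planted areas are commensurate — the same logic as scoring
  precision@k at k = number of planted pairs.

## Trajectory analysis

All operations are pure analysis of supplied PDB coordinates (one frame
per MODEL; HETATM records excluded and counted; hydrogens kept but
flagged by element and excluded from contacts). No simulation is run,
and no assumption is made about initial chain separation.

* **RMSD**: optimal rigid superposition via the SVD (Kabsch)
  construction with reflection correction; atoms correspond by order
  within the selection; ≥ 3 atoms required. Verified against an
  independent implementation to 1e-8 Å.
* **Radius of gyration**: √(Σm|r−r_com|²/Σm), unit masses unless given.
* **Contacts**: residues of two chains are in contact iff at least
  `min_atom_pairs` (default 2) heavy-atom pairs are separated by
  strictly less than `cutoff` (default 5.0 Å). The pair-count reading
  of "at least two heavy atoms" was chosen; `min_atom_pairs=1`
  reproduces the laxer single-pair reading. Native-contact fractions
  re-apply the same rule per frame against a reference map.
* **Debye–Hückel energy**: V = K_elec Σᵢ<ⱼ qᵢqⱼ e^(−rᵢⱼ/l_D)/(ε_r rᵢⱼ)
  with K_elec = 332.24 kcal·mol⁻¹·e⁻²·Å. Default beads: the Cβ atom
  (Cα for glycine) of each charged residue with integer pH-7 charges;
  both the bead mask and charges are overridable. l_D may be given
  directly (default 10 Å) or derived from temperature and ionic
  strength as l_D = √(ε_r ε₀ k_B T / (2 N_A e² I)) in SI units
  converted to Å — cross-checked in tests against the 0.304 nm/√I
  rule for water and consistent with the ~10 Å default at 0.1 M,
  300 K. Coincident charged beads (r = 0) raise an error.

## Pipeline and reproducibility

`run_pipeline` chains pair → couple → map → hotspots → profile on
files, writing every intermediate, a human-readable summary (complex,
cMSA depth, predicted interaction labels) and a JSON manifest with the
package version, the full configuration, and SHA-256 digests of every
output. A single seed in the configuration feeds every stochastic step
(only the permutation test), so reruns are byte-identical. Stage
failures propagate with the stage name; earlier outputs are retained.

## Numerical choices and limitations

* The convolution uses exact direct summation (`convolve2d`), not FFT,
  so it matches literal window sums to ~1e-13 even at 80×80.
* The joint pseudo-likelihood fit stores an (Lq)² coupling matrix and
  L-BFGS history; with the 21-state alphabet this is comfortable to
  L ≈ 500 columns on a laptop-class machine but grows quadratically —
  masking to non-TM columns before fitting is the practical route for
  multi-domain proteins.
* Sequence reweighting is O(M²L) with chunking; ~1 s at M = 2000.
* Quantile thresholding uses strict inequality, which makes the
  constant-map degenerate case fall out naturally (no cell is strictly
  above the quantile of a constant).
* Score TSVs round to 6 significant digits; dense CSV maps keep 10.
  Byte-identical reproducibility refers to rerunning the same build on
  the same platform; cross-platform BLAS differences can perturb the
  last digits of fitted couplings.
* Hot-spot rectangles are bounding boxes; a strongly diagonal
  interaction patch is reported as the box containing it, which
  overstates its area. The rectangle semantics — the field's standard
  way of reporting interacting peptide pairs — were kept deliberately.
* The identity-band filter and best-isoform rule need a reference on
  alignment coordinates; no internal aligner is provided.
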