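# spdca

**Structure-prior-assisted direct coupling analysis: interface hot-spot
prediction for protein heterodimers.**

Transient protein–protein interactions — G-protein-coupled receptor
heterodimers are the motivating case — are held together by a few
interface residues ("hot-spots") that are expensive to map
experimentally. `spdca` predicts the interacting peptide stretches of
two proteins from sequence data alone, and ships the analysis criteria
used to check such predictions on simulated coordinates. It is a
library first (importable API plus `examples/`), with a thin `spdca`
command-line wrapper for file-based workflows.

The method in brief:

1. **Paired alignment.** Ortholog alignments of the two proteins are
   filtered to a 70–90% identity band against a reference, reduced to
   one isoform per species, and concatenated species-by-species into a
   cMSA.
2. **Coupling inference.** A Potts model
   P(x) ∝ exp(Σᵢ hᵢ(xᵢ) + Σᵢ<ⱼ Jᵢⱼ(xᵢ,xⱼ)) is fitted by regularized
   pseudo-likelihood maximization (plmDCA) with sequence reweighting;
   pairs are scored by the Frobenius norm of the zero-sum-gauge
   coupling blocks with average-product correction. The inter-protein
   block P_ij of this score matrix is the evolutionary interaction
   signal.
3. **Structure-prior convolution.** Because real interfaces are
   contiguous peptides, the scores are pooled with a Gaussian kernel,

       Q_ij = Σ_{α=i−l}^{i+l} Σ_{β=j−l}^{j+l} P_{αβ} exp(−(a(α−i)² + b(β−j)²)),

   optionally masked by protein topology (transmembrane segments are
   excluded by default). Defaults a = b = 0.001, l = 21. Top-scoring
   regions of Q become labeled hot-spot rectangles ("C-Ter/N-Ter", …).
4. **Characterization & validation.** Sliding-window physicochemical
   profiles contrast predicted interfaces against the rest of the
   sequence (permutation test); trajectory analysis computes Kabsch
   RMSD, radius of gyration, residue contact maps (≥ 2 heavy-atom pairs
   < 5 Å), native-contact fractions, and screened Debye–Hückel
   energies with K_elec = 332.24 kcal·mol⁻¹·e⁻²·Å.

A synthetic-data module generates paired alignments from Potts models
with *planted* inter-protein couplings, so the whole pipeline is
testable against known ground truth without any external database.
See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

`examples/01_interface_prediction.py` plants a 7-residue interacting
peptide pair between two 30-residue synthetic proteins, samples 2000
paired sequences, and runs the full prediction:

```text
$ python examples/01_interface_prediction.py
sampled paired alignment: 2000 rows x (30+30) columns
effective sequences after reweighting: 2000
planted region:   A 11-17 x B 13-19
top-1 hot-spot:   A 11-17 x B 12-20 (peak 33.84, mean 24.49)
area Jaccard overlap with truth: 0.78
```

The top-1 rectangle recovers the planted peptides almost exactly: the
A-axis span matches residue-for-residue and the B-axis span is one
residue wider on each side (the kernel smooths the boundary), giving an
area Jaccard overlap of 0.78 against a chance level near the planted
area fraction (~0.05). `peak`/`mean` are relative convolved scores —
Q is a ranking, not a calibrated probability.

The other examples are equally short: `02_topology_priors.py` (packaged
GPCR topology tables, prior masks, domain labeling),
`03_property_profiles.py` (physicochemical contrasts with permutation
p-values), `04_trajectory_analysis.py` (RMSD/Rg/contacts/Debye–Hückel
on a toy trajectory).

File-based workflows mirror the same steps:

```bash
spdca simulate --la 30 --lb 30 --q 8 --pairs 5 --m 2000 --seed 7 -o sim/
spdca map sim/sim.fasta --a 0.05 --b 0.05 --l 5 -o sim/qmap.csv
spdca hotspots sim/qmap.csv -o sim/hotspots.tsv
spdca run config.cfg            # full pipeline from a key=value file
```

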