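# Methods

## The prediction problem

An intact N-glycopeptide fragmented by HCD with stepped collision energy
produces three families of fragment ions: peptide backbone b/y ions (with
glycan-bearing variants carrying one HexNAc or a cross-ring remnant of the
reducing-end HexNAc), glycan Y ions (the peptide retaining a root-containing
part of the glycan, down to the naked peptide Y0), and glycan B (oxonium)
ions from the antennae.  `glycospec` predicts the relative intensities of all
of these for a precursor defined by (peptide sequence, modifications,
glycosite, glycan topology, charge), together with the fraction *r* of total
fragment intensity carried by the peptide part.

Glycans are unordered rooted trees over five monosaccharide classes (Hex,
HexNAc, NeuAc, NeuGc, Fuc); linkage and anomericity are outside the model's
resolution and are not represented.  Branch order carries no information:
every component of the package (canonical serialization, child-sum tree
cells, canonical cleavage ordering) is constructed to be invariant under
branch permutation, which the test suite asserts to 1e-6 on the full
forward pass.

## Model

* **Peptide encoder.**  Each residue is a 20-dim one-hot vector concatenated
  with a 6-dim elemental-composition vector (H, C, N, O, S, P) of its
  modification (zeros when unmodified), fed to two stacked bidirectional
  LSTM layers (hidden size *h*, default 256) with dropout 0.25.
* **Glycan encoder.**  Monosaccharides are 5-dim one-hots on tree nodes; a
  child-sum tree LSTM (hidden *h*) traverses bottom-up, summing child hidden
  states so sibling order is immaterial.
* **Fusion.**  The glycan root state maps through a dense layer into the
  peptide feature at the glycosite; the peptide final state maps into the
  root node feature; a learned 2-dim embedding of the precursor charge
  (supported charges 1–6) is concatenated on both sides.
* **Peptide head.**  Two further BiLSTM layers; for each backbone cleavage
  the features of the two flanking positions pass a dense layer + ReLU,
  yielding 4 intensities (b/y at 1+/2+).  The glycan-bearing b/y variants
  share their naked channel: their matched intensities are summed into one
  training target per (cleavage, series, charge).
* **Glycan head.**  A second, top-down tree LSTM gives every node a view of
  residues above, below and in sibling branches.  For each glycosidic
  cleavage, attention-weighted sums of the lost-node and retained-node
  features are concatenated into a 2*h* vector (512 at default size).  Each
  structure-specific fragment aggregates its boundary cleavages with an
  LSTM (cleavages shuffled during training; canonically ordered by (edge
  depth, canonical lost-subtree string) at evaluation) followed by softmax
  attention; a dense + ReLU head emits Y intensities at 1+–3+ (and a 1-dim
  B head at 1+ when enabled).  Composition-level intensities are the sums
  over isomeric structure fragments — the conservation law the fragmentation
  graph makes explicit and the tests assert.
* **Ratio head.**  Attention-pooled peptide and glycan features pass a dense
  layer + sigmoid to give *r* ∈ (0, 1); the assembled spectrum scales the
  peptide part to *r* and the glycan part (Y + B) to 1 − *r*.

At the default sizes the model holds ~7.2 M parameters (~5.3 M peptide-side,
~1.9 M glycan-side).

The network runs on a small tape-based reverse-mode autodiff engine written
for this package (numpy, float64).  Whole LSTM layer passes and tree
traversals are single fused tape ops with hand-derived backward passes,
verified against numeric gradients in the test suite.

## Training

The loss is a weighted sum of spectral-angle losses — SA(s₁, s₂) =
(2/π)·arccos(s₁·s₂ / |s₁||s₂|) — over the whole spectrum, the peptide part
and the glycan Y part, plus the squared error of *r* (and the SA of the B
part for the B model).  A part with no matched experimental ions contributes
no term for that spectrum.  Weights follow dynamic weight average: per-task
ratios of the previous two epochs' mean losses pass a softmax (temperature
2, the convention of the originating multi-task method) scaled by the task
count; the first two epochs use uniform weights.

Optimization is Adam, batch size 16, learning rate warmed up linearly from 0
to 1e-3 over 5 epochs then cosine-annealed with warm restarts (first
interval 15 epochs, doubling after each restart, floor 0).  Finetuning uses
lr 1e-3 without warmup and multiplies it by 0.1 whenever validation total
loss fails to improve by 1e-4 for 5 consecutive epochs.  The B model trains
on top of a fitted base model with everything except the B head frozen
(asserted bit-wise) at lr 1e-4 under the same warmup/restart schedule.
Datasets split 3/5 / 1/5 / 1/5 (train/validation/holdout) at precursor
level; the best checkpoint is chosen by validation total loss with uniform
weights (the selection statistic was an open choice; uniform weighting keeps
it comparable across epochs as DWA weights move).

Numerical choices: gradients are clipped to global norm 5 per batch; the
cosine of the SA loss is clipped to ±(1 − 1e-7) so the gradient stays finite
at perfect similarity; an all-zero predicted part is floored at norm 1e-9
inside the loss; dropout acts only in training mode; non-finite losses abort
with a diagnostic rather than continuing.

## The synthetic-data generator

The simulator provides ground truth where none is measurable: random
tryptic-like peptides (length 7–12, C-terminal K/R, an N-X-S/T sequon at the
glycosite) and N-glycans grown on the canonical HexNAc₂Hex₃ core (5–9
residues; class mix 30% high-mannose / 50% complex / 20% hybrid; core
fucose 30%, bisecting HexNAc 20%, antennary fucose on 15% of antennae),
precursor charges 2–4.  Y-ion truth follows a cleavage-propensity rule:
each structure fragment receives exp(−Σ λ) over its boundary cleavages with
λ_core = 1.2 and λ_branch = 0.4, encoding that the core survives collisions
branches do not.  B fragments decay exponentially in size with a 4× oxonium
boost for mono/disaccharides.  Peptide b/y ions follow a smooth positional
profile (Gaussian bumps centred at 0.35/0.55 of the sequence, width 0.25)
with residue factors (×2 for cleavage N-terminal to proline, ×0.5
C-terminal to it, ×0.8 after glycine).  Parts mix with
r ~ Beta(mean 0.25, concentration 10) — glycan fragments usually dominate —
and the observed copy applies multiplicative log-normal noise (CV 10%) and
5% random ion dropout.  Spectra failing the matched-ion filters (≥5 b/y,
≥5 Y, and ≥2 B when B ions are modelled) are regenerated.

What the simulator does not emulate: m/z-dependent noise, interfering
co-isolated precursors, isotope envelopes, unannotated peaks (real spectra
carry 66–74% unannotated intensity), collision-energy dependence, and any
chemistry linking peptide sequence to glycan fragmentation.  Passing the
recovery and ranking suites therefore demonstrates that the architecture
can learn and invert a structure-determined fragmentation rule at desk
scale — not that this reimplementation reaches instrument-grade accuracy on
real data, which would require the public training corpora and full-scale
training.

## Desk-scale problem sizes

The package's own validation runs at sizes a laptop CPU handles comfortably:
the recovery check trains a reduced model (hidden 32, dropout 0 — at this
capacity on 300 spectra the check targets the ability to recover the rule,
not regularized generalization; the 256/0.25 defaults remain for real use)
for 60 epochs on 300 simulated spectra and requires median SA_total ≤ 0.25
against the noiseless truth of 60 held-out spectra, majority over 3 seeds
(evaluation stops once the majority is decided).  The ranking
self-consistency check ranks 200 model-generated queries (10% multiplicative
noise) within a 400-structure synthetic glycan space and requires the true
topology first in ≥80% and in the top three in ≥95% of isomer-rich cases.
Library checks run on a 100-entry predicted library.

## Design choices on open points

* **Cross-ring remnant mass** 83.03711 Da (C4H5NO retained on the peptide),
  the prevailing 0,2-ring-cleavage convention for GlcNAc in glycoproteomics
  search engines.
* **B-fragment scope**: complete subtrees rooted at branch nodes, each also
  prepended with the adjacent arm mannose; a fragment's cleavage set is its
  full retained/lost boundary.  Oligomannose branches yield no B ions, so
  high-mannose glycans have none.  The bisecting HexNAc sits on the central
  core mannose and is not treated as a branch.
* **Intact glycan** is not a Y ion (a fragment requires ≥1 cleavage); Y0
  arises from the peptide-glycan attachment cleavage.
* **Peak matching** defaults to 20 ppm (configurable); each theoretical
  fragment takes its closest in-tolerance peak and each peak feeds at most
  one fragment, globally closest-first.
* **Consensus spectra**: replicates are normalized to unit total per part
  and averaged — order- and scale-invariant; the peptide fraction is carried
  as the mean of replicate ratios.  MSE of the ratio is averaged per batch.
* **Ranking**: the score is α(1 − SA_Y) + β(1 − SA_B) with α = β = 0.5; when
  no B term exists the Y term is renormalized by α.  The peptide-part SA is
  computed and reported but never scored.  Ties break on the canonical
  glycan string.  Query peaks matching no candidate's theoretical fragments
  never enter an aligned vector, so the discard rule is score-neutral by
  construction (asserted in tests).
* **Retention-time proxy** for libraries without supplied RT: a
  hydrophobicity-sum (Kyte–Doolittle) linear proxy, tagged as synthetic; a
  trained RT model is out of scope.
* **Entrapment entries** swap library glycans for structures whose
  composition is absent from the library, keeping counts within 10% of the
  library size.

## Known limitations

Single glycosite per peptide; no ETD (c/z) or a/x ions, neutral losses or
isotope envelopes; topology-only glycans (no linkage isomers); no
instrument/CE metadata encoders; the numpy engine trains desk-scale models
only — the default 7 M-parameter configuration is exercised for shape and
invariant checks, not full training.
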