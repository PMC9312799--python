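# Methods

## Problem and model

`solbinder` designs short peptide binders for protein–protein interaction
(PPI) interfaces while controlling aqueous solubility. PPI interfaces are
flat, wide, and hydrophobic, so sequence optimization driven purely by a
structure-prediction confidence oracle enriches tryptophan, tyrosine,
phenylalanine and leucine and yields poorly soluble peptides. The package
counteracts this by adding a weighted, differentiable solubility loss to
the oracle losses and optimizing both simultaneously rather than filtering
after the fact.

The binder is a soft sequence: logits $Z \in \mathbb{R}^{N\times 20}$ over
the canonical alphabet (fixed alphabetical column order ACDEFGHIKLMNPQRSTVWY
everywhere — logits, profiles, PFMs — to exclude silent permutation bugs).
The solubility loss is the arithmetic mean of normalized per-residue index
values; on probability rows it is the per-position expectation, which is
linear in the probabilities, bounded in [0, 1], and coincides exactly with
the discrete lookup mean at one-hot. A geometric-mean variant
(`solubility_loss(..., mean="geometric")`, geometric mean of the
per-position expectations with a 1e-12 floor) is provided for sensitivity
analysis only; the arithmetic form is canonical and is the only form used
in the shipped tests.

## Index tables

Three scales are bundled as two-column TSVs with their provenance in the
file headers:

- **Hydrophobicity** (Argos et al. 1982, membrane-burial scale) and
  **hydropathy** (Kyte & Doolittle 1982): high raw value = hydrophobic;
  used as-is after min-max normalization to [0, 1].
- **SWI** (Solubility-Weighted Index, Bhandari et al. 2020): high raw value
  *favours* solubility, so the normalized values are inverted (1 − x),
  which exactly reverses the rank order.

After orientation the zero-loss residues are Q (hydrophobicity),
R (hydropathy) and E (SWI). SWI values are stored rounded to four decimals;
ranks and relative spacing are unaffected. Non-canonical residue codes
(X, B, Z, U) are rejected everywhere with an error naming the position,
never silently scored. Note one factual quirk of the Kyte–Doolittle scale:
W (−0.9) and Y (−1.3) fall slightly *below* the 20-residue median, so on
the hydropathy index the aromatic residues W and Y are not
above-median-insoluble, although the class {W, Y, F, L} as a whole scores
far worse than the hydrophilic class {R, K, D, E, N, Q} on all three
indices.

## Optimization

Three stages, default 100/100/10 iterations:

1. **soft** — rows decoded by softmax at temperature 1.0;
2. **temp** — temperature annealed linearly from 1.0 to 0.01, sharpening
   the distributions toward one-hot;
3. **hard** — forward pass uses the exact argmax one-hot (alphabetically
   first residue on ties); gradients are straight-through, differentiating
   the softmax at unit backward temperature so they remain informative
   after the anneal has saturated the forward distributions.

The optimizer is plain gradient descent on the logits with per-iteration
global L2 gradient normalization and a fixed step size of 0.1. All losses
used here are linear in the probabilities, so gradients are chained
analytically through the softmax Jacobian; correctness is checked against
central finite differences (1e-5 relative tolerance) in the tests. Logits
initialize from a seeded Gaussian with standard deviation 0.01 — close
enough to uniform to act as a random starting sequence, small enough that
the loss signal rather than initialization noise resolves near-ties between
similar residues (e.g. Q vs S/T on the hydrophobicity scale) before the
anneal freezes the decision. The best sequence of a run is the hard-stage
record of minimal total loss, earliest iteration on ties. A non-finite
oracle loss aborts the run with a diagnostic naming the iteration.

Temperature endpoints, the anneal shape, the learning rate, and the init
distribution are package design choices; the stage structure, iteration
counts, weight sweep values, and best-sequence rule follow the standard
binder-hallucination protocol.

## Surrogate oracle

The oracle contract is a callable `SoftSequence -> OracleOutput` whose named
losses are ≥ 0, finite, and differentiable with respect to the probability
matrix; a structure-predictor-backed adapter can implement it externally.
The bundled surrogate scores against a fixed interface profile
(N × 20 favourabilities in [0, 1], every row attaining 1): its `interface`
loss is one minus the mean expected favourability, and a constant-zero
`confidence` loss exercises multi-component weighting. The default profile
gives preference 1.0 to W/Y/F/L everywhere, 0.1 to hydrophilic residues and
0.3 to the rest in the core (positions 4–11, where unconstrained
hallucinated binders concentrate aromatics), and a flat 0.8 elsewhere on
the flanks. Because W/Y/F/L score much worse than R/K/D/E/N/Q on all three
solubility indices, the surrogate and solubility losses are in deliberate
tension and the weight sweep produces a genuine trade-off.

What the surrogate emulates is the *direction* of the real system's
behaviour — hydrophobic/aromatic enrichment at weight 0, increasing
hydrophilic content and decreasing solubility loss as the weight rises.
What it does not emulate: structure, epistasis between positions (its loss
is position-separable, so designs converge to per-position optima and, with
symmetric profiles, to near-homopolymers), binding free energies, or any
correlation between its score and real docking affinity. Passing tests
therefore validate the engine, losses, gradients, and harness — not
binding predictions for real proteins.

## Evaluation harness

- `score_sequence` is the discrete solubility loss (identical to the engine
  at one-hot; cross-checked to 1e-12).
- Baselines: seeded uniform random sequences, and the full single-
  substitution enumeration (19 × N variants; for the 13-residue p53 peptide
  ETFSDLWKLLPEN, 247). Full enumeration is the deterministic superset of a
  sampled substitution baseline.
- Dual-threshold filter: pass iff solubility score **strictly** above the
  solubility threshold and affinity **strictly** below the affinity
  threshold (binding free energy convention: more negative = stronger).
  Defaults are the PDIQ+'N' reference values, logS 0.4420 and affinity
  −22.5. External logS/docking scores are ingested from CSV; the internal
  index mean is the fallback solubility score, and affinity filtering is
  unavailable without external scores.
- Position frequency matrices: counts and frequencies per position,
  exported as CSV for standard logo-drawing tools.

## Problem sizes and determinism

The shipped tests and the acceptance script use binder length 13, the full
100/100/10 schedule, 20-seed sweeps for trade-off statistics, a
1000-record filter fixture, and 100 random sequences for the one-hot
equivalence check — sizes at which every property being asserted is already
stable, while a full run of the suite completes in seconds. All randomness
flows through seeded `numpy` generators and the numerics are
single-threaded, so identical configurations reproduce byte-identical
artifacts; the run manifest (config, package version, seeds) suffices to
reproduce any design run.

## Known limitations

- The surrogate oracle is a stand-in; no claim is made that its losses
  approximate structure-prediction confidences or binding energies.
- Solubility indices are per-residue and additive; conformer- or
  context-dependent solubility (and logS itself) is out of scope and must
  be supplied externally.
- The solubility loss applies only to the designed binder positions; the
  target protein never enters the solubility term.
- The geometric-mean loss variant is undefined at exact zeros and is
  floored at 1e-12; it is excluded from the canonical protocol.
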