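# Methods

## Model overview

`maskless` models light-directed (photolithographic) DNA library synthesis
as a per-molecule stochastic process driven by three physical inputs: a
photomask schedule, a dose model, and base-wise coupling chemistry.

Synthesis proceeds 3'→5' with phosphoramidites flowed in the fixed order
A→C→G→T. The mask stack is derived deterministically from the panel: a
feature is ON in cycle c exactly when its next unsynthesized base equals
the cycle base, so decoding a feature's ON cycles reconstructs its
sequence (this duality is property-tested). A 67-mer needs ~190 cycles;
each base waits 1–4 cycles for its slot depending on the previous base
(the *wait number*).

Per cycle, each molecule passes four stochastic steps; every other part of
the cycle (oxidation, washes) is treated as ideal:

1. **Exposure.** A protected terminus becomes reactive with probability
   `1 − exp(−k·E)`. ON features receive the nominal dose scaled by the
   feature's illumination factor; OFF features receive the stray dose (see
   below). A failed ON deprotection leaves the terminus protected — the
   scheduled base is skipped when a later exposure succeeds: a deletion.
2. **Coupling.** Chemistry is global (reagents flow over the whole cell):
   any reactive terminus couples the cycle base with the base-specific
   efficiency, mask state notwithstanding. Stray-deprotected OFF features
   therefore gain insertions; a terminus left reactive by a failed coupling
   is rescued by the next flowed base — a cycle-order substitution.
3. **Capping** (optional). A still-reactive terminus is permanently capped
   with the capping efficiency, truncating the molecule.
4. **Blocking.** A small per-cycle probability of irreversible chain loss,
   standing in for chemical degradation and dead mirrors. Capped and
   blocked states are absorbing.

Reads are the synthesized strings reversed to 5'→3', optionally passed
through a uniform per-base substitution floor representing sequencing
noise. One master seed drives per-feature child RNG streams
(`SeedSequence([seed, feature_index])`), so results are independent of
iteration order and reproducible byte-for-byte.

## Dose model

* Photolysis rate constant: `k = −ln(1 − yield)/E`, default calibrated to
  95% yield at 3 J/cm² (k ≈ 0.9986 per J/cm²). The same closed form
  predicts 99.75% at 6 J/cm²; yields are invariant to splitting an
  exposure into sub-exposures (exponential additivity, property-tested).
* Stray dose for an OFF feature during one exposure, as a fraction of the
  nominal dose:
  `g·f_ON + side_leak·(#ON side neighbors)/4 + corner_leak·(#ON corner
  neighbors)/4 + reflection`, with `f_ON` the ON-mirror fraction of the
  current mask. Defaults: side_leak 0.5% and corner_leak 0.05% of a full
  exposure per fully-exposed neighbor (edge diffraction scale);
  `g ≈ 0.0026` from the provided calibration routine, which inverts a
  first-order insertion budget (insertions/bp ≈ p_stray·(C − L)/L for L-mers
  over C cycles) targeting 0.6%/bp at the 4×4-feature (44%-active) design
  density. The budget treats the layout's active fraction as the
  per-exposure ON fraction; in a real stack only ~¼ of active mirrors are
  ON per cycle, so the global channel alone contributes ~0.15%/bp and the
  neighbor-leak channels the remainder — the default configuration measures
  ~0.6–0.7%/bp total, and insertion pressure scales linearly with active
  density (the 44%→11% contrast reproduces the expected ~4× reduction).
* Illumination profile: `1 − a·r^b` with `r` the per-axis-normalized
  Euclidean center distance divided by √2, so the corners (r = 1) are
  dimmer than edge midpoints (r ≈ 0.71). Defaults a = 0.1, b = 4: a flat
  plateau with degradation confined near the border. The *concentric area
  index* (1 = center … 4 = outer ring) instead uses the Chebyshev distance,
  so area 4 is the full border ring including all corners.
* Reflection: an optional uniform extra dose over a mirror-coordinate
  rectangle (an uncovered corner of the UV-absorber back chamber),
  optionally active only after a configurable cycle fraction (fluid
  evaporation late in synthesis).

## Alignment and event classification

Reads are aligned to their intended reference (truth-table pairing when
available, best-of-panel otherwise) with an affine-gap global aligner
(match +1, mismatch −2, gap open −4, gap extend −1), backed by
`Bio.Align.PairwiseAligner`. Two refinements matter:

* **Truncations.** A capped or blocked molecule is missing the reference's
  5' *prefix* (synthesis is 3'→5'). The reference-left end gap pays the
  normal gap-open but extends at −0.01/base, so a long missing prefix costs
  essentially one gap-open; a leading reference gap of ≥3 bases is
  classified as *truncation* and excluded from every rate denominator.
  Shorter leading gaps are counted as ordinary deletions — they are almost
  always genuine photolysis failures. This keeps deletion and insertion
  rates invariant under capping (verified within Monte-Carlo error) while
  recovering a configured 5% photolysis shortfall to within 3 MC σ at the
  standard scale. Leading deletions of a run length ≥3 remain inherently
  ambiguous with truncations; the residual bias is ≪0.01 pct pt.
* **Determinism.** After alignment, indel runs are shifted to their
  leftmost score-equivalent position (homopolymer left-alignment), making
  event positions deterministic and convention-stable.

One known distortion is inherent to the prescribed scores: the DP strictly
prefers merging `del–match–del` (−9) into `del-run + substitution` (−8), so
a deletion-only process at ~5%/bp shows a ~0.3%/bp apparent substitution
rate and an elevated deletion→deletion dinucleotide share. Short-read
heuristic aligners with comparable affine penalties behave the same way;
the per-bp *deletion* rate itself is unaffected. Analyses of the
substitution channel (coupling-efficiency recovery) are therefore run in
regimes without deletions, where the distortion vanishes.

A read is *readable* when alignment identity (matches/covered positions)
reaches `min_identity` (default 50%); unreadable reads are excluded from
rate denominators and counted separately.

## Estimators and statistics

* All rates are % per bp with covered (non-truncated) reference bases of
  readable alignments as the common denominator, so
  total = deletion + insertion + substitution exactly.
* **Deletion run lengths** are reported both as bases-in-runs (classes sum
  to the overall deletion rate) and as runs per bp. The independence
  prediction for an L-run is simply `p^L` (4%/bp → 0.16% doubles, 0.0064%
  triples).
* **Coupling efficiencies.** A failed coupling of base B is rescued by
  next(B) in cycle order; the rescue is *observed* as a B→next(B)
  substitution only when the reference base 5' of B differs from next(B) —
  otherwise it realigns as a deletion of B (the G-before-T case). The
  corrected estimator divides the observed B→next(B) rate (over covered B
  positions with a 5' neighbor) by q_B = P(5'-neighbor ≠ next(B)), computed
  from the panel itself. At the standard recovery scale it returns
  99.70 ± 0.02 for a true e_G = 99.7% and ≥99.9 for A/C/T at 99.95%. The
  estimator is invalid on capped data (the substitution channel is
  suppressed) and then returns naive estimates only, with a warning.
* **Wait histogram.** Each insertion record (multi-base insertions count
  once) is binned by the wait number of its reference flanks; records at
  sequence ends or against truncated flanks are excluded. Wait-1 counts are
  near zero by construction — no exposure event separates two
  consecutive-cycle couplings — so the histogram rises strictly with wait.
* **Per-cycle rates** map each reference position to the cycle in which it
  couples; an insertion is attributed to the cycle of its 5' flank (the
  coupling that closed the exposure window it occurred in — the true cycle
  inside the window is unrecoverable post hoc).
* **Spatial statistics** aggregate raw event counts per feature, so any
  regrouping (areas, whole array) reproduces the pooled rates exactly;
  area summaries are weighted by covered bases for the same reason. The
  area-contrast permutation test shuffles area labels across features and
  compares base-weighted mean rates. Unreadable-cluster detection labels
  8-connected components of low-coverage features on the feature grid and
  reports bounding boxes.

## Panel design

Sequences are sampled base-by-base under the homopolymer cap (default: no
run >3 in the variable region; fixed poly-dC/poly-dA handles are excluded
from both the cap and coverage credit), then deficient k-mers are greedily
spliced into oligos that lack them, with a bounded repair budget. Coverage
is required for every *admissible* k-mer — one whose own longest run fits
the cap; k-mers needing longer runs cannot occur in any cap-compliant
sequence, so demanding them would make the joint constraints infeasible.
At the flagship scale (20 000 × 67-mers, k = 7, ≥7 oligos per 7-mer) the
sampled panel covers every admissible 7-mer with large margin.

## Problem sizes and defaults

Parameter-recovery runs use 200 features × 500 molecules of 67-mers
(~6.7M reference bases, ~1.6M G coupling opportunities), which puts the
Monte-Carlo σ of the deletion rate near 0.008 pct pt and of the recovered
G efficiency near 0.005 pct pt. Directional contrasts (capping on/off,
edge fall-off vs flat, density scaling, reflection A/B) use 100–225
features × 40–200 molecules. Chemistry defaults: e_A/C/T = 99.95%,
e_G = 99.7%, capping efficiency 99.9% (off by default), sequencing noise
floor 0.05%/base, block rate 0.

## What the generator does and does not emulate

It emulates the error structure the coupling-cycle mechanism implies:
photolysis-limited deletions, wait-number-dependent insertions,
cycle-order substitutions, capping-induced truncation, spatially varying
illumination, density-proportional global scatter, and excess multi-base
deletion runs via blocking. It does not emulate PCR/adapter-ligation bias,
quality-score structure, chimeric reads, the diffraction physics behind
the leakage constants (they enter as parameters), depurination or other
sequence-dependent side chemistry, or the alignment periodicity artifacts
reported for real pipelines. Passing recovery tests therefore validates
the analysis chain against the model's own mechanisms, not against every
property of wet-lab data.

## Known limitations

* Stray dose is accounted at feature granularity; mirror-level dose maps
  within a feature are not modelled.
* The truncation/deletion boundary at the read's 5' start is ambiguous for
  leading runs ≥3; rates carry a sub-0.01 pct pt bias from this choice.
* The corrected coupling-efficiency estimator assumes at most one rescue
  per failure (second-order failures are neglected) and degrades when the
  deletion channel is strong (phantom-substitution contamination).
* Blocked/capped tails are excluded as truncations, so absorbing-state
  degradation manifests in coverage and read length rather than in
  deletion-run statistics (only 1–2 base leading gaps appear there).
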