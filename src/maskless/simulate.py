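"""Monte-Carlo simulation of the photolithographic coupling cycle.

Each molecule on each feature is followed through every synthesis cycle of
the mask stack (exposure -> coupling -> optional capping -> blocking):

1. *Exposure*: if the molecule's feature is ON, a protected terminus becomes
   reactive (free 5'-OH) with the photolysis yield of the nominal dose scaled
   by the feature's illumination factor; if OFF, with the (much smaller)
   yield of the stray dose.  Failed deprotection on an ON cycle leaves the
   terminus protected -- the scheduled base is skipped when a later exposure
   succeeds, producing a *deletion*.
2. *Coupling*: phosphoramidite chemistry is global, so any reactive terminus
   couples the cycle's base with the base-specific efficiency, regardless of
   the mask.  A stray-deprotected OFF feature therefore gains an *insertion*;
   a terminus left reactive by a failed coupling is rescued by the next flowed
   base, a cycle-order *substitution* (G->T being the canonical case).
3. *Capping* (optional): a still-reactive terminus is permanently capped with
   the capping efficiency, truncating the molecule instead of letting it
   substitute.
4. *Blocking*: with a small per-cycle probability the chain is irreversibly
   blocked (chemical degradation / dead mirrors), the stand-in mechanism for
   excess multi-base deletion runs.

Reads are the synthesized 3'->5' base strings reversed to 5'->3', optionally
passed through a uniform substitution noise floor standing in for sequencing
error.  One master seed drives per-feature child RNG streams, so results do
not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import COUPLING_ORDER, ArrayLayout, MaskStack
from .photochem import PhotochemParams, illumination_factor, photolysis_yield

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# terminus states
_PROTECTED, _FREE, _CAPPED, _BLOCKED = 0, 1, 2, 3


@dataclass(frozen=True)
class ChemParams:
    """Stochastic chemistry parameters of one simulated synthesis.

    coupling_efficiency        per-base stepwise coupling probability
                               (G couples less efficiently than A/C/T)
    capping_enabled/efficiency capping after each coupling (truncates
                               rather than substitutes)
    baseline_substitution_rate uniform per-base substitution floor applied to
                               finished reads (sequencing/other noise)
    block_rate                 per-cycle per-molecule irreversible blocking
    molecules_per_feature      molecules simulated per feature
    stage2_*                   optional two-stage synthesis discontinuity: at
                               cycle fraction ``stage2_start_fraction`` the
                               block rate switches to ``stage2_block_rate``
                               and coupling efficiencies are scaled by
                               ``stage2_coupling_scale``
    """

    coupling_efficiency: dict[str, float] = field(
        default_factory=lambda: {"A": 0.9995, "C": 0.9995, "G": 0.997,
                                 "T": 0.9995})
    capping_enabled: bool = False
    capping_efficiency: float = 0.999
    baseline_substitution_rate: float = 0.0005
    block_rate: float = 0.0
    molecules_per_feature: int = 100
    seed: int = 0
    stage2_start_fraction: float | None = None
    stage2_block_rate: float = 0.0
    stage2_coupling_scale: float = 1.0

    def __post_init__(self) -> None:
        probs = list(self.coupling_efficiency.values()) + [
            self.capping_efficiency, self.baseline_substitution_rate,
            self.block_rate, self.stage2_block_rate]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if set(self.coupling_efficiency) != set("ACGT"):
            raise ValueError("coupling_efficiency must cover A, C, G, T")


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    feature_id: str
    reference_id: str


@dataclass
class ReadSet:
    """Simulated reads plus per-read truth (feature and reference)."""

    reads: list[SimRead]
    n_empty: int = 0

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def to_fastq(self, path, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n"
                         f"{quality_char * len(r.sequence)}\n")


def truth_table(readset: ReadSet, layout: ArrayLayout) -> pd.DataFrame:
    """One row per read: read_id, feature_id, reference_id, row, col."""
    rows = []
    for r in readset.reads:
        f = layout.feature(r.feature_id)
        rows.append({"read_id": r.read_id, "feature_id": r.feature_id,
                     "reference_id": r.reference_id,
                     "row": f.top_row, "col": f.left_col})
    return pd.DataFrame(rows, columns=["read_id", "feature_id",
                                       "reference_id", "row", "col"])


def _off_dose_matrix(layout: ArrayLayout, masks: MaskStack,
                     photo: PhotochemParams) -> np.ndarray:
    """Stray dose (J/cm^2) per feature per cycle, vectorized on the cell grid."""
    n_feat = len(layout.features)
    n_cyc = len(masks)
    cells = np.array(layout.cell_coords, dtype=int)
    gr = cells[:, 0].max() + 1
    gc = cells[:, 1].max() + 1
    idx_of = {f.feature_id: i for i, f in enumerate(layout.features)}
    mirrors = np.array([f.n_mirrors for f in layout.features], dtype=float)
    total_mirrors = layout.geometry.n_mirrors

    refl = np.zeros(n_feat)
    if photo.reflection_enabled and photo.reflection_region is not None:
        r0, c0, r1, c1 = photo.reflection_region
        for i, f in enumerate(layout.features):
            fr, fc = f.center
            if r0 <= fr < r1 and c0 <= fc < c1:
                refl[i] = photo.reflection_extra_dose

    dose = np.zeros((n_feat, n_cyc))
    grid = np.zeros((gr + 2, gc + 2), dtype=float)  # padded ON indicator
    for c, (_, _, on) in enumerate(masks.cycles):
        on_vec = np.zeros(n_feat, dtype=bool)
        for fid in on:
            on_vec[idx_of[fid]] = True
        f_on = float(mirrors[on_vec].sum()) / total_mirrors
        grid[:] = 0.0
        grid[cells[:, 0] + 1, cells[:, 1] + 1] = on_vec
        side = (grid[:-2, 1:-1] + grid[2:, 1:-1]
                + grid[1:-1, :-2] + grid[1:-1, 2:])
        corner = (grid[:-2, :-2] + grid[:-2, 2:]
                  + grid[2:, :-2] + grid[2:, 2:])
        n_side = side[cells[:, 0], cells[:, 1]]
        n_corner = corner[cells[:, 0], cells[:, 1]]
        frac = (photo.global_scatter_coeff * f_on
                + photo.side_leak * n_side / 4.0
                + photo.corner_leak * n_corner / 4.0)
        cf = c / max(n_cyc - 1, 1)
        if cf >= photo.reflection_onset_fraction:
            frac = frac + refl
        dose[:, c] = photo.nominal_exposure * frac
        dose[on_vec, c] = 0.0  # ON features get the intended dose instead
    return dose


def simulate_synthesis(
    sequences: dict[str, str],
    layout: ArrayLayout,
    masks: MaskStack,
    photo: PhotochemParams,
    chem: ChemParams,
) -> ReadSet:
    """Run the per-molecule Monte-Carlo over the full mask stack.

    *sequences* maps oligo id -> 5'->3' reference sequence; every layout
    feature must be assigned one.  Deterministic for a fixed ``chem.seed``.
    """
    n_cyc = len(masks)
    if n_cyc == 0:
        raise ValueError("empty mask stack")
    for f in layout.features:
        if f.feature_id not in layout.assignment:
            raise ValueError(f"feature {f.feature_id} has no assigned oligo")
        if layout.assignment[f.feature_id] not in sequences:
            raise ValueError(
                f"oligo {layout.assignment[f.feature_id]} missing from panel")

    cycle_bases = [b for _, b, _ in masks.cycles]
    on_sets = [on for _, _, on in masks.cycles]
    off_dose = _off_dose_matrix(layout, masks, photo)
    k = photo.k_rate
    p_off = 1.0 - np.exp(-k * off_dose)  # (n_feat, n_cyc)

    eff = {b: chem.coupling_efficiency[b] for b in COUPLING_ORDER}
    stage2_at = (int(round(chem.stage2_start_fraction * n_cyc))
                 if chem.stage2_start_fraction is not None else None)

    M = chem.molecules_per_feature
    reads: list[SimRead] = []
    n_empty = 0
    for fi, feat in enumerate(layout.features):
        fid = feat.feature_id
        oid = layout.assignment[fid]
        p_on = photolysis_yield(
            photo.nominal_exposure * illumination_factor(layout, fid, photo),
            k)
        rng = np.random.default_rng(np.random.SeedSequence([chem.seed, fi]))
        terminus = np.zeros(M, dtype=np.uint8)
        synthesized: list[list[str]] = [[] for _ in range(M)]
        for c in range(n_cyc):
            base = cycle_bases[c]
            is_on = fid in on_sets[c]
            p_dep = p_on if is_on else p_off[fi, c]
            in_stage2 = stage2_at is not None and c >= stage2_at
            e = eff[base] * (chem.stage2_coupling_scale if in_stage2 else 1.0)
            block = (chem.stage2_block_rate if in_stage2 else chem.block_rate)

            # exposure
            if p_dep > 0.0:
                protected = terminus == _PROTECTED
                hit = protected & (rng.random(M) < p_dep)
                terminus[hit] = _FREE
            # coupling (global chemistry: mask-independent)
            free = terminus == _FREE
            if free.any():
                coupled = free & (rng.random(M) < e)
                for m in np.nonzero(coupled)[0]:
                    synthesized[m].append(base)
                terminus[coupled] = _PROTECTED
                # capping
                if chem.capping_enabled:
                    still = free & ~coupled
                    capped = still & (rng.random(M) < chem.capping_efficiency)
                    terminus[capped] = _CAPPED
            # blocking
            if block > 0.0:
                active = (terminus == _PROTECTED) | (terminus == _FREE)
                blocked = active & (rng.random(M) < block)
                terminus[blocked] = _BLOCKED

        noise_rng = (np.random.default_rng(
            np.random.SeedSequence([chem.seed, fi, 1]))
            if chem.baseline_substitution_rate > 0 else None)
        for m in range(M):
            if not synthesized[m]:
                n_empty += 1
                continue
            seq = "".join(reversed(synthesized[m]))  # 5'->3'
            if noise_rng is not None:
                seq = _noisy(seq, chem.baseline_substitution_rate, noise_rng)
            reads.append(SimRead(f"{fid}:{m}", seq, fid, oid))
    return ReadSet(reads=reads, n_empty=n_empty)


_BASE_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def _noisy(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        base_idx = _BASE_LUT[arr[idx]]
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode()


def add_sequencing_noise(readset: ReadSet, rate: float,
                         seed: int = 0) -> ReadSet:
    """Substitute each base to a uniformly chosen different base w.p. *rate*."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return ReadSet(reads=list(readset.reads), n_empty=readset.n_empty)
    rng = np.random.default_rng(seed)
    out = [replace(r, sequence=_noisy(r.sequence, rate, rng))
           for r in readset.reads]
    return ReadSet(reads=out, n_empty=readset.n_empty)
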