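"""Alignment of reads to their references and synthesis-error statistics.

Reads are globally aligned to their intended reference with affine gap
penalties (match +1, mismatch -2, gap open -4, gap extend -1 per base).  The
reference-left end gap pays the usual open cost but extends almost freely
(-0.01 per base): synthesis proceeds 3'->5', so a capped or blocked molecule
is missing the *5' prefix* of its reference, and a leading gap of three or
more bases is classified as a *truncation* rather than a deletion run and
excluded from all rate denominators.  Gap placement is
made deterministic by a left-normalization pass (indels are shifted to the
leftmost equivalent position within homopolymers/repeats).

Per-reference-position events are {match, substitution, deletion,
truncation}; insertions live in the slots between positions.  All rates are
reported as % per bp with the covered (non-truncated) reference bases of
readable alignments as denominator.  A read is *readable* when its alignment
identity (matches / covered positions) reaches ``min_identity``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .layout import COUPLING_ORDER

_ORDER_INDEX = {b: i for i, b in enumerate(COUPLING_ORDER)}
#: next base flowed after each base under the A->C->G->T cycle order
NEXT_IN_ORDER = {"A": "C", "C": "G", "G": "T", "T": "A"}

# event codes
MATCH, SUB, DEL, TRUNC = 0, 1, 2, 3

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap global scoring with a cheap-to-extend reference-left gap.

    The left reference gap pays the full gap-open cost (so single missing
    bases near the read start stay classified as deletions) but extends at
    ``trunc_per_base`` only, so the long missing 5' prefix of a truncated
    molecule costs essentially one gap-open however long it is.  A leading
    reference gap shorter than ``trunc_min_len`` is still recorded as a
    deletion run; longer ones are truncations.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    trunc_per_base: float = -0.01
    trunc_min_len: int = 3
    min_identity: float = 0.5

    def make_aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # biopython scores the first gap base with open_gap_score; the
        # conventional open+extend for a length-1 gap is open + extend.
        a.open_gap_score = self.gap_open + self.gap_extend
        a.extend_gap_score = self.gap_extend
        a.open_left_deletion_score = self.gap_open + self.gap_extend
        a.extend_left_deletion_score = self.trunc_per_base
        return a


@dataclass
class AlignmentEvents:
    """Classified alignment of one read against one reference."""

    ref_id: str
    read_id: str
    codes: np.ndarray              # (L,) uint8 event per reference position
    obs: np.ndarray                # (L,) uint8 ascii observed base (0 if none)
    insertions: list[tuple[int, str]]  # (slot, bases): inserted before ref[slot]
    score: float

    @property
    def covered(self) -> int:
        return int((self.codes != TRUNC).sum())

    @property
    def matches(self) -> int:
        return int((self.codes == MATCH).sum())

    @property
    def identity(self) -> float:
        c = self.covered
        return self.matches / c if c else 0.0

    @property
    def trunc_len(self) -> int:
        return int((self.codes == TRUNC).sum())


def _columns_from_coordinates(coords: np.ndarray) -> list[tuple[int, int]]:
    """Alignment columns as (ref index or -1, read index or -1)."""
    cols: list[tuple[int, int]] = []
    for s in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, s]), int(coords[0, s + 1])
        q0, q1 = int(coords[1, s]), int(coords[1, s + 1])
        if t1 > t0 and q1 > q0:           # aligned block
            for d in range(t1 - t0):
                cols.append((t0 + d, q0 + d))
        elif t1 > t0:                      # reference only: deletion
            for d in range(t1 - t0):
                cols.append((t0 + d, -1))
        else:                              # read only: insertion
            for d in range(q1 - q0):
                cols.append((-1, q0 + d))
    return cols


def _left_normalize(cols: list[tuple[int, int]], ref: str, read: str) -> None:
    """Shift indel runs to their leftmost equivalent (homopolymer) position."""
    changed = True
    while changed:
        changed = False
        i = 0
        n = len(cols)
        while i < n:
            t, q = cols[i]
            if t >= 0 and q >= 0:
                i += 1
                continue
            j = i
            is_del = q < 0
            while j < n and ((cols[j][1] < 0) if is_del else (cols[j][0] < 0)):
                j += 1
            # run is cols[i:j]; try shifting left through a match column
            while i > 0:
                pt, pq = cols[i - 1]
                if pt < 0 or pq < 0 or ref[pt] != read[pq]:
                    break
                if is_del:
                    ok = ref[pt] == ref[cols[j - 1][0]]
                else:
                    ok = read[pq] == read[cols[j - 1][1]]
                if not ok:
                    break
                # rotate: previous aligned column moves to the run's end
                if is_del:
                    new_run = [(cols[i - 1][0], -1)] + \
                              [(cols[k][0], -1) for k in range(i, j - 1)]
                    cols[i - 1:j] = new_run + [(cols[j - 1][0], pq)]
                else:
                    new_run = [(-1, cols[i - 1][1])] + \
                              [(-1, cols[k][1]) for k in range(i, j - 1)]
                    cols[i - 1:j] = new_run + [(pt, cols[j - 1][1])]
                i -= 1
                j -= 1
                changed = True
            i = j


def _events_from_columns(cols: list[tuple[int, int]], ref: str, read: str,
                         ref_id: str, read_id: str, score: float,
                         trunc_min_len: int) -> AlignmentEvents:
    L = len(ref)
    codes = np.full(L, DEL, dtype=np.uint8)
    obs = np.zeros(L, dtype=np.uint8)
    insertions: list[tuple[int, str]] = []
    pending_ins: list[str] = []
    next_ref = 0
    leading_gap = 0
    first_read_seen = False
    for t, q in cols:
        if t >= 0 and q >= 0:
            first_read_seen = True
            if pending_ins:
                insertions.append((t, "".join(pending_ins)))
                pending_ins = []
            if ref[t] == read[q]:
                codes[t] = MATCH
            else:
                codes[t] = SUB
            obs[t] = ord(read[q])
            next_ref = t + 1
        elif q >= 0:  # insertion
            first_read_seen = True
            pending_ins.append(read[q])
        else:  # deletion of ref[t]
            if not first_read_seen:
                leading_gap += 1
            codes[t] = DEL
            next_ref = t + 1
    if pending_ins:
        insertions.append((next_ref, "".join(pending_ins)))
    if leading_gap >= trunc_min_len:
        codes[:leading_gap] = TRUNC
    return AlignmentEvents(ref_id=ref_id, read_id=read_id, codes=codes,
                           obs=obs, insertions=insertions, score=score)


_ALIGNER_CACHE: dict[AlignScoring, Align.PairwiseAligner] = {}


def align_read(read: str, reference: str,
               scoring: AlignScoring | None = None,
               ref_id: str = "ref", read_id: str = "read") -> AlignmentEvents:
    """Optimal global alignment of *read* against *reference*, classified.

    Degenerate (empty) reads yield all-deletion events.
    """
    scoring = scoring or AlignScoring()
    if not reference:
        raise ValueError("empty reference")
    if not read:
        return AlignmentEvents(
            ref_id=ref_id, read_id=read_id,
            codes=np.full(len(reference), DEL, dtype=np.uint8),
            obs=np.zeros(len(reference), dtype=np.uint8),
            insertions=[], score=0.0)
    aligner = _ALIGNER_CACHE.get(scoring)
    if aligner is None:
        aligner = scoring.make_aligner()
        _ALIGNER_CACHE[scoring] = aligner
    aln = aligner.align(reference, read)[0]
    cols = _columns_from_coordinates(np.asarray(aln.coordinates))
    _left_normalize(cols, reference, read)
    return _events_from_columns(cols, reference, read, ref_id, read_id,
                                float(aln.score), scoring.trunc_min_len)


def classify_events(aln: AlignmentEvents, reference: str) -> pd.DataFrame:
    """Flat event table for one alignment (position, event, expected, observed).

    Insertions are rows with event='insertion', position = the slot index,
    and flanking reference bases recorded for wait-number analysis.
    """
    rows = []
    names = {MATCH: "match", SUB: "substitution", DEL: "deletion",
             TRUNC: "truncation"}
    for i, code in enumerate(aln.codes):
        rows.append({"position": i, "event": names[int(code)],
                     "expected": reference[i],
                     "observed": chr(aln.obs[i]) if aln.obs[i] else ""})
    L = len(reference)
    for slot, bases in aln.insertions:
        rows.append({"position": slot, "event": "insertion",
                     "expected": "", "observed": bases,
                     "flank_5p": reference[slot - 1] if slot >= 1 else "",
                     "flank_3p": reference[slot] if slot < L else ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Aggregated event matrices
# ---------------------------------------------------------------------------

@dataclass
class EventMatrix:
    """Stacked alignment events for a panel of equal-length references."""

    codes: np.ndarray       # (N, L) uint8
    obs: np.ndarray         # (N, L) uint8 ascii; ref base at matches
    refs: np.ndarray        # (N, L) uint8 ascii reference bases
    ref_ids: list[str]
    read_ids: list[str]
    feature_ids: list[str] | None
    ins_read: np.ndarray    # (n_ins,) row index per insertion record
    ins_slot: np.ndarray    # (n_ins,) slot (insert before ref[slot])
    ins_len: np.ndarray     # (n_ins,) inserted bases in the record
    readable: np.ndarray    # (N,) bool
    identity: np.ndarray    # (N,)
    min_identity: float

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def ref_len(self) -> int:
        return self.codes.shape[1]

    @property
    def n_unreadable(self) -> int:
        return int((~self.readable).sum())

    @classmethod
    def from_alignments(
        cls,
        alignments: Sequence[AlignmentEvents],
        references: Mapping[str, str],
        feature_ids: Sequence[str] | None = None,
        min_identity: float = 0.5,
    ) -> "EventMatrix":
        if not alignments:
            raise ValueError("no alignments")
        lengths = {len(a.codes) for a in alignments}
        if len(lengths) != 1:
            raise ValueError("references must have equal length")
        L = lengths.pop()
        N = len(alignments)
        codes = np.empty((N, L), dtype=np.uint8)
        obs = np.empty((N, L), dtype=np.uint8)
        refs = np.empty((N, L), dtype=np.uint8)
        ins_read, ins_slot, ins_len = [], [], []
        ident = np.empty(N)
        for i, a in enumerate(alignments):
            codes[i] = a.codes
            obs[i] = a.obs
            refs[i] = np.frombuffer(references[a.ref_id].encode(),
                                    dtype=np.uint8)
            for slot, bases in a.insertions:
                ins_read.append(i)
                ins_slot.append(slot)
                ins_len.append(len(bases))
            ident[i] = a.identity
        # observed base at matches is the reference base
        m = codes == MATCH
        obs[m] = refs[m]
        covered = (codes != TRUNC).sum(axis=1)
        readable = (covered > 0) & (ident >= min_identity)
        return cls(codes=codes, obs=obs, refs=refs,
                   ref_ids=[a.ref_id for a in alignments],
                   read_ids=[a.read_id for a in alignments],
                   feature_ids=list(feature_ids) if feature_ids else None,
                   ins_read=np.array(ins_read, dtype=int),
                   ins_slot=np.array(ins_slot, dtype=int),
                   ins_len=np.array(ins_len, dtype=int),
                   readable=readable, identity=ident,
                   min_identity=min_identity)

    def _mask(self, readable_only: bool) -> np.ndarray:
        return self.readable if readable_only else np.ones(self.n_reads, bool)

    def subset(self, row_mask: np.ndarray) -> "EventMatrix":
        idx = np.nonzero(row_mask)[0]
        keep_ins = np.isin(self.ins_read, idx)
        remap = -np.ones(self.n_reads, dtype=int)
        remap[idx] = np.arange(idx.size)
        return EventMatrix(
            codes=self.codes[idx], obs=self.obs[idx], refs=self.refs[idx],
            ref_ids=[self.ref_ids[i] for i in idx],
            read_ids=[self.read_ids[i] for i in idx],
            feature_ids=([self.feature_ids[i] for i in idx]
                         if self.feature_ids else None),
            ins_read=remap[self.ins_read[keep_ins]],
            ins_slot=self.ins_slot[keep_ins],
            ins_len=self.ins_len[keep_ins],
            readable=self.readable[idx], identity=self.identity[idx],
            min_identity=self.min_identity)


def align_readset(readset, references: Mapping[str, str],
                  scoring: AlignScoring | None = None,
                  min_identity: float = 0.5) -> EventMatrix:
    """Align every read of a simulated :class:`~maskless.simulate.ReadSet`
    to its true reference (truth-table pairing)."""
    scoring = scoring or AlignScoring()
    alns, fids = [], []
    for r in readset:
        alns.append(align_read(r.sequence, references[r.reference_id],
                               scoring, ref_id=r.reference_id,
                               read_id=r.read_id))
        fids.append(r.feature_id)
    return EventMatrix.from_alignments(alns, references, feature_ids=fids,
                                       min_identity=min_identity)


def align_reads(reads: Iterable[tuple[str, str]],
                references: Mapping[str, str],
                truth: Mapping[str, str] | None = None,
                scoring: AlignScoring | None = None,
                min_identity: float = 0.5) -> EventMatrix:
    """Align (read_id, sequence) pairs; pair by *truth* (read_id -> ref_id)
    when given, else by the best-scoring reference over the panel."""
    scoring = scoring or AlignScoring()
    alns = []
    for read_id, seq in reads:
        if truth is not None:
            rid = truth[read_id]
            alns.append(align_read(seq, references[rid], scoring,
                                   ref_id=rid, read_id=read_id))
        else:
            best = None
            for rid in references:
                a = align_read(seq, references[rid], scoring,
                               ref_id=rid, read_id=read_id)
                if best is None or a.score > best.score:
                    best = a
            alns.append(best)
    return EventMatrix.from_alignments(alns, references,
                                       min_identity=min_identity)


# ---------------------------------------------------------------------------
# Rates and matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rates:
    """Per-bp error rates in %, sharing the covered-base denominator."""

    deletion: float
    insertion: float
    substitution: float
    n_ref_bases: int
    mean_deletion_len: float = float("nan")
    mean_insertion_len: float = float("nan")

    @property
    def total(self) -> float:
        return self.deletion + self.insertion + self.substitution


def per_bp_rates(em: EventMatrix, readable_only: bool = True) -> Rates:
    mask = em._mask(readable_only)
    codes = em.codes[mask]
    denom = int((codes != TRUNC).sum())
    if denom == 0:
        raise ValueError("zero covered reference bases")
    n_del = int((codes == DEL).sum())
    n_sub = int((codes == SUB).sum())
    idx = np.nonzero(mask)[0]
    keep = np.isin(em.ins_read, idx)
    n_ins = int(em.ins_len[keep].sum())
    del_runs = _deletion_runs(codes)
    return Rates(
        deletion=100.0 * n_del / denom,
        insertion=100.0 * n_ins / denom,
        substitution=100.0 * n_sub / denom,
        n_ref_bases=denom,
        mean_deletion_len=(float(del_runs.mean()) if del_runs.size
                           else float("nan")),
        mean_insertion_len=(float(em.ins_len[keep].mean()) if keep.any()
                            else float("nan")),
    )


def _deletion_runs(codes: np.ndarray) -> np.ndarray:
    """Lengths of maximal deletion runs (per row) in a code matrix."""
    d = codes == DEL
    padded = np.zeros((d.shape[0], d.shape[1] + 2), dtype=bool)
    padded[:, 1:-1] = d
    starts = padded[:, 1:] & ~padded[:, :-1]
    ends = ~padded[:, 1:] & padded[:, :-1]
    s_rows, s_cols = np.nonzero(starts)
    e_rows, e_cols = np.nonzero(ends)
    return e_cols - s_cols


def substitution_matrix(em: EventMatrix,
                        readable_only: bool = True) -> pd.DataFrame:
    """4x4 expected->observed substitution rates, % per covered bp."""
    mask = em._mask(readable_only)
    codes, obs, refs = em.codes[mask], em.obs[mask], em.refs[mask]
    denom = int((codes != TRUNC).sum())
    out = np.zeros((4, 4))
    sub = codes == SUB
    for xi, x in enumerate(_BASE_BYTES):
        for yi, y in enumerate(_BASE_BYTES):
            if xi == yi:
                continue
            out[xi, yi] = 100.0 * int((sub & (refs == x) & (obs == y)).sum()) / denom
    bases = list(COUPLING_ORDER)
    return pd.DataFrame(out, index=bases, columns=bases)


def match_matrix(em: EventMatrix, readable_only: bool = True) -> pd.DataFrame:
    """P(observe column | expect row) over {A,C,G,T,deletion}; rows sum to 1."""
    mask = em._mask(readable_only)
    codes, obs, refs = em.codes[mask], em.obs[mask], em.refs[mask]
    bases = list(COUPLING_ORDER)
    out = np.zeros((4, 5))
    for xi, x in enumerate(_BASE_BYTES):
        here = (refs == x) & (codes != TRUNC)
        n = int(here.sum())
        if n == 0:
            continue
        for yi, y in enumerate(_BASE_BYTES):
            out[xi, yi] = int((here & (obs == y) & (codes != DEL)).sum()) / n
        out[xi, 4] = int((here & (codes == DEL)).sum()) / n
    return pd.DataFrame(out, index=bases, columns=bases + ["deletion"])


def deletion_run_lengths(em: EventMatrix,
                         readable_only: bool = True) -> pd.DataFrame:
    """Deletion-run statistics by run length 1, 2, 3+ (% per covered bp).

    ``rate_bases`` counts the bases inside runs of each length class (the
    classes then sum to the overall deletion rate); ``rate_runs`` counts the
    runs themselves.
    """
    mask = em._mask(readable_only)
    codes = em.codes[mask]
    denom = int((codes != TRUNC).sum())
    runs = _deletion_runs(codes)
    rows = []
    for cls in (1, 2, 3):
        sel = runs == cls if cls < 3 else runs >= 3
        rows.append({
            "run_length": f"{cls}" if cls < 3 else "3+",
            "rate_bases": 100.0 * float(runs[sel].sum()) / denom,
            "rate_runs": 100.0 * float(sel.sum()) / denom,
        })
    return pd.DataFrame(rows).set_index("run_length")


def expected_independent_run_rate(single_rate: float, run_length: int) -> float:
    """Chance (in %) of *run_length* consecutive independent deletions.

    *single_rate* is the per-base deletion rate in %; e.g. 4% doubles to
    0.16% and triples to 0.0064%.
    """
    return 100.0 * (single_rate / 100.0) ** run_length


# ---------------------------------------------------------------------------
# Cycle bookkeeping
# ---------------------------------------------------------------------------

def coupling_cycle_index(sequence: str, position: int) -> int:
    """0-based synthesis cycle in which *position* (5'->3' index) couples."""
    if not 0 <= position < len(sequence):
        raise IndexError("position outside sequence")
    return int(cycle_indices(sequence)[position])


def cycle_indices(sequence: str) -> np.ndarray:
    """Per-position synthesis cycle indices for a 5'->3' sequence."""
    out = np.empty(len(sequence), dtype=int)
    total = 0
    prev = None
    for j, base in enumerate(reversed(sequence)):
        idx = _ORDER_INDEX[base]
        if prev is None:
            total += idx + 1
        else:
            total += (idx - prev - 1) % 4 + 1
        prev = idx
        out[len(sequence) - 1 - j] = total - 1
    return out


def wait_number(base_3p: str, base_5p: str) -> int:
    """Cycles elapsed between the couplings of two adjacent bases (1..4).

    *base_3p* couples first (synthesis is 3'->5'); a repeat (X, X) waits a
    full cycle of 4.
    """
    return (_ORDER_INDEX[base_5p] - _ORDER_INDEX[base_3p] - 1) % 4 + 1


def insertion_wait_histogram(em: EventMatrix,
                             readable_only: bool = True) -> pd.Series:
    """Insertion record counts binned by the wait number of their reference
    flanks.  Insertions at sequence ends or against truncated flanks are
    excluded; multi-base insertions count once."""
    mask = em._mask(readable_only)
    counts = dict.fromkeys((1, 2, 3, 4), 0)
    L = em.ref_len
    for r, slot in zip(em.ins_read, em.ins_slot):
        if not mask[r] or slot < 1 or slot > L - 1:
            continue
        if em.codes[r, slot - 1] == TRUNC or em.codes[r, slot] == TRUNC:
            continue
        b5 = chr(em.refs[r, slot - 1])
        b3 = chr(em.refs[r, slot])
        counts[wait_number(b3, b5)] += 1
    return pd.Series(counts, name="insertions").rename_axis("wait")


def per_cycle_rates(em: EventMatrix, references: Mapping[str, str],
                    readable_only: bool = True) -> pd.DataFrame:
    """Deletion/insertion/substitution rates (%) per synthesis cycle.

    Reference positions map to the cycle in which they couple; an insertion
    is attributed to the cycle of its 5' flank (the coupling that closed the
    exposure window it occurred in).
    """
    mask = em._mask(readable_only)
    cyc_of: dict[str, np.ndarray] = {
        rid: cycle_indices(seq) for rid, seq in references.items()}
    n_cyc = 1 + max(int(c.max()) for c in cyc_of.values())
    denom = np.zeros(n_cyc)
    dele = np.zeros(n_cyc)
    sub = np.zeros(n_cyc)
    ins = np.zeros(n_cyc)
    rows = np.nonzero(mask)[0]
    for r in rows:
        cyc = cyc_of[em.ref_ids[r]]
        codes = em.codes[r]
        ok = codes != TRUNC
        np.add.at(denom, cyc[ok], 1)
        np.add.at(dele, cyc[codes == DEL], 1)
        np.add.at(sub, cyc[codes == SUB], 1)
    keep = np.isin(em.ins_read, rows)
    for r, slot, ln in zip(em.ins_read[keep], em.ins_slot[keep],
                           em.ins_len[keep]):
        cyc = cyc_of[em.ref_ids[r]]
        pos = slot - 1 if slot >= 1 else 0
        ins[cyc[min(pos, len(cyc) - 1)]] += ln
    with np.errstate(invalid="ignore", divide="ignore"):
        df = pd.DataFrame({
            "n_bases": denom.astype(int),
            "deletion": 100.0 * dele / denom,
            "insertion": 100.0 * ins / denom,
            "substitution": 100.0 * sub / denom,
        })
    df.index.name = "cycle"
    return df


def per_position_rates(em: EventMatrix,
                       readable_only: bool = True) -> pd.DataFrame:
    """Match/deletion/insertion/substitution rates (%) vs reference position."""
    mask = em._mask(readable_only)
    codes = em.codes[mask]
    covered = (codes != TRUNC).sum(axis=0).astype(float)
    ins = np.zeros(em.ref_len + 1)
    idx = np.nonzero(mask)[0]
    keep = np.isin(em.ins_read, idx)
    np.add.at(ins, em.ins_slot[keep], em.ins_len[keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        df = pd.DataFrame({
            "n_reads": covered.astype(int),
            "match": 100.0 * (codes == MATCH).sum(axis=0) / covered,
            "deletion": 100.0 * (codes == DEL).sum(axis=0) / covered,
            "substitution": 100.0 * (codes == SUB).sum(axis=0) / covered,
            "insertion": 100.0 * ins[:em.ref_len] / covered,
        })
    df.index.name = "position"
    return df


def estimate_coupling_efficiencies(em: EventMatrix, capped: bool = False,
                                   readable_only: bool = True) -> pd.DataFrame:
    """Stepwise coupling efficiencies (%) from cycle-order substitutions.

    A failed coupling of base B, uncapped, is rescued by the next flowed base
    next(B), observed as a B->next(B) substitution -- unless the reference
    base 5' of B *is* next(B), in which case the rescue realigns as a deletion
    of B.  The corrected estimate divides the observed B->next(B) rate by the
    probability q_B that the 5'-neighboring reference base differs from
    next(B).  Invalid for capped syntheses (the substitution channel is
    suppressed): then only the naive estimate is returned.
    """
    if capped:
        warnings.warn("coupling-efficiency estimator is invalid on capped "
                      "data; returning naive estimates only", stacklevel=2)
    mask = em._mask(readable_only)
    codes, obs, refs = em.codes[mask], em.obs[mask], em.refs[mask]
    rows = []
    for base in COUPLING_ORDER:
        nxt = NEXT_IN_ORDER[base]
        b, nb = ord(base), ord(nxt)
        # positions with a 5' neighbor (index >= 1)
        here = (refs[:, 1:] == b) & (codes[:, 1:] != TRUNC)
        n = int(here.sum())
        if n == 0:
            rows.append({"base": base, "naive": float("nan"),
                         "corrected": float("nan"), "n_positions": 0})
            continue
        n_sub = int((here & (codes[:, 1:] == SUB) & (obs[:, 1:] == nb)).sum())
        rate = n_sub / n
        q = int((here & (refs[:, :-1] != nb)).sum()) / n
        naive = 100.0 * (1.0 - rate)
        corrected = 100.0 * (1.0 - rate / q) if (q > 0 and not capped) \
            else float("nan")
        rows.append({"base": base, "naive": naive, "corrected": corrected,
                     "n_positions": n})
    return pd.DataFrame(rows).set_index("base")


def dinucleotide_distribution(em: EventMatrix,
                              readable_only: bool = True) -> pd.DataFrame:
    """5x5 distribution of consecutive observed states {A,C,G,T,deletion}.

    Rows are the state at the 5' position of each covered adjacent pair,
    columns the state at the 3' position; rows are normalized to sum to 1.
    """
    mask = em._mask(readable_only)
    codes, obs = em.codes[mask], em.obs[mask]
    state = np.where(codes == DEL, 4, _BASE_IDX[obs]).astype(np.int8)
    state[(codes != DEL) & (obs == 0)] = -1   # truncated: no state
    a = state[:, :-1]
    b = state[:, 1:]
    ok = (a >= 0) & (b >= 0)
    counts = np.zeros((5, 5))
    np.add.at(counts, (a[ok], b[ok]), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / counts.sum(axis=1, keepdims=True)
    labels = list(COUPLING_ORDER) + ["deletion"]
    return pd.DataFrame(frac, index=labels, columns=labels)
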