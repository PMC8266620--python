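"""Design of k-mer covering oligonucleotide panels.

Panels for synthesis-fidelity studies are built so that every short k-mer is
represented in several distinct oligos (so that per-k-mer error statistics have
support across many spatial positions and sequence contexts) while avoiding
long homopolymers, which both complicate synthesis and confound alignment.

The generator is randomized with rejection/repair: sequences are sampled
base-by-base under the homopolymer cap, then any under-covered k-mer is greedily
patched into sequences that do not yet contain it.  A k-mer is *admissible* if
its own longest homopolymer run does not exceed the cap; only admissible k-mers
can (and must) be covered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_SET = frozenset(BASES)


class DesignError(ValueError):
    """Raised for infeasible specs or failed generation."""


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-letter run in *seq*.

    >>> max_homopolymer_run("AAACAA")
    3
    """
    if not seq:
        raise ValueError("empty sequence")
    invalid = set(seq) - _BASE_SET
    if invalid:
        raise ValueError(f"invalid characters in sequence: {sorted(invalid)}")
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class DesignSpec:
    """Constraints for a covering oligo panel.

    n_oligos            number of unique sequences
    oligo_len           total length (nt) including any fixed ends
    k                   k-mer length for the coverage requirement
    min_oligo_coverage  minimum number of distinct oligos containing each
                        admissible k-mer (counted on variable regions)
    max_homopolymer     longest tolerated single-base run in the variable region
    fixed_5p/fixed_3p   constant flanks (e.g. poly-dC / poly-dA handles)
    """

    n_oligos: int
    oligo_len: int
    k: int
    min_oligo_coverage: int = 1
    max_homopolymer: int = 3
    fixed_5p: str = ""
    fixed_3p: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_homopolymer < 1:
            raise DesignError("max_homopolymer must be >= 1")
        if self.k > self.oligo_len:
            raise DesignError(f"k={self.k} exceeds oligo_len={self.oligo_len}")
        for end in (self.fixed_5p, self.fixed_3p):
            if set(end) - _BASE_SET:
                raise DesignError(f"fixed end {end!r} has invalid characters")
        if self.variable_len < self.k:
            raise DesignError(
                f"variable region ({self.variable_len} nt) shorter than k={self.k}"
            )
        windows = self.n_oligos * (self.oligo_len - self.k + 1)
        need = self.min_oligo_coverage * 4**self.k
        if windows < need:
            raise DesignError(
                "infeasible spec: n_oligos*(oligo_len-k+1) = "
                f"{windows} < min_oligo_coverage*4^k = {need}"
            )

    @property
    def variable_len(self) -> int:
        return self.oligo_len - len(self.fixed_5p) - len(self.fixed_3p)


@dataclass
class OligoLibrary:
    """Ordered panel of named 5'->3' sequences satisfying a :class:`DesignSpec`."""

    entries: list[tuple[str, str]]
    spec: DesignSpec

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.entries)

    def variable_region(self, seq: str) -> str:
        s = self.spec
        end = len(seq) - len(s.fixed_3p)
        return seq[len(s.fixed_5p):end]

    def validate(self) -> None:
        """Check every library invariant; raise DesignError on violation."""
        s = self.spec
        if len(self.entries) != s.n_oligos:
            raise DesignError("entry count != n_oligos")
        seqs = [q for _, q in self.entries]
        if len(set(seqs)) != len(seqs):
            raise DesignError("duplicate sequences")
        if len(set(self.ids)) != len(self.ids):
            raise DesignError("duplicate ids")
        for oid, q in self.entries:
            if len(q) != s.oligo_len:
                raise DesignError(f"{oid}: length {len(q)} != {s.oligo_len}")
            if not q.startswith(s.fixed_5p) or not q.endswith(s.fixed_3p):
                raise DesignError(f"{oid}: fixed ends missing")
            var = self.variable_region(q)
            if max_homopolymer_run(var) > s.max_homopolymer:
                raise DesignError(f"{oid}: homopolymer run > {s.max_homopolymer}")
        cov = kmer_oligo_coverage(self, s.k)
        for kmer in admissible_kmers(s.k, s.max_homopolymer):
            if cov.get(kmer, 0) < s.min_oligo_coverage:
                raise DesignError(
                    f"k-mer {kmer} covered by {cov.get(kmer, 0)} oligos "
                    f"< {s.min_oligo_coverage}"
                )


def admissible_kmers(k: int, max_homopolymer: int) -> list[str]:
    """All k-mers whose internal homopolymer run is within the cap."""
    if max_homopolymer >= k:
        return ["".join(p) for p in itertools.product(BASES, repeat=k)]
    out = []
    for p in itertools.product(BASES, repeat=k):
        s = "".join(p)
        if max_homopolymer_run(s) <= max_homopolymer:
            out.append(s)
    return out


def kmer_oligo_coverage(lib: OligoLibrary, k: int) -> dict[str, int]:
    """Map k-mer -> number of *distinct* oligos whose variable region contains it.

    Presence is counted once per oligo regardless of occurrence count; k-mers
    spanning the fixed-end boundary are not credited.
    """
    if not lib.entries:
        raise DesignError("empty library")
    if k > lib.spec.oligo_len:
        raise ValueError("k exceeds oligo length")
    counts: dict[str, int] = {}
    for _, seq in lib.entries:
        var = lib.variable_region(seq)
        seen = {var[i:i + k] for i in range(len(var) - k + 1)}
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _sample_variable(rng: np.random.Generator, length: int, max_run: int) -> str:
    """Sample one variable region base-by-base under the homopolymer cap."""
    out = []
    run = 0
    prev = None
    for _ in range(length):
        if prev is not None and run >= max_run:
            choices = [b for b in BASES if b != prev]
        else:
            choices = BASES
        b = choices[rng.integers(len(choices))]
        if b == prev:
            run += 1
        else:
            prev, run = b, 1
        out.append(b)
    return "".join(out)


def _splice_ok(var: str, pos: int, kmer: str, max_run: int) -> str | None:
    """Replace var[pos:pos+k] with kmer; return new region if cap still holds."""
    cand = var[:pos] + kmer + var[pos + len(kmer):]
    if max_homopolymer_run(cand) > max_run:
        return None
    return cand


def design_library(spec: DesignSpec, max_repair_rounds: int = 25) -> OligoLibrary:
    """Generate an :class:`OligoLibrary` satisfying *spec*.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`DesignError` if the
    spec is infeasible or coverage cannot be repaired within the retry budget
    (the worst-covered k-mer is reported).
    """
    rng = np.random.default_rng(spec.seed)
    n_var = spec.variable_len
    seen: set[str] = set()
    variables: list[str] = []
    attempts = 0
    while len(variables) < spec.n_oligos:
        var = _sample_variable(rng, n_var, spec.max_homopolymer)
        attempts += 1
        if attempts > 50 * spec.n_oligos + 1000:
            raise DesignError("could not sample enough unique sequences")
        if var in seen:
            continue
        seen.add(var)
        variables.append(var)

    required = admissible_kmers(spec.k, spec.max_homopolymer)
    width = len(str(spec.n_oligos - 1))

    def build() -> OligoLibrary:
        entries = [
            (f"oligo_{i:0{width}d}", spec.fixed_5p + v + spec.fixed_3p)
            for i, v in enumerate(variables)
        ]
        return OligoLibrary(entries=entries, spec=spec)

    for _ in range(max_repair_rounds):
        lib = build()
        cov = kmer_oligo_coverage(lib, spec.k)
        deficits = [
            (kmer, cov.get(kmer, 0))
            for kmer in required
            if cov.get(kmer, 0) < spec.min_oligo_coverage
        ]
        if not deficits:
            return lib
        # Greedy repair: splice each deficient k-mer into random oligos that
        # do not yet contain it, keeping the homopolymer cap and uniqueness.
        for kmer, have in deficits:
            need = spec.min_oligo_coverage - have
            order = rng.permutation(spec.n_oligos)
            for idx in order:
                if need <= 0:
                    break
                var = variables[idx]
                if kmer in var:
                    continue
                positions = rng.permutation(n_var - spec.k + 1)
                for pos in positions:
                    cand = _splice_ok(var, int(pos), kmer, spec.max_homopolymer)
                    if cand is not None and cand not in seen:
                        seen.discard(var)
                        seen.add(cand)
                        variables[idx] = cand
                        need -= 1
                        break

    lib = build()
    cov = kmer_oligo_coverage(lib, spec.k)
    worst = min(required, key=lambda m: cov.get(m, 0))
    raise DesignError(
        f"coverage not reached after {max_repair_rounds} repair rounds; "
        f"worst k-mer {worst} covered by {cov.get(worst, 0)} "
        f"< {spec.min_oligo_coverage}"
    )


def design_report(lib: OligoLibrary) -> pd.DataFrame:
    """Per-k-mer coverage table (k-mer, oligo count, admissible flag)."""
    s = lib.spec
    cov = kmer_oligo_coverage(lib, s.k)
    adm = set(admissible_kmers(s.k, s.max_homopolymer))
    rows = [
        {"kmer": m, "n_oligos": c, "admissible": m in adm}
        for m, c in sorted(cov.items())
    ]
    return pd.DataFrame(rows)
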