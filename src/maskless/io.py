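"""File formats: FASTA/FASTQ panels and reads, truth tables, SAM ingestion.

PBM mask files live in :mod:`maskless.layout` next to the mask generator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiler import DEL, MATCH, SUB, TRUNC, AlignmentEvents, EventMatrix


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"read_id", "feature_id", "reference_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return df


def ingest_sam(path: str | Path, references: Mapping[str, str],
               min_identity: float = 0.5) -> EventMatrix:
    """Build an event matrix from an externally produced SAM alignment.

    CIGAR operations M/=/X/I/D/S are honored; substitution identity comes
    from comparing the read sequence with the panel reference (no MD tag
    needed when the panel FASTA is supplied).  Reference positions left of
    the alignment start are classified as truncation, consistent with the
    internal aligner; positions right of the alignment end as deletion.
    Unmapped and secondary/supplementary records are skipped.
    """
    alns: list[AlignmentEvents] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.query_sequence is None):
                continue
            ref = references.get(rec.reference_name)
            if ref is None:
                raise ValueError(
                    f"{rec.reference_name} not in the reference panel")
            L = len(ref)
            codes = np.full(L, DEL, dtype=np.uint8)
            codes[:rec.reference_start] = TRUNC
            obs = np.zeros(L, dtype=np.uint8)
            insertions: list[tuple[int, str]] = []
            read = rec.query_sequence.upper()
            qpos = 0
            rpos = rec.reference_start
            pending: list[str] = []
            for op, length in rec.cigartuples:
                if op in (0, 7, 8):        # M, =, X
                    for _ in range(length):
                        if pending:
                            insertions.append((rpos, "".join(pending)))
                            pending = []
                        codes[rpos] = MATCH if read[qpos] == ref[rpos] else SUB
                        obs[rpos] = ord(read[qpos])
                        qpos += 1
                        rpos += 1
                elif op == 1:               # I
                    pending.extend(read[qpos:qpos + length])
                    qpos += length
                elif op == 2:               # D
                    rpos += length
                elif op == 4:               # S
                    qpos += length
                elif op == 5:               # H
                    pass
                else:
                    raise ValueError(
                        f"unsupported CIGAR op {op} in read {rec.query_name}")
            if pending:
                insertions.append((rpos, "".join(pending)))
            alns.append(AlignmentEvents(
                ref_id=rec.reference_name, read_id=rec.query_name,
                codes=codes, obs=obs, insertions=insertions,
                score=float(rec.mapping_quality)))
    if not alns:
        raise ValueError(f"{path}: no usable alignments")
    return EventMatrix.from_alignments(alns, references,
                                       min_identity=min_identity)
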