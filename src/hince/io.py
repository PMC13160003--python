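"""Readers and writers for the on-disk formats.

FASTA for sequences (via Biopython), TSV for label tables, embedding
matrices and BLAST outfmt-6-style hit tables, JSON for reports.  Every
reader/writer pair round-trips exactly (floats to full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import EmbeddingSet
from .ec import ECLabel, ProteinRecord, Rejection, normalize_and_parse
from .splits import SimilarityHit


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercased sequence; id is the first whitespace token of the header."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_label_table(
    path: str | Path,
    fasta: Optional[Mapping[str, str]] = None,
) -> tuple[list[ProteinRecord], list[dict]]:
    """Read a TSV with columns ``entry``, ``ec`` and optionally ``sequence``.

    ECs go through normalization; malformed rows are returned in a rejects
    list (with line numbers and reasons), never silently dropped.  When a
    FASTA mapping is given it supplies/overrides sequences, joined on entry.
    An optional ``evidence_experimental`` column (true/false) is honored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("entry", "ec"):
        if col not in df.columns:
            raise ValueError(f"label table missing required column {col!r}")
    has_seq = "sequence" in df.columns
    has_ev = "evidence_experimental" in df.columns
    if not has_seq and fasta is None:
        raise ValueError("label table has no 'sequence' column and no FASTA was given")
    records: list[ProteinRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        entry = str(row.entry)
        parsed = normalize_and_parse(str(row.ec))
        if isinstance(parsed, Rejection):
            rejects.append({"line": i, "entry": entry,
                            "ec": parsed.raw, "reason": parsed.reason})
            continue
        if fasta is not None and entry in fasta:
            seq = fasta[entry]
        elif has_seq and isinstance(row.sequence, str):
            seq = row.sequence.upper()
        else:
            rejects.append({"line": i, "entry": entry, "ec": str(row.ec),
                            "reason": "missing_sequence"})
            continue
        ev = None
        if has_ev and isinstance(row.evidence_experimental, str):
            ev = row.evidence_experimental.strip().lower() in ("true", "1", "yes")
        records.append(ProteinRecord(entry=entry, ec=parsed, sequence=seq,
                                     evidence_experimental=ev))
    return records, rejects


def write_label_table(path: str | Path, records: Sequence[ProteinRecord],
                      with_sequence: bool = True) -> None:
    rows = []
    for r in records:
        row = {"entry": r.entry, "ec": str(r.ec)}
        if with_sequence:
            row["sequence"] = r.sequence
        if r.evidence_experimental is not None:
            row["evidence_experimental"] = str(r.evidence_experimental).lower()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_embeddings(path: str | Path) -> EmbeddingSet:
    """TSV: first column the entry id, remaining columns the vector."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    dim: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] in ("entry", "id"):
                continue  # optional header
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(vec)} values, expected {dim})")
            ids.append(parts[0])
            rows.append(vec)
    if not ids:
        return EmbeddingSet(ids=[], matrix=np.empty((0, 0)))
    return EmbeddingSet(ids=ids, matrix=np.stack(rows))


def write_embeddings(path: str | Path, embeddings: EmbeddingSet) -> None:
    with open(path, "w") as fh:
        for i, entry in enumerate(embeddings.ids):
            vals = "\t".join(repr(float(v)) for v in embeddings.matrix[i])
            fh.write(f"{entry}\t{vals}\n")


def read_hit_table(path: str | Path) -> list[SimilarityHit]:
    """BLAST tabular (outfmt-6 style): qseqid, sseqid, pident, length [+ ignored]."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                pident = float(parts[2])
                length = int(float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric pident/length") from exc
            hits.append(SimilarityHit(qseqid=parts[0], sseqid=parts[1],
                                      pident=pident, length=length))
    return hits


def write_hit_table(path: str | Path, hits: Sequence[SimilarityHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.qseqid}\t{h.sseqid}\t{h.pident}\t{h.length}\n")


def write_split_manifest(path: str | Path, train: Sequence[ProteinRecord],
                         test: Sequence[ProteinRecord]) -> None:
    rows = ([{"entry": r.entry, "ec": str(r.ec), "split": "train"} for r in train]
            + [{"entry": r.entry, "ec": str(r.ec), "split": "test"} for r in test])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_predictions(path: str | Path, predictions) -> None:
    rows = [{"query": p.query, "predicted_ec": str(p.predicted_ec),
             "neighbor": p.neighbor, "similarity": repr(p.similarity)}
            for p in predictions]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[tuple[str, ECLabel]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        parsed = normalize_and_parse(row.predicted_ec)
        if isinstance(parsed, Rejection):
            raise ValueError(f"invalid EC in predictions: {row.predicted_ec!r}")
        out.append((str(row.query), parsed))
    return out
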