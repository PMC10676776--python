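"""FASTA and tabular input/output.

FASTA reading goes through Biopython (multi-record, wrapped lines,
case-insensitive); sequences are validated against the strict ACGT alphabet
on load, with an opt-in mode that drops offending records with a logged
warning instead of failing.  Tabular outputs (encodings, metrics, GA
trajectories) are tab-separated with a header row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import DnaSequence, InvalidSequenceError
from .zcurve import ZSpaceConfig, component_names

logger = logging.getLogger(__name__)


def read_fasta(path: "str | Path", on_invalid: str = "error") -> list[DnaSequence]:
    """Read a FASTA file into validated DnaSequence records, in file order.

    ``on_invalid``: "error" rejects non-ACGT records, "drop" skips them with
    a warning.  Duplicate record ids are always an error.
    """
    if on_invalid not in ("error", "drop"):
        raise ValueError("on_invalid must be 'error' or 'drop'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[DnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            out.append(DnaSequence(rec.id, str(rec.seq)))
        except InvalidSequenceError as exc:
            if on_invalid == "drop":
                logger.warning("dropping record %r: %s", rec.id, exc)
            else:
                raise
    return out


def write_fasta(
    seqs: list[DnaSequence],
    path: "str | Path",
    line_width: int = 70,
    annotations: "dict[str, dict] | None" = None,
) -> None:
    """Write FASTA; optional per-id annotations become ``key=value`` header fields."""
    records = []
    for s in seqs:
        desc = ""
        if annotations and s.id in annotations:
            desc = " ".join(f"{k}={v}" for k, v in annotations[s.id].items())
        records.append(SeqRecord(Seq(s.seq), id=s.id, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=line_width or None)
    writer.write_file(records)


def parse_header_annotations(path: "str | Path") -> dict[str, dict[str, str]]:
    """Recover ``key=value`` fields written by write_fasta header annotations."""
    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()[1:]  # first token is the id
        out[rec.id] = dict(f.split("=", 1) for f in fields if "=" in f)
    return out


def write_encodings(
    path: "str | Path", ids: list[str], matrix: np.ndarray, config: ZSpaceConfig
) -> None:
    """One row per sequence: id column then the named Z-space components (TSV)."""
    df = pd.DataFrame(matrix, columns=component_names(config))
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def write_cv_report(result, path: "str | Path") -> None:
    """Per-fold and aggregate ACC/MCC/AUC as structured JSON."""
    payload = {
        "folds": [vars(f) for f in result.folds],
        "aggregate": result.summary(),
        "k": result.k,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_trajectory(trajectory: pd.DataFrame, path: "str | Path") -> None:
    trajectory.to_csv(path, sep="\t", index=False)
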