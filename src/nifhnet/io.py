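"""File formats: FASTA with key=value headers and labeled TSV matrices."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motu import AmpliconRecord

__all__ = ["read_fasta", "write_fasta", "read_matrix", "write_matrix"]


def _header_line_numbers(path: Path) -> dict[str, int]:
    numbers: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                rec_id = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                numbers.setdefault(rec_id, lineno)
    return numbers


def read_fasta(path) -> list[AmpliconRecord]:
    """Read amplicons whose headers carry ``log=`` / ``species=`` metadata.

    Header scheme: ``>read_id log=L01 species=Fagus [motu=M001]``.  A record
    without a ``log`` key is rejected with its header line number.
    """
    path = Path(path)
    lines = _header_line_numbers(path)
    records: list[AmpliconRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            part.split("=", 1) for part in rec.description.split()[1:] if "=" in part
        )
        if "log" not in fields:
            lineno = lines.get(rec.id, "?")
            raise ValueError(
                f"{path}:{lineno}: header {rec.description!r} is missing the log id"
            )
        records.append(
            AmpliconRecord(
                id=rec.id,
                sequence=str(rec.seq),
                log_id=fields["log"],
                species=fields.get("species"),
                truth_motu=fields.get("motu"),
            )
        )
    return records


def write_fasta(records: list[AmpliconRecord], path) -> None:
    """Write amplicons with their metadata in the key=value header scheme."""
    out = []
    for rec in records:
        parts = [f"log={rec.log_id}"]
        if rec.species is not None:
            parts.append(f"species={rec.species}")
        if rec.truth_motu is not None:
            parts.append(f"motu={rec.truth_motu}")
        out.append(
            SeqRecord(Seq(rec.sequence), id=rec.id, description=" ".join(parts))
        )
    SeqIO.write(out, str(path), "fasta")


def write_matrix(matrix: pd.DataFrame, path, dialect: str = "abundance") -> None:
    """Write a labeled matrix as TSV with the dialect flagged in a comment."""
    if dialect not in ("abundance", "binary"):
        raise ValueError(f"dialect must be 'abundance' or 'binary', got {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"# matrix-dialect: {dialect}\n")
        matrix.to_csv(fh, sep="\t")


def read_matrix(path) -> tuple[pd.DataFrame, str]:
    """Read a TSV matrix, returning (matrix, dialect) and validating cells."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        dialect = "abundance"
        if first.startswith("#"):
            if "matrix-dialect:" in first:
                dialect = first.split("matrix-dialect:", 1)[1].strip()
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO

    try:
        matrix = pd.read_csv(StringIO(body), sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed matrix ({exc})") from exc
    if matrix.isna().any().any():
        raise ValueError(f"{path}: ragged or missing cells")
    values = matrix.to_numpy()
    if (values < 0).any():
        raise ValueError(f"{path}: negative abundances")
    if dialect == "binary" and not ((values == 0) | (values == 1)).all():
        raise ValueError(f"{path}: binary matrix contains cells other than 0/1")
    return matrix, dialect
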