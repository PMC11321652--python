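"""Standard-format I/O and run configuration.

FASTA/FASTQ parsing is delegated to Biopython's low-level iterators; this
module adds the error reporting and normalisation contracts the pipeline
relies on (uppercased sequences, parse errors that name the offending line
or record, transparent gzip support) plus the '#'-prefixed metadata header
written at the top of every output table so that runs are auditable and
byte-reproducible.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class ParseError(ValueError):
    """Malformed FASTA/FASTQ/TSV input."""


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]`` with sequences uppercased.

    Raises :class:`ParseError` naming the line number when the file does not
    start with a ``'>'`` header.
    """
    with _open_text(path) as handle:
        lines = handle.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(
                f"{path}: line {lineno}: expected FASTA header starting with '>'"
            )
        break
    with _io.StringIO("\n".join(lines)) as handle:
        return [(title.split()[0] if title else "", seq.upper())
                for title, seq in SimpleFastaParser(handle)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "wt") as out:
        for rid, seq in records:
            out.write(f">{rid}\n{seq}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(id, sequence, quality)`` tuples from plain or gzipped FASTQ.

    Sequences are uppercased. A truncated record or a sequence/quality
    length mismatch raises :class:`ParseError` carrying the record id.
    """
    with _open_text(path) as handle:
        last_id = "<start of file>"
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                rid = title.split()[0]
                last_id = rid
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {rid}: sequence/quality length mismatch"
                    )
                yield rid, seq.upper(), qual
        except ValueError as exc:  # Biopython signals truncation/malformation
            if isinstance(exc, ParseError):
                raise
            raise ParseError(
                f"{path}: malformed FASTQ near record {last_id}: {exc}"
            ) from exc


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for rid, seq, qual in records:
            out.write(f"@{rid}\n{seq}\n+\n{qual}\n")


@dataclass
class RunConfig:
    """Tunables shared across pipeline stages.

    seed: master seed for every stochastic step, recorded in output headers.
    mismatch_budget: substitutions outside the quantification window a read
        may carry before being discarded as off-amplicon.
    min_reads: minimum passing reads before frequencies are reported.
    window_threshold: fraction of the maximum per-position frequency a
        position must reach to belong to the editing window.
    pseudocount: added to every pool count in enrichment scoring.
    """

    seed: int = 0
    mismatch_budget: int = 5
    min_reads: int = 100
    window_threshold: float = 0.3
    pseudocount: float = 0.5
    quant_window: tuple[int, int] = (-3, 12)

    def __post_init__(self) -> None:
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.mismatch_budget < 0 or self.min_reads < 0:
            raise ValueError("mismatch_budget and min_reads must be >= 0")
        self.quant_window = tuple(self.quant_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mismatch_budget": self.mismatch_budget,
            "min_reads": self.min_reads,
            "window_threshold": self.window_threshold,
            "pseudocount": self.pseudocount,
            "quant_window": list(self.quant_window),
        }

    def digest(self) -> str:
        """Short stable hash of the configuration, for output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(config: RunConfig | None = None, **extra: object) -> list[str]:
    """'#'-prefixed header lines carrying config hash, seed and extras.

    Deliberately timestamp-free so identical runs emit identical bytes.
    """
    lines = []
    if config is not None:
        lines.append(f"# config_hash={config.digest()}")
        lines.append(f"# seed={config.seed}")
    for key, value in sorted(extra.items()):
        lines.append(f"# {key}={value}")
    return lines


def write_tsv(
    path: str | Path,
    header: list[str],
    rows: Iterable[Iterable[object]],
    config: RunConfig | None = None,
    **extra: object,
) -> None:
    with open(path, "wt") as out:
        for line in metadata_header(config, **extra):
            out.write(line + "\n")
        out.write("\t".join(header) + "\n")
        for row in rows:
            out.write("\t".join(str(v) for v in row) + "\n")


def read_tsv_rows(path: str | Path) -> tuple[dict[str, str], list[str], list[list[str]]]:
    """Read a pipeline TSV back: (metadata, column names, rows)."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ParseError(f"{path}: no header row found")
    return meta, header, rows
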