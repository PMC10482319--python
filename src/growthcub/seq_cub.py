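"""Coding-sequence handling and codon usage bias (CUB) scoring.

Reads CDS collections from FASTA or GenBank, applies quality filters
(length divisible by 3, declared-vs-counted length agreement, removal of
unrealistically long sequences), and scores each gene with a codon-weight
metric such as the Codon Adaptation Index (CAI) or tRNA Adaptation Index
(tAI): the geometric mean of the per-codon weights, computed in log space.
"""

from __future__ import annotations

import gzip
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codon_tables import SENSE_CODONS, STOP_CODONS, example_weights

logger = logging.getLogger(__name__)

AMBIGUOUS_KEY = "ambiguous"

__all__ = [
    "CdsRecord",
    "CodonWeightTable",
    "CubScore",
    "read_cds",
    "filter_cds",
    "codon_counts",
    "cub_score",
    "score_all",
    "load_weight_table",
    "write_scores",
    "AMBIGUOUS_KEY",
]


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence: id, nucleotide string, optional source metadata.

    ``declared_length`` carries a declared CDS length (bases) when the input
    format provides coordinates (GenBank); it is None for plain FASTA.
    """

    id: str
    seq: str
    source_meta: str | None = None
    declared_length: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("CdsRecord id must be nonempty")
        if not self.seq:
            raise ValueError(f"CdsRecord {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CodonWeightTable:
    """Codon -> relative-adaptiveness weight map defining a CUB metric.

    Weights live in (0, 1]; a weight of exactly 0 is rejected because it
    would zero the geometric mean of every sequence using that codon.
    """

    metric_name: str
    weights: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if len(codon) != 3 or any(b not in "ACGT" for b in codon):
                raise ValueError(f"malformed codon {codon!r}")
            if not (0 < w <= 1):
                raise ValueError(
                    f"weight for {codon} is {w}; weights must be in (0, 1] "
                    "(use a small positive pseudo-weight instead of 0)"
                )
        missing = set(SENSE_CODONS) - set(self.weights)
        if missing:
            logger.warning(
                "%s weight table missing %d sense codons: %s",
                self.metric_name, len(missing), ",".join(sorted(missing)),
            )

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.weights

    @classmethod
    def example(cls, metric_name: str = "CAI", decay: float = 0.5) -> "CodonWeightTable":
        """Illustrative synthetic table (see :mod:`growthcub._codon_tables`)."""
        return cls(metric_name, example_weights(decay), provenance="synthetic illustrative table")


@dataclass(frozen=True)
class CubScore:
    gene_id: str
    metric_name: str
    value: float


class MissingWeightError(KeyError):
    """A scored codon has no entry in the weight table."""


class UndefinedScoreError(ValueError):
    """No scorable codons remain (L = 0)."""


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_cds(path: str | Path, format: Literal["fasta", "genbank"] = "fasta") -> list[CdsRecord]:
    """Read coding sequences from a FASTA or GenBank flat file.

    For GenBank input only CDS features are extracted (with strand-aware
    extraction of the nucleotide sequence); locus_tag is preferred as the
    id, falling back to gene name then a positional id. Duplicate ids are
    disambiguated with a deterministic ``.dup<k>`` suffix and a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[CdsRecord] = []
    if format == "fasta":
        with _open_maybe_gz(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                records.append(CdsRecord(id=rec.id, seq=str(rec.seq), source_meta=rec.description))
    elif format == "genbank":
        with _open_maybe_gz(path) as fh:
            for gb in SeqIO.parse(fh, "genbank"):
                for feat in gb.features:
                    if feat.type != "CDS":
                        continue
                    quals = feat.qualifiers
                    fid = (quals.get("locus_tag") or quals.get("gene") or [None])[0]
                    if fid is None:
                        fid = f"{gb.id}_CDS_{len(records) + 1}"
                    seq = str(feat.extract(gb.seq))
                    strand = "+" if feat.location.strand in (1, None) else "-"
                    meta = f"{strand}:{int(feat.location.start)}..{int(feat.location.end)}"
                    declared = int(len(feat.location))
                    records.append(
                        CdsRecord(id=fid, seq=seq, source_meta=meta, declared_length=declared)
                    )
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise ValueError(f"no coding sequences found in {path}")
    # deterministic suffix disambiguation of duplicate ids, in file order
    seen: dict[str, int] = {}
    out: list[CdsRecord] = []
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            new_id = f"{rec.id}.dup{seen[rec.id]}"
            warnings.warn(f"duplicate CDS id {rec.id!r} renamed to {new_id!r}")
            rec = CdsRecord(new_id, rec.seq, rec.source_meta, rec.declared_length)
        else:
            seen[rec.id] = 0
        out.append(rec)
    return out


def filter_cds(
    records: Sequence[CdsRecord], max_len_factor: float = 5.0
) -> tuple[list[CdsRecord], list[tuple[CdsRecord, str]]]:
    """Apply CDS quality filters; return (kept, removed-with-reason).

    Removal reasons (machine-readable): ``not_multiple_of_3`` (frame),
    ``length_mismatch`` (declared length disagrees with counted bases;
    only checkable when coordinate metadata exists), ``too_long`` (longer
    than ``max_len_factor`` times the median length over ALL input records,
    median computed before any removal).
    """
    if not records:
        raise ValueError("no records to filter")
    if max_len_factor <= 0:
        raise ValueError("max_len_factor must be positive")
    median_len = float(np.median([len(r) for r in records]))
    kept: list[CdsRecord] = []
    removed: list[tuple[CdsRecord, str]] = []
    for rec in records:
        if len(rec) % 3 != 0:
            removed.append((rec, "not_multiple_of_3"))
        elif rec.declared_length is not None and rec.declared_length != len(rec):
            removed.append((rec, "length_mismatch"))
        elif len(rec) > max_len_factor * median_len:
            removed.append((rec, "too_long"))
        else:
            kept.append(rec)
    return kept, removed


def codon_counts(
    record: CdsRecord, drop_stop: bool = True, drop_start: bool = False
) -> dict[str, int]:
    """Count in-frame codons 5'->3'; N-containing codons go under 'ambiguous'.

    The terminal stop codon is excluded when ``drop_stop`` (only if the last
    codon actually is a stop); the first codon is excluded when ``drop_start``.
    """
    seq = record.seq
    if len(seq) % 3 != 0:
        raise ValueError(f"{record.id}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if drop_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if drop_start and codons:
        codons = codons[1:]
    counts: dict[str, int] = {}
    for c in codons:
        key = c if set(c) <= set("ACGT") else AMBIGUOUS_KEY
        counts[key] = counts.get(key, 0) + 1
    return counts


def cub_score(
    record: CdsRecord,
    table: CodonWeightTable,
    drop_stop: bool = True,
    drop_start: bool = False,
) -> CubScore:
    """Geometric mean of codon weights, computed in log space.

    value = exp((1/L) * sum over scored codons of ln w(codon)), with
    ambiguous (N-containing) codons excluded from both numerator and L.
    Internal stop codons (after terminal-stop handling) raise
    MissingWeightError unless the table carries weights for them.
    """
    counts = codon_counts(record, drop_stop=drop_stop, drop_start=drop_start)
    log_sum = 0.0
    n = 0
    for codon, k in counts.items():
        if codon == AMBIGUOUS_KEY:
            continue
        if codon not in table:
            raise MissingWeightError(
                f"codon {codon} in {record.id} has no weight in table {table.metric_name!r}"
            )
        log_sum += k * math.log(table[codon])
        n += k
    if n == 0:
        raise UndefinedScoreError(f"{record.id}: no scorable codons")
    return CubScore(record.id, table.metric_name, math.exp(log_sum / n))


def score_all(
    records: Iterable[CdsRecord],
    tables: Sequence[CodonWeightTable],
    drop_stop: bool = True,
    drop_start: bool = False,
) -> pd.DataFrame:
    """Score every record with every table; tidy frame (gene_id, metric, value)."""
    rows = []
    for rec in records:
        for table in tables:
            s = cub_score(rec, table, drop_stop=drop_stop, drop_start=drop_start)
            rows.append((s.gene_id, s.metric_name, s.value))
    return pd.DataFrame(rows, columns=["gene_id", "metric", "value"])


def load_weight_table(path: str | Path, metric_name: str) -> CodonWeightTable:
    """Load a codon-weight TSV (columns: codon, weight) into a validated table."""
    df = pd.read_csv(path, sep="\t")
    if not {"codon", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'codon' and 'weight'")
    weights = {str(c).upper(): float(w) for c, w in zip(df["codon"], df["weight"])}
    return CodonWeightTable(metric_name, weights, provenance=str(path))


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False)
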