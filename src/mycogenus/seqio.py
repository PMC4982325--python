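"""Domain types and readers/writers for sequences, lineages, features and models.

The on-disk formats are deliberately plain text: FASTA for sequences, a
tab-separated lineage table (one row per sequence id, ranked
phylum..genus[, species]), ARFF for Weka interoperability, and a versioned
JSON model file.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "Lineage",
    "SequenceRecord",
    "FastaFormatError",
    "LineageFormatError",
    "ModelFormatError",
    "read_fasta",
    "write_fasta",
    "read_lineages",
    "write_lineages",
    "load_dataset",
    "write_arff",
    "save_model",
    "load_model",
]

RANK_NAMES = ("phylum", "class_", "order", "family", "genus", "species")

MODEL_FORMAT = "mycogenus-nb"
MODEL_VERSION = 1


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header, empty sequence, ...)."""


class LineageFormatError(ValueError):
    """Malformed lineage table (wrong column count, duplicate id, ...)."""


class ModelFormatError(ValueError):
    """Unreadable or incompatible model file."""


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic lineage phylum..genus, optionally species.

    Any rank may be empty; curation filters decide which emptiness is fatal.
    Genus, when present, must be a single token (binomial handling lives in
    the species field).
    """

    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        for rank in RANK_NAMES:
            value = getattr(self, rank)
            if "\t" in value:
                raise ValueError(f"rank {rank!r} contains a tab: {value!r}")
        if self.genus and len(self.genus.split()) != 1:
            raise ValueError(f"genus must be a single token, got {self.genus!r}")

    def ranks(self) -> tuple[str, ...]:
        return tuple(getattr(self, rank) for rank in RANK_NAMES)


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with id and ranked lineage."""

    id: str
    seq: str
    lineage: Lineage = field(default_factory=Lineage)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def genus(self) -> str:
        return self.lineage.genus


def _validate_fasta_text(path: Path) -> None:
    """Light structural pass so errors can carry line numbers.

    Parsing proper is delegated to Bio.SeqIO below; this pass only rejects
    inputs Bio.SeqIO would silently tolerate or report without location.
    """
    seen_header = False
    header_line = 0
    header_id = ""
    has_seq = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if seen_header and not has_seq:
                    raise FastaFormatError(
                        f"record {header_id!r} (line {header_line}) has an empty sequence"
                    )
                if not stripped[1:].strip():
                    raise FastaFormatError(f"malformed FASTA header at line {lineno}")
                seen_header = True
                header_line = lineno
                header_id = stripped[1:].split()[0]
                has_seq = False
            else:
                if not seen_header:
                    raise FastaFormatError(
                        f"sequence data before any FASTA header at line {lineno}"
                    )
                has_seq = True
    if seen_header and not has_seq:
        raise FastaFormatError(
            f"record {header_id!r} (line {header_line}) has an empty sequence"
        )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered (id, sequence) pairs.

    Sequences are upper-cased; multi-line records are joined. Malformed
    headers and empty records raise :class:`FastaFormatError` naming the
    offending record/line.
    """
    path = Path(path)
    _validate_fasta_text(path)
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Iterable[SequenceRecord | tuple[str, str]], path: str | Path) -> None:
    """Write records (SequenceRecord or (id, seq) pairs) as FASTA."""
    bio_records = []
    for rec in records:
        if isinstance(rec, SequenceRecord):
            rid, seq = rec.id, rec.seq
        else:
            rid, seq = rec
        bio_records.append(_BioSeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(bio_records, str(path), "fasta")


def read_lineages(path: str | Path) -> dict[str, Lineage]:
    """Read a tab-separated lineage table: id, phylum..genus[, species].

    Lines starting with '#' are ignored. Missing trailing ranks become empty
    strings. Duplicate ids and rows with the wrong column count raise
    :class:`LineageFormatError` with the row number.
    """
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if not 6 <= len(cols) <= 7:
                raise LineageFormatError(
                    f"row {lineno}: expected 6-7 tab-separated columns, got {len(cols)}"
                )
            rid = cols[0].strip()
            if rid in lineages:
                raise LineageFormatError(f"row {lineno}: duplicate id {rid!r}")
            ranks = [c.strip() for c in cols[1:]]
            ranks += [""] * (6 - len(ranks))
            lineages[rid] = Lineage(*ranks)
    return lineages


def write_lineages(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tphylum\tclass\torder\tfamily\tgenus\tspecies\n")
        for rec in records:
            fh.write(rec.id + "\t" + "\t".join(rec.lineage.ranks()) + "\n")


def load_dataset(fasta_path: str | Path, lineage_path: str | Path) -> list[SequenceRecord]:
    """Join a FASTA file with its lineage table into SequenceRecords.

    Sequences without a lineage row get an all-empty lineage (the taxonomy
    filter removes them downstream).
    """
    lineages = read_lineages(lineage_path)
    return [
        SequenceRecord(rid, seq, lineages.get(rid, Lineage()))
        for rid, seq in read_fasta(fasta_path)
    ]


_ARFF_NEEDS_QUOTE = re.compile(r"[\s,{}'\"%]")


def _arff_quote(value: str) -> str:
    if value == "" or _ARFF_NEEDS_QUOTE.search(value):
        return "'" + value.replace("'", r"\'") + "'"
    return value


def write_arff(vectors, config, relation_name: str, path: str | Path) -> None:
    """Write feature vectors as a Weka ARFF file.

    One numeric attribute per feature — k-mers in lexicographic order, then
    ``norm_length`` and ``gc_percent`` as configured — followed by a nominal
    ``class`` attribute enumerating the genera, then one data row per vector.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("cannot write ARFF from an empty vector list")
    names = config.feature_names()
    for vec in vectors:
        if len(vec.values) != config.n_features:
            raise ValueError(
                f"vector {vec.source_id!r} has {len(vec.values)} values, "
                f"expected {config.n_features} for k={config.k}"
            )
    classes = sorted({vec.label for vec in vectors})
    with open(path, "w") as fh:
        fh.write(f"@relation {_arff_quote(relation_name)}\n\n")
        for name in names:
            fh.write(f"@attribute {name} numeric\n")
        fh.write("@attribute class {" + ",".join(_arff_quote(c) for c in classes) + "}\n")
        fh.write("\n@data\n")
        for vec in vectors:
            row = ",".join(repr(float(v)) for v in vec.values)
            fh.write(row + "," + _arff_quote(vec.label) + "\n")


def save_model(results, path: str | Path) -> None:
    """Serialize a fitted naive Bayes model as versioned plain-text JSON."""
    cfg = results.feature_config
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "k": cfg.k,
        "include_length": cfg.include_length,
        "include_gc": cfg.include_gc,
        "train_avg_length": float(results.train_avg_length),
        "classes": list(results.classes),
        "log_priors": [float(x) for x in results.log_priors],
        "means": [[float(x) for x in row] for row in results.means],
        "variances": [[float(x) for x in row] for row in results.variances],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`; exact round-trip."""
    from .features import FeatureConfig
    from .naive_bayes import GenusNaiveBayesResults

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"unreadable model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path} is not a {MODEL_FORMAT} model file")
    if payload.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"model version {payload.get('version')} unsupported (expected {MODEL_VERSION})"
        )
    required = {"k", "include_length", "include_gc", "train_avg_length",
                "classes", "log_priors", "means", "variances"}
    missing = required - payload.keys()
    if missing:
        raise ModelFormatError(f"model file missing fields: {sorted(missing)}")
    cfg = FeatureConfig(
        k=payload["k"],
        include_length=payload["include_length"],
        include_gc=payload["include_gc"],
    )
    import numpy as np

    return GenusNaiveBayesResults(
        classes=list(payload["classes"]),
        log_priors=np.asarray(payload["log_priors"], dtype=float),
        means=np.asarray(payload["means"], dtype=float),
        variances=np.asarray(payload["variances"], dtype=float),
        feature_config=cfg,
        train_avg_length=float(payload["train_avg_length"]),
    )
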