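"""Database curation: the filter chain that turns raw labeled ITS1 sequences
into a classifier-ready dataset.

Steps, in order: taxonomy filter (genus present, no invalid-taxonomy
markers, species binomial consistent with genus), dereplication at 100 %
identity (exact duplicates and substring containment), length filter
(100-400 nt inclusive), and a per-genus abundance floor (>= 5 by default).
Every step emits an audit entry (input, removed, output counts).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqio import SequenceRecord

__all__ = [
    "CurationConfig",
    "AuditEntry",
    "CurationAudit",
    "filter_taxonomy",
    "filter_length",
    "dereplicate",
    "filter_min_per_genus",
    "run_curation",
]

DEFAULT_REJECT_MARKERS = (
    "incertae sedis",
    "environmental",
    "uncultured",
    "unidentified",
)


@dataclass(frozen=True)
class CurationConfig:
    min_len: int = 100
    max_len: int = 400
    min_per_genus: int = 5
    reject_markers: tuple[str, ...] = DEFAULT_REJECT_MARKERS

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_per_genus < 1:
            raise ValueError("min_per_genus must be >= 1")
        object.__setattr__(
            self, "reject_markers", tuple(m.lower() for m in self.reject_markers)
        )


@dataclass
class AuditEntry:
    """Counts for one curation step; notes hold step-specific detail."""

    step: str
    n_in: int
    n_removed: int
    n_out: int
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_out == self.n_in - self.n_removed


@dataclass
class CurationAudit:
    entries: list[AuditEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.step, e.n_in, e.n_removed, e.n_out) for e in self.entries],
            columns=["step", "n_in", "n_removed", "n_out"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_taxonomy(
    records: Sequence[SequenceRecord], config: CurationConfig
) -> tuple[list[SequenceRecord], AuditEntry]:
    """Drop records with unusable taxonomy.

    A record is kept iff its genus is non-empty, no rank value contains a
    reject marker (case-insensitive), and — when a species is annotated — the
    species is a binomial whose first token equals the genus.
    """
    kept = []
    for rec in records:
        lin = rec.lineage
        if not lin.genus:
            continue
        lowered = [r.lower() for r in lin.ranks()]
        if any(marker in rank for rank in lowered for marker in config.reject_markers):
            continue
        if lin.species:
            tokens = lin.species.split()
            if len(tokens) < 2 or tokens[0] != lin.genus:
                continue
        kept.append(rec)
    entry = AuditEntry("taxonomy", len(records), len(records) - len(kept), len(kept))
    return kept, entry


def filter_length(
    records: Sequence[SequenceRecord], config: CurationConfig
) -> tuple[list[SequenceRecord], AuditEntry]:
    """Keep records with min_len <= length <= max_len (bounds inclusive)."""
    kept = [r for r in records if config.min_len <= r.length <= config.max_len]
    entry = AuditEntry("length", len(records), len(records) - len(kept), len(kept))
    return kept, entry


def dereplicate(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], AuditEntry]:
    """Remove redundancy at 100 % identity.

    A record is removed when its sequence equals, or occurs as a contiguous
    substring of, another record's sequence; the representative of each such
    group is its longest member (ties broken by lexicographically smallest
    id). Survivors keep their input order. Same-strand only: reverse
    complements are not considered identical.
    """
    records = list(records)
    # longest first, then smallest id, so the first container found is the
    # designated representative
    order = sorted(records, key=lambda r: (-r.length, r.id))
    kept_ordered: list[SequenceRecord] = []
    replaced_by: dict[str, str] = {}
    for rec in order:
        rep = None
        for cand in kept_ordered:
            if rec.seq in cand.seq:
                rep = cand
                break
        if rep is None:
            kept_ordered.append(rec)
        else:
            replaced_by[rec.id] = rep.id
    kept_ids = {r.id for r in kept_ordered}
    kept = [r for r in records if r.id in kept_ids]
    by_id = {r.id: r for r in records}
    conflicts = sorted(
        rid
        for rid, rep_id in replaced_by.items()
        if by_id[rid].lineage.genus != by_id[rep_id].lineage.genus
    )
    entry = AuditEntry(
        "dereplicate",
        len(records),
        len(replaced_by),
        len(kept),
        notes={"replaced_by": replaced_by, "label_conflicts": conflicts},
    )
    return kept, entry


def filter_min_per_genus(
    records: Sequence[SequenceRecord],
    config: CurationConfig,
    rank: str = "genus",
) -> tuple[list[SequenceRecord], AuditEntry]:
    """Keep records whose genus (or species, rank='species') has at least
    ``min_per_genus`` records in the input to this step."""
    if rank not in ("genus", "species"):
        raise ValueError(f"rank must be 'genus' or 'species', got {rank!r}")
    key = lambda r: getattr(r.lineage, rank)
    counts = Counter(key(r) for r in records)
    kept = [r for r in records if counts[key(r)] >= config.min_per_genus]
    entry = AuditEntry(
        f"min_per_{rank}", len(records), len(records) - len(kept), len(kept)
    )
    return kept, entry


def run_curation(
    records: Sequence[SequenceRecord],
    config: CurationConfig | None = None,
    floor_rank: str = "genus",
) -> tuple[list[SequenceRecord], CurationAudit]:
    """Full chain: taxonomy -> dereplicate -> length -> per-genus floor.

    The abundance floor runs last because the earlier steps change counts.
    ``floor_rank='species'`` applies the floor per species instead (the
    species-level dataset-reduction variant).
    """
    config = config or CurationConfig()
    audit = CurationAudit()
    kept, entry = filter_taxonomy(records, config)
    audit.entries.append(entry)
    kept, entry = dereplicate(kept)
    audit.entries.append(entry)
    kept, entry = filter_length(kept, config)
    audit.entries.append(entry)
    kept, entry = filter_min_per_genus(kept, config, rank=floor_rank)
    audit.entries.append(entry)
    return kept, audit
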