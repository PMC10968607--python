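"""Reading, standardization and curation of candidate lipoxygenase sequences.

Candidate LOX sequences arrive as protein FASTA.  Curation keeps a sequence
only if it is long enough to plausibly span a LOX domain and if it preserves
enough of the five iron-coordination residues (three His, one Asn, one
Ile/Leu) to be a credible lipoxygenase.  Sequences failing either rule are
reported with the first failing reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .coordination import CoordinationPattern

#: The 20 standard one-letter amino-acid codes plus the ambiguity letter X.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Source(str, enum.Enum):
    """Provenance of a protein record."""

    USER = "user"
    FIXTURE = "fixture"


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate LOX protein sequence.

    Parameters
    ----------
    id : str
        Accession-like identifier, unique within a dataset.
    residues : str
        Uppercase amino-acid string (standard 20 letters plus ``X``).
    organism : str
        Free-text organism / description field.
    source : Source
        Whether the record came from the user or a generated fixture.
    """

    id: str
    residues: str
    organism: str = ""
    source: Source = Source.USER

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: disallowed residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class Decision(str, enum.Enum):
    """Curation outcome for one record."""

    KEPT = "kept"
    REMOVED_FRAGMENT = "removed_fragment"
    REMOVED_FEW_SITES = "removed_few_sites"
    REMOVED_NO_DOMAIN = "removed_no_domain"


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds governing which candidate sequences are kept.

    ``min_sites`` is the minimum number of preserved iron-coordination
    residues (of five); ``min_length`` operationalizes "sequence fragment"
    as anything shorter than a plausible LOX domain.
    """

    min_sites: int = 3
    min_length: int = 200
    require_terminal_hydrophobic: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.min_sites <= 5:
            raise ValueError("min_sites must be in [0, 5]")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


@dataclass
class CurationReport:
    """Per-record curation decisions plus summary counts."""

    decisions: dict[str, Decision] = field(default_factory=dict)

    @property
    def kept_ids(self) -> list[str]:
        return [i for i, d in self.decisions.items() if d is Decision.KEPT]

    @property
    def counts(self) -> dict[Decision, int]:
        out = {d: 0 for d in Decision}
        for d in self.decisions.values():
            out[d] += 1
        return out

    def to_rows(
        self,
        records: Mapping[str, "ProteinRecord"],
        completeness: Mapping[str, int],
    ) -> list[dict[str, object]]:
        """Tabular form (id, decision, length, completeness) for TSV export."""
        return [
            {
                "id": rid,
                "decision": dec.value,
                "length": len(records[rid]),
                "completeness": completeness[rid],
            }
            for rid, dec in self.decisions.items()
        ]


def read_fasta(path: str | Path, source: Source = Source.USER) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the record id and
    the remainder the organism/description.  Sequences are uppercased, and
    gap (``-``, ``.``) and stop (``*``) characters are stripped.

    Raises
    ------
    ValueError
        If the file contains no records or duplicate ids.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id in {path}: {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("-", "").replace(".", "").replace("*", "")
        organism = rec.description[len(rec.id):].strip()
        records.append(
            ProteinRecord(id=rec.id, residues=residues, organism=organism, source=source)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving id and description."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.organism)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def filter_candidates(
    records: Sequence[ProteinRecord],
    patterns: Sequence["CoordinationPattern"],
    config: CurationConfig | None = None,
) -> CurationReport:
    """Apply the inclusion rules to candidate sequences.

    A record is kept iff its length is at least ``config.min_length`` and its
    coordination-pattern completeness is at least ``config.min_sites``.
    Removal reasons are assigned in rule order: fragment first, then too few
    coordination sites.  Completeness 0 is reported as ``removed_no_domain``
    (no recognizable LOX coordination signature at all).  With
    ``require_terminal_hydrophobic`` set, the terminal Ile/Leu site must
    itself be found.

    ``patterns`` must be aligned 1:1 with ``records`` (same ids, same order
    not required).
    """
    from .coordination import SiteRole

    config = config or CurationConfig()
    by_id = {p.record_id: p for p in patterns}
    rec_ids = {r.id for r in records}
    if set(by_id) != rec_ids:
        missing = sorted(rec_ids - set(by_id)) + sorted(set(by_id) - rec_ids)
        raise ValueError(f"records and patterns disagree on ids: {missing}")

    report = CurationReport()
    for rec in records:
        pat = by_id[rec.id]
        if len(rec) < config.min_length:
            report.decisions[rec.id] = Decision.REMOVED_FRAGMENT
        elif pat.completeness == 0 and config.min_sites > 0:
            report.decisions[rec.id] = Decision.REMOVED_NO_DOMAIN
        elif pat.completeness < config.min_sites or (
            config.require_terminal_hydrophobic
            and not pat.site(SiteRole.T5).found
        ):
            report.decisions[rec.id] = Decision.REMOVED_FEW_SITES
        else:
            report.decisions[rec.id] = Decision.KEPT
    return report
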