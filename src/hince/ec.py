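"""Enzyme Commission (EC) labels: parsing, validation, hierarchy prefixes, cleaning.

An EC number is a four-field hierarchical classifier ``class.subclass.
sub-subclass.serial`` (e.g. ``2.1.3.4``).  The first field names the reaction
type (oxidoreductase, transferase, ...), the second the substrate or group
transformed, the third the mechanism, and the fourth the specific activity.
Throughout this package "EC4" means the full four-field label and "EC3 family"
the first three fields.

Cleaning turns a raw annotation table into a single-label corpus by removing
multifunction proteins, malformed or catch-all (``99``) labels, and exact
(EC, sequence) duplicates.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True, order=True)
class ECLabel:
    """A validated four-field EC number."""

    fields: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.fields) != 4:
            raise ValueError(f"EC label needs exactly 4 fields, got {self.fields!r}")
        for f in self.fields:
            if not isinstance(f, int) or f < 1:
                raise ValueError(f"EC fields must be positive integers, got {self.fields!r}")
            if f == 99:
                raise ValueError("EC field 99 (catch-all) is not permitted")

    def __str__(self) -> str:
        return ".".join(str(f) for f in self.fields)

    def prefix(self, depth: int) -> str:
        """Dotted prefix identifier at ``depth`` in 1..4; depth 4 is the full label."""
        return ec_prefix(self, depth)


#: Rejection reason tags produced by :func:`normalize_and_parse`.
REJECT_INCOMPLETE = "incomplete"
REJECT_INVALID = "invalid"
REJECT_FORBIDDEN_99 = "forbidden_99"


@dataclass(frozen=True)
class Rejection:
    """A value (not an exception) explaining why a raw EC string was not accepted."""

    raw: str
    reason: str


_EC_PREFIX_RE = re.compile(r"^\s*(?:EC[:\s]*)?", re.IGNORECASE)


def normalize_and_parse(raw: str) -> ECLabel | Rejection:
    """Parse raw EC text into an :class:`ECLabel`, or return a tagged :class:`Rejection`.

    Normalization strips an optional ``EC`` prefix and surrounding whitespace.
    Rejection reasons: ``incomplete`` (fewer than 4 fields), ``invalid``
    (non-digit field after normalization), ``forbidden_99`` (any field equal
    to 99, the EC "other" catch-all).
    """
    text = _EC_PREFIX_RE.sub("", str(raw)).strip()
    parts = text.split(".")
    if len(parts) < 4:
        return Rejection(raw, REJECT_INCOMPLETE)
    if len(parts) > 4:
        return Rejection(raw, REJECT_INVALID)
    values = []
    for p in parts:
        p = p.strip()
        if not p.isdigit():
            return Rejection(raw, REJECT_INVALID)
        values.append(int(p))
    if any(v == 99 for v in values):
        return Rejection(raw, REJECT_FORBIDDEN_99)
    if any(v < 1 for v in values):
        return Rejection(raw, REJECT_INVALID)
    return ECLabel(tuple(values))


def ec_prefix(label: ECLabel, depth: int) -> str:
    """The first ``depth`` fields of ``label`` as a dotted identifier."""
    if depth not in (1, 2, 3, 4):
        raise ValueError(f"depth must be in 1..4, got {depth}")
    return ".".join(str(f) for f in label.fields[:depth])


@dataclass
class ProteinRecord:
    """One protein: entry id, validated EC label, amino-acid sequence.

    ``evidence_experimental`` records whether the (entry, EC, sequence)
    annotation is experimentally supported; ``None`` means unknown.
    """

    entry: str
    ec: ECLabel
    sequence: str
    evidence_experimental: Optional[bool] = None


#: Disposition tags used in cleaning reports.
DISP_KEPT = "kept"
DISP_MULTIFUNCTION = "removed_multifunction"
DISP_INVALID = "removed_invalid"
DISP_DUPLICATE = "removed_duplicate"


@dataclass
class CleaningReport:
    kept: int = 0
    removed_multifunction: int = 0
    removed_invalid: int = 0
    removed_duplicate: int = 0
    dispositions: list[tuple[str, str]] = field(default_factory=list)  # (entry, tag)

    @property
    def total(self) -> int:
        return (self.kept + self.removed_multifunction
                + self.removed_invalid + self.removed_duplicate)

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "removed_multifunction": self.removed_multifunction,
            "removed_invalid": self.removed_invalid,
            "removed_duplicate": self.removed_duplicate,
            "dispositions": [list(d) for d in self.dispositions],
        }


def clean_records(
    records: Sequence[tuple[str, str, str]],
) -> tuple[list[ProteinRecord], CleaningReport]:
    """Apply the deterministic three-rule cleaning pipeline.

    ``records`` is a list of ``(entry_id, raw_ec_text, sequence)`` rows; an
    entry may appear on several rows (one per annotated EC).  Rules apply in
    order, and each row is counted under the first rule that removes it:

    1. *multifunction*: every row of any entry associated with two or more
       distinct raw EC strings (valid or not) is removed;
    2. *invalid*: rows whose EC fails :func:`normalize_and_parse` are removed;
    3. *duplicate*: among rows sharing an identical (canonical EC, sequence)
       pair, only the first in input order is kept.
    """
    report = CleaningReport()
    # rule 1: group by entry id, count distinct raw EC strings
    ecs_per_entry: dict[str, set[str]] = {}
    for entry, raw_ec, _seq in records:
        ecs_per_entry.setdefault(entry, set()).add(str(raw_ec).strip())
    multifunction = {e for e, ecs in ecs_per_entry.items() if len(ecs) >= 2}

    kept: list[ProteinRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    for entry, raw_ec, seq in records:
        if entry in multifunction:
            report.removed_multifunction += 1
            report.dispositions.append((entry, DISP_MULTIFUNCTION))
            continue
        parsed = normalize_and_parse(raw_ec)
        if isinstance(parsed, Rejection):
            report.removed_invalid += 1
            report.dispositions.append((entry, DISP_INVALID))
            continue
        key = (str(parsed), seq)
        if key in seen_pairs:
            report.removed_duplicate += 1
            report.dispositions.append((entry, DISP_DUPLICATE))
            continue
        seen_pairs.add(key)
        kept.append(ProteinRecord(entry=entry, ec=parsed, sequence=seq))
        report.kept += 1
        report.dispositions.append((entry, DISP_KEPT))
    return kept, report


def label_counts(labels: Iterable[ECLabel], depth: int) -> Counter:
    """Count occurrences of each depth-``depth`` prefix class."""
    return Counter(ec_prefix(ec, depth) for ec in labels)
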