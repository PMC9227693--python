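"""Curated literature library of directional metabolite reports.

A *library* is a collection of clinical metabolomics studies, each reporting
a set of metabolites as up- (+1) or down-regulated (-1) in tumor versus
control samples. Vote counting reduces the library, per sample type, to a
per-metabolite tally (n_up, n_down) that feeds the Beta-binomial posterior
in :mod:`metabarcode.votecount`.

On-disk format is long-form UTF-8 TSV, one row per
(study, sample_type, metabolite, direction), with per-study case/control
subject counts repeated on each row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

SAMPLE_TYPES = ("blood", "tissue", "feces")
PLATFORMS = ("GC-MS", "LC-MS", "NMR", "CE-MS", "multi")

LIBRARY_COLUMNS = [
    "study_id",
    "sample_type",
    "platform",
    "n_case",
    "n_control",
    "metabolite",
    "direction",
]

_DIRECTION_ALIASES = {"+1": 1, "1": 1, "up": 1, "-1": -1, "−1": -1, "down": -1}


class LibraryFormatError(ValueError):
    """Raised when a library file violates the row-level contract."""


@dataclass
class StudyRecord:
    """One clinical study: metadata plus its directional metabolite reports."""

    study_id: str
    sample_type: str
    platform: str
    n_case: int
    n_control: int
    reports: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"study {self.study_id!r}: sample_type {self.sample_type!r} "
                f"not in {SAMPLE_TYPES}"
            )
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"study {self.study_id!r}: platform {self.platform!r} "
                f"not in {PLATFORMS}"
            )
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError(
                f"study {self.study_id!r}: case/control counts must be >= 1"
            )
        seen: set[str] = set()
        for met, direction in self.reports:
            if direction not in (1, -1):
                raise ValueError(
                    f"study {self.study_id!r}: direction for {met!r} must be +1/-1"
                )
            if met in seen:
                raise ValueError(
                    f"study {self.study_id!r}: metabolite {met!r} reported twice"
                )
            seen.add(met)


@dataclass
class MetaboliteVote:
    """Per-metabolite vote tally for one sample type.

    ``n_up``/``n_down`` count the studies reporting the metabolite up- or
    down-regulated; ``frequency`` is their sum (the number of independent
    studies mentioning the metabolite). ``cum_case``/``cum_control`` are the
    cumulative subject counts of the contributing studies.
    """

    metabolite_id: str
    sample_type: str
    n_up: int
    n_down: int
    cum_case: int
    cum_control: int

    @property
    def frequency(self) -> int:
        return self.n_up + self.n_down


def _coerce_direction(value: object, row: int) -> int:
    text = str(value).strip().lower()
    if text in _DIRECTION_ALIASES:
        return _DIRECTION_ALIASES[text]
    raise LibraryFormatError(
        f"row {row}: direction {value!r} not one of +1/-1/up/down"
    )


def load_library(path) -> list[StudyRecord]:
    """Read a long-form TSV library into validated :class:`StudyRecord` s.

    Rows are grouped by (study_id, sample_type); a study assayed on more
    than one sample type yields one record per sample type. Row numbers in
    error messages are 1-based counting the header as row 1.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
    if missing:
        raise LibraryFormatError(f"missing columns: {missing}")

    records: dict[tuple[str, str], StudyRecord] = {}
    seen_rows: set[tuple[str, str, str]] = set()
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2
        direction = _coerce_direction(row["direction"], rowno)
        key = (str(row["study_id"]), str(row["sample_type"]))
        triple = (*key, str(row["metabolite"]))
        if triple in seen_rows:
            raise LibraryFormatError(
                f"row {rowno}: duplicate report of {triple[2]!r} "
                f"by study {triple[0]!r} ({triple[1]})"
            )
        seen_rows.add(triple)
        try:
            n_case = int(row["n_case"])
            n_control = int(row["n_control"])
        except (TypeError, ValueError) as exc:
            raise LibraryFormatError(f"row {rowno}: non-integer subject count") from exc
        if n_case < 1 or n_control < 1:
            raise LibraryFormatError(f"row {rowno}: non-positive subject count")
        if key not in records:
            try:
                records[key] = StudyRecord(
                    study_id=key[0],
                    sample_type=key[1],
                    platform=str(row["platform"]),
                    n_case=n_case,
                    n_control=n_control,
                )
            except ValueError as exc:
                raise LibraryFormatError(f"row {rowno}: {exc}") from exc
        rec = records[key]
        if (rec.n_case, rec.n_control) != (n_case, n_control):
            raise LibraryFormatError(
                f"row {rowno}: inconsistent subject counts within study {key[0]!r}"
            )
        rec.reports.append((str(row["metabolite"]), direction))
    return list(records.values())


def write_library(records: list[StudyRecord], path) -> None:
    """Write records back to the long-form TSV (inverse of :func:`load_library`)."""
    rows = [
        {
            "study_id": rec.study_id,
            "sample_type": rec.sample_type,
            "platform": rec.platform,
            "n_case": rec.n_case,
            "n_control": rec.n_control,
            "metabolite": met,
            "direction": direction,
        }
        for rec in records
        for met, direction in rec.reports
    ]
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def load_alias_map(path) -> dict[str, str]:
    """Read a two-column alias -> canonical-id TSV (columns: alias, kegg_id)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"alias", "kegg_id"}.issubset(frame.columns):
        raise LibraryFormatError("alias map needs columns: alias, kegg_id")
    return dict(zip(frame["alias"], frame["kegg_id"]))


def normalize_ids(
    records: list[StudyRecord],
    mapping: dict[str, str],
    unmapped: str = "keep",
) -> list[StudyRecord]:
    """Replace metabolite names by canonical (KEGG) identifiers.

    Two aliases of one study mapping to the same id are merged when their
    directions agree and raise otherwise — a study may not vote twice on one
    compound. ``unmapped`` is either ``"keep"`` (keep verbatim, warn) or
    ``"drop"``.
    """
    if unmapped not in ("keep", "drop"):
        raise ValueError("unmapped policy must be 'keep' or 'drop'")
    out: list[StudyRecord] = []
    unmapped_names: set[str] = set()
    for rec in records:
        merged: dict[str, int] = {}
        for met, direction in rec.reports:
            if met in mapping:
                canonical = mapping[met]
            elif unmapped == "drop":
                continue
            else:
                unmapped_names.add(met)
                canonical = met
            if canonical in merged:
                if merged[canonical] != direction:
                    raise ValueError(
                        f"study {rec.study_id!r}: aliases of {canonical!r} "
                        "reported with opposite directions"
                    )
                continue
            merged[canonical] = direction
        out.append(replace(rec, reports=list(merged.items())))
    if unmapped_names:
        warnings.warn(
            f"{len(unmapped_names)} metabolite name(s) had no canonical id "
            "and were kept verbatim",
            stacklevel=2,
        )
    return out


def tally_votes(
    records: list[StudyRecord], sample_type: str | None
) -> list[MetaboliteVote]:
    """Count up/down study votes per metabolite within one sample type.

    Each study contributes at most one vote per metabolite regardless of how
    many analytical platforms it used. ``sample_type=None`` pools votes over
    all records passed in (the overall-frequency screen). Returns one tally
    per metabolite seen in at least one study, in first-appearance order.
    """
    if sample_type is not None and sample_type not in SAMPLE_TYPES:
        raise ValueError(f"unknown sample type {sample_type!r}")
    label = sample_type if sample_type is not None else "all"
    tallies: dict[str, MetaboliteVote] = {}
    for rec in records:
        if sample_type is not None and rec.sample_type != sample_type:
            continue
        for met, direction in rec.reports:
            if met not in tallies:
                tallies[met] = MetaboliteVote(met, label, 0, 0, 0, 0)
            vote = tallies[met]
            if direction > 0:
                vote.n_up += 1
            else:
                vote.n_down += 1
            vote.cum_case += rec.n_case
            vote.cum_control += rec.n_control
    return list(tallies.values())


def filter_by_frequency(
    votes: list[MetaboliteVote], min_frequency: int = 3
) -> list[MetaboliteVote]:
    """Keep metabolites reported by at least ``min_frequency`` studies (inclusive)."""
    if min_frequency < 1:
        raise ValueError("min_frequency must be >= 1")
    return [v for v in votes if v.frequency >= min_frequency]


def votes_to_frame(votes: list[MetaboliteVote]) -> pd.DataFrame:
    """Tabulate tallies for export (one row per metabolite)."""
    return pd.DataFrame(
        {
            "metabolite": [v.metabolite_id for v in votes],
            "sample_type": [v.sample_type for v in votes],
            "n_up": [v.n_up for v in votes],
            "n_down": [v.n_down for v in votes],
            "frequency": [v.frequency for v in votes],
            "cum_case": [v.cum_case for v in votes],
            "cum_control": [v.cum_control for v in votes],
        }
    )
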