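"""Input-quality rules for protein feature annotation.

Three aids keep community edits clean before they reach the store:

* coordinate sanity — a positional feature must satisfy
  ``1 <= start <= end <= sequence_length`` (equality allowed, so
  single-residue features such as a phosphosite are legal); the
  non-positional encoding ``start = end = 0`` is also accepted;
* ontology-guided term entry — type-ahead suggestions for the ``type``
  field from the Sequence Ontology (SO), Protein Modification ontology
  (MOD) and BioSapiens annotation vocabulary (BS), and for the
  ``method`` field from the Evidence Code Ontology (ECO);
* protein defaults — ``orientation`` and ``phase`` are genomic fields
  with no meaning on a protein and default to the not-applicable tokens.

Issues are data, not exceptions: :func:`validate_feature` returns every
applicable :class:`ValidationIssue`, so a form can show them all at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources

from .dasgff import Feature
from .errors import InputError

SUGGESTION_LIMIT = 10


class IssueCode(str, Enum):
    START_AFTER_END = "START_AFTER_END"
    OUT_OF_RANGE = "OUT_OF_RANGE"
    NONPOSITIVE_START = "NONPOSITIVE_START"
    MISSING_ID = "MISSING_ID"
    BAD_ENUM = "BAD_ENUM"


@dataclass(frozen=True)
class ValidationIssue:
    code: IssueCode
    field: str
    message: str


@dataclass(frozen=True)
class OntologyTermList:
    """A controlled vocabulary subset: (term_id, term_name) pairs."""

    ontology_id: str  # SO | MOD | BS | ECO
    terms: tuple[tuple[str, str], ...]

    def __post_init__(self):
        ids = [t[0] for t in self.terms]
        if len(ids) != len(set(ids)):
            raise InputError(
                f"duplicate term ids in ontology {self.ontology_id!r}")


def load_term_list(ontology_id: str, path: str | None = None) -> OntologyTermList:
    """Load a two-column TSV (term_id, term_name) term list.

    With no ``path``, the subset bundled with the package is used.
    """
    if path is None:
        ref = resources.files("daswriteback.ontologies") / (
            ontology_id.lower() + ".tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    terms = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        term_id, _, term_name = line.partition("\t")
        terms.append((term_id.strip(), term_name.strip()))
    return OntologyTermList(ontology_id=ontology_id.upper(), terms=tuple(terms))


def load_bundled_ontologies() -> dict[str, OntologyTermList]:
    return {oid: load_term_list(oid) for oid in ("SO", "MOD", "BS", "ECO")}


# ---------------------------------------------------------------------------


def validate_feature(f: Feature, sequence_length: int) -> list[ValidationIssue]:
    """All coordinate/identity issues for a feature on a protein of the
    given length; an empty list means the feature is acceptable."""
    if sequence_length < 1:
        raise InputError(f"sequence_length must be >= 1, got {sequence_length}")
    issues: list[ValidationIssue] = []
    if not f.feature_id:
        issues.append(ValidationIssue(
            IssueCode.MISSING_ID, "feature_id", "feature id must be non-empty"))
    if f.orientation not in ("+", "-", "0"):
        issues.append(ValidationIssue(
            IssueCode.BAD_ENUM, "orientation",
            f"orientation {f.orientation!r} not one of +, -, 0"))
    if f.phase not in ("0", "1", "2", "-"):
        issues.append(ValidationIssue(
            IssueCode.BAD_ENUM, "phase",
            f"phase {f.phase!r} not one of 0, 1, 2, -"))
    if f.start == 0 and f.end == 0:
        return issues  # non-positional: no range checks
    if f.start < 1:
        issues.append(ValidationIssue(
            IssueCode.NONPOSITIVE_START, "start",
            f"start must be >= 1, got {f.start}"))
    if f.start > f.end:
        issues.append(ValidationIssue(
            IssueCode.START_AFTER_END, "start",
            f"start {f.start} is after end {f.end}"))
    if f.end > sequence_length:
        issues.append(ValidationIssue(
            IssueCode.OUT_OF_RANGE, "end",
            f"end {f.end} exceeds the protein length {sequence_length}"))
    return issues


_FIELD_ONTOLOGIES = {"type": ("SO", "MOD", "BS"), "method": ("ECO",)}


def suggest_terms(field: str, prefix: str,
                  lists: dict[str, OntologyTermList],
                  limit: int = SUGGESTION_LIMIT) -> list[tuple[str, str]]:
    """Type-ahead suggestions: case-insensitive prefix matches on term
    name or term id, ranked by name, capped at ``limit``.

    ``field="type"`` searches SO+MOD+BS; ``field="method"`` searches ECO.
    An empty prefix yields the first ``limit`` terms by name.
    """
    try:
        ontology_ids = _FIELD_ONTOLOGIES[field]
    except KeyError:
        raise InputError(f"unknown field {field!r}; expected 'type' or 'method'")
    needle = prefix.lower()
    hits = []
    for oid in ontology_ids:
        term_list = lists.get(oid)
        if term_list is None:
            continue
        for term_id, term_name in term_list.terms:
            if (term_name.lower().startswith(needle)
                    or term_id.lower().startswith(needle)):
                hits.append((term_id, term_name))
    hits.sort(key=lambda t: (t[1].lower(), t[0]))
    return hits[:limit]


def apply_protein_defaults(f: Feature) -> Feature:
    """Fill unset orientation/phase with the not-applicable tokens
    (``"0"`` and ``"-"``); set values are left untouched.  Idempotent."""
    orientation = f.orientation if f.orientation else "0"
    phase = f.phase if f.phase else "-"
    return replace(f, orientation=orientation, phase=phase)
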