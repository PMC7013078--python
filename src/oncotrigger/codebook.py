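"""Trigger codebook: code-set matching and the shipped default definitions.

A trigger is defined by one or more *clauses*; a candidate event requires at
least one matching code from every clause within the trigger's co-occurrence
window. Clauses are lists of :class:`CodeSet` objects (match any one), so a
single clinical concept can be expressed across coding systems (e.g. the
transfusion clause matches ICD-9 V58.2, its ICD-10 companion Z51.31, or
CPT 36430). Exposure-linkage rules — which cancer-directed treatments can
"cause" a trigger, how long after treatment it may appear, and how long one
event persists — live beside the definitions.

Defaults ship as versioned YAML resources under ``oncotrigger/resources``
and can be partially overridden from a user file via :func:`load_codebook`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from pathlib import Path

import yaml

from .claims_model import ALL_SYSTEMS, DRUG, normalize_code

CATEGORIES = frozenset(
    {
        "general_care",
        "vital_signs",
        "orders",
        "laboratories",
        "medication_related",
        "consultations",
    }
)

EXPOSURE_TYPES = ("surgery", "radiation", "chemotherapy")

CONSTRAINT_FLAGS = frozenset(
    {
        "requires_not_poa",
        "new_use_only",
        "not_same_day_as_surgery",
        "post_radiation_only",
        "post_index_surgery_30d",
    }
)  # plus "requires_specialty:<name>" parameterized flags


class CodebookError(ValueError):
    """Malformed codebook content."""


@dataclass(frozen=True)
class CodeSet:
    """A set of normalized codes within one coding system.

    Matching is exact-or-prefix with explicit exclusions; exclusions apply
    after a positive exact/prefix match.
    """

    system: str
    exact: frozenset[str] = frozenset()
    prefixes: frozenset[str] = frozenset()
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.system not in ALL_SYSTEMS:
            raise CodebookError(f"unknown coding system {self.system!r}")
        if not self.exact and not self.prefixes:
            raise CodebookError("code set has neither exact codes nor prefixes")


def match_code(code: str, system: str, cs: CodeSet) -> bool:
    """True iff ``code`` (normalized) in ``system`` matches the code set."""
    if system != cs.system:
        return False
    if code in cs.exclusions:
        return False
    if code in cs.exact:
        return True
    return any(code.startswith(p) for p in cs.prefixes)


def match_any(code: str, system: str, codesets) -> bool:
    return any(match_code(code, system, cs) for cs in codesets)


@dataclass(frozen=True)
class TriggerDefinition:
    trigger_id: str
    display_name: str
    category: str
    clauses: tuple[tuple[CodeSet, ...], ...]
    co_occurrence_days: int = 0
    constraints: frozenset[str] = frozenset()
    supporting: tuple[CodeSet, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CodebookError(
                f"{self.trigger_id}: unknown category {self.category!r}"
            )
        if not self.clauses or any(not clause for clause in self.clauses):
            raise CodebookError(f"{self.trigger_id}: empty clause")
        if self.co_occurrence_days < 0:
            raise CodebookError(f"{self.trigger_id}: negative co_occurrence_days")
        for flag in self.constraints:
            if flag in CONSTRAINT_FLAGS or flag.startswith("requires_specialty:"):
                continue
            raise CodebookError(f"{self.trigger_id}: unknown constraint {flag!r}")

    @property
    def required_specialty(self) -> str | None:
        for flag in self.constraints:
            if flag.startswith("requires_specialty:"):
                return flag.split(":", 1)[1].lower()
        return None


@dataclass(frozen=True)
class ExposureRule:
    trigger_id: str
    eligible_exposures: frozenset[str]
    lookback_days: int
    persistence_days: int

    def __post_init__(self) -> None:
        if not self.eligible_exposures:
            raise CodebookError(f"{self.trigger_id}: no eligible exposures")
        bad = self.eligible_exposures - set(EXPOSURE_TYPES)
        if bad:
            raise CodebookError(f"{self.trigger_id}: unknown exposure types {bad}")
        if self.lookback_days < 1 or self.persistence_days < 1:
            raise CodebookError(
                f"{self.trigger_id}: lookback/persistence must be >= 1 day"
            )


@dataclass
class Codebook:
    """Trigger definitions plus all auxiliary code sets the pipeline needs."""

    triggers: dict[str, TriggerDefinition]
    rules: dict[str, ExposureRule]
    treatments: dict[str, tuple[CodeSet, ...]]
    cancers: dict[str, tuple[CodeSet, ...]]
    recurrence: tuple[CodeSet, ...]
    secondary_malignancy: tuple[CodeSet, ...]
    new_use_lookback_days: int = 90
    version: int = 1

    def __post_init__(self) -> None:
        missing = set(self.triggers) ^ set(self.rules)
        if missing:
            raise CodebookError(f"triggers without rules (or vice versa): {missing}")
        _check_treatment_disjointness(self.treatments)


def _check_treatment_disjointness(treatments) -> None:
    """Every treatment code must classify as exactly one exposure type.

    Checked per coding system on exact codes and prefixes (a prefix of one
    type nested under another type's prefix is also an overlap).
    """
    types = list(treatments)
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            for cs_a in treatments[a]:
                for cs_b in treatments[b]:
                    if cs_a.system != cs_b.system:
                        continue
                    inter = set(cs_a.exact) & set(cs_b.exact)
                    if inter:
                        raise CodebookError(
                            f"treatment sets {a}/{b} share codes {sorted(inter)}"
                        )
                    for p in cs_a.prefixes:
                        for q in cs_b.prefixes:
                            if p.startswith(q) or q.startswith(p):
                                raise CodebookError(
                                    f"treatment sets {a}/{b} have nested "
                                    f"prefixes {p}/{q}"
                                )
                    for code in cs_a.exact:
                        if any(code.startswith(q) for q in cs_b.prefixes):
                            raise CodebookError(
                                f"treatment code {code} ({a}) falls under a "
                                f"{b} prefix"
                            )
                    for code in cs_b.exact:
                        if any(code.startswith(p) for p in cs_a.prefixes):
                            raise CodebookError(
                                f"treatment code {code} ({b}) falls under a "
                                f"{a} prefix"
                            )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _norm_set(values, system: str) -> frozenset[str]:
    return frozenset(normalize_code(str(v), system) for v in values or ())


def _parse_codeset(entry: dict) -> CodeSet:
    system = entry.get("system")
    if system not in ALL_SYSTEMS:
        raise CodebookError(f"code set with unknown system {system!r}")
    return CodeSet(
        system=system,
        exact=_norm_set(entry.get("exact"), system),
        prefixes=_norm_set(entry.get("prefixes"), system),
        exclusions=_norm_set(entry.get("exclusions"), system),
    )


def _parse_trigger(trigger_id: str, block: dict) -> tuple[TriggerDefinition, ExposureRule]:
    try:
        clauses = tuple(
            tuple(_parse_codeset(cs) for cs in clause)
            for clause in block.get("clauses", ())
        )
        definition = TriggerDefinition(
            trigger_id=trigger_id,
            display_name=block.get("display_name", trigger_id),
            category=block.get("category", "general_care"),
            clauses=clauses,
            co_occurrence_days=int(block.get("co_occurrence_days", 0)),
            constraints=frozenset(block.get("constraints", ())),
            supporting=tuple(
                _parse_codeset(cs) for cs in block.get("supporting", ())
            ),
        )
        rule = ExposureRule(
            trigger_id=trigger_id,
            eligible_exposures=frozenset(block.get("exposures", ())),
            lookback_days=int(block.get("lookback_days", 30)),
            persistence_days=int(block.get("persistence_days", 30)),
        )
    except CodebookError as exc:
        raise CodebookError(f"trigger {trigger_id!r}: {exc}") from exc
    return definition, rule


def _read_resource(name: str) -> dict:
    ref = importlib_resources.files("oncotrigger.resources").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_codebook() -> Codebook:
    """The shipped default codebook: 16 triggers plus auxiliary code sets."""
    trig_doc = _read_resource("triggers.yaml")
    treat_doc = _read_resource("treatments.yaml")
    cancer_doc = _read_resource("cancer.yaml")

    triggers: dict[str, TriggerDefinition] = {}
    rules: dict[str, ExposureRule] = {}
    for trigger_id, block in trig_doc["triggers"].items():
        definition, rule = _parse_trigger(trigger_id, block)
        triggers[trigger_id] = definition
        rules[trigger_id] = rule

    treatments = {
        etype: tuple(_parse_codeset(cs) for cs in entries)
        for etype, entries in treat_doc["treatments"].items()
    }
    cancers = {
        ctype: tuple(_parse_codeset(cs) for cs in entries)
        for ctype, entries in cancer_doc["cancers"].items()
    }
    return Codebook(
        triggers=triggers,
        rules=rules,
        treatments=treatments,
        cancers=cancers,
        recurrence=tuple(_parse_codeset(cs) for cs in cancer_doc["recurrence"]),
        secondary_malignancy=tuple(
            _parse_codeset(cs) for cs in cancer_doc["secondary_malignancy"]
        ),
        new_use_lookback_days=int(trig_doc.get("new_use_lookback_days", 90)),
        version=int(trig_doc.get("version", 1)),
    )


_OVERRIDABLE_RULE_FIELDS = {"exposures", "lookback_days", "persistence_days"}


def load_codebook(path: str | Path | None = None) -> Codebook:
    """Load the default codebook with field-wise overrides from a user file.

    The override file mirrors the shipped ``triggers.yaml`` layout. Known
    trigger_ids are merged field by field (only the named fields change);
    unknown trigger_ids define new triggers and must be complete. A
    ``treatments:`` section, if present, replaces treatment code sets per
    exposure type.
    """
    book = default_codebook()
    if path is None:
        return book
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    triggers = dict(book.triggers)
    rules = dict(book.rules)
    for trigger_id, block in (doc.get("triggers") or {}).items():
        if trigger_id in triggers:
            base_def = triggers[trigger_id]
            base_rule = rules[trigger_id]
            merged = {
                "display_name": base_def.display_name,
                "category": base_def.category,
                "co_occurrence_days": base_def.co_occurrence_days,
                "constraints": sorted(base_def.constraints),
                "exposures": sorted(base_rule.eligible_exposures),
                "lookback_days": base_rule.lookback_days,
                "persistence_days": base_rule.persistence_days,
            }
            merged.update(block)
            if "clauses" not in block:
                # clauses unchanged: rebuild around the existing tuple
                rule = ExposureRule(
                    trigger_id=trigger_id,
                    eligible_exposures=frozenset(merged["exposures"]),
                    lookback_days=int(merged["lookback_days"]),
                    persistence_days=int(merged["persistence_days"]),
                )
                definition = replace(
                    base_def,
                    display_name=merged["display_name"],
                    category=merged["category"],
                    co_occurrence_days=int(merged["co_occurrence_days"]),
                    constraints=frozenset(merged["constraints"]),
                )
            else:
                definition, rule = _parse_trigger(trigger_id, merged)
            triggers[trigger_id] = definition
            rules[trigger_id] = rule
        else:
            definition, rule = _parse_trigger(trigger_id, block)
            triggers[trigger_id] = definition
            rules[trigger_id] = rule

    treatments = dict(book.treatments)
    for etype, entries in (doc.get("treatments") or {}).items():
        if etype not in EXPOSURE_TYPES:
            raise CodebookError(f"unknown exposure type {etype!r}")
        treatments[etype] = tuple(_parse_codeset(cs) for cs in entries)

    return Codebook(
        triggers=triggers,
        rules=rules,
        treatments=treatments,
        cancers=book.cancers,
        recurrence=book.recurrence,
        secondary_malignancy=book.secondary_malignancy,
        new_use_lookback_days=int(
            doc.get("new_use_lookback_days", book.new_use_lookback_days)
        ),
        version=book.version,
    )
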