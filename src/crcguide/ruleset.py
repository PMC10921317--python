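"""Row-enumerated decision tables: format, loading, enumeration, validation.

The guideline is encoded as *row-enumerated* tables: one row per fully
specified scenario, so the printed scenario counts of the guideline are
directly checkable properties of the file.  A ruleset file declares

* a feature vocabulary (lesion risk-feature codes, mapped to lesion class),
* a modified-Charlson configuration (condition weights + age points),
* discriminator variables whose values select a table within a section
  (e.g. the lesion profile of the latest colonoscopy), and
* four sections — screening, first_surveillance, subsequent_surveillance,
  cessation — each a list of tables; every table declares its own input
  variables (with bins) and its scenario rows.

Completeness and disjointness are verified by enumerating the cross-product
of every table's declared variable domains and checking that each point
matches exactly one row (:func:`validate_ruleset`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .errors import EnumerationError, RulesetParseError, RulesetReferenceError

SECTIONS = ("screening", "first_surveillance", "subsequent_surveillance", "cessation")


@dataclass(frozen=True)
class Band:
    """One bin of an integer-valued variable; ``max`` None means open-ended."""

    label: str
    min: int
    max: Optional[int]

    def contains(self, value: int) -> bool:
        if value < self.min:
            return False
        return self.max is None or value <= self.max


@dataclass(frozen=True)
class VariableDecl:
    """Declaration of one decision-table input variable.

    kind 'integer-range' variables carry bins; 'category' and 'boolean'
    variables carry an explicit value list.  ``source`` names the case field
    (or derived quantity) that feeds the variable.  ``absent_label`` is the
    label used when the source value is absent, and ``na_if`` restricts the
    variable to that label exactly when another variable takes a given value
    (e.g. a diagnosis-age bin is 'na' iff the relative count bin is '0').
    """

    name: str
    kind: str  # integer-range | category | boolean
    source: str
    bands: tuple[Band, ...] = ()
    values: tuple[str, ...] = ()
    absent_label: Optional[str] = None
    na_if: Optional[tuple[str, str]] = None  # (other variable, its value)

    def labels(self) -> tuple[str, ...]:
        """All labels this variable can take, absent-label included."""
        if self.kind == "integer-range":
            base = tuple(b.label for b in self.bands)
        else:
            base = self.values
        if self.absent_label is not None and self.absent_label not in base:
            base = base + (self.absent_label,)
        return base

    def band_for(self, value: int) -> Optional[str]:
        for b in self.bands:
            if b.contains(value):
                return b.label
        return None


@dataclass(frozen=True)
class Rule:
    """One scenario row: a conjunction of (variable = value | variable in set)
    clauses plus the recommendation payload (provenance excluded; it is the
    row's own identity)."""

    row_id: str
    when: dict[str, object]  # var -> label or list of labels (in-set)
    recommendation: dict[str, object]

    def matches(self, point: dict[str, str]) -> bool:
        for var, expected in self.when.items():
            actual = point.get(var)
            if isinstance(expected, (list, tuple)):
                if actual not in expected:
                    return False
            elif actual != expected:
                return False
        return True


@dataclass(frozen=True)
class Table:
    """One decision table: selector values (discriminators), local variable
    declarations, and row-enumerated scenarios."""

    table_id: str
    select: dict[str, str]
    variables: tuple[VariableDecl, ...]
    rows: tuple[Rule, ...]

    def variable(self, name: str) -> VariableDecl:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass
class Ruleset:
    """A loaded guideline ruleset (header + four sections of tables)."""

    meta: dict
    vocabulary: dict[str, str]  # feature code -> lesion class
    charlson_weights: dict[str, int]
    charlson_age_points: tuple[Band, ...]  # band label unused; points in meta
    charlson_age_point_values: dict[str, int]
    min_assessment_age: int
    discriminators: dict[str, tuple[str, ...]]
    sections: dict[str, tuple[Table, ...]]

    def section(self, name: str) -> tuple[Table, ...]:
        if name not in self.sections:
            raise KeyError(f"unknown section {name!r}")
        return self.sections[name]


@dataclass
class ValidationReport:
    """Completeness/disjointness report for a ruleset.

    ``gaps`` are enumerated points matched by no row; ``overlaps`` are
    (point, row ids) matched by more than one row; ``unreachable`` rows match
    no enumerated point.  ``counts`` are distinct scenario rows per section
    and ``headline_count`` the guideline's advertised total (screening +
    subsequent-surveillance scenarios).
    """

    counts: dict[str, int] = field(default_factory=dict)
    table_counts: dict[str, int] = field(default_factory=dict)
    gaps: list[dict] = field(default_factory=list)
    overlaps: list[dict] = field(default_factory=list)
    unreachable: list[dict] = field(default_factory=list)
    structural_defects: list[str] = field(default_factory=list)

    @property
    def headline_count(self) -> int:
        return self.counts.get("screening", 0) + self.counts.get("subsequent_surveillance", 0)

    @property
    def ok(self) -> bool:
        return not (self.gaps or self.overlaps or self.unreachable or self.structural_defects)

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "counts": self.counts,
            "headline_count": self.headline_count,
            "table_counts": self.table_counts,
            "gaps": self.gaps,
            "overlaps": self.overlaps,
            "unreachable": self.unreachable,
            "structural_defects": self.structural_defects,
        }

    def to_text(self) -> str:
        lines = ["ruleset validation: " + ("OK" if self.ok else "DEFECTS FOUND")]
        for sec, n in self.counts.items():
            lines.append(f"  {sec}: {n} scenario rows")
        lines.append(f"  headline scenario count: {self.headline_count}")
        for label, entries in (("gap", self.gaps), ("overlap", self.overlaps),
                               ("unreachable row", self.unreachable)):
            for e in entries:
                lines.append(f"  {label}: {e}")
        for d in self.structural_defects:
            lines.append(f"  structural: {d}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Parsing

def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise RulesetParseError(f"{path}: {msg}")


def _parse_bands(raw, path: str) -> tuple[Band, ...]:
    bands = []
    for i, b in enumerate(raw):
        _require(isinstance(b, dict) and "label" in b and "min" in b, f"{path}[{i}]",
                 "band needs 'label' and 'min'")
        bands.append(Band(label=str(b["label"]), min=int(b["min"]),
                          max=None if b.get("max") is None else int(b["max"])))
    return tuple(bands)


def _parse_variable(raw, path: str) -> VariableDecl:
    _require(isinstance(raw, dict), path, "variable declaration must be a mapping")
    for key in ("name", "kind", "source"):
        _require(key in raw, path, f"missing '{key}'")
    kind = raw["kind"]
    _require(kind in ("integer-range", "category", "boolean"), f"{path}.kind",
             f"unknown kind {kind!r}")
    bands: tuple[Band, ...] = ()
    values: tuple[str, ...] = ()
    if kind == "integer-range":
        bands = _parse_bands(raw.get("bands", []), f"{path}.bands")
    elif kind == "boolean":
        values = ("true", "false")
    else:
        values = tuple(str(v) for v in raw.get("values", []))
        _require(len(values) > 0, f"{path}.values", "category variable needs values")
    na_if = None
    if raw.get("na_if") is not None:
        na_if = (str(raw["na_if"]["var"]), str(raw["na_if"]["equals"]))
    return VariableDecl(
        name=str(raw["name"]), kind=kind, source=str(raw["source"]),
        bands=bands, values=values,
        absent_label=None if raw.get("absent_label") is None else str(raw["absent_label"]),
        na_if=na_if,
    )


def _parse_table(raw, path: str, discriminators: dict[str, tuple[str, ...]]) -> Table:
    _require(isinstance(raw, dict), path, "table must be a mapping")
    _require("id" in raw, path, "missing 'id'")
    _require("rows" in raw and isinstance(raw["rows"], list) and raw["rows"],
             f"{path}.rows", "table needs a non-empty row list")
    variables = tuple(_parse_variable(v, f"{path}.vars[{i}]")
                      for i, v in enumerate(raw.get("vars", [])))
    var_names = {v.name for v in variables}
    select = {str(k): str(v) for k, v in (raw.get("select") or {}).items()}
    for k, v in select.items():
        _require(k in discriminators, f"{path}.select",
                 f"selector variable {k!r} is not a declared discriminator")
        _require(v in discriminators[k], f"{path}.select",
                 f"value {v!r} not in domain of discriminator {k!r}")
    rows = []
    for i, r in enumerate(raw["rows"]):
        rpath = f"{path}.rows[{i}]"
        _require(isinstance(r, dict) and "id" in r and "when" in r and "rec" in r,
                 rpath, "row needs 'id', 'when' and 'rec'")
        when = {}
        for var, val in r["when"].items():
            if var not in var_names:
                raise RulesetReferenceError(
                    f"{rpath}.when: predicate references undeclared variable {var!r}")
            when[str(var)] = ([str(x) for x in val] if isinstance(val, (list, tuple))
                              else str(val))
        rows.append(Rule(row_id=str(r["id"]), when=when, recommendation=dict(r["rec"])))
    return Table(table_id=str(raw["id"]), select=select,
                 variables=variables, rows=tuple(rows))


def load_ruleset(source: str | Path | dict) -> Ruleset:
    """Parse and structurally validate a ruleset from YAML text, a path, or
    an already-decoded mapping.

    Raises :class:`RulesetParseError` (naming the offending document path) on
    schema violations and :class:`RulesetReferenceError` when a rule predicate
    references an undeclared variable.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if (
            isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                         and Path(source).exists())
        ) else str(source)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise RulesetParseError(f"document: not valid YAML ({e})") from e
    _require(isinstance(doc, dict), "document", "top level must be a mapping")
    for key in ("sections", "manifest", "charlson", "vocabulary"):
        _require(key in doc, "document", f"missing '{key}'")

    charlson = doc["charlson"]
    _require("weights" in charlson and "age_points" in charlson, "charlson",
             "needs 'weights' and 'age_points'")
    weights = {str(k): int(v) for k, v in charlson["weights"].items()}
    _require(all(w >= 0 for w in weights.values()), "charlson.weights",
             "weights must be >= 0")
    age_bands = _parse_bands(charlson["age_points"], "charlson.age_points")
    age_point_values = {str(b["label"]): int(b["points"])
                        for b in charlson["age_points"]}
    # age bands must partition [0, 120]
    cursor = 0
    for b in sorted(age_bands, key=lambda b: b.min):
        _require(b.min == cursor, "charlson.age_points",
                 f"bands must partition [0,120]; gap/overlap at {b.min}")
        cursor = (b.max if b.max is not None else 120) + 1
    _require(cursor == 121, "charlson.age_points", "bands must cover ages up to 120")

    discriminators = {str(k): tuple(str(x) for x in v)
                      for k, v in (doc.get("discriminators") or {}).items()}

    manifest = {str(k): int(v) for k, v in doc["manifest"].items()}
    sections_raw = doc["sections"]
    _require(isinstance(sections_raw, dict) and sections_raw, "sections",
             "sections manifest must be a non-empty mapping")
    sections: dict[str, tuple[Table, ...]] = {}
    seen_row_ids: set[str] = set()
    for sec in SECTIONS:
        _require(sec in sections_raw, f"sections.{sec}", "section missing")
        tables = tuple(
            _parse_table(t, f"sections.{sec}[{i}]", discriminators)
            for i, t in enumerate(sections_raw[sec])
        )
        _require(len(tables) == manifest.get(sec, -1), f"sections.{sec}",
                 f"table count {len(tables)} does not match manifest "
                 f"{manifest.get(sec)}")
        for t in tables:
            for r in t.rows:
                _require(r.row_id not in seen_row_ids, f"sections.{sec}",
                         f"duplicate row id {r.row_id!r}")
                seen_row_ids.add(r.row_id)
        sections[sec] = tables

    cess = doc.get("cessation") or {}
    return Ruleset(
        meta=dict(doc.get("meta") or {}),
        vocabulary={str(k): str(v) for k, v in doc["vocabulary"].items()},
        charlson_weights=weights,
        charlson_age_points=age_bands,
        charlson_age_point_values=age_point_values,
        min_assessment_age=int(cess.get("min_assessment_age", 75)),
        discriminators=discriminators,
        sections=sections,
    )


# ---------------------------------------------------------------------------
# Enumeration

def _table_points(table: Table) -> list[dict[str, str]]:
    """Cross-product of a table's declared variable domains, applicability
    constraints applied, selector values merged in."""
    domains = []
    for v in table.variables:
        labels = v.labels()
        if not labels:
            raise EnumerationError(
                f"table {table.table_id}: variable {v.name!r} has an "
                "unbounded/empty domain and cannot be enumerated")
        domains.append((v, labels))
    points = []
    for combo in itertools.product(*(labels for _, labels in domains)):
        point = dict(table.select)
        for (v, _), label in zip(domains, combo):
            point[v.name] = label
        # conditional applicability: var == absent_label iff na_if holds
        ok = True
        for v, _ in domains:
            if v.na_if is None or v.absent_label is None:
                continue
            other, value = v.na_if
            should_be_na = point.get(other) == value
            if (point[v.name] == v.absent_label) != should_be_na:
                ok = False
                break
        if ok:
            points.append(point)
    return points


def enumerate_scenarios(ruleset: Ruleset, section: str) -> list[dict[str, str]]:
    """All input points of a section: the union over its tables of each
    table's declared cross-product (selectors included), deduplicated and in
    deterministic lexicographic order."""
    tables = ruleset.section(section)
    seen = set()
    points = []
    for t in tables:
        for p in _table_points(t):
            key = tuple(sorted(p.items()))
            if key not in seen:
                seen.add(key)
                points.append(p)
    points.sort(key=lambda p: tuple(sorted(p.items())))
    return points


# ---------------------------------------------------------------------------
# Validation

def validate_ruleset(ruleset: Ruleset) -> ValidationReport:
    """Exhaustively check completeness and disjointness of every table.

    For every enumerated point of every table, the point must match exactly
    one row of that table; zero matches are reported as gaps, multiple
    matches as overlaps.  Rows matching no point are unreachable.  Where a
    section is split across tables by discriminator variables, the selector
    combinations must tile the discriminator domain exactly once.
    """
    report = ValidationReport()
    for sec in SECTIONS:
        tables = ruleset.section(sec)
        report.counts[sec] = sum(len(t.rows) for t in tables)
        selectors_seen: dict[tuple, str] = {}
        sel_vars: set[str] = set()
        for t in tables:
            report.table_counts[t.table_id] = len(t.rows)
            sel_vars.update(t.select)
            sel_key = tuple(sorted(t.select.items()))
            if sel_key in selectors_seen:
                report.structural_defects.append(
                    f"{sec}: tables {selectors_seen[sel_key]} and {t.table_id} "
                    f"share selector {dict(sel_key)}")
            selectors_seen[sel_key] = t.table_id
            matched_rows: set[str] = set()
            for point in _table_points(t):
                hits = [r.row_id for r in t.rows if r.matches(point)]
                local = {k: v for k, v in point.items() if k not in t.select}
                if not hits:
                    report.gaps.append({"table": t.table_id, "point": local})
                elif len(hits) > 1:
                    report.overlaps.append(
                        {"table": t.table_id, "rows": sorted(hits), "point": local})
                matched_rows.update(hits)
            for r in t.rows:
                if r.row_id not in matched_rows:
                    report.unreachable.append({"table": t.table_id, "row": r.row_id})
        # discriminator combinations must be covered exactly once
        if sel_vars:
            expected = set(itertools.product(
                *(ruleset.discriminators[v] for v in sorted(sel_vars))))
            actual = set()
            for t in tables:
                combo = tuple(t.select.get(v) for v in sorted(sel_vars))
                if None in combo:
                    report.structural_defects.append(
                        f"{sec}: table {t.table_id} does not set all selector "
                        f"variables {sorted(sel_vars)}")
                else:
                    actual.add(combo)
            for missing in sorted(expected - actual):
                report.structural_defects.append(
                    f"{sec}: no table for selector combination "
                    f"{dict(zip(sorted(sel_vars), missing))}")
    return report


def iter_rows(ruleset: Ruleset, section: str) -> Iterable[tuple[Table, Rule]]:
    for t in ruleset.section(section):
        for r in t.rows:
            yield t, r
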