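"""BEL-subset data model, parser and serializer.

The curation dialect handled here is the small slice of the Biological
Expression Language (BEL 2.x) needed to encode heme/coagulation knowledge:
``term relation term`` statements over nine entity functions, six causal or
associative relations, and ``SET``/``UNSET`` blocks carrying the citation,
evidence text and experimental-context annotations (cell type, species,
setting, heme dose, administration route, binding affinity).

Nested statements (an object that is itself a statement), protein
modifications, fusions and translocations are outside the subset and are
rejected with a diagnostic naming the offending line.  The grammar is
documented in ``docs/bel_subset.md``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "BelTerm",
    "AnnotationSet",
    "BelStatement",
    "BelDocument",
    "DocumentHeader",
    "ParseIssue",
    "BelParseError",
    "EXCLUDED",
    "parse_term",
    "parse_statement",
    "parse_document",
    "serialize_term",
    "serialize_statement",
    "serialize_document",
    "normalize_entity",
    "normalize_document",
    "HEME_SYNONYMS",
    "HEME_FORMULATION_BLOCKLIST",
    "RELATIONS",
    "FUNCTIONS",
]

# ---------------------------------------------------------------------------
# vocabulary

FUNCTIONS = (
    "protein",
    "gene",
    "rna",
    "mirna",
    "abundance",
    "complex",
    "bioProcess",
    "pathology",
    "reaction",
)

#: short BEL function keywords -> canonical function names
_FUNC_ALIASES = {
    "p": "protein",
    "proteinAbundance": "protein",
    "g": "gene",
    "geneAbundance": "gene",
    "r": "rna",
    "rnaAbundance": "rna",
    "m": "mirna",
    "microRNAAbundance": "mirna",
    "a": "abundance",
    "abundance": "abundance",
    "complex": "complex",
    "complexAbundance": "complex",
    "bp": "bioProcess",
    "biologicalProcess": "bioProcess",
    "path": "pathology",
    "pathology": "pathology",
    "rxn": "reaction",
    "reaction": "reaction",
}

_FUNC_TO_KEYWORD = {
    "protein": "p",
    "gene": "g",
    "rna": "r",
    "mirna": "m",
    "abundance": "a",
    "complex": "complex",
    "bioProcess": "bp",
    "pathology": "path",
    "reaction": "rxn",
}

RELATIONS = (
    "increases",
    "directlyIncreases",
    "decreases",
    "directlyDecreases",
    "association",
    "regulates",
)

_RELATION_ALIASES = {
    "->": "increases",
    "=>": "directlyIncreases",
    "-|": "decreases",
    "=|": "directlyDecreases",
    "--": "association",
    "reg": "regulates",
    **{r: r for r in RELATIONS},
}

_RELATION_TO_SYMBOL = {
    "increases": "->",
    "directlyIncreases": "=>",
    "decreases": "-|",
    "directlyDecreases": "=|",
    "association": "--",
    "regulates": "reg",
}

NAMESPACES = ("HGNC", "CHEBI", "MESH", "GO", "TEXT")

SETTINGS = ("in_vitro", "in_vivo", "ex_vivo")
ROUTES = ("incubation", "intravenous", "retroorbital", "other")
DOSE_UNITS = ("µM", "mM", "nmol", "µmol/kg", "mg/kg")
KD_UNITS = ("nM", "µM")


class BelParseError(ValueError):
    """Raised for malformed BEL text; carries line/token context when known."""


class _Excluded:
    """Singleton marker returned for blocklisted heme formulations."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "EXCLUDED"

    def __bool__(self) -> bool:
        return False


EXCLUDED = _Excluded()


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BelTerm:
    """One BEL term: a namespaced entity or a complex/reaction of terms.

    Complex and reaction components are stored sorted by canonical key, so
    two terms that differ only in component order compare equal and share a
    key.  ``activity`` records the ``act(...)`` molecular-activity modifier.
    """

    function: str
    namespace: str = ""
    name: str = ""
    components: tuple["BelTerm", ...] = ()
    activity: bool = False

    def __post_init__(self) -> None:
        if self.function not in FUNCTIONS:
            raise ValueError(f"unknown BEL function {self.function!r}")
        if self.function in ("complex", "reaction"):
            if not self.components:
                raise ValueError(f"{self.function} term requires components")
            ordered = tuple(sorted(self.components, key=lambda t: t.key))
            object.__setattr__(self, "components", ordered)
        else:
            if self.components:
                raise ValueError("leaf terms cannot carry components")
            if not self.namespace or not self.name:
                raise ValueError("leaf terms require namespace and name")

    @property
    def is_leaf(self) -> bool:
        return self.function not in ("complex", "reaction")

    @property
    def key(self) -> str:
        """Deterministic canonical key; case- and order-insensitive."""
        if self.is_leaf:
            return f"{self.function}:{self.namespace}:{self.name.casefold()}"
        inner = ",".join(c.key for c in self.components)
        return f"{self.function}({inner})"

    def walk(self):
        """Yield this term and, recursively, every component term."""
        yield self
        for c in self.components:
            yield from c.walk()


@dataclass
class AnnotationSet:
    """Experimental-context annotations attached to one statement.

    Dose and K_D are structured (value + unit, plus an ``up_to`` qualifier for
    doses reported as upper bounds); anything the parser cannot interpret is
    preserved verbatim in ``extras`` so no curated context is lost.
    """

    cell_type: str | None = None
    species: str | None = None
    setting: str | None = None
    dose_value: float | None = None
    dose_unit: str | None = None
    dose_qualifier: str | None = None
    route: str | None = None
    kd_value: float | None = None
    kd_unit: str | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.setting is not None and self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.route is not None and self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.dose_value is not None and self.dose_unit is None:
            raise ValueError("dose_value requires dose_unit")
        if self.kd_value is not None:
            if self.kd_unit is None:
                raise ValueError("kd_value requires kd_unit")
            if self.kd_value <= 0:
                raise ValueError("kd_value must be positive")
        if self.dose_qualifier is not None and self.dose_qualifier not in (
            "exact",
            "up_to",
        ):
            raise ValueError(f"unknown dose qualifier {self.dose_qualifier!r}")

    def is_empty(self) -> bool:
        return self == AnnotationSet()


@dataclass
class BelStatement:
    subject: BelTerm
    relation: str
    object: BelTerm
    citation: str = "NA"
    evidence: str = ""
    annotations: AnnotationSet = field(default_factory=AnnotationSet)

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if not re.fullmatch(r"\d+|NA", self.citation):
            raise ValueError(f"citation must be a PMID or 'NA': {self.citation!r}")

    @property
    def dedup_key(self) -> tuple[str, str, str, str, str]:
        """Identity used for edge de-duplication across documents."""
        return (
            self.subject.key,
            self.relation,
            self.object.key,
            self.citation,
            self.evidence,
        )


@dataclass
class DocumentHeader:
    name: str = ""
    version: str = ""
    namespaces: dict[str, str] = field(default_factory=dict)


@dataclass
class ParseIssue:
    line_number: int
    message: str
    token: str = ""
    severity: str = "error"  # "error" | "warning"


@dataclass
class BelDocument:
    statements: list[BelStatement] = field(default_factory=list)
    header: DocumentHeader = field(default_factory=DocumentHeader)
    issues: list[ParseIssue] = field(default_factory=list)
    #: line accounting: (n_statements, n_errors, n_other) sums to input lines
    line_counts: tuple[int, int, int] = (0, 0, 0)

    @property
    def errors(self) -> list[ParseIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ParseIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def same_statements(self, other: "BelDocument") -> bool:
        """Statement-multiset equality, the round-trip identity."""
        a = sorted(map(_statement_sort_key, self.statements))
        b = sorted(map(_statement_sort_key, other.statements))
        return a == b


def _statement_sort_key(s: BelStatement) -> tuple:
    ann = s.annotations
    return s.dedup_key + (
        ann.cell_type or "",
        ann.species or "",
        ann.setting or "",
        repr(ann.dose_value),
        ann.dose_unit or "",
        ann.dose_qualifier or "",
        ann.route or "",
        repr(ann.kd_value),
        ann.kd_unit or "",
        tuple(sorted(ann.extras.items())),
    )


# ---------------------------------------------------------------------------
# term parsing (recursive descent)

_IDENT_RE = re.compile(r"[A-Za-z0-9_][A-Za-z0-9_.\-]*")


class _TermParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> BelParseError:
        return BelParseError(f"{message} at position {self.pos} in {self.text!r}")

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        self.skip_ws()
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1

    def ident(self) -> str:
        self.skip_ws()
        m = _IDENT_RE.match(self.text, self.pos)
        if not m:
            raise self.error("expected identifier")
        self.pos = m.end()
        return m.group(0)

    def quoted_or_ident(self) -> str:
        self.skip_ws()
        if self.peek() == '"':
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted string")
                ch = self.text[self.pos]
                if ch == "\\" and self.pos + 1 < len(self.text):
                    out.append(self.text[self.pos + 1])
                    self.pos += 2
                    continue
                if ch == '"':
                    self.pos += 1
                    break
                out.append(ch)
                self.pos += 1
            return "".join(out)
        return self.ident()

    def term(self) -> BelTerm:
        self.skip_ws()
        keyword = self.ident()
        if keyword == "act":
            self.expect("(")
            inner = self.term()
            self.expect(")")
            if not inner.is_leaf and inner.function != "complex":
                raise self.error("act() applies to molecular abundances")
            return replace(inner, activity=True)
        function = _FUNC_ALIASES.get(keyword)
        if function is None:
            raise self.error(f"unknown BEL function {keyword!r}")
        self.expect("(")
        if function in ("complex", "reaction"):
            components = [self.term()]
            self.skip_ws()
            while self.peek() == ",":
                self.pos += 1
                components.append(self.term())
                self.skip_ws()
            if len(components) < 2 and function == "complex":
                raise self.error("complex() requires at least two components")
            self.expect(")")
            return BelTerm(function=function, components=tuple(components))
        namespace = self.ident()
        self.expect(":")
        name = self.quoted_or_ident()
        if not name:
            raise self.error("empty entity name")
        self.expect(")")
        return BelTerm(function=function, namespace=namespace, name=name)


def parse_term(text: str) -> BelTerm:
    """Parse a single BEL term expression such as ``complex(a(CHEBI:heme), p(HGNC:PROC))``."""
    parser = _TermParser(text)
    term = parser.term()
    parser.skip_ws()
    if parser.pos != len(text):
        raise parser.error("trailing text after term")
    return term


def serialize_term(term: BelTerm) -> str:
    keyword = _FUNC_TO_KEYWORD[term.function]
    if term.is_leaf:
        name = term.name
        if not _IDENT_RE.fullmatch(name):
            name = '"' + name.replace("\\", "\\\\").replace('"', '\\"') + '"'
        body = f"{keyword}({term.namespace}:{name})"
    else:
        inner = ", ".join(serialize_term(c) for c in term.components)
        body = f"{keyword}({inner})"
    return f"act({body})" if term.activity else body


# ---------------------------------------------------------------------------
# statement parsing


def _split_statement(line: str) -> tuple[str, str, str]:
    """Split ``subject relation object`` at parenthesis depth zero."""
    depth = 0
    in_quote = False
    i = 0
    tokens = sorted(_RELATION_ALIASES, key=len, reverse=True)
    while i < len(line):
        ch = line[i]
        if ch == '"' and (i == 0 or line[i - 1] != "\\"):
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif depth == 0 and ch.isspace():
                j = i
                while j < len(line) and line[j].isspace():
                    j += 1
                rest = line[j:]
                for tok in tokens:
                    if rest.startswith(tok):
                        after = rest[len(tok):]
                        if after[:1].isspace():
                            return line[:i].strip(), tok, after.strip()
                i = j
                continue
        i += 1
    raise BelParseError(f"no relation found in statement: {line!r}")


def parse_statement(
    line: str,
    citation: str = "NA",
    evidence: str = "",
    annotations: AnnotationSet | None = None,
) -> BelStatement:
    subject_text, relation_token, object_text = _split_statement(line)
    relation = _RELATION_ALIASES[relation_token]
    if object_text.startswith("("):
        raise BelParseError(
            "nested statements (object is itself a statement) are outside the "
            f"supported subset: {line!r}"
        )
    subject = parse_term(subject_text)
    obj = parse_term(object_text)
    return BelStatement(
        subject=subject,
        relation=relation,
        object=obj,
        citation=citation,
        evidence=evidence,
        annotations=annotations or AnnotationSet(),
    )


# ---------------------------------------------------------------------------
# annotation state machine

_KNOWN_ANNOTATION_KEYS = {
    "celltype": "cell_type",
    "species": "species",
    "setting": "setting",
    "dose": "dose",
    "route": "route",
    "kd": "kd",
}

_SETTING_VALUES = {
    "in vitro": "in_vitro",
    "in_vitro": "in_vitro",
    "in vivo": "in_vivo",
    "in_vivo": "in_vivo",
    "ex vivo": "ex_vivo",
    "ex_vivo": "ex_vivo",
}

_DOSE_RE = re.compile(
    r"^(?:(?P<upto>up\s+to)\s+)?(?P<value>\d+(?:\.\d+)?)\s*"
    r"(?P<unit>µM|uM|mM|nmol|µmol/kg|umol/kg|mg/kg)$"
)
_KD_RE = re.compile(r"^~?\s*(?P<value>\d+(?:\.\d+)?)\s*(?P<unit>nM|µM|uM)$")


def _normalize_unit(unit: str) -> str:
    return unit.replace("uM", "µM").replace("umol", "µmol")


class _AnnotationState:
    """Mutable SET/UNSET state threaded through a document parse."""

    def __init__(self) -> None:
        self.citation = "NA"
        self.evidence = ""
        self.fields: dict[str, object] = {}
        self.extras: dict[str, str] = {}

    def snapshot(self) -> AnnotationSet:
        return AnnotationSet(extras=dict(self.extras), **self.fields)

    def apply_set(self, key: str, value: str, line_no: int, issues: list[ParseIssue]) -> None:
        lowered = key.casefold()
        if lowered == "citation":
            if not re.fullmatch(r"\d+|NA", value):
                issues.append(
                    ParseIssue(line_no, f"citation must be a PMID or NA: {value!r}", value)
                )
                return
            self.citation = value
        elif lowered == "evidence" or lowered == "support":
            self.evidence = value
        elif lowered == "celltype":
            self.fields["cell_type"] = value
        elif lowered == "species":
            self.fields["species"] = value
        elif lowered == "setting":
            setting = _SETTING_VALUES.get(value.casefold())
            if setting is None:
                issues.append(
                    ParseIssue(line_no, f"unknown Setting value {value!r}", value, "warning")
                )
                self.extras["Setting"] = value
            else:
                self.fields["setting"] = setting
        elif lowered == "dose":
            m = _DOSE_RE.match(value.strip())
            if m is None:
                # keep unparseable dose text verbatim and flag it
                issues.append(
                    ParseIssue(line_no, f"unparseable dose {value!r}", value, "warning")
                )
                self.extras["Dose"] = value
            else:
                self.fields["dose_value"] = float(m.group("value"))
                self.fields["dose_unit"] = _normalize_unit(m.group("unit"))
                self.fields["dose_qualifier"] = "up_to" if m.group("upto") else "exact"
                self.extras.pop("Dose", None)
        elif lowered == "route":
            route = value.strip().casefold()
            self.fields["route"] = route if route in ROUTES else "other"
            if route not in ROUTES:
                self.extras["Route"] = value
        elif lowered == "kd":
            m = _KD_RE.match(value.strip())
            if m is None:
                issues.append(
                    ParseIssue(line_no, f"unparseable KD {value!r}", value, "warning")
                )
                self.extras["KD"] = value
            else:
                self.fields["kd_value"] = float(m.group("value"))
                self.fields["kd_unit"] = _normalize_unit(m.group("unit"))
        else:
            issues.append(
                ParseIssue(
                    line_no,
                    f"unknown annotation key {key!r} preserved verbatim",
                    key,
                    "warning",
                )
            )
            self.extras[key] = value

    def apply_unset(self, key: str) -> None:
        lowered = key.casefold()
        if lowered == "all":
            self.__init__()
        elif lowered == "citation":
            self.citation = "NA"
        elif lowered in ("evidence", "support"):
            self.evidence = ""
        elif lowered == "celltype":
            self.fields.pop("cell_type", None)
        elif lowered == "species":
            self.fields.pop("species", None)
        elif lowered == "setting":
            self.fields.pop("setting", None)
            self.extras.pop("Setting", None)
        elif lowered == "dose":
            for f in ("dose_value", "dose_unit", "dose_qualifier"):
                self.fields.pop(f, None)
            self.extras.pop("Dose", None)
        elif lowered == "route":
            self.fields.pop("route", None)
            self.extras.pop("Route", None)
        elif lowered == "kd":
            for f in ("kd_value", "kd_unit"):
                self.fields.pop(f, None)
            self.extras.pop("KD", None)
        else:
            self.extras.pop(key, None)


_SET_RE = re.compile(r'^SET\s+(?P<key>[A-Za-z_][A-Za-z0-9_]*)\s*=\s*(?P<value>.+)$')
_SET_DOC_RE = re.compile(
    r'^SET\s+DOCUMENT\s+(?P<key>[A-Za-z_][A-Za-z0-9_]*)\s*=\s*(?P<value>.+)$'
)
_UNSET_RE = re.compile(r"^UNSET\s+(?P<key>[A-Za-z_][A-Za-z0-9_]*|ALL)$")
_DEFINE_NS_RE = re.compile(
    r'^DEFINE\s+NAMESPACE\s+(?P<ns>[A-Za-z0-9_]+)\s+AS\s+(?P<rest>.+)$'
)


def _unquote(value: str) -> str:
    value = value.strip()
    if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
        return value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
    return value


def parse_document(text: str, strict: bool = False) -> BelDocument:
    """Parse a BEL script into a :class:`BelDocument`.

    In strict mode the first malformed statement raises
    :class:`BelParseError`; otherwise errors are collected in
    ``document.issues`` with their line numbers and parsing continues.  Every
    input line is accounted for as a statement, an error, or an
    annotation/blank/comment line.
    """
    doc = BelDocument()
    state = _AnnotationState()
    n_statements = n_errors = n_other = 0
    lines = text.splitlines()
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("//"):
            n_other += 1
            continue
        m = _SET_DOC_RE.match(line)
        if m:
            key, value = m.group("key"), _unquote(m.group("value"))
            if key.casefold() == "name":
                doc.header.name = value
            elif key.casefold() == "version":
                doc.header.version = value
            n_other += 1
            continue
        m = _DEFINE_NS_RE.match(line)
        if m:
            doc.header.namespaces[m.group("ns")] = _unquote(m.group("rest"))
            n_other += 1
            continue
        m = _SET_RE.match(line)
        if m:
            state.apply_set(m.group("key"), _unquote(m.group("value")), line_no, doc.issues)
            n_other += 1
            continue
        m = _UNSET_RE.match(line)
        if m:
            state.apply_unset(m.group("key"))
            n_other += 1
            continue
        try:
            statement = parse_statement(
                line,
                citation=state.citation,
                evidence=state.evidence,
                annotations=state.snapshot(),
            )
        except (BelParseError, ValueError) as exc:
            if strict:
                raise BelParseError(f"line {line_no}: {exc}") from exc
            doc.issues.append(ParseIssue(line_no, str(exc), line))
            n_errors += 1
            continue
        doc.statements.append(statement)
        n_statements += 1
    doc.line_counts = (n_statements, n_errors, n_other)
    return doc


# ---------------------------------------------------------------------------
# serialization


def _format_number(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(value)


def _annotation_setmap(statement: BelStatement) -> dict[str, str]:
    """The SET key/value pairs that reproduce a statement's context."""
    ann = statement.annotations
    out: dict[str, str] = {}
    out["Citation"] = statement.citation
    if statement.evidence:
        out["Evidence"] = statement.evidence
    if ann.cell_type is not None:
        out["CellType"] = ann.cell_type
    if ann.species is not None:
        out["Species"] = ann.species
    if ann.setting is not None:
        out["Setting"] = ann.setting.replace("_", " ")
    if ann.dose_value is not None:
        prefix = "up to " if ann.dose_qualifier == "up_to" else ""
        out["Dose"] = f"{prefix}{_format_number(ann.dose_value)} {ann.dose_unit}"
    if ann.route is not None:
        out["Route"] = ann.route
    if ann.kd_value is not None:
        out["KD"] = f"{_format_number(ann.kd_value)} {ann.kd_unit}"
    for key in sorted(ann.extras):
        out[key] = ann.extras[key]
    return out


def serialize_statement(statement: BelStatement) -> str:
    return (
        f"{serialize_term(statement.subject)} "
        f"{_RELATION_TO_SYMBOL[statement.relation]} "
        f"{serialize_term(statement.object)}"
    )


def _quote(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def serialize_document(doc: BelDocument) -> str:
    """Serialize to BEL script text; SET lines are emitted only on change."""
    lines: list[str] = []
    header = doc.header
    if header.name:
        lines.append(f"SET DOCUMENT Name = {_quote(header.name)}")
    if header.version:
        lines.append(f"SET DOCUMENT Version = {_quote(header.version)}")
    for ns in sorted(header.namespaces):
        lines.append(f"DEFINE NAMESPACE {ns} AS {_quote(header.namespaces[ns])}")
    if lines:
        lines.append("")
    active: dict[str, str] = {}
    for statement in doc.statements:
        wanted = _annotation_setmap(statement)
        for key in sorted(set(active) - set(wanted)):
            lines.append(f"UNSET {key}")
        for key, value in wanted.items():
            if active.get(key) != value:
                lines.append(f"SET {key} = {_quote(value)}")
        active = wanted
        lines.append(serialize_statement(statement))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# entity normalization

#: heme synonyms curated to the single canonical entity a(CHEBI:heme)
HEME_SYNONYMS = frozenset({"heme", "hemin", "hematin"})
#: therapeutic heme formulations excluded from curation
HEME_FORMULATION_BLOCKLIST = frozenset({"heme arginate", "heme-albumin"})

_CANONICAL_HEME = BelTerm(function="abundance", namespace="CHEBI", name="heme")


def normalize_entity(
    term: BelTerm,
    synonyms: frozenset[str] | set[str] = HEME_SYNONYMS,
    blocklist: frozenset[str] | set[str] = HEME_FORMULATION_BLOCKLIST,
) -> BelTerm | _Excluded:
    """Map heme synonyms to the canonical heme entity; exclude formulations.

    Idempotent; terms outside the synonym and blocklist tables pass through
    unchanged.  Only leaf terms are normalized here — use
    :func:`normalize_document` to apply the rule recursively through
    complexes.
    """
    if not term.is_leaf:
        raise ValueError("normalize_entity applies to leaf terms")
    name = term.name.casefold()
    if name in blocklist:
        return EXCLUDED
    if name in synonyms:
        return replace(_CANONICAL_HEME, activity=term.activity)
    return term


def _normalize_term(term: BelTerm, synonyms, blocklist) -> BelTerm | _Excluded:
    if term.is_leaf:
        return normalize_entity(term, synonyms, blocklist)
    components = []
    for c in term.components:
        normalized = _normalize_term(c, synonyms, blocklist)
        if normalized is EXCLUDED:
            return EXCLUDED
        components.append(normalized)
    return replace(term, components=tuple(components))


def normalize_document(
    doc: BelDocument,
    synonyms: frozenset[str] | set[str] = HEME_SYNONYMS,
    blocklist: frozenset[str] | set[str] = HEME_FORMULATION_BLOCKLIST,
) -> tuple[BelDocument, int]:
    """Normalize every entity in a document; drop blocklisted statements.

    Returns the normalized document and the number of statements excluded
    because a term (or a complex component) named a heme formulation.
    """
    kept: list[BelStatement] = []
    n_excluded = 0
    for statement in doc.statements:
        subject = _normalize_term(statement.subject, synonyms, blocklist)
        obj = _normalize_term(statement.object, synonyms, blocklist)
        if subject is EXCLUDED or obj is EXCLUDED:
            n_excluded += 1
            continue
        kept.append(replace(statement, subject=subject, object=obj))
    out = BelDocument(
        statements=kept,
        header=doc.header,
        issues=list(doc.issues),
        line_counts=doc.line_counts,
    )
    return out, n_excluded
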