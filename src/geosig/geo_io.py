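"""Domain types and file I/O for GEO-style expression studies.

The central objects are :class:`Study` (series-level metadata, per-sample
metadata and a genes x samples expression matrix), :class:`Submission`
(a curator's choice of control and perturbation samples with an entity
label) and :class:`Signature` (the differential-expression result: a full
per-gene coefficient vector plus discrete up/down gene lists).

Three text dialects are supported for studies:

``tsv_bundle``
    A directory with ``study.tsv`` (key<TAB>value), ``samples.tsv``
    (one row per sample) and ``expression.tsv`` (genes x samples).
``series_matrix``
    A single file in the style of GEO series-matrix exports:
    ``!Series_*`` and ``!Sample_*`` header lines followed by the matrix
    between ``!series_matrix_table_begin`` / ``!series_matrix_table_end``.
``soft_simplified``
    ``^SERIES`` / ``^SAMPLE`` blocks of ``!key = value`` lines followed
    by a ``^MATRIX`` block.

Gene identifiers are assumed to be platform-collapsed symbols already;
probe-to-gene collapsing is a documented pre-step outside this package.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

ORGANISMS = ("human", "mouse", "rat")
SIGNATURE_TYPES = ("gene", "disease", "drug")
PERTURBATION_DIRECTIONS = ("knockdown", "knockout", "overexpression", "mutation", "other")

_DIALECTS = ("series_matrix", "soft_simplified", "tsv_bundle")


def parse_scan_date(text: str | None) -> _dt.date | None:
    """Parse a scan date as ISO-8601 or MM/DD/YY (CEL convention).

    Unparseable or empty input yields ``None``: dates are never fabricated.
    """
    if text is None:
        return None
    text = text.strip()
    if not text or text.lower() in {"na", "none", "null"}:
        return None
    for fmt in ("%Y-%m-%d", "%m/%d/%y", "%m/%d/%Y"):
        try:
            return _dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    return None


@dataclass
class Sample:
    """One profiled sample (GSM-like) with its free-text metadata."""

    sample_id: str
    title: str = ""
    description: str = ""
    characteristics: str = ""
    source_name: str = ""
    scan_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise IntegrityError("sample_id must be nonempty")
        if isinstance(self.scan_date, str):
            self.scan_date = parse_scan_date(self.scan_date)

    def text_fields(self) -> dict[str, str]:
        return {
            "title": self.title,
            "description": self.description,
            "characteristics": self.characteristics,
            "source_name": self.source_name,
        }


@dataclass
class Study:
    """A GEO-like series: metadata, samples and one expression matrix.

    ``expression`` is a DataFrame with unique gene symbols as the index
    and sample ids as columns; every column must name a declared sample.
    """

    study_id: str
    title: str = ""
    summary: str = ""
    keywords: str = ""
    organism: str = "human"
    samples: list[Sample] = field(default_factory=list)
    expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise IntegrityError("study_id must be nonempty")
        if self.organism not in ORGANISMS:
            raise IntegrityError(
                f"organism {self.organism!r} not in {ORGANISMS}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"duplicate sample ids in study {self.study_id}")
        if self.expression is not None:
            if self.expression.index.has_duplicates:
                dup = self.expression.index[self.expression.index.duplicated()][0]
                raise IntegrityError(f"duplicate gene identifier {dup!r}")
            declared = set(ids)
            for col in self.expression.columns:
                if col not in declared:
                    raise IntegrityError(
                        f"expression column {col!r} has no declared sample "
                        f"in study {self.study_id}"
                    )
            if self.expression.columns.has_duplicates:
                raise IntegrityError("duplicate expression columns")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def text(self) -> str:
        return " ".join(t for t in (self.title, self.summary, self.keywords) if t)


@dataclass
class Submission:
    """A curator's control/perturbation sample selection for one study."""

    curator_id: str
    study_id: str
    control_ids: frozenset[str]
    perturbation_ids: frozenset[str]
    signature_type: str
    entity_label: str
    perturbation_direction: str | None = None

    def __post_init__(self) -> None:
        self.control_ids = frozenset(self.control_ids)
        self.perturbation_ids = frozenset(self.perturbation_ids)
        if self.signature_type not in SIGNATURE_TYPES:
            raise IntegrityError(
                f"signature_type {self.signature_type!r} not in {SIGNATURE_TYPES}"
            )
        if self.perturbation_direction is not None and (
            self.perturbation_direction not in PERTURBATION_DIRECTIONS
        ):
            raise IntegrityError(
                f"perturbation_direction {self.perturbation_direction!r} invalid"
            )

    def group_key(self) -> tuple:
        """Identity of the contrast; used for duplicate collapsing."""
        return (
            self.study_id,
            tuple(sorted(self.control_ids)),
            tuple(sorted(self.perturbation_ids)),
        )

    def swapped(self) -> "Submission":
        return Submission(
            curator_id=self.curator_id,
            study_id=self.study_id,
            control_ids=self.perturbation_ids,
            perturbation_ids=self.control_ids,
            signature_type=self.signature_type,
            entity_label=self.entity_label,
            perturbation_direction=self.perturbation_direction,
        )


@dataclass
class Signature:
    """A perturbation-versus-control differential expression signature.

    ``coefficients`` holds the full per-gene statistic; ``up_genes`` and
    ``down_genes`` are the discrete top sets served for set-based
    similarity queries.
    """

    signature_id: str
    study_id: str
    control_ids: frozenset[str]
    perturbation_ids: frozenset[str]
    signature_type: str
    entity_label: str
    coefficients: dict[str, float]
    up_genes: list[str]
    down_genes: list[str]
    method: str = "cd"
    provenance: str = "manual"
    confidence: float | None = None

    def __post_init__(self) -> None:
        self.control_ids = frozenset(self.control_ids)
        self.perturbation_ids = frozenset(self.perturbation_ids)
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise IntegrityError(f"up/down overlap: {sorted(overlap)[:3]}")
        for g in self.up_genes:
            if g not in self.coefficients:
                raise IntegrityError(f"up gene {g!r} missing from coefficients")
            if not self.coefficients[g] > 0:
                raise IntegrityError(f"up gene {g!r} has non-positive coefficient")
        for g in self.down_genes:
            if g not in self.coefficients:
                raise IntegrityError(f"down gene {g!r} missing from coefficients")
            if not self.coefficients[g] < 0:
                raise IntegrityError(f"down gene {g!r} has non-negative coefficient")
        if self.provenance not in ("manual", "auto"):
            raise IntegrityError(f"provenance {self.provenance!r} invalid")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise IntegrityError("confidence must lie in [0, 1]")

    def gene_set_pair(self):
        from .similarity import GeneSetPair

        return GeneSetPair(up=frozenset(self.up_genes), down=frozenset(self.down_genes))


@dataclass
class Vocabulary:
    """A controlled vocabulary: canonical terms plus alias -> canonical map."""

    kind: str
    terms: frozenset[str]
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = frozenset(self.terms)
        for alias, canon in self.synonyms.items():
            if canon not in self.terms:
                raise IntegrityError(
                    f"synonym {alias!r} maps to unknown term {canon!r}"
                )
        self._lower_terms = {t.lower(): t for t in self.terms}
        self._lower_syn = {a.lower(): c for a, c in self.synonyms.items()}

    def canonicalize(self, name: str) -> str | None:
        """Map a raw label to its canonical term, or None if unrecognized."""
        low = name.strip().lower()
        if low in self._lower_terms:
            return self._lower_terms[low]
        return self._lower_syn.get(low)

    def __contains__(self, name: str) -> bool:
        return self.canonicalize(name) is not None


def read_vocabulary(path: str | Path, kind: str) -> Vocabulary:
    """Read a vocabulary file: one term per line, ``alias<TAB>canonical``
    lines define synonyms."""
    terms: set[str] = set()
    synonyms: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            terms.add(parts[0])
        elif len(parts) == 2:
            synonyms[parts[0]] = parts[1]
        else:
            raise ParseError(f"{path}:{lineno}: expected 1 or 2 fields")
    return Vocabulary(kind=kind, terms=frozenset(terms), synonyms=synonyms)


# ---------------------------------------------------------------------------
# Study readers / writers


def read_study(path: str | Path, dialect: str) -> Study:
    """Read a study file (or directory for ``tsv_bundle``) into a Study.

    Raises :class:`ParseError` on malformed input and
    :class:`IntegrityError` if the parsed pieces violate Study invariants
    (for example an expression column with no declared sample).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file or directory: {path}")
    if dialect == "tsv_bundle":
        return _read_tsv_bundle(path)
    if dialect == "series_matrix":
        return _read_series_matrix(path)
    return _read_soft_simplified(path)


def write_study(study: Study, path: str | Path, dialect: str) -> None:
    """Write a Study in the named dialect (inverse of :func:`read_study`)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    if dialect == "tsv_bundle":
        _write_tsv_bundle(study, path)
    elif dialect == "series_matrix":
        _write_series_matrix(study, path)
    else:
        _write_soft_simplified(study, path)


_SAMPLE_COLUMNS = [
    "sample_id",
    "title",
    "description",
    "characteristics",
    "source_name",
    "scan_date",
]


def _read_expression_table(lines: list[str], origin: str) -> pd.DataFrame:
    if not lines:
        raise ParseError(f"{origin}: empty expression table")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{origin}: expression header needs >= 2 columns")
    cols = header[1:]
    genes, rows = [], []
    for i, line in enumerate(lines[1:], 2):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{origin}: row {i} has {len(parts)} fields, expected {len(header)}"
            )
        genes.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{origin}: row {i}: non-numeric value ({exc})") from None
    return pd.DataFrame(rows, index=genes, columns=cols)


def _read_tsv_bundle(path: Path) -> Study:
    if not path.is_dir():
        raise ParseError(f"tsv_bundle expects a directory: {path}")
    meta_path = path / "study.tsv"
    samples_path = path / "samples.tsv"
    expr_path = path / "expression.tsv"
    for p in (meta_path, samples_path):
        if not p.exists():
            raise ParseError(f"missing {p.name} in bundle {path}")
    meta: dict[str, str] = {}
    for lineno, line in enumerate(meta_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise ParseError(f"{meta_path}:{lineno}: expected key<TAB>value")
        key, _, value = line.partition("\t")
        meta[key] = value
    samples = []
    sample_lines = samples_path.read_text().splitlines()
    if not sample_lines:
        raise ParseError(f"{samples_path}: empty")
    header = sample_lines[0].split("\t")
    for lineno, line in enumerate(sample_lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{samples_path}:{lineno}: field count mismatch")
        rec = dict(zip(header, parts))
        samples.append(
            Sample(
                sample_id=rec.get("sample_id", ""),
                title=rec.get("title", ""),
                description=rec.get("description", ""),
                characteristics=rec.get("characteristics", ""),
                source_name=rec.get("source_name", ""),
                scan_date=parse_scan_date(rec.get("scan_date")),
            )
        )
    expression = None
    if expr_path.exists():
        expression = _read_expression_table(
            expr_path.read_text().splitlines(), str(expr_path)
        )
    return Study(
        study_id=meta.get("study_id", ""),
        title=meta.get("title", ""),
        summary=meta.get("summary", ""),
        keywords=meta.get("keywords", ""),
        organism=meta.get("organism", "human"),
        samples=samples,
        expression=expression,
    )


def _write_tsv_bundle(study: Study, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "study_id": study.study_id,
        "title": study.title,
        "summary": study.summary,
        "keywords": study.keywords,
        "organism": study.organism,
    }
    (path / "study.tsv").write_text(
        "".join(f"{k}\t{v}\n" for k, v in meta.items())
    )
    lines = ["\t".join(_SAMPLE_COLUMNS)]
    for s in study.samples:
        lines.append(
            "\t".join(
                [
                    s.sample_id,
                    s.title,
                    s.description,
                    s.characteristics,
                    s.source_name,
                    s.scan_date.isoformat() if s.scan_date else "",
                ]
            )
        )
    (path / "samples.tsv").write_text("\n".join(lines) + "\n")
    if study.expression is not None:
        _write_expression_table(study.expression, path / "expression.tsv")


def _write_expression_table(expr: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ID_REF\t" + "\t".join(expr.columns) + "\n")
        for gene, row in expr.iterrows():
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _quote(value: str) -> str:
    return '"' + value.replace('"', "'") + '"'


def _unquote(value: str) -> str:
    value = value.strip()
    if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
        return value[1:-1]
    return value


def _read_series_matrix(path: Path) -> Study:
    series: dict[str, str] = {}
    sample_rows: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        if not raw.strip():
            continue
        if raw.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if raw.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(raw)
            continue
        if raw.startswith("!Series_"):
            key, _, value = raw.partition("\t")
            series[key[len("!Series_"):]] = _unquote(value)
        elif raw.startswith("!Sample_"):
            key, *values = raw.split("\t")
            sample_rows[key[len("!Sample_"):]] = [_unquote(v) for v in values]
        else:
            raise ParseError(f"{path}:{lineno}: unrecognized line {raw[:40]!r}")
    accessions = sample_rows.get("geo_accession")
    if not accessions:
        raise ParseError(f"{path}: missing !Sample_geo_accession line")
    n = len(accessions)

    def row(key: str) -> list[str]:
        values = sample_rows.get(key, [""] * n)
        if len(values) != n:
            raise ParseError(f"{path}: !Sample_{key} has {len(values)} fields, expected {n}")
        return values

    samples = [
        Sample(
            sample_id=accessions[i],
            title=row("title")[i],
            description=row("description")[i],
            characteristics=row("characteristics_ch1")[i],
            source_name=row("source_name_ch1")[i],
            scan_date=parse_scan_date(row("scan_date")[i]),
        )
        for i in range(n)
    ]
    expression = _read_expression_table(table_lines, str(path)) if table_lines else None
    return Study(
        study_id=series.get("geo_accession", ""),
        title=series.get("title", ""),
        summary=series.get("summary", ""),
        keywords=series.get("keywords", ""),
        organism=series.get("organism", "human"),
        samples=samples,
        expression=expression,
    )


def _write_series_matrix(study: Study, path: Path) -> None:
    lines = [
        "!Series_geo_accession\t" + _quote(study.study_id),
        "!Series_title\t" + _quote(study.title),
        "!Series_summary\t" + _quote(study.summary),
        "!Series_keywords\t" + _quote(study.keywords),
        "!Series_organism\t" + _quote(study.organism),
    ]

    def sample_line(key: str, values: Iterable[str]) -> str:
        return "!Sample_" + key + "\t" + "\t".join(_quote(v) for v in values)

    lines.append(sample_line("geo_accession", (s.sample_id for s in study.samples)))
    lines.append(sample_line("title", (s.title for s in study.samples)))
    lines.append(sample_line("description", (s.description for s in study.samples)))
    lines.append(
        sample_line("characteristics_ch1", (s.characteristics for s in study.samples))
    )
    lines.append(sample_line("source_name_ch1", (s.source_name for s in study.samples)))
    lines.append(
        sample_line(
            "scan_date",
            (s.scan_date.isoformat() if s.scan_date else "" for s in study.samples),
        )
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        if study.expression is not None:
            fh.write("!series_matrix_table_begin\n")
            expr = study.expression
            fh.write("ID_REF\t" + "\t".join(expr.columns) + "\n")
            for gene, row in expr.iterrows():
                fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
            fh.write("!series_matrix_table_end\n")


def _read_soft_simplified(path: Path) -> Study:
    series: dict[str, str] = {}
    samples: list[Sample] = []
    current: dict[str, str] | None = None
    table_lines: list[str] = []
    mode = "series"

    def flush() -> None:
        nonlocal current
        if current is not None:
            samples.append(
                Sample(
                    sample_id=current.get("id", ""),
                    title=current.get("title", ""),
                    description=current.get("description", ""),
                    characteristics=current.get("characteristics_ch1", ""),
                    source_name=current.get("source_name_ch1", ""),
                    scan_date=parse_scan_date(current.get("scan_date")),
                )
            )
            current = None

    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("^SERIES"):
            mode = "series"
            _, _, value = line.partition("=")
            series["geo_accession"] = value.strip()
        elif line.startswith("^SAMPLE"):
            flush()
            mode = "sample"
            _, _, value = line.partition("=")
            current = {"id": value.strip()}
        elif line.startswith("^MATRIX"):
            flush()
            mode = "matrix"
        elif line.startswith("!"):
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected '!key = value'")
            key, _, value = line[1:].partition("=")
            key = key.strip()
            value = value.strip()
            if mode == "series":
                if not key.startswith("Series_"):
                    raise ParseError(f"{path}:{lineno}: unexpected key {key!r}")
                series[key[len("Series_"):]] = value
            elif mode == "sample" and current is not None:
                if not key.startswith("Sample_"):
                    raise ParseError(f"{path}:{lineno}: unexpected key {key!r}")
                current[key[len("Sample_"):]] = value
            else:
                raise ParseError(f"{path}:{lineno}: metadata after ^MATRIX")
        elif mode == "matrix":
            table_lines.append(line)
        else:
            raise ParseError(f"{path}:{lineno}: unrecognized line {line[:40]!r}")
    flush()
    expression = _read_expression_table(table_lines, str(path)) if table_lines else None
    return Study(
        study_id=series.get("geo_accession", ""),
        title=series.get("title", ""),
        summary=series.get("summary", ""),
        keywords=series.get("keywords", ""),
        organism=series.get("organism", "human"),
        samples=samples,
        expression=expression,
    )


def _write_soft_simplified(study: Study, path: Path) -> None:
    lines = [
        f"^SERIES = {study.study_id}",
        f"!Series_title = {study.title}",
        f"!Series_summary = {study.summary}",
        f"!Series_keywords = {study.keywords}",
        f"!Series_organism = {study.organism}",
    ]
    for s in study.samples:
        lines.append(f"^SAMPLE = {s.sample_id}")
        lines.append(f"!Sample_title = {s.title}")
        lines.append(f"!Sample_description = {s.description}")
        lines.append(f"!Sample_characteristics_ch1 = {s.characteristics}")
        lines.append(f"!Sample_source_name_ch1 = {s.source_name}")
        lines.append(
            "!Sample_scan_date = "
            + (s.scan_date.isoformat() if s.scan_date else "")
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        if study.expression is not None:
            fh.write("^MATRIX\n")
            expr = study.expression
            fh.write("ID_REF\t" + "\t".join(expr.columns) + "\n")
            for gene, row in expr.iterrows():
                fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT and signature JSON


def write_gmt(signatures: Sequence[Signature], path: str | Path) -> None:
    """Write up/down gene sets as GMT: two lines per signature
    (``<id>_up`` and ``<id>_down``), tab-separated name, description,
    then gene symbols. Byte-stable for a fixed input order."""
    if not signatures:
        logger.warning("write_gmt called with an empty signature list: %s", path)
    with open(path, "w") as fh:
        for sig in signatures:
            desc = f"{sig.study_id}|{sig.signature_type}|{sig.entity_label}"
            fh.write("\t".join([f"{sig.signature_id}_up", desc, *sig.up_genes]) + "\n")
            fh.write("\t".join([f"{sig.signature_id}_down", desc, *sig.down_genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into ``{set_name: (description, genes)}``."""
    out: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 2 fields")
        out[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return out


_SIGNATURE_MANDATORY = (
    "signature_id",
    "study_id",
    "control_ids",
    "perturbation_ids",
    "signature_type",
    "entity_label",
    "coefficients",
    "up_genes",
    "down_genes",
)


def write_signature_json(signature: Signature) -> dict:
    """Serialize a Signature to a plain JSON-compatible dict."""
    return {
        "signature_id": signature.signature_id,
        "study_id": signature.study_id,
        "control_ids": sorted(signature.control_ids),
        "perturbation_ids": sorted(signature.perturbation_ids),
        "signature_type": signature.signature_type,
        "entity_label": signature.entity_label,
        "coefficients": {g: float(v) for g, v in signature.coefficients.items()},
        "up_genes": list(signature.up_genes),
        "down_genes": list(signature.down_genes),
        "method": signature.method,
        "provenance": signature.provenance,
        "confidence": signature.confidence,
    }


def read_signature_json(doc: Mapping) -> Signature:
    """Deserialize; missing mandatory fields raise :class:`SchemaError`."""
    missing = [k for k in _SIGNATURE_MANDATORY if k not in doc]
    if missing:
        raise SchemaError(f"signature JSON missing fields: {missing}")
    return Signature(
        signature_id=doc["signature_id"],
        study_id=doc["study_id"],
        control_ids=frozenset(doc["control_ids"]),
        perturbation_ids=frozenset(doc["perturbation_ids"]),
        signature_type=doc["signature_type"],
        entity_label=doc["entity_label"],
        coefficients={g: float(v) for g, v in doc["coefficients"].items()},
        up_genes=list(doc["up_genes"]),
        down_genes=list(doc["down_genes"]),
        method=doc.get("method", "cd"),
        provenance=doc.get("provenance", "manual"),
        confidence=doc.get("confidence"),
    )


def save_signatures(signatures: Sequence[Signature], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([write_signature_json(s) for s in signatures], fh, indent=1)


def load_signatures(path: str | Path) -> list[Signature]:
    with open(path) as fh:
        docs = json.load(fh)
    return [read_signature_json(d) for d in docs]
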