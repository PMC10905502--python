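"""Reading and writing bibliographic records and annotation tables.

MEDLINE (nbib) exports are parsed with :mod:`Bio.Medline`; delimited tables
with pandas. All free text is canonicalized on ingestion (Unicode minus and
en/em dashes to ``-``, non-breaking/thin spaces to plain spaces, curly
apostrophes to ``'``) so the extraction grammar only ever sees one dash.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Medline

from .types import (
    AbstractAnnotation,
    AbstractRecord,
    BayesKind,
    BayesToken,
    CallBasis,
    CallValue,
    CIToken,
    Comparator,
    EffectMeasureToken,
    EstimateFamily,
    Polarity,
    PValueToken,
    ReportingStyle,
    SignificanceCall,
    SignificanceTerm,
    StudyDesign,
    TermTemplate,
)

__all__ = [
    "AbstractRecord",
    "normalize_text",
    "read_medline",
    "read_table",
    "write_medline",
    "write_annotations",
    "read_annotations",
]

# Canonical replacements applied before tokenization. CI ranges in abstracts
# routinely use en-dashes ("76–84%") and minus signs ("−0.2").
_CHAR_MAP = str.maketrans(
    {
        "−": "-",  # minus sign
        "–": "-",  # en dash
        "—": "-",  # em dash
        " ": " ",  # no-break space
        " ": " ",  # thin space
        " ": " ",  # narrow no-break space
        "‘": "'",
        "’": "'",
        "“": '"',
        "”": '"',
    }
)


def normalize_text(text: str) -> str:
    """Map typographic dash/space/quote variants to ASCII equivalents."""
    return text.translate(_CHAR_MAP)


def _parse_year(dp: str) -> int | None:
    """Year = the first 4-digit token of the DP field ("2021 Mar 4" -> 2021)."""
    for tok in dp.replace("-", " ").replace("/", " ").split():
        if len(tok) == 4 and tok.isdigit():
            year = int(tok)
            if 1800 <= year <= 2100:
                return year
    return None


def _read_text(path: str | Path) -> str:
    raw = Path(path).read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def read_medline(path: str | Path, report: dict | None = None) -> list[AbstractRecord]:
    """Read a tagged-field MEDLINE/nbib export.

    One record per PMID block; blocks without a PMID are skipped and counted
    in *report* (keys ``parsed``, ``skipped_no_id``, ``missing_abstract``).
    Records lacking an AB tag keep an empty abstract — eligibility screening,
    not ingestion, decides their fate.
    """
    text = _read_text(path)
    records: list[AbstractRecord] = []
    skipped = 0
    missing_ab = 0
    import io

    for rec in Medline.parse(io.StringIO(text)):
        pmid = rec.get("PMID", "").strip()
        if not pmid:
            skipped += 1
            continue
        abstract = normalize_text(rec.get("AB", "") or "")
        if not abstract:
            missing_ab += 1
        records.append(
            AbstractRecord(
                record_id=pmid,
                title=normalize_text(rec.get("TI", "") or ""),
                abstract=abstract,
                journal=normalize_text(rec.get("JT", "") or ""),
                year=_parse_year(rec.get("DP", "") or ""),
                pub_types=frozenset(rec.get("PT", []) or []),
                language_hint=(rec.get("LA", [None]) or [None])[0],
            )
        )
    if report is not None:
        report.update(
            parsed=len(records), skipped_no_id=skipped, missing_abstract=missing_ab
        )
    return records


DEFAULT_COLUMN_MAP = {
    "record_id": "record_id",
    "title": "title",
    "abstract": "abstract",
    "journal": "journal",
    "year": "year",
    "pub_types": "pub_types",
}


def read_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
    pub_type_delimiter: str = ";",
) -> list[AbstractRecord]:
    """Read a delimited table with a header row into records.

    *column_map* maps the canonical field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to the file's column names.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for field_name in ("record_id", "title", "abstract"):
        if cmap[field_name] not in df.columns:
            raise KeyError(
                f"column {cmap[field_name]!r} (mapped from {field_name!r}) "
                f"not found in {path}"
            )
    records = []
    for _, row in df.iterrows():
        year_raw = row.get(cmap["year"], "")
        year = _parse_year(str(year_raw)) if year_raw else None
        pts = row.get(cmap["pub_types"], "")
        pub_types = frozenset(
            t.strip() for t in str(pts).split(pub_type_delimiter) if t.strip()
        )
        records.append(
            AbstractRecord(
                record_id=str(row[cmap["record_id"]]),
                title=normalize_text(str(row[cmap["title"]])),
                abstract=normalize_text(str(row[cmap["abstract"]])),
                journal=normalize_text(str(row.get(cmap["journal"], ""))),
                year=year,
                pub_types=pub_types,
            )
        )
    return records


def _wrap_field(tag: str, value: str, width: int = 80) -> list[str]:
    words = value.split()
    if not words:
        return [f"{tag:<4}- "]
    lines = [f"{tag:<4}- {words[0]}"]
    for word in words[1:]:
        if len(lines[-1]) + 1 + len(word) > width:
            lines.append("      " + word)
        else:
            lines[-1] += " " + word
    return lines


def write_medline(records: Iterable[AbstractRecord], path: str | Path) -> None:
    """Write records as a tagged-field MEDLINE/nbib export."""
    blocks = []
    for rec in records:
        lines = _wrap_field("PMID", rec.record_id)
        if rec.year is not None:
            lines += _wrap_field("DP", f"{rec.year} Jan")
        lines += _wrap_field("TI", rec.title)
        if rec.abstract:
            lines += _wrap_field("AB", rec.abstract)
        if rec.journal:
            lines += _wrap_field("JT", rec.journal)
        for pt in sorted(rec.pub_types):
            lines += _wrap_field("PT", pt)
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Annotation serialization (JSON-lines and TSV, lossless round trip)
# ---------------------------------------------------------------------------

_TOKEN_LISTS = ("pvalues", "cis", "terms", "effects", "bayes")
_TOKEN_CLASS = {
    "pvalues": PValueToken,
    "cis": CIToken,
    "terms": SignificanceTerm,
    "effects": EffectMeasureToken,
    "bayes": BayesToken,
}

_ENUM_FIELDS = {
    "comparator": Comparator,
    "comparator_orig": Comparator,
    "estimate_family": EstimateFamily,
    "polarity": Polarity,
    "template": TermTemplate,
    "kind": BayesKind,
}


def _token_to_dict(token) -> dict:
    d = asdict(token)
    for key, val in list(d.items()):
        if hasattr(val, "value"):
            d[key] = val.value
    if d.get("call") is not None:
        d["call"] = {"value": token.call.value.value, "basis": token.call.basis.value}
    return d


def _token_from_dict(cls, d: dict):
    d = dict(d)
    call = d.pop("call", None)
    for key, enum_cls in _ENUM_FIELDS.items():
        if key in d and d[key] is not None:
            d[key] = enum_cls(d[key])
    token = cls(**d)
    if call is not None:
        token.call = SignificanceCall(CallValue(call["value"]), CallBasis(call["basis"]))
    return token


def _annotation_to_rows(ann: AbstractAnnotation) -> list[dict]:
    from .classification import reporting_style  # local import avoids a cycle

    rows = []
    for list_name in _TOKEN_LISTS:
        for token in getattr(ann, list_name):
            rows.append(
                {
                    "row_type": "token",
                    "record_id": ann.record_id,
                    "token_class": list_name,
                    "payload": _token_to_dict(token),
                }
            )
    style = ann.style.value if ann.style is not None else reporting_style(ann).value
    rows.append(
        {
            "row_type": "abstract",
            "record_id": ann.record_id,
            "token_class": "",
            "payload": {
                "year": ann.year,
                "journal": ann.journal,
                "design": ann.design.value,
                "design_unreliable": ann.design_unreliable,
                "reclassified_count": ann.reclassified_count,
                "style": style,
                "has_inference": ann.has_inference,
                "n_sentences": len(ann.sentences),
            },
        }
    )
    return rows


def write_annotations(
    annotations: Sequence[AbstractAnnotation],
    path: str | Path,
    fmt: str = "json",
) -> None:
    """Serialize annotations: one row per token plus one abstract-level row.

    ``fmt="json"`` writes JSON-lines; ``fmt="tsv"`` a tab-separated table with
    the parsed fields JSON-encoded in a payload column. Both round-trip
    losslessly through :func:`read_annotations`.
    """
    rows = [row for ann in annotations for row in _annotation_to_rows(ann)]
    path = Path(path)
    if fmt == "json":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    elif fmt == "tsv":
        flat = [
            {
                "row_type": r["row_type"],
                "record_id": r["record_id"],
                "token_class": r["token_class"],
                "payload": json.dumps(r["payload"], sort_keys=True),
            }
            for r in rows
        ]
        pd.DataFrame(flat, columns=["row_type", "record_id", "token_class", "payload"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


def read_annotations(path: str | Path, fmt: str = "json") -> list[AbstractAnnotation]:
    """Inverse of :func:`write_annotations` (token spans and calls included;
    sentence texts are not serialized and come back empty)."""
    path = Path(path)
    if fmt == "json":
        rows = [json.loads(line) for line in path.read_text("utf-8").splitlines() if line]
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        rows = [
            {
                "row_type": r.row_type,
                "record_id": r.record_id,
                "token_class": r.token_class,
                "payload": json.loads(r.payload),
            }
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    anns: dict[str, AbstractAnnotation] = {}
    order: list[str] = []
    for row in rows:
        rid = str(row["record_id"])
        if rid not in anns:
            anns[rid] = AbstractAnnotation(record_id=rid)
            order.append(rid)
        ann = anns[rid]
        if row["row_type"] == "token":
            cls_name = row["token_class"]
            token = _token_from_dict(_TOKEN_CLASS[cls_name], row["payload"])
            getattr(ann, cls_name).append(token)
        else:
            p = row["payload"]
            ann.year = p["year"]
            ann.journal = p["journal"]
            ann.design = StudyDesign(p["design"])
            ann.design_unreliable = bool(p["design_unreliable"])
            ann.reclassified_count = int(p["reclassified_count"])
            ann.style = ReportingStyle(p["style"])
    return [anns[r] for r in order]
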