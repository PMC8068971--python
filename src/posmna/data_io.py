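"""Readers and writers: molecule files, pair tables, model JSON, reports.

All tabular formats are UTF-8 TSV with ``#`` comment lines (TSV rather than
CSV so SMILES never need quoting).  Writers are deterministic: stable sort
orders and shortest-round-trip float formatting, so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .chemgraph import MolecularGraph, prepare
from .descriptors import DEFAULT_LEVEL, mna_set, posmna_set
from .errors import DataFormatError, PosmnaError
from .model import (
    CYP_ACTIVITIES,
    FORMAT_VERSION,
    PairInteractionClassifier,
    PairRecord,
    PredictionRecord,
    TrainingTable,
    pair_key,
)
from .validation import ValidationReport

import numpy as np


def _fmt(x: float) -> str:
    return repr(float(x))


# ----------------------------------------------------------------- molecules

def read_molecules(
    path,
    fmt: str | None = None,
    strict: bool = True,
    strip_salts: bool = False,
) -> tuple[dict[str, MolecularGraph], list[str]]:
    """Read a molecule library into prepared graphs.

    SMILES files hold one ``id<TAB>smiles`` per line; SDF files are V2000
    with the id taken from the title line.  Returns ``(molecules, errors)``;
    in strict mode any record failure raises instead of being collected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".mol"} else "smiles"
    if fmt not in {"smiles", "sdf"}:
        raise DataFormatError(f"unknown molecule format {fmt!r}")

    records: list[tuple[str, str]] = []
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 'id<TAB>smiles', got {line!r}"
                )
            records.append((parts[0], parts[1]))
    else:
        block: list[str] = []
        for line in path.read_text().splitlines():
            if line.strip() == "$$$$":
                if block:
                    rid = block[0].strip() or f"record{len(records) + 1}"
                    records.append((rid, "\n".join(block)))
                block = []
            else:
                block.append(line)
        if any(l.strip() for l in block):
            rid = block[0].strip() or f"record{len(records) + 1}"
            records.append((rid, "\n".join(block)))

    molecules: dict[str, MolecularGraph] = {}
    errors: list[str] = []
    for rid, text in records:
        if rid in molecules:
            raise DataFormatError(f"{path}: duplicate molecule id {rid!r}")
        try:
            molecules[rid] = prepare(text, record_id=rid, strip_salts=strip_salts)
        except PosmnaError as exc:
            if strict:
                raise
            errors.append(str(exc))
    if not molecules:
        raise DataFormatError(f"{path}: no valid molecule records")
    return molecules, errors


def write_molecules(path, records: list[tuple[str, str]], header: str | None = None):
    """Write ``(id, smiles)`` records as an ``id<TAB>smiles`` file."""
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(f"{rid}\t{smi}" for rid, smi in records)
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------- pair tables

def read_pair_rows(path) -> list[tuple[str, str, str]]:
    """Raw ``(id_a, id_b, activity)`` rows of a pair-table TSV."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if [p.lower() for p in parts[:3]] == ["id_a", "id_b", "activity"]:
            continue  # header row (may follow comment lines)
        if len(parts) != 3:
            raise DataFormatError(
                f"{path}:{lineno}: expected 'id_a<TAB>id_b<TAB>activity', got {line!r}"
            )
        rows.append((parts[0], parts[1], parts[2]))
    return rows


def write_pair_rows(path, rows: list[tuple[str, str, str]], header: str | None = None):
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("id_a\tid_b\tactivity")
    lines.extend("\t".join(r) for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def read_pair_table(
    path,
    molecules: dict[str, MolecularGraph],
    activities=CYP_ACTIVITIES,
    level: int = DEFAULT_LEVEL,
) -> TrainingTable:
    """Resolve a pair-table TSV against a molecule map into a TrainingTable.

    Pair keys are unordered — ``(A, B)`` and ``(B, A)`` rows address the same
    pair — and duplicate (pair, activity) rows collapse.  Descriptor sets are
    computed once per unique pair.
    """
    activities = tuple(activities)
    vocab = set(activities)
    labels: dict[tuple[str, str], set[str]] = {}
    for lineno, (a, b, act) in enumerate(read_pair_rows(path), start=1):
        for mid in (a, b):
            if mid not in molecules:
                raise DataFormatError(
                    f"{path} row {lineno}: unknown molecule id {mid!r}"
                )
        if act not in vocab:
            raise DataFormatError(
                f"{path} row {lineno}: unknown activity {act!r}"
            )
        labels.setdefault(pair_key(a, b), set()).add(act)

    counts = {a: sum(a in v for v in labels.values()) for a in activities}
    logging.getLogger(__name__).info(
        "read %d unique pairs from %s; per-activity counts: %s",
        len(labels), path, counts,
    )
    mna_cache = {mid: mna_set(g, level) for mid, g in molecules.items()
                 if any(mid in k for k in labels)}
    pairs = []
    for key in sorted(labels):
        a, b = key
        desc = posmna_set(mna_cache[a], mna_cache[b]).descriptors
        pairs.append(PairRecord(key=key, labels=frozenset(labels[key]), descriptors=desc))
    return TrainingTable(pairs=pairs, activities=activities)


# -------------------------------------------------------------- model files

def save_model(m: PairInteractionClassifier, path, level: int = DEFAULT_LEVEL):
    """Serialize a fitted model to versioned JSON."""
    doc = {
        "format_version": FORMAT_VERSION,
        "level": level,
        "smoothing": m.smoothing,
        "threshold": m.threshold,
        "activities": list(m.activities_),
        "n_pairs": int(m.n_pairs_),
        "n_active": [int(x) for x in m.n_active_],
        "descriptors": {
            d: [int(m.n_with_descriptor_[i])]
            + [int(x) for x in m.n_active_with_descriptor_[i]]
            for d, i in sorted(m.descriptor_index_.items())
        },
        "calibration_active": [
            [float(x) for x in arr] for arr in m.calibration_active_
        ],
        "calibration_inactive": [
            [float(x) for x in arr] for arr in m.calibration_inactive_
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_model(path) -> PairInteractionClassifier:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise DataFormatError(
            f"{path}: model format {version!r} does not match {FORMAT_VERSION!r}"
        )
    m = PairInteractionClassifier(
        smoothing=doc["smoothing"],
        activities=tuple(doc["activities"]),
        threshold=doc.get("threshold", 0.0),
    )
    acts = tuple(doc["activities"])
    m.activities_ = acts
    m.classes_ = np.asarray(acts, dtype=object)
    m.n_pairs_ = doc["n_pairs"]
    m.n_active_ = np.asarray(doc["n_active"], dtype=np.int64)
    items = sorted(doc["descriptors"].items())
    m.descriptor_index_ = {d: i for i, (d, _) in enumerate(items)}
    m.n_with_descriptor_ = np.asarray([v[0] for _, v in items], dtype=np.int64)
    m.n_active_with_descriptor_ = np.asarray(
        [v[1:] for _, v in items], dtype=np.int64
    )
    m.calibration_active_ = [
        np.asarray(a, dtype=float) for a in doc["calibration_active"]
    ]
    m.calibration_inactive_ = [
        np.asarray(a, dtype=float) for a in doc["calibration_inactive"]
    ]
    m.level_ = doc["level"]
    return m


# ------------------------------------------------------------------ reports

def prediction_rows(pair_id: str, rec: PredictionRecord, threshold: float = 0.0):
    rows = []
    for r in rec.rows:
        rows.append(
            (
                pair_id,
                r.activity,
                _fmt(r.score),
                _fmt(r.pa),
                _fmt(r.pi),
                _fmt(r.dp),
                "YES" if r.dp > threshold else "NO",
            )
        )
    return rows


def write_predictions(path, rows, header: str | None = None):
    """Prediction TSV: pair_id, activity, S, Pa, Pi, dP, yes_no (dP-descending per pair)."""
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("pair_id\tactivity\tS\tPa\tPi\tdP\tyes_no")
    lines.extend("\t".join(r) for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def write_validation_report(path, report: ValidationReport, header: str | None = None):
    """Validation TSV: one row per activity plus a final Average row."""
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("activity\tn_active\tn_inactive\tIAP")
    for r in report.rows:
        lines.append(f"{r.activity}\t{r.n_active}\t{r.n_inactive}\t{_fmt(r.iap)}")
    lines.append(f"Average\t\t\t{_fmt(report.average_iap)}")
    Path(path).write_text("\n".join(lines) + "\n")


def validation_report_dict(report: ValidationReport) -> dict:
    return {
        "activities": [
            {
                "activity": r.activity,
                "n_active": r.n_active,
                "n_inactive": r.n_inactive,
                "iap": r.iap,
            }
            for r in report.rows
        ],
        "average_iap": report.average_iap,
    }
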