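"""Reading and writing report corpora, label files and persisted models.

A corpus lives on disk either as a directory of ``<report_id>.txt`` files
plus a ``labels.csv`` (header ``report_id,label``), or as a single JSONL
file with one record per report (keys ``report_id``, ``text``,
``modality``, ``label``).  Trained models persist as a single versioned
JSON document so they are human-inspectable and diff-able.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

logger = logging.getLogger("radtriage")

MODEL_FORMAT_VERSION = "radtriage-model-1"


class CorpusError(ValueError):
    """Fatal problem with corpus or label input."""


class ModelPersistenceError(ValueError):
    """Fatal problem reading or writing a persisted model."""


class Modality(str, Enum):
    mammogram = "mammogram"
    ct = "ct"
    plain_film = "plain_film"
    ultrasound = "ultrasound"
    mri = "mri"
    other = "other"


class Label(str, Enum):
    low = "low"
    high = "high"


@dataclass(frozen=True)
class ClinicalReport:
    """One raw free-text report with an optional gold priority label."""

    report_id: str
    raw_text: str
    modality: Modality = Modality.other
    label: Optional[Label] = None


@dataclass
class Corpus:
    """An ordered collection of reports, iterated sorted by report_id.

    Sorting at construction makes every downstream computation (training
    counts, evaluation tables, CLI output) reproducible across runs and
    filesystems.
    """

    reports: Sequence[ClinicalReport]
    name: str = ""

    def __post_init__(self) -> None:
        ordered = sorted(self.reports, key=lambda r: r.report_id)
        seen: set[str] = set()
        for r in ordered:
            if r.report_id in seen:
                raise CorpusError(f"duplicate report_id: {r.report_id!r}")
            seen.add(r.report_id)
        self.reports = list(ordered)

    def __iter__(self) -> Iterator[ClinicalReport]:
        return iter(self.reports)

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def labels(self) -> dict[str, Optional[Label]]:
        return {r.report_id: r.label for r in self.reports}


def _parse_label(raw: str, context: str) -> Label:
    value = raw.strip().lower()
    try:
        return Label(value)
    except ValueError:
        raise CorpusError(
            f"invalid label {raw!r} for {context}: expected 'low' or 'high'"
        ) from None


def _parse_modality(raw: Optional[str]) -> Modality:
    if raw is None or str(raw).strip() == "":
        return Modality.other
    try:
        return Modality(str(raw).strip().lower())
    except ValueError:
        raise CorpusError(f"invalid modality {raw!r}") from None


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        logger.warning("invalid UTF-8 in %s; bad bytes replaced", path)
        return data.decode("utf-8", errors="replace")


def read_labels(labels_path: Path) -> dict[str, Label]:
    """Read a ``report_id,label`` CSV; labels case-insensitive on read."""
    labels: dict[str, Label] = {}
    with open(labels_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"report_id", "label"} <= set(
            n.strip().lower() for n in reader.fieldnames
        ):
            raise CorpusError(
                f"{labels_path}: expected CSV header 'report_id,label'"
            )
        for row in reader:
            row = {k.strip().lower(): v for k, v in row.items() if k}
            rid = (row.get("report_id") or "").strip()
            if not rid:
                continue
            if rid in labels:
                raise CorpusError(f"duplicate report_id in labels: {rid!r}")
            labels[rid] = _parse_label(row.get("label") or "", f"report {rid!r}")
    return labels


def _load_directory(path: Path, labels: Mapping[str, Label]) -> list[ClinicalReport]:
    reports = []
    txt_files = sorted(path.glob("*.txt"))
    for f in txt_files:
        rid = f.stem
        reports.append(
            ClinicalReport(
                report_id=rid,
                raw_text=_read_text(f),
                modality=Modality.other,
                label=labels.get(rid),
            )
        )
    return reports


def _load_jsonl(path: Path, labels: Mapping[str, Label]) -> list[ClinicalReport]:
    reports = []
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            rid = str(rec["report_id"])
            label = rec.get("label")
            if rid in labels:
                lab: Optional[Label] = labels[rid]
            elif label is not None:
                lab = _parse_label(str(label), f"record {rid!r}")
            else:
                lab = None
            reports.append(
                ClinicalReport(
                    report_id=rid,
                    raw_text=str(rec.get("text", "")),
                    modality=_parse_modality(rec.get("modality")),
                    label=lab,
                )
            )
    return reports


def load_corpus(path: str | Path, labels_path: str | Path | None = None) -> Corpus:
    """Load a corpus from a report directory or a JSONL file.

    Labels from ``labels_path`` are attached by report_id; a label that
    references an unknown report is a fatal error.  Reports without a
    label get ``label=None``.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus path does not exist: {path}")
    labels: dict[str, Label] = {}
    if labels_path is not None:
        labels_path = Path(labels_path)
        if not labels_path.exists():
            raise CorpusError(f"labels path does not exist: {labels_path}")
        labels = read_labels(labels_path)

    if path.is_dir():
        reports = _load_directory(path, labels)
    else:
        reports = _load_jsonl(path, labels)

    known = {r.report_id for r in reports}
    unknown = sorted(set(labels) - known)
    if unknown:
        raise CorpusError(
            f"label references unknown report_id {unknown[0]!r}"
            + (f" (+{len(unknown) - 1} more)" if len(unknown) > 1 else "")
        )
    if not reports:
        logger.warning("corpus at %s contains no reports", path)
    return Corpus(reports=reports, name=path.name)


def save_corpus(
    corpus: Corpus, path: str | Path, fmt: str = "dir", labels_path: str | Path | None = None
) -> None:
    """Write a corpus as a report directory + labels.csv, or as JSONL.

    With ``fmt="dir"``, ``path`` is the directory and labels go to
    ``labels_path`` (default ``<path>/labels.csv``).  With ``fmt="jsonl"``
    everything is written into the single JSONL file at ``path``.
    Labels are written lowercase.
    """
    path = Path(path)
    if fmt == "dir":
        path.mkdir(parents=True, exist_ok=True)
        for r in corpus:
            (path / f"{r.report_id}.txt").write_text(r.raw_text, encoding="utf-8")
        lp = Path(labels_path) if labels_path is not None else path / "labels.csv"
        with open(lp, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["report_id", "label"])
            for r in corpus:
                if r.label is not None:
                    writer.writerow([r.report_id, r.label.value])
    elif fmt == "jsonl":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            for r in corpus:
                rec = {
                    "report_id": r.report_id,
                    "text": r.raw_text,
                    "modality": r.modality.value,
                    "label": r.label.value if r.label is not None else None,
                }
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown corpus format {fmt!r} (expected 'dir' or 'jsonl')")


def save_model(model, path: str | Path) -> None:
    """Persist a trained model as a versioned JSON document."""
    if model.n_high < 1 or model.n_low < 1:
        raise ModelPersistenceError(
            "refusing to save an under-trained model: need at least one "
            f"document per class (n_high={model.n_high}, n_low={model.n_low})"
        )
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_high": model.n_high,
        "n_low": model.n_low,
        "smoothing_alpha": model.smoothing_alpha,
        "clamp_low": model.clamp_low,
        "clamp_high": model.clamp_high,
        "cond_prob_high": {f: model.cond_prob_high[f] for f in sorted(model.cond_prob_high)},
        "cond_prob_low": {f: model.cond_prob_low[f] for f in sorted(model.cond_prob_low)},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; exact inverse of it."""
    from .bayes_classifier import TrainedModel  # local import: avoid cycle

    path = Path(path)
    if not path.exists():
        raise ModelPersistenceError(f"model file does not exist: {path}")
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelPersistenceError(f"corrupted model file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelPersistenceError(
            f"model format version mismatch: file has {version!r}, "
            f"this package reads {MODEL_FORMAT_VERSION!r}"
        )
    try:
        return TrainedModel(
            n_high=int(doc["n_high"]),
            n_low=int(doc["n_low"]),
            cond_prob_high=dict(doc["cond_prob_high"]),
            cond_prob_low=dict(doc["cond_prob_low"]),
            smoothing_alpha=float(doc["smoothing_alpha"]),
            clamp_low=float(doc["clamp_low"]),
            clamp_high=float(doc["clamp_high"]),
        )
    except KeyError as exc:
        raise ModelPersistenceError(f"model file {path} missing field {exc}") from exc
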