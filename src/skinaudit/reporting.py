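"""End-to-end document audit and representation reporting.

``audit_document`` runs the full pipeline — ingest, skin-image detection,
skin-pixel segmentation, tone classification — and aggregates per-image
results into a :class:`RepresentationReport` whose headline number is the
proportion of dark-skin (FST V-VI) images among classified skin images.
Every counted image stays traceable to its (page, bbox) provenance.
"""

from __future__ import annotations

import csv
import json
import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .detection import DetectionModel, predict_detector
from .features import detection_features
from .ingestion import ImageRecord, extract_images
from .segmentation import RefineParams, SkinRanges, segment_skin
from .tone import EmptyMaskError, classify_tone_ita, predict_tone, DEFAULT_ITA_TABLE

__all__ = ["ImageAuditRecord", "RepresentationReport", "audit_document",
           "build_report", "render_report"]


@dataclass
class ImageAuditRecord:
    """Per-image outcome with provenance."""

    page: int
    bbox: tuple[float, float, float, float]
    is_skin: bool
    skin_score: float
    tone_class: str | None = None   # "I-IV", "V-VI", or None
    tone_score: float | None = None
    n_skin_pixels: int = 0
    excluded: bool = False          # skin image whose mask came back empty


@dataclass
class RepresentationReport:
    doc_id: str
    n_images_total: int
    n_skin: int
    n_nonskin: int
    n_dark: int
    n_light: int
    n_excluded: int
    prop_dark: float | None
    images: list[ImageAuditRecord] = field(default_factory=list)

    def validate(self) -> None:
        assert self.n_images_total == self.n_skin + self.n_nonskin
        assert self.n_skin == self.n_dark + self.n_light + self.n_excluded
        if self.prop_dark is not None:
            assert 0.0 <= self.prop_dark <= 1.0


def build_report(doc_id: str, records: list[ImageAuditRecord]) -> RepresentationReport:
    n_skin = sum(r.is_skin for r in records)
    n_dark = sum(r.tone_class == "V-VI" for r in records)
    n_light = sum(r.tone_class == "I-IV" for r in records)
    n_excluded = sum(r.excluded for r in records)
    denom = n_dark + n_light
    report = RepresentationReport(
        doc_id=doc_id,
        n_images_total=len(records),
        n_skin=n_skin,
        n_nonskin=len(records) - n_skin,
        n_dark=n_dark,
        n_light=n_light,
        n_excluded=n_excluded,
        prop_dark=(n_dark / denom) if denom else None,
        images=records,
    )
    report.validate()
    return report


def audit_document(document, detector: DetectionModel, tone_model=None, *,
                   ita_table=DEFAULT_ITA_TABLE, min_dim: int = 100,
                   ranges: SkinRanges | None = None,
                   refine: RefineParams | None = None) -> RepresentationReport:
    """Audit one document.

    ``tone_model`` is a fitted ensemble or CNN tone model; pass None to
    use ITA-table classification (training-free).  Skin images whose
    segmentation mask is empty are excluded from the tone denominator and
    counted separately.
    """
    if detector is None:
        raise ValueError("a fitted detector is required")
    records = extract_images(document, min_dim=min_dim)
    doc_id = records[0].doc_id if records else Path(str(document)).stem
    audits: list[ImageAuditRecord] = []
    for rec in records:
        feats = detection_features(rec.pixels)
        proba, labels = predict_detector(detector, feats[None, :])
        is_skin = bool(labels[0])
        audit = ImageAuditRecord(page=rec.page, bbox=rec.bbox,
                                 is_skin=is_skin, skin_score=float(proba[0]))
        if is_skin:
            mask = segment_skin(rec.pixels, ranges, refine)
            audit.n_skin_pixels = int(mask.sum())
            try:
                if tone_model is None:
                    label = classify_tone_ita(rec.pixels, mask, ita_table)
                else:
                    label = predict_tone(tone_model, rec.pixels, mask)
                audit.tone_class = label.fst_class
                audit.tone_score = label.score
            except EmptyMaskError:
                audit.excluded = True
        audits.append(audit)
    return build_report(doc_id, audits)


def _report_dict(report: RepresentationReport) -> dict:
    d = asdict(report)
    d["images"] = [asdict(r) for r in report.images]
    return d


def report_from_dict(d: dict) -> RepresentationReport:
    images = [ImageAuditRecord(**{**r, "bbox": tuple(r["bbox"])}) for r in d["images"]]
    kwargs = {k: v for k, v in d.items() if k != "images"}
    rep = RepresentationReport(images=images, **kwargs)
    rep.validate()
    return rep


def render_report(report: RepresentationReport, fmt: str = "json") -> str:
    """Render as machine JSON, human Markdown, or per-image CSV."""
    if fmt == "json":
        return json.dumps(_report_dict(report), indent=2)
    if fmt == "markdown":
        lines = [f"# Skin tone representation audit: {report.doc_id}", ""]
        if report.n_skin == 0:
            lines.append("No skin images detected.")
        else:
            pd = ("n/a" if report.prop_dark is None
                  else f"{100 * report.prop_dark:.1f}%")
            lines += [
                f"- images extracted: {report.n_images_total}",
                f"- skin images: {report.n_skin} "
                f"(excluded, no skin pixels found: {report.n_excluded})",
                f"- non-skin images: {report.n_nonskin}",
                f"- FST I-IV (light): {report.n_light}",
                f"- FST V-VI (dark): {report.n_dark}",
                f"- proportion dark among classified skin images: {pd}",
            ]
        return "\n".join(lines) + "\n"
    if fmt == "csv":
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["page", "x0", "y0", "x1", "y1", "is_skin", "skin_score",
                    "tone_class", "tone_score", "n_skin_pixels", "excluded"])
        for r in report.images:
            w.writerow([r.page, *[f"{v:.2f}" for v in r.bbox], int(r.is_skin),
                        f"{r.skin_score:.4f}", r.tone_class or "",
                        "" if r.tone_score is None else f"{r.tone_score:.4f}",
                        r.n_skin_pixels, int(r.excluded)])
        return buf.getvalue()
    raise ValueError(f"unknown format {fmt!r}; choose json, markdown or csv")
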