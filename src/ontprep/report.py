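"""Tuning report: machine-readable JSON plus a static HTML rendering.

The JSON payload is the single source of truth (chosen cutoffs per AP end,
the per-length best-F_beta table, similarity and location histograms of the
true vs random samples, and output category counts). The HTML is a pure
function of the JSON — regenerating it from the same payload is
byte-identical — and every number shown in it comes from the payload.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np

from .autotune import CutoffFitResults
from .schema import AP_IDS

SIMILARITY_BIN_WIDTH = 0.02
LOCATION_N_BINS = 40


def _histogram(values, bins) -> dict:
    counts, edges = np.histogram(values, bins=bins)
    return {"edges": [round(float(e), 6) for e in edges],
            "counts": [int(c) for c in counts]}


def build_report_payload(fit: CutoffFitResults,
                         counts: dict[str, int] | None = None) -> dict:
    """Assemble the report JSON payload from a cutoff fit."""
    if fit.model is None or fit.per_length is None:
        raise ValueError("report needs a fit with its model and diagnostics")
    samples = fit.model.samples
    aps = {}
    for ap_id in AP_IDS:
        chosen = fit.cutoffs[ap_id]
        ap_samples = [s for s in samples if s.ap_id == ap_id
                      and s.ap_sub_length == chosen.ap_sub_length]
        max_loc = max((s.read_length for s in ap_samples), default=1)
        loc_bins = np.linspace(0, max_loc, LOCATION_N_BINS + 1)
        sim_bins = np.arange(0.0, 1.0 + SIMILARITY_BIN_WIDTH,
                             SIMILARITY_BIN_WIDTH)
        histograms = {}
        for label in ("true", "random"):
            group = [s for s in ap_samples if s.label == label]
            histograms[label] = {
                "similarity": _histogram([s.similarity for s in group],
                                         sim_bins),
                "end_distance": _histogram([s.end_distance for s in group],
                                           loc_bins),
                "n": len(group),
            }
        per_length = fit.per_length[fit.per_length["ap_id"] == ap_id]
        aps[ap_id] = {
            "cutoffs": asdict(chosen),
            "histograms": histograms,
            "per_length": per_length.drop(columns="ap_id").to_dict("records"),
        }
    payload = {
        "beta": fit.beta,
        "n_samples": len(samples),
        "aps": aps,
        "counts": dict(counts or {}),
    }
    validate_report(payload)
    return payload


def _schema() -> dict:
    text = resources.files("ontprep").joinpath("data/report_schema.json").read_text()
    return json.loads(text)


def validate_report(payload: dict, schema: dict | None = None,
                    path: str = "$") -> None:
    """Structural validation against the shipped report schema.

    Checks types, required keys and array item types (a deliberately small
    subset of JSON-schema semantics). Raises ValueError on the first
    violation, naming the offending path.
    """
    if schema is None:
        schema = _schema()
    expected = schema.get("type")
    checkers = {
        "object": dict, "array": list, "string": str, "boolean": bool,
        "number": (int, float), "integer": int,
    }
    if expected and not isinstance(payload, checkers[expected]):
        raise ValueError(f"{path}: expected {expected}, "
                         f"got {type(payload).__name__}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in payload:
                raise ValueError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in payload:
                validate_report(payload[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key, value in payload.items():
                if key not in props:
                    validate_report(value, extra, f"{path}.{key}")
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(payload):
            validate_report(item, schema["items"], f"{path}[{i}]")


def _bars(hist: dict, color: str) -> str:
    counts = hist["counts"]
    peak = max(counts) or 1
    bars = "".join(
        f'<div class="bar" style="height:{60 * c / peak:.1f}px;'
        f'background:{color}" title="{c}"></div>'
        for c in counts
    )
    return f'<div class="hist">{bars}</div>'


def render_html(payload: dict) -> str:
    """Static HTML view of a report payload (deterministic, self-contained)."""
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>AP cutoff tuning report</title><style>",
        "body{font-family:sans-serif;margin:2em;color:#222}",
        "table{border-collapse:collapse;margin:1em 0}",
        "td,th{border:1px solid #bbb;padding:4px 10px;text-align:right}",
        "th{background:#eee}",
        ".hist{display:flex;align-items:flex-end;height:64px;gap:1px;"
        "margin:4px 0 12px}",
        ".bar{width:8px;min-height:1px}",
        "</style></head><body>",
        "<h1>Adapter/primer cutoff tuning report</h1>",
        f"<p>beta = {payload['beta']:g}; alignment samples = "
        f"{payload['n_samples']}</p>",
    ]
    for ap_id, ap in payload["aps"].items():
        c = ap["cutoffs"]
        parts += [
            f"<h2>{ap_id} AP</h2>",
            "<table><tr><th>similarity cutoff</th><th>location cutoff</th>"
            "<th>AP substring length</th><th>precision</th><th>recall</th>"
            "<th>F_beta</th></tr>",
            f"<tr><td>{c['similarity_cutoff']:.2f}</td>"
            f"<td>{c['location_cutoff']}</td><td>{c['ap_sub_length']}</td>"
            f"<td>{c['precision']:.4f}</td><td>{c['recall']:.4f}</td>"
            f"<td>{c['f_beta']:.4f}</td></tr></table>",
            "<h3>Similarity distributions (true / random)</h3>",
            _bars(ap["histograms"]["true"]["similarity"], "#2a9d8f"),
            _bars(ap["histograms"]["random"]["similarity"], "#e76f51"),
            "<h3>End-distance distributions (true / random)</h3>",
            _bars(ap["histograms"]["true"]["end_distance"], "#2a9d8f"),
            _bars(ap["histograms"]["random"]["end_distance"], "#e76f51"),
            "<h3>Best F_beta per AP substring length</h3>",
            "<table><tr><th>L</th><th>s_cut</th><th>loc_cut</th>"
            "<th>P</th><th>R</th><th>F_beta</th></tr>",
        ]
        for row in ap["per_length"]:
            parts.append(
                f"<tr><td>{row['ap_sub_length']}</td>"
                f"<td>{row['similarity_cutoff']:.2f}</td>"
                f"<td>{row['location_cutoff']}</td>"
                f"<td>{row['precision']:.4f}</td><td>{row['recall']:.4f}</td>"
                f"<td>{row['f_beta']:.4f}</td></tr>")
        parts.append("</table>")
    if payload["counts"]:
        parts.append("<h2>Output categories</h2><table>"
                     "<tr><th>category</th><th>reads</th></tr>")
        for key, value in payload["counts"].items():
            parts.append(f"<tr><td>{key}</td><td>{value}</td></tr>")
        parts.append("</table>")
    parts.append("</body></html>")
    return "".join(parts)


def write_report(fit: CutoffFitResults, counts: dict[str, int] | None,
                 prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.report.json`` and ``<prefix>.report.html``."""
    payload = build_report_payload(fit, counts)
    prefix = Path(prefix)
    json_path = prefix.with_name(prefix.name + ".report.json")
    html_path = prefix.with_name(prefix.name + ".report.html")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    html_path.write_text(render_html(payload))
    return json_path, html_path
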