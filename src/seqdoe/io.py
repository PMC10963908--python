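"""Readers and writers for designs, responses, truths and fit reports.

All CSV writers emit '#'-prefixed provenance comment headers (tool version,
generator words, a content hash) that the readers skip, so write->read
round-trips are bit-exact. Decimal point, no thousands separators.
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import CodedDesign, DefiningWord
from .errors import ParseError, SchemaError
from .factors import Factor
from .model import FitResult, validate_response_table
from .synthetic import GroundTruth


def _content_hash(text: str) -> str:
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def _read_commented_csv(path):
    comments = []
    body = []
    with open(path) as fh:
        for line in fh:
            (comments if line.startswith("#") else body).append(line)
    if not body:
        raise SchemaError(f"{path}: no data rows")
    return comments, "".join(body)


# ---------------------------------------------------------------------------
# designs


def write_design(design: CodedDesign, path) -> None:
    frame = design.to_frame()
    csv = frame.to_csv()
    gens = ";".join(w.label(design.factor_names) for w in design.generators)
    header = (
        f"# seqdoe {__version__} design\n"
        f"# generators: {gens}\n"
        f"# hash: {_content_hash(csv)}\n"
    )
    Path(path).write_text(header + csv)


def _parse_generator_labels(label_field: str, names):
    gens = []
    for label in filter(None, label_field.split(";")):
        sign = 1
        if label.startswith("-"):
            sign, label = -1, label[1:]
        try:
            members = frozenset(names.index(n) for n in label.split(":"))
        except ValueError:
            raise ParseError(f"generator {label!r} names unknown factors")
        gens.append(DefiningWord(members, sign))
    return tuple(gens)


def read_design(path) -> CodedDesign:
    """Read a design CSV (header of factor names, cells -1/1, optional
    leading run_id column, optional provenance comments)."""
    comments, body = _read_commented_csv(path)
    try:
        frame = pd.read_csv(_io.StringIO(body))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.columns[0] == "run_id":
        frame = frame.set_index("run_id")
        run_ids = tuple(str(r) for r in frame.index)
    else:
        run_ids = ()
    if frame.shape[1] == 0:
        raise SchemaError(f"{path}: no factor columns")
    if any(str(c).startswith("Unnamed") for c in frame.columns):
        raise SchemaError(f"{path}: missing or unnamed header fields")
    values = frame.to_numpy()
    bad = np.argwhere(~np.isin(values, (-1, 1)))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path}: cell at row {r + 1}, column {frame.columns[c]!r} is "
            f"{values[r, c]!r}, expected -1 or 1"
        )
    names = tuple(str(c) for c in frame.columns)
    generators = ()
    for line in comments:
        if line.startswith("# generators:"):
            generators = _parse_generator_labels(
                line.split(":", 1)[1].strip(), list(names)
            )
    return CodedDesign(
        values.astype(np.int8), names, generators=generators, run_ids=run_ids
    )


# ---------------------------------------------------------------------------
# responses


def write_response(responses: pd.DataFrame, path, seed=None) -> None:
    validate_response_table(responses)
    csv = responses.to_csv(index=False)
    header = (
        f"# seqdoe {__version__} responses\n"
        f"# seed: {seed}\n"
        f"# hash: {_content_hash(csv)}\n"
    )
    Path(path).write_text(header + csv)


def read_response(path, design: CodedDesign | None = None) -> pd.DataFrame:
    _, body = _read_commented_csv(path)
    try:
        frame = pd.read_csv(_io.StringIO(body))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return validate_response_table(frame, design)


# ---------------------------------------------------------------------------
# factor configs and truths


def read_factors(path) -> tuple[Factor, ...]:
    """YAML mapping name -> {category, low, high}; order = column order."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping of factor names")
    factors = []
    for name, spec in raw.items():
        try:
            factors.append(
                Factor(str(name), spec["category"], str(spec["low"]),
                       str(spec["high"]))
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(
                f"{path}: factor {name!r} needs category/low/high"
            ) from exc
    return tuple(factors)


def write_factors(factors, path) -> None:
    data = {
        f.name: {"category": f.category, "low": f.low_label, "high": f.high_label}
        for f in factors
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_truth(truth: GroundTruth, path) -> None:
    data = {
        "factors": list(truth.factor_names),
        "beta0": truth.beta0,
        "main_effects": dict(truth.main_effects),
        "interactions": {
            ":".join(pair): coef for pair, coef in truth.interactions.items()
        },
        "noise_cv": truth.noise_cv,
        "floor": truth.floor,
        "noise_model": truth.noise_model,
        "seed": truth.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_truth(path) -> GroundTruth:
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return GroundTruth(
            factor_names=tuple(raw["factors"]),
            beta0=float(raw["beta0"]),
            main_effects=raw.get("main_effects", {}),
            interactions={
                tuple(k.split(":")): v
                for k, v in raw.get("interactions", {}).items()
            },
            noise_cv=float(raw.get("noise_cv", 0.15)),
            floor=float(raw.get("floor", 0.0)),
            noise_model=raw.get("noise_model", "lognormal"),
            seed=raw.get("seed"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed truth file") from exc


# ---------------------------------------------------------------------------
# fit reports


def write_fit_report(fit: FitResult, outdir, prefix: str = "fit") -> None:
    """Tidy coefficient CSV plus a JSON metrics summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = fit.summary_frame()
    csv = frame.to_csv(index=False)
    header = f"# seqdoe {__version__} fit report\n# hash: {_content_hash(csv)}\n"
    (outdir / f"{prefix}_coefficients.csv").write_text(header + csv)
    summary = {
        "adj_r2": None if np.isnan(fit.adj_r_squared) else fit.adj_r_squared,
        "r2": None if np.isnan(fit.r_squared) else fit.r_squared,
        "mae": fit.mae,
        "n_obs": fit.n_obs,
        "n_terms": fit.n_terms,
    }
    (outdir / f"{prefix}_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
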