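"""Score-file reading/writing and the JSON evaluation report.

The file surface follows the forensic convention: tab-separated lines of
``label<TAB>log10(LR)``, labels 1/0 (aliases "target"/"nontarget" and
"same"/"different" accepted), LR column in base-10 logs.  Internally all
log-LRs are natural-log; the conversion happens here and only here (via
:func:`ecelab.bayes.natural_from_log10`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayes import LRSet, log10_from_natural, natural_from_log10

__all__ = [
    "SCHEMA_VERSION",
    "ScoreFileDialect",
    "ScoreFileError",
    "read_scores",
    "write_scores",
    "build_report",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = "1.0"

_LABEL_ALIASES = {
    "1": 1, "0": 0,
    "target": 1, "nontarget": 0,
    "same": 1, "different": 0,
}


class ScoreFileError(ValueError):
    """A score file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class ScoreFileDialect:
    """How a score file is laid out.

    Columns are fixed as (label, score); the dialect controls the
    delimiter, an optional header line, and the log base of the score
    column (10 at the file surface by default, converted to natural log
    in memory).
    """

    delimiter: str = "\t"
    header: bool = False
    log_base: float = 10.0
    label_aliases: dict = field(default_factory=lambda: dict(_LABEL_ALIASES))

    def to_natural(self, values):
        if self.log_base == 10.0:
            return natural_from_log10(values)
        return np.asarray(values, dtype=float) * np.log(self.log_base)

    def from_natural(self, values):
        if self.log_base == 10.0:
            return log10_from_natural(values)
        return np.asarray(values, dtype=float) / np.log(self.log_base)


def read_scores(path, dialect: ScoreFileDialect = ScoreFileDialect()) -> LRSet:
    """Read a two-column (label, log-LR) score file into an :class:`LRSet`.

    Parse failures raise :class:`ScoreFileError` naming the line number.
    A file containing only one class is read with a warning; operations
    that need both classes fail later with a precondition error.
    """
    path = Path(path)
    labels, scores = [], []
    with path.open() as fh:
        lines = fh.read().splitlines()
    start = 1 if dialect.header else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(dialect.delimiter)
        if len(parts) < 2:
            raise ScoreFileError(
                f"{path}:{lineno}: expected 2 columns (label, score), "
                f"got {len(parts)}: {line!r}"
            )
        tok = parts[0].strip().lower()
        if tok not in dialect.label_aliases:
            raise ScoreFileError(
                f"{path}:{lineno}: unknown label token {parts[0]!r}"
            )
        try:
            score = float(parts[1])
        except ValueError:
            raise ScoreFileError(
                f"{path}:{lineno}: score {parts[1]!r} is not a number"
            ) from None
        if np.isnan(score):
            raise ScoreFileError(f"{path}:{lineno}: NaN score is not allowed")
        labels.append(dialect.label_aliases[tok])
        scores.append(score)
    if not scores:
        raise ScoreFileError(f"{path}: no trials found")
    lr_set = LRSet(dialect.to_natural(scores), np.array(labels), name=path.stem)
    if lr_set.n1 == 0 or lr_set.n2 == 0:
        warnings.warn(
            f"{path}: only one class present (N1={lr_set.n1}, N2={lr_set.n2})",
            stacklevel=2,
        )
    return lr_set


def write_scores(
    lr_set: LRSet, path, dialect: ScoreFileDialect = ScoreFileDialect()
) -> None:
    """Write an LR set as a score file (17 significant digits, so a
    read-back reproduces the log-LRs to well under 1e-12)."""
    path = Path(path)
    surf = dialect.from_natural(lr_set.log_lr)
    with path.open("w") as fh:
        if dialect.header:
            fh.write(f"label{dialect.delimiter}log{dialect.log_base:g}_lr\n")
        for lab, s in zip(lr_set.label, surf):
            fh.write(f"{int(lab)}{dialect.delimiter}{s:.17g}\n")


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        if np.isnan(x):
            return "nan"
        if np.isinf(x):
            return "inf" if x > 0 else "-inf"
        return x
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, list):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    return x


def build_report(curve, cllr_triple, auc_value, reliability, metadata=None) -> dict:
    """Assemble the evaluation report document.

    Log-odds axes are base-10; all entropies/Cllr values are bits (both
    conventions are recorded in the document).  Non-finite numbers are
    serialized as the strings "inf"/"-inf"/"nan" so the JSON round-trips
    exactly through the standard parser.
    """
    c, cmin, ccal = cllr_triple
    doc = {
        "schema_version": SCHEMA_VERSION,
        "conventions": {
            "prior_axis": "base-10 log odds of P(theta1)",
            "entropy_units": "bits",
        },
        "ece_curve": {
            "prior_log10_odds": curve.prior_log10_odds,
            "ece": curve.ece,
            "ece_min": curve.ece_min,
            "neutral": curve.neutral,
        },
        "cllr": {"cllr": c, "cllr_min": cmin, "cllr_cal": ccal},
        "auc": auc_value,
        "reliability": {
            "prior_p1": reliability.prior.p1,
            "bin_left": reliability.bin_left,
            "bin_right": reliability.bin_right,
            "mean_predicted": reliability.mean_predicted,
            "frequency": reliability.frequency,
            "count": reliability.count,
        },
        "metadata": metadata or {},
    }
    return _jsonable(doc)


def write_report(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
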