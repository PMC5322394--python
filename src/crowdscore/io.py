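"""CSV/JSON input-output and run configuration.

All tabular artifacts are flat UTF-8 comma-separated files with a header
row; class labels are single letters (A–D).  Configurations and reports
are JSON.  Readers validate schemas up front and report offending rows
by line number so malformed inputs fail before any computation runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .contributor_qc import QCPolicy
from .crowd_sim import SimulationConfig
from .label_model import FOUR_CLASS, LabelScheme, SCHEMES

__all__ = [
    "ParseError",
    "RunConfig",
    "read_votes",
    "read_reference",
    "read_nuclei",
    "read_tests",
    "write_table",
    "load_run_config",
    "config_hash",
]

VOTE_COLUMNS = ("image_id", "contributor_id", "label")
REFERENCE_COLUMNS = ("image_id", "patient_id", "ref_label")
NUCLEI_COLUMNS = ("image_id", "contributor_id", "n_positive", "n_negative")
TEST_COLUMNS = ("contributor_id", "question_index", "correct")


class ParseError(ValueError):
    """A CSV failed schema validation; the message points at the rows."""


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty")
    missing = set(required) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    return frame


def _check_labels(frame: pd.DataFrame, column: str, scheme: LabelScheme,
                  path) -> None:
    bad = ~frame[column].isin(scheme.codes)
    if bad.any():
        lines = (frame.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise ParseError(
            f"{path}: column {column!r} has labels outside scheme "
            f"{scheme.name} at lines {lines}"
        )


def read_votes(path, scheme: LabelScheme = FOUR_CLASS) -> pd.DataFrame:
    """Crowd vote table: image_id, contributor_id, label[, trust, ...]."""
    frame = _read_csv(path, VOTE_COLUMNS)
    _check_labels(frame, "label", scheme, path)
    if "trust" in frame.columns:
        bad = frame["trust"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ParseError(f"{path}: trust values outside [0,1]")
    return frame


def read_reference(path, scheme: LabelScheme) -> pd.DataFrame:
    """Reference label table: image_id, patient_id, ref_label."""
    frame = _read_csv(path, REFERENCE_COLUMNS)
    _check_labels(frame, "ref_label", scheme, path)
    return frame


def read_nuclei(path) -> pd.DataFrame:
    """Nucleus count table: image_id, contributor_id, n_positive, n_negative."""
    frame = _read_csv(path, NUCLEI_COLUMNS)
    for col in ("n_positive", "n_negative"):
        if (frame[col] < 0).any():
            lines = (frame.index[frame[col] < 0] + 2).tolist()[:5]
            raise ParseError(f"{path}: negative {col} at lines {lines}")
    if "has_nuclei" not in frame.columns:
        frame["has_nuclei"] = (frame["n_positive"] + frame["n_negative"]) > 0
    return frame


def read_tests(path) -> pd.DataFrame:
    """Test-question outcome log: contributor_id, question_index, correct."""
    return _read_csv(path, TEST_COLUMNS)


def write_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serialisable to JSON."""

    mode: str = "image"  # image | nuclei
    aggregator: str = "cv"
    seed: int = 0
    scheme: str = "four_class"
    qc_policy: QCPolicy = field(default_factory=QCPolicy)
    simulation: Optional[SimulationConfig] = None
    votes_path: Optional[str] = None
    nuclei_path: Optional[str] = None
    reference_path: Optional[str] = None
    outdir: Optional[str] = None
    apply_qc: bool = False

    def label_scheme(self) -> LabelScheme:
        return SCHEMES[self.scheme]

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        if self.simulation is not None and self.simulation.error_kernel is not None:
            data["simulation"]["error_kernel"] = (
                self.simulation.kernel().tolist()
            )
        return data


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a JSON file; nested blocks are optional."""
    with open(path) as fh:
        data = json.load(fh)
    if "qc_policy" in data:
        data["qc_policy"] = QCPolicy(**data["qc_policy"])
    if data.get("simulation") is not None:
        sim = dict(data["simulation"])
        for key in ("images_per_patient_probs", "class_prevalence"):
            if key in sim:
                sim[key] = tuple(sim[key])
        data["simulation"] = SimulationConfig(**sim)
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form, for provenance logs."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()
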