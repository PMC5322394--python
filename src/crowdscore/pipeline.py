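"""End-to-end pipelines: gate → aggregate → patient rollup → metrics.

Two modes mirror the two crowdsourcing tasks: ``image`` fuses 4-class
votes (CV/CT/wCV/wCT) and merges the result to the pathologist 3-class
scale; ``nuclei`` fuses nucleus counts through the median positivity
index, which is already 3-class.  Patient calls are the median of the
patient's image labels; agreement with the reference is reported at
3-class and (after merging positives) 2-class granularity, alongside a
provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import __version__
from .aggregation import (
    aggregate_images,
    aggregate_nuclei_images,
    aggregate_patients,
)
from .contributor_qc import gate
from .crowd_sim import simulate_dataset
from .io import (
    RunConfig,
    config_hash,
    read_nuclei,
    read_reference,
    read_votes,
    write_table,
)
from .label_model import (
    FOUR_CLASS,
    THREE_CLASS,
    TWO_CLASS,
    scheme_mapping,
)
from .metrics import AgreementReport, agreement_report, confusion

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    image_labels: pd.DataFrame
    patient_labels: pd.DataFrame
    reference_patients: pd.DataFrame
    reports: dict[str, AgreementReport]
    confusions: dict[str, pd.DataFrame]
    provenance: dict

    def agreement_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "reports": {k: r.to_dict() for k, r in self.reports.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _merge_codes(labels: pd.Series, from_scheme, to_scheme) -> pd.Series:
    mapping = {
        code: cls.code for code, cls in scheme_mapping(from_scheme, to_scheme).items()
    }
    return labels.map(mapping)


def _load_inputs(config: RunConfig) -> dict[str, pd.DataFrame]:
    if config.simulation is not None:
        return simulate_dataset(config.simulation, seed=config.seed)
    data: dict[str, pd.DataFrame] = {}
    if config.reference_path is None:
        raise ValueError("config needs either a simulation block or input paths")
    ref = read_reference(config.reference_path, THREE_CLASS)
    data["reference"] = ref.rename(columns={})
    if config.mode == "image":
        if config.votes_path is None:
            raise ValueError("image mode needs votes_path")
        data["votes"] = read_votes(config.votes_path, FOUR_CLASS)
    else:
        if config.nuclei_path is None:
            raise ValueError("nuclei mode needs nuclei_path")
        data["nuclei"] = read_nuclei(config.nuclei_path)
    return data


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute one labeling pipeline and return (and optionally write) results."""
    if config.mode not in ("image", "nuclei"):
        raise ValueError(f"mode must be 'image' or 'nuclei', got {config.mode!r}")
    data = _load_inputs(config)
    reference = data["reference"]
    ref_col = "ref_label" if "ref_label" in reference.columns else "label"

    if config.mode == "image":
        votes = data["votes"]
        if config.apply_qc and {"timestamp", "is_test_question"} <= set(
            votes.columns
        ):
            gated = gate(votes, config.qc_policy)
            votes = gated[gated["status"] == "trusted"]
            if votes.empty:
                raise ValueError("no trusted votes left after QC gating")
        agg4 = aggregate_images(votes, method=config.aggregator, scheme=FOUR_CLASS)
        image_labels = agg4.copy()
        image_labels["label"] = _merge_codes(
            agg4["label"], FOUR_CLASS, THREE_CLASS
        )
    else:
        image_labels = aggregate_nuclei_images(data["nuclei"], THREE_CLASS)
        n_unscorable = int((image_labels["label"] == "NA").sum())
        if n_unscorable:
            warnings.warn(f"{n_unscorable} images unscorable from counts")

    per_image_ref = reference.drop_duplicates("image_id").set_index("image_id")
    missing = set(image_labels["image_id"]) - set(per_image_ref.index)
    if missing:
        raise ValueError(
            f"reference labels missing for images: {sorted(missing)[:10]}"
        )
    image_labels = image_labels.merge(
        per_image_ref[["patient_id"]].reset_index(), on="image_id", how="left"
    )

    patient_labels = aggregate_patients(image_labels, THREE_CLASS)
    ref_patients = (
        reference.drop_duplicates("patient_id")[["patient_id", ref_col]]
        .rename(columns={ref_col: "label"})
        .set_index("patient_id")
    )
    merged = patient_labels.set_index("patient_id").join(
        ref_patients, rsuffix="_ref", how="inner"
    )

    actual3 = merged["label_ref"].tolist()
    predicted3 = merged["label"].tolist()
    actual2 = _merge_codes(merged["label_ref"], THREE_CLASS, TWO_CLASS).tolist()
    predicted2 = _merge_codes(merged["label"], THREE_CLASS, TWO_CLASS).tolist()

    reports = {
        "three_class": agreement_report(actual3, predicted3, THREE_CLASS),
        "two_class": agreement_report(actual2, predicted2, TWO_CLASS),
    }
    confusions = {
        "three_class": confusion(actual3, predicted3, THREE_CLASS.codes).to_frame(),
        "two_class": confusion(actual2, predicted2, TWO_CLASS.codes).to_frame(),
    }
    provenance = {
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "mode": config.mode,
        "aggregator": config.aggregator if config.mode == "image" else "nuclei",
        "version": __version__,
        "n_images": int(len(image_labels)),
        "n_patients": int(len(merged)),
    }
    result = PipelineResult(
        image_labels=image_labels,
        patient_labels=patient_labels,
        reference_patients=ref_patients.reset_index(),
        reports=reports,
        confusions=confusions,
        provenance=provenance,
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(image_labels, outdir / "aggregated_images.csv")
        write_table(patient_labels, outdir / "patient_labels.csv")
        for name, frame in confusions.items():
            frame.rename_axis("actual").to_csv(outdir / f"confusion_{name}.csv")
        (outdir / "agreement.json").write_text(result.agreement_json())
    return result
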