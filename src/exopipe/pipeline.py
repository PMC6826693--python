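"""Fixed-order pipeline orchestration with a reproducible run manifest.

Stage order (immutable): reliability filter → global-mean normalization →
detection filter → batch (PVCA) verdict → imputation → differential
expression → signature selection (optional) → chemoresistance index →
k-means stratification → association & survival.  A significant batch
verdict halts the run unless explicitly overridden, because no batch
correction is applied downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .batch import assess_batch_effect, run_pvca
from .datatypes import AnalysisConfig, ChemoresistanceList, CTMatrix
from .diffexpr import differential_expression, significance_filter
from .preprocess import (
    coefficient_of_variation,
    count_detected,
    detection_filter,
    filter_reliable_ct,
    impute_missing,
    normalize_global_mean,
)
from .resistance import (
    association_tests,
    chemoresistance_index,
    kmeans_stratify,
    logrank_efs,
    modulation_directions,
)
from .signature import select_signature

log = logging.getLogger("exopipe")

STAGES = (
    "reliability_filter",
    "normalization",
    "detection_filter",
    "batch_verdict",
    "imputation",
    "differential_expression",
    "signature_selection",
    "chemoresistance_index",
    "stratification",
    "association_survival",
)


class BatchEffectError(RuntimeError):
    """Raised when PVCA flags a significant batch effect and no override
    was requested."""


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config, input digests, seed,
    per-stage shapes and the decisions taken."""

    config: dict
    input_digests: dict[str, str]
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    decisions: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        log.info("stage %s: %s", stage, info)
        self.stages.append({"stage": stage, **info})

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "input_digests": self.input_digests,
                "stages": self.stages,
                "decisions": self.decisions,
            },
            indent=2,
            default=str,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _digest_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(sep="\t", na_rep="NA").encode()
    ).hexdigest()


@dataclass
class PipelineResult:
    normalized: object
    qc_counts: pd.DataFrame
    dropped_assays: list[str]
    cv_report: object
    pvca: object
    batch_verdict: str
    diffexpr: pd.DataFrame
    significant: pd.DataFrame
    signature: object | None
    ci: object
    clusters: object
    associations: pd.DataFrame | None
    survival: object | None
    manifest: RunManifest


def run_pipeline(
    ct: CTMatrix,
    clinical: pd.DataFrame,
    clist: ChemoresistanceList,
    config: AnalysisConfig | None = None,
    run_signature: bool = True,
    override_batch: bool = False,
) -> PipelineResult:
    """Execute the full analysis in the fixed stage order.

    Raises :class:`BatchEffectError` if the PVCA verdict is
    "significant" and ``override_batch`` is False.  Stage preconditions
    propagate with the stage name attached.
    """
    config = config or AnalysisConfig()
    manifest = RunManifest(
        config=config.to_dict(),
        input_digests={
            "ct": _digest_frame(ct.ct),
            "clinical": _digest_frame(clinical),
            "chemoresistance_list": hashlib.sha256(
                str([(e.mirna, e.drug, e.direction) for e in clist.entries]).encode()
            ).hexdigest(),
        },
        seed=config.random_seed,
    )

    def run_stage(name, fn):
        try:
            return fn()
        except BatchEffectError:
            raise
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    reliable = run_stage(
        "reliability_filter",
        lambda: filter_reliable_ct(ct, config.ct_min, config.ct_max),
    )
    manifest.record(
        "reliability_filter",
        n_samples=len(reliable.samples),
        n_mirnas=len(reliable.mirnas),
        n_missing=reliable.n_missing(),
    )

    norm = run_stage(
        "normalization", lambda: normalize_global_mean(reliable, config.ct_max)
    )
    qc_counts = count_detected(norm)
    cv_report = coefficient_of_variation(ct, norm)
    manifest.record(
        "normalization",
        median_cv_raw=float(cv_report.cv_raw.median()),
        median_cv_normalized=float(cv_report.cv_normalized.median()),
        ks_pvalue=cv_report.ks_pvalue,
    )

    norm_f, dropped = run_stage(
        "detection_filter",
        lambda: detection_filter(norm, config.detection_fraction),
    )
    manifest.record(
        "detection_filter",
        n_kept=len(norm_f.mirnas),
        n_dropped=len(dropped),
    )

    norm_i = run_stage("imputation", lambda: impute_missing(norm_f))

    # timepoint is a known design axis of two-timepoint cohorts; modeling it
    # keeps its (large) variance from bleeding into the origin component
    pvca = run_stage(
        "batch_verdict",
        lambda: run_pvca(
            norm_i,
            clinical,
            batch_factor="origin",
            bio_factors=("age", "inss_stage", "mycn", "timepoint"),
        ),
    )
    verdict = assess_batch_effect(pvca, "origin", config.wapv_batch_threshold)
    manifest.record(
        "batch_verdict",
        wapv_origin=float(pvca.wapv["origin"]),
        verdict=verdict,
        overridden=bool(override_batch and verdict == "significant"),
    )
    manifest.decisions["batch"] = verdict
    if verdict == "significant" and not override_batch:
        raise BatchEffectError(
            f"PVCA flags a significant batch effect "
            f"(WAPV origin = {pvca.wapv['origin']:.3f} >= "
            f"{config.wapv_batch_threshold}); no correction is applied by "
            "this pipeline — rerun with override_batch=True to proceed"
        )

    manifest.record(
        "imputation",
        n_imputed=int(norm_i.imputed.sum().sum()),
    )

    table = run_stage(
        "differential_expression", lambda: differential_expression(norm_i)
    )
    sig_table = significance_filter(table, config.fc_threshold_log2, config.alpha)
    manifest.record(
        "differential_expression",
        n_tested=len(table),
        n_significant=len(sig_table),
    )

    signature = None
    if run_signature:
        try:
            signature, _ = select_signature(
                norm_i, clinical, mixing=config.elasticnet_mixing
            )
            manifest.record(
                "signature_selection",
                n_selected=len(signature.selected_mirnas),
                chosen_penalty=signature.chosen_penalty,
            )
        except ValueError as exc:
            manifest.record("signature_selection", skipped=str(exc))
    else:
        manifest.record("signature_selection", skipped="disabled")

    directions = modulation_directions(norm_i)
    ci = run_stage(
        "chemoresistance_index", lambda: chemoresistance_index(directions, clist)
    )
    manifest.record(
        "chemoresistance_index",
        n_patients=len(ci.ci),
        drugs=list(ci.ci.columns),
        excluded_drugs=ci.excluded_drugs,
    )

    clusters = run_stage(
        "stratification",
        lambda: kmeans_stratify(ci, k=config.kmeans_k, seed=config.random_seed),
    )
    manifest.record(
        "stratification",
        sizes={int(c): int((clusters.labels == c).sum()) for c in sorted(clusters.labels.unique())},
    )

    associations = None
    survival = None
    if config.kmeans_k == 2:
        associations = run_stage(
            "association_survival", lambda: association_tests(clusters, clinical)
        )
        survival = run_stage(
            "association_survival", lambda: logrank_efs(clusters, clinical)
        )
        manifest.record(
            "association_survival",
            logrank_p=survival.logrank_p,
        )
    else:
        manifest.record("association_survival", skipped="k != 2")

    return PipelineResult(
        normalized=norm_i,
        qc_counts=qc_counts,
        dropped_assays=dropped,
        cv_report=cv_report,
        pvca=pvca,
        batch_verdict=verdict,
        diffexpr=table,
        significant=sig_table,
        signature=signature,
        ci=ci,
        clusters=clusters,
        associations=associations,
        survival=survival,
        manifest=manifest,
    )
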