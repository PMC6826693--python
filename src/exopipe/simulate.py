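"""Synthetic two-timepoint exo-miRNA CT cohorts.

The generator emulates the statistical structure the pipeline assumes:
per-assay baseline CTs, per-sample technical offsets (what global-mean
normalization removes), per-center assay-specific batch shifts, a global
end-of-induction downregulation on a subset of assays, response-group
signature effects on three designated miRNAs, latent chemoresistance
status driving concordant modulation of the literature-listed miRNAs,
detection censoring at the CT ceiling, and exponential event-free
survival whose hazard depends on the latent resistance status.

It models CT-level statistics only, not exosome biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CTMatrix,
    PROGNOSTIC_DRUGS,
    ChemoresistanceList,
    canonical_mirna,
    make_sample_id,
    validate_clinical,
)
from .io_tables import load_reference_chemoresistance_list

#: end-of-induction median fold changes planted on the signature miRNAs in
#: minor-response patients (CT shift = −fold change)
DEFAULT_SIGNATURE_EFFECTS = {
    "hsa-miR-29c": 6.52,
    "hsa-let-7b": 3.31,
    "hsa-miR-342-3p": 2.83,
}


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    The cohort mirrors the modeled study: 52 patients sampled at onset
    and at the end of induction (104 samples), 381 assays with detection
    censoring at CT 32, a predominantly Italian four-center origin mix,
    and the observed MR/PR/VGPR/NA response frequencies.
    """

    n_patients: int = 52
    n_mirnas: int = 381
    seed: int = 0
    baseline_ct_low: float = 18.0
    baseline_ct_high: float = 30.0
    noise_sd: float = 0.5
    sample_offset_sd: float = 0.5
    detection_ceiling: float = 32.0
    global_downregulation_shift: float = 2.0
    downregulated_fraction: float = 0.3
    batch_levels: tuple[str, ...] = ("IT", "ES", "UK", "FR")
    batch_probs: tuple[float, ...] = (0.7, 0.1, 0.1, 0.1)
    batch_sd: float = 0.1
    response_probs: tuple[float, ...] = (6 / 52, 33 / 52, 8 / 52, 5 / 52)  # MR, PR, VGPR, NA
    signature_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_EFFECTS)
    )
    resistance_prevalence: float = 0.5
    resistance_effect: float = 1.0
    linked_drugs: tuple[str, ...] = PROGNOSTIC_DRUGS
    #: prevalence of the per-drug independent statuses (non-linked drugs);
    #: None means same as resistance_prevalence, 0 plants no modulation there
    independent_drug_prevalence: float | None = None
    efs_base_hazard: float = 0.008  # events per month
    hazard_ratio_resistant: float = 3.0
    censoring_rate: float = 0.005  # per month
    chemoresistance_list: ChemoresistanceList | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("noise_sd", "sample_offset_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for probs, what in ((self.batch_probs, "batch_probs"), (self.response_probs, "response_probs")):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{what} must be nonnegative and sum to 1")
        if len(self.batch_probs) != len(self.batch_levels):
            raise ValueError("batch_probs must match batch_levels")
        if not (0 <= self.resistance_prevalence <= 1):
            raise ValueError("resistance_prevalence must be in [0, 1]")
        if not (0 <= self.downregulated_fraction <= 1):
            raise ValueError("downregulated_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted quantities that recovery tests check against."""

    resistant: pd.Series  # shared latent status driving the linked drugs + EFS
    resistance_by_drug: pd.DataFrame  # patient x drug boolean
    signature_effects: dict[str, float]
    downregulated_mirnas: list[str]
    batch_sd: float
    batch_shifts: pd.DataFrame  # center x miRNA
    sample_offsets: pd.Series
    origin: pd.Series


@dataclass
class SyntheticCohort:
    ct: CTMatrix
    clinical: pd.DataFrame
    truth: GroundTruth


def _mirna_names(n: int, clist: ChemoresistanceList, signature: dict[str, float]) -> list[str]:
    named = list(dict.fromkeys([*clist.mirnas, *signature]))
    if len(named) > n:
        raise ValueError(
            f"n_mirnas={n} is smaller than the {len(named)} named assays"
        )
    fillers = [f"hsa-miR-sim-{i:04d}" for i in range(n - len(named))]
    return named + fillers


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a synthetic cohort under the configured study conditions.

    CT(sample, assay) = baseline + sample offset + center x assay batch
    shift + end-of-induction effects (global downregulation subset,
    MR-only signature shifts, resistance-concordant shifts signed by the
    chemoresistance list) + Gaussian noise; draws above the detection
    ceiling are censored to missing.  EFS times are exponential with the
    hazard multiplied for latent-resistant patients and independent
    exponential right-censoring.
    """
    rng = np.random.default_rng(config.seed)
    clist = config.chemoresistance_list or load_reference_chemoresistance_list()
    mirnas = _mirna_names(config.n_mirnas, clist, config.signature_effects)
    n_m = len(mirnas)
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]

    baseline = rng.uniform(config.baseline_ct_low, config.baseline_ct_high, n_m)

    origin = rng.choice(config.batch_levels, size=config.n_patients, p=config.batch_probs)
    batch_shifts = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, (len(config.batch_levels), n_m)),
        index=list(config.batch_levels),
        columns=mirnas,
    )

    response = rng.choice(
        ["MR", "PR", "VGPR", "NA"], size=config.n_patients, p=config.response_probs
    )

    n_down = int(round(config.downregulated_fraction * n_m))
    down_idx = rng.choice(n_m, size=n_down, replace=False)
    down_mask = np.zeros(n_m)
    down_mask[down_idx] = 1.0

    sig_shift = np.zeros(n_m)
    mcol = {m: j for j, m in enumerate(mirnas)}
    for m, eff in config.signature_effects.items():
        sig_shift[mcol[m]] = eff

    # shared latent resistance drives the linked (prognostic) drugs and the
    # EFS hazard; the remaining drugs get independent latent statuses
    shared = rng.random(config.n_patients) < config.resistance_prevalence
    drugs = clist.drugs_with_entries()
    res_by_drug = pd.DataFrame(False, index=patients, columns=drugs)
    for d in drugs:
        if d in config.linked_drugs:
            res_by_drug[d] = shared
        else:
            prev = (
                config.resistance_prevalence
                if config.independent_drug_prevalence is None
                else config.independent_drug_prevalence
            )
            res_by_drug[d] = rng.random(config.n_patients) < prev

    # per-patient resistance shift on each assay: direction "up" in the list
    # means expression rises (CT falls) in resistant patients
    res_shift = np.zeros((config.n_patients, n_m))
    for d in drugs:
        sign_map = clist.by_drug(d)
        for m in mirnas:
            key = canonical_mirna(m)
            if key in sign_map:
                s = -1.0 if sign_map[key] == "up" else 1.0
                res_shift[res_by_drug[d].to_numpy(), mcol[m]] += s * config.resistance_effect

    rows = {}
    sample_offsets = {}
    for i, p in enumerate(patients):
        for tp in ("onset", "end"):
            sid = make_sample_id(p, tp)
            offset = rng.normal(0.0, config.sample_offset_sd)
            sample_offsets[sid] = offset
            mu = baseline + offset + batch_shifts.loc[origin[i]].to_numpy()
            if tp == "end":
                mu = mu + config.global_downregulation_shift * down_mask
                if response[i] == "MR":
                    mu = mu + sig_shift
                mu = mu + res_shift[i]
            ct = mu + rng.normal(0.0, config.noise_sd, n_m)
            ct[ct > config.detection_ceiling] = np.nan
            rows[sid] = ct
    ct_df = pd.DataFrame.from_dict(rows, orient="index", columns=mirnas)

    hazard = config.efs_base_hazard * np.where(shared, config.hazard_ratio_resistant, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, config.n_patients)
    else:
        censor_time = np.full(config.n_patients, np.inf)
    efs_time = np.minimum(event_time, censor_time)
    efs_event = (event_time <= censor_time).astype(int)

    inss = rng.choice(["4", "3", "4S"], size=config.n_patients, p=(47 / 52, 4 / 52, 1 / 52))
    mycn = rng.choice(
        ["AMPL", "NO AMPL", "NA"], size=config.n_patients, p=(22 / 52, 25 / 52, 5 / 52)
    )
    clinical = validate_clinical(
        pd.DataFrame(
            {
                "patient_id": patients,
                "inss_stage": inss,
                "mycn": mycn,
                "induction_response": response,
                "relapse": np.where(efs_event == 1, "yes", "no"),
                "efs_time": np.round(efs_time, 2),
                "efs_event": efs_event,
                "origin": origin,
                "age": np.round(rng.uniform(6, 120, config.n_patients), 1),
            }
        )
    )

    truth = GroundTruth(
        resistant=pd.Series(shared, index=patients, name="resistant"),
        resistance_by_drug=res_by_drug,
        signature_effects=dict(config.signature_effects),
        downregulated_mirnas=[mirnas[j] for j in sorted(down_idx)],
        batch_sd=config.batch_sd,
        batch_shifts=batch_shifts,
        sample_offsets=pd.Series(sample_offsets, name="sample_offset"),
        origin=pd.Series(origin, index=patients, name="origin"),
    )
    return SyntheticCohort(ct=CTMatrix(ct_df), clinical=clinical, truth=truth)


def planted_truth_report(cohort: SyntheticCohort) -> dict[str, pd.DataFrame | pd.Series | list]:
    """Ground-truth tables for recovery tests: latent labels and planted
    effects, keyed by quantity."""
    t = cohort.truth
    return {
        "resistant": t.resistant,
        "resistance_by_drug": t.resistance_by_drug,
        "signature_effects": pd.Series(t.signature_effects),
        "downregulated_mirnas": list(t.downregulated_mirnas),
        "origin": t.origin,
        "sample_offsets": t.sample_offsets,
        "batch_sd": t.batch_sd,
    }


def simulate_batch_matrix(
    n_samples: int = 50,
    n_mirnas: int = 100,
    batch_fraction: float = 0.3,
    n_centers: int = 4,
    seed: int = 0,
) -> tuple["pd.DataFrame", pd.DataFrame, float]:
    """Minimal complete expression matrix with a known batch-variance
    fraction, for variance-decomposition calibration.

    Each entry is center-by-assay batch shift plus unit-variance noise;
    the batch SD is chosen so the batch component contributes
    ``batch_fraction`` of the total variance.  Returns (NormalizedMatrix,
    clinical table, injected fraction).
    """
    from .datatypes import NormalizedMatrix

    rng = np.random.default_rng(seed)
    if not (0 <= batch_fraction < 1):
        raise ValueError("batch_fraction must be in [0, 1)")
    sigma_b = np.sqrt(batch_fraction / (1 - batch_fraction))
    mirnas = [f"hsa-miR-sim-{i:04d}" for i in range(n_mirnas)]
    patients = [f"P{i + 1:03d}" for i in range(n_samples)]
    samples = [make_sample_id(p, "onset") for p in patients]
    centers = np.array([f"C{i % n_centers}" for i in range(n_samples)])
    shifts = rng.normal(0.0, sigma_b, (n_centers, n_mirnas))
    center_ix = np.array([int(c[1:]) for c in centers])
    x = shifts[center_ix] + rng.normal(0.0, 1.0, (n_samples, n_mirnas))
    delta = pd.DataFrame(x, index=samples, columns=mirnas)
    detected = pd.DataFrame(True, index=samples, columns=mirnas)
    imputed = pd.DataFrame(False, index=samples, columns=mirnas)
    norm = NormalizedMatrix(delta, detected, imputed)
    clinical = validate_clinical(
        pd.DataFrame(
            {
                "patient_id": patients,
                "inss_stage": rng.choice(["4", "3"], n_samples, p=(0.9, 0.1)),
                "mycn": rng.choice(["AMPL", "NO AMPL"], n_samples),
                "induction_response": rng.choice(["MR", "PR", "VGPR"], n_samples),
                "relapse": "no",
                "efs_time": 36.0,
                "efs_event": 0,
                "origin": centers,
                "age": rng.uniform(6, 120, n_samples),
            }
        )
    )
    return norm, clinical, batch_fraction
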