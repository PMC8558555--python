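"""End-to-end per-patient analysis: filter, annotate, cluster, subtype.

This is the glue the CLI and the recovery experiments run: raw
per-specimen call tables go in, a per-patient evolutionary subtype call
comes out, together with the intermediate objects (filtered profiles,
shared/private partition, driver classification, clone trajectory) for
downstream cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .calls import FilterReport, MutationCall, SpecimenProfile, apply_filters
from .clonality import SharedPartition, cluster_clones, partition_mutations
from .drivers import DriverCall, DriverGeneList, classify_driver_events, driver_event_keys
from .simulate import SyntheticCohort
from .subtypes import SubtypeCall, Trajectory, assign_subtype, build_trajectory


@dataclass
class PatientAnalysis:
    """All per-patient products of the pipeline."""

    patient_id: str
    stroma: SpecimenProfile
    neoplasm: SpecimenProfile
    stroma_report: FilterReport
    neoplasm_report: FilterReport
    partition: SharedPartition
    driver_calls: list[DriverCall]
    trajectory: Trajectory
    subtype: SubtypeCall


def analyze_patient(
    stroma_calls: Sequence[MutationCall],
    neoplasm_calls: Sequence[MutationCall],
    normal_calls: Sequence[MutationCall] = (),
    blood_calls: Sequence[MutationCall] = (),
    genes: Optional[DriverGeneList] = None,
    tcf: float = 1.0,
    seed: int = 0,
    max_clusters: int = 6,
    presence_fraction: float = 0.5,
) -> PatientAnalysis:
    """Run the full pipeline for one patient's paired specimens.

    ``tcf`` is the neoplastic tumor cell fraction used as clustering
    purity (1.0 when unknown).  Raises when the neoplastic component
    retains no mutations — such patients cannot be subtyped and are
    excluded upstream in cohort runs.
    """
    if not neoplasm_calls:
        raise ValueError("patient has no neoplastic calls")
    patient_id = neoplasm_calls[0].patient_id

    def control(calls: Sequence[MutationCall], component: str) -> SpecimenProfile:
        return SpecimenProfile(
            patient_id=patient_id, component=component, mutations=list(calls)
        )

    normal = control(normal_calls, "normal") if normal_calls else None
    blood = control(blood_calls, "blood") if blood_calls else None

    if stroma_calls:
        stroma, s_report = apply_filters(
            stroma_calls, matched_normal=normal, matched_blood=blood
        )
    else:
        stroma = SpecimenProfile(patient_id=patient_id, component="stroma")
        s_report = FilterReport(0, {}, 0, {})
    neoplasm, n_report = apply_filters(
        neoplasm_calls, matched_normal=normal, matched_blood=blood
    )
    if not neoplasm.mutations:
        raise ValueError(f"patient {patient_id}: no retained neoplastic mutations")

    driver_calls = classify_driver_events(neoplasm, genes)
    drivers = driver_event_keys(driver_calls)
    partition = partition_mutations(stroma, neoplasm)
    purity = tcf if 0.0 < tcf <= 1.0 else 1.0
    clusters = cluster_clones(neoplasm, purity=purity, max_clusters=max_clusters, seed=seed)
    trajectory = build_trajectory(
        patient_id, clusters, partition, drivers, presence_fraction
    )
    subtype = assign_subtype(trajectory, partition, drivers, stroma=stroma)
    return PatientAnalysis(
        patient_id=patient_id,
        stroma=stroma,
        neoplasm=neoplasm,
        stroma_report=s_report,
        neoplasm_report=n_report,
        partition=partition,
        driver_calls=driver_calls,
        trajectory=trajectory,
        subtype=subtype,
    )


def analyze_synthetic_cohort(
    cohort: SyntheticCohort,
    genes: Optional[DriverGeneList] = None,
    seed: int = 0,
) -> dict[str, PatientAnalysis]:
    """Run the pipeline over a generated cohort, keyed by patient id.

    Patients whose neoplastic component retains nothing after filtering
    are skipped (they cannot be subtyped).
    """
    tcf_by_pid = {t.patient_id: t.tcf for t in cohort.truths}
    out: dict[str, PatientAnalysis] = {}
    for i, (pid, by_component) in enumerate(cohort.calls.items()):
        try:
            out[pid] = analyze_patient(
                stroma_calls=by_component.get("stroma", []),
                neoplasm_calls=by_component.get("neoplasm", []),
                normal_calls=by_component.get("normal", []),
                blood_calls=by_component.get("blood", []),
                genes=genes,
                tcf=tcf_by_pid.get(pid, 1.0),
                seed=(seed + 7919 * i) % (2**31 - 1),
            )
        except ValueError:
            continue
    return out
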