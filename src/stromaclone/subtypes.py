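"""Evolutionary subtyping of paired stroma/neoplasm profiles.

Clones inferred in the neoplastic component are ordered by mean CCF
(descending); the highest-prevalence cluster is the trunk, presumed
earliest.  Each patient is then assigned one of four subtypes by how
much of the neoplastic clonal architecture is imprinted on the stroma:

* **A** — full concordance: every neoplastic clone and every driver
  event is also found in the stroma ("neoplasm-like", strong form).
* **B** — the stroma carries the initial clone and its driver events
  but lacks at least one later clone ("neoplasm-like", partial form).
* **C** — total absence of neoplastic mutations in the stroma.
* **D** — anything else: e.g. a later clone present without the trunk,
  or the trunk present without any shared driver event.

Subtypes A and B together define *neoplasm-like stroma*.  A clone
counts as present in stroma when at least ``presence_fraction`` of its
member mutations are shared (inclusive threshold); the fraction is
configurable because presence is a judgement call at the margin.
Stroma-private mutations play no role in the subtype predicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .calls import SpecimenProfile
from .clonality import CloneCluster, Key, SharedPartition

PRESENCE_FRACTION = 0.5

SUBTYPES = ("A", "B", "C", "D")


@dataclass
class Trajectory:
    """Clone clusters of the neoplastic component in emergence order."""

    patient_id: str
    clusters: list[CloneCluster]
    stromal_presence: list[bool]
    driver_keys_per_cluster: list[list[Key]]

    @property
    def trunk(self) -> CloneCluster:
        return self.clusters[0]

    @property
    def trunk_driver_keys(self) -> list[Key]:
        return self.driver_keys_per_cluster[0]


@dataclass(frozen=True)
class SubtypeCall:
    """Per-patient evolutionary subtype with stromal gene status."""

    patient_id: str
    subtype: str
    stromal_kras: bool
    stromal_tp53: bool
    stromal_any_mutation: bool
    trunk_cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")

    @property
    def neoplasm_like(self) -> bool:
        return self.subtype in ("A", "B")


def clone_presence_in_stroma(
    cluster: CloneCluster,
    partition: SharedPartition,
    presence_fraction: float = PRESENCE_FRACTION,
) -> bool:
    """Is a neoplastic clone detectable in the stroma?

    True when at least ``presence_fraction`` of its member mutations lie
    in the shared set (inclusive comparison).
    """
    if not cluster.member_keys:
        return False
    shared = sum(1 for k in cluster.member_keys if k in partition.shared)
    return shared / len(cluster.member_keys) >= presence_fraction


def build_trajectory(
    patient_id: str,
    clusters: Sequence[CloneCluster],
    partition: SharedPartition,
    driver_keys: Iterable[Key],
    presence_fraction: float = PRESENCE_FRACTION,
) -> Trajectory:
    """Assemble the emergence-ordered trajectory with stromal presence flags.

    ``clusters`` must already be ranked by mean neoplastic CCF
    descending (as returned by :func:`stromaclone.clonality.cluster_clones`);
    ``driver_keys`` are the neoplastic driver-event variant keys.
    """
    if not clusters:
        raise ValueError(f"patient {patient_id}: no neoplastic clusters")
    driver_set = set(driver_keys)
    ordered = sorted(clusters, key=lambda c: c.rank)
    presence = [
        clone_presence_in_stroma(c, partition, presence_fraction) for c in ordered
    ]
    per_cluster = [[k for k in c.member_keys if k in driver_set] for c in ordered]
    for c, flag in zip(ordered, per_cluster):
        c.contains_driver = bool(flag)
    return Trajectory(
        patient_id=patient_id,
        clusters=list(ordered),
        stromal_presence=presence,
        driver_keys_per_cluster=per_cluster,
    )


def assign_subtype(
    trajectory: Trajectory,
    partition: SharedPartition,
    driver_keys: Iterable[Key],
    stroma: Optional[SpecimenProfile] = None,
) -> SubtypeCall:
    """Assign the evolutionary subtype for one patient.

    Predicates are evaluated in the fixed order C, A, B, D, which makes
    them mutually exclusive and exhaustive for any patient with at least
    one retained neoplastic mutation:

    * C — the shared set is empty;
    * A — every neoplastic clone is present in stroma and every
      neoplastic driver event is shared;
    * B — the trunk is present, at least one driver event is shared,
      and every trunk driver event is shared;
    * D — otherwise.
    """
    n_keys = {k for c in trajectory.clusters for k in c.member_keys}
    if not n_keys:
        raise ValueError(
            f"patient {trajectory.patient_id}: no neoplastic mutations to subtype"
        )
    driver_set = set(driver_keys) & n_keys
    shared_drivers = driver_set & partition.shared
    trunk_drivers = set(trajectory.trunk_driver_keys)

    if not partition.shared:
        subtype = "C"
    elif all(trajectory.stromal_presence) and driver_set <= partition.shared:
        subtype = "A"
    elif (
        trajectory.stromal_presence[0]
        and shared_drivers
        and trunk_drivers <= partition.shared
    ):
        subtype = "B"
    else:
        subtype = "D"

    gene_status = {"KRAS": False, "TP53": False}
    any_mut = False
    if stroma is not None:
        gene_status = stromal_gene_status(stroma, ("KRAS", "TP53"))
        any_mut = len(stroma.mutations) > 0
    return SubtypeCall(
        patient_id=trajectory.patient_id,
        subtype=subtype,
        stromal_kras=gene_status["KRAS"],
        stromal_tp53=gene_status["TP53"],
        stromal_any_mutation=any_mut,
        trunk_cluster_id=trajectory.trunk.cluster_id,
    )


def stromal_gene_status(
    stroma: SpecimenProfile, genes: Sequence[str] = ("KRAS", "TP53")
) -> dict[str, bool]:
    """Per-gene mutant flags for a filtered stromal profile.

    A gene is flagged when at least one retained stromal mutation falls
    in it; multiple distinct mutations in one gene still mean one flag.
    """
    present = {m.gene.upper() for m in stroma.mutations}
    return {g: g.upper() in present for g in genes}
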