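"""Synthetic paired stroma/neoplasm cohort generator.

Emulates the data-generating process the analysis assumes: each patient
carries a clone tree whose trunk holds hotspot drivers (KRAS codon
12/61, TP53 DNA-binding-domain missense, truncating CDKN2A/SMAD4), with
Poisson passenger mutations per clone.  Neoplasm-derived cells seed the
stroma according to a target evolutionary subtype (A: all clones, B:
trunk but not all later clones, C: none, D: two discordant archetypes),
and the stroma additionally acquires private mutations of its own.
Reads are sampled per specimen with negative-binomial depth around
1000x and binomial alt counts, so every downstream stage can be tested
against ground truth.  Disease-free survival is exponential with a
hazard multiplier for neoplasm-like (A/B) patients.

Clone CCFs are *inclusive*: a clone's CCF counts its descendants, so a
child's CCF never exceeds its parent's within the neoplasm.  Stromal
CCFs are assigned directly per subtype rather than through a stromal
purity model; the D archetype with a later clone present but the trunk
absent deliberately breaks tree consistency in the stroma, because that
is the observed discordance it reproduces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .calls import MutationCall, write_tsv, write_vcf
from .stats import ClinicalRecord

SUBTYPES = ("A", "B", "C", "D")


class SubtypeNotRealizable(ValueError):
    """The drawn clone tree cannot realize the requested subtype."""


# hotspot catalogs: (protein_change, chrom, pos, ref, alt, effect)
KRAS_HOTSPOTS = [
    ("G12C", "12", 25398285, "C", "A", "missense"),
    ("G12D", "12", 25398284, "C", "T", "missense"),
    ("G12R", "12", 25398285, "C", "G", "missense"),
    ("G12V", "12", 25398284, "C", "A", "missense"),
    ("Q61H", "12", 25380275, "T", "G", "missense"),
    ("Q61R", "12", 25380276, "T", "C", "missense"),
]
#: cohort-shaped hotspot weights (G12V and G12D dominate)
KRAS_WEIGHTS = np.array([1, 11, 2, 12, 2, 1], dtype=float) / 29.0

TP53_DBD_MISSENSE = [
    ("R175H", "17", 7578406, "C", "T", "missense"),
    ("Y220C", "17", 7578190, "T", "C", "missense"),
    ("M237I", "17", 7577570, "C", "T", "missense"),
    ("R248Q", "17", 7577538, "C", "T", "missense"),
    ("R273H", "17", 7577120, "C", "T", "missense"),
    ("R282W", "17", 7577094, "G", "A", "missense"),
]

CDKN2A_TRUNCATING = [
    ("R58*", "9", 21971186, "G", "A", "nonsense"),
    ("E88*", "9", 21971096, "C", "A", "nonsense"),
    ("L63Pfs*10", "9", 21971170, "CT", "C", "frameshift"),
]

SMAD4_TRUNCATING = [
    ("Q245*", "18", 48586285, "C", "T", "nonsense"),
    ("W302*", "18", 48591918, "G", "A", "nonsense"),
    ("R361*", "18", 48604676, "C", "T", "nonsense"),
]

DRIVER_CATALOG = {
    "KRAS": (KRAS_HOTSPOTS, KRAS_WEIGHTS),
    "TP53": (TP53_DBD_MISSENSE, None),
    "CDKN2A": (CDKN2A_TRUNCATING, None),
    "SMAD4": (SMAD4_TRUNCATING, None),
}

# position bases keeping synthetic mutation classes collision-free
_PASSENGER_BASE = 10_000_000
_PRIVATE_BASE = 50_000_000
_GERMLINE_BASE = 90_000_000
_ARTIFACT_BASE = 120_000_000


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults mirror the study conditions.

    ``mean_depth``/``depth_dispersion`` parameterize negative-binomial
    specimen depth (dispersion is the NB size parameter; 25 loosely
    reproduces observed per-specimen ranges of roughly 360-1700x at a
    median near 1000x).  ``tcf_distribution`` gives Beta parameters for
    the tumor cell fraction, one pair for mutant-stroma patients and one
    for wild-type-stroma patients.  ``stroma_tumor_fraction`` is the
    fraction of stromal cells that are neoplasm-derived — unknown in
    real tissue, so it is a free parameter here.  Hazards are per-month.
    """

    n_patients: int = 50
    clone_count_range: tuple[int, int] = (2, 5)
    trunk_driver_probs: dict[str, float] = field(
        default_factory=lambda: {
            "KRAS": 0.94,
            "TP53": 0.86,
            "CDKN2A": 0.24,
            "SMAD4": 0.18,
        }
    )
    passengers_per_clone: float = 1.5
    subtype_mix: tuple[float, float, float, float] = (
        12 / 39,
        20 / 39,
        5 / 39,
        2 / 39,
    )
    stroma_private_mutation_rate: float = 0.33
    mean_depth: float = 1000.0
    depth_dispersion: float = 25.0
    tcf_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"mutant": (5.0, 3.0), "wildtype": (3.0, 5.0)}
    )
    stroma_tumor_fraction: float = 0.5
    baseline_hazard: float = 0.06
    neoplasm_like_hazard_ratio: float = 3.0
    censoring_horizon: float = 30.0
    seed: int = 0
    min_clone_ccf: float = 0.12
    min_ccf_separation: float = 0.10
    germline_snps_per_patient: float = 2.0
    artifacts_per_specimen: float = 1.5

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.clone_count_range
        if lo < 1 or hi < lo:
            raise ValueError("clone_count_range lower bound must be >= 1 and <= upper")
        if abs(sum(self.subtype_mix) - 1.0) > 1e-9 or min(self.subtype_mix) < 0:
            raise ValueError("subtype_mix must be a probability vector")
        for name in (
            "passengers_per_clone",
            "stroma_private_mutation_rate",
            "mean_depth",
            "depth_dispersion",
            "baseline_hazard",
            "neoplasm_like_hazard_ratio",
            "censoring_horizon",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for p in self.trunk_driver_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("trunk_driver_probs must be probabilities")
        if not 0.0 < self.stroma_tumor_fraction < 1.0:
            raise ValueError("stroma_tumor_fraction must be in (0, 1)")


@dataclass
class SimMutation:
    """One true mutation with its per-component cancer-cell fractions."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    protein_change: str
    effect: str
    is_driver: bool
    clone_index: int
    ccf_neoplasm: float
    ccf_stroma: float = 0.0
    stroma_private: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimClone:
    """A node of the true clone tree (CCFs inclusive of descendants)."""

    index: int
    parent: Optional[int]
    ccf_neoplasm: float
    ccf_stroma: float = 0.0
    mutations: list[SimMutation] = field(default_factory=list)


@dataclass
class PatientTruth:
    """Ground-truth channel for one synthetic patient."""

    patient_id: str
    clones: list[SimClone]
    stroma_private: list[SimMutation]
    subtype: str
    tcf: float

    @property
    def neoplasm_like(self) -> bool:
        return self.subtype in ("A", "B")

    @property
    def all_mutations(self) -> list[SimMutation]:
        return [m for c in self.clones for m in c.mutations] + self.stroma_private

    def gene_in_stroma(self, gene: str) -> bool:
        return any(
            m.gene == gene and m.ccf_stroma > 0 for m in self.all_mutations
        )


@dataclass
class SyntheticCohort:
    """Generated calls, clinical table and truth for a whole cohort."""

    config: SimulationConfig
    truths: list[PatientTruth]
    calls: dict[str, dict[str, list[MutationCall]]]  # patient -> component -> calls
    clinical: list[ClinicalRecord]


# ---------------------------------------------------------------------------
# clone tree


def simulate_clone_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> list[SimClone]:
    """Draw one patient's clone tree with trunk drivers and passengers.

    The trunk has neoplastic CCF 1.  Each additional clone attaches to a
    parent with spare capacity and takes a stick-breaking share of it;
    clones keep a minimum CCF and minimum pairwise CCF separation so
    that distinct clonal populations are distinguishable by VAF, as the
    trajectory reconstruction assumes.
    """
    lo, hi = config.clone_count_range
    n_clones = int(rng.integers(lo, hi + 1))
    clones = [SimClone(index=0, parent=None, ccf_neoplasm=1.0)]
    taken = {0: 0.0}  # per-parent CCF already given to children

    for idx in range(1, n_clones):
        placed = False
        for _ in range(40):
            candidates = [
                c
                for c in clones
                if c.ccf_neoplasm - taken[c.index] >= config.min_clone_ccf
            ]
            if not candidates:
                break
            parent = candidates[int(rng.integers(len(candidates)))]
            capacity = parent.ccf_neoplasm - taken[parent.index]
            ccf = float(rng.uniform(config.min_clone_ccf, capacity))
            if all(
                abs(ccf - c.ccf_neoplasm) >= config.min_ccf_separation
                for c in clones
            ):
                clones.append(
                    SimClone(index=idx, parent=parent.index, ccf_neoplasm=ccf)
                )
                taken[parent.index] += ccf
                taken[idx] = 0.0
                placed = True
                break
        if not placed:
            break

    trunk = clones[0]
    for gene, prob in config.trunk_driver_probs.items():
        if rng.random() < prob:
            catalog, weights = DRIVER_CATALOG[gene]
            i = int(rng.choice(len(catalog), p=weights))
            pchange, chrom, pos, ref, alt, effect = catalog[i]
            trunk.mutations.append(
                SimMutation(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    protein_change=pchange,
                    effect=effect,
                    is_driver=True,
                    clone_index=0,
                    ccf_neoplasm=1.0,
                )
            )

    counter = 0
    for clone in clones:
        n_pass = int(rng.poisson(config.passengers_per_clone))
        for _ in range(n_pass):
            chrom = str(1 + counter % 22)
            pos = _PASSENGER_BASE + counter * 137
            clone.mutations.append(
                SimMutation(
                    chrom=chrom,
                    pos=pos,
                    ref="A",
                    alt="G",
                    gene=f"PSG{counter:04d}",
                    protein_change="",
                    effect="missense",
                    is_driver=False,
                    clone_index=clone.index,
                    ccf_neoplasm=clone.ccf_neoplasm,
                )
            )
            counter += 1
    return clones


def _subtree(clones: Sequence[SimClone], root: int) -> set[int]:
    children: dict[int, list[int]] = {}
    for c in clones:
        if c.parent is not None:
            children.setdefault(c.parent, []).append(c.index)
    out, stack = set(), [root]
    while stack:
        i = stack.pop()
        out.add(i)
        stack.extend(children.get(i, []))
    return out


def seed_stroma(
    clones: list[SimClone],
    target_subtype: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SimMutation]:
    """Assign stromal CCFs realizing the target subtype; returns private mutations.

    Mutates ``clones`` in place.  A patient-level attenuation factor
    scales neoplastic CCFs down in the stroma, so each clone's stromal
    CCF never exceeds its neoplastic CCF.  Raises
    :class:`SubtypeNotRealizable` when the tree cannot express the
    target (e.g. a single-clone tree cannot be B).
    """
    if target_subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {target_subtype!r}")
    trunk = clones[0]
    trunk_drivers = [m for m in trunk.mutations if m.is_driver]
    atten = float(rng.uniform(0.75, 1.0))

    def set_clone_stroma(clone: SimClone, ccf: float) -> None:
        clone.ccf_stroma = ccf
        for m in clone.mutations:
            m.ccf_stroma = ccf

    if target_subtype == "A":
        if not trunk_drivers:
            raise SubtypeNotRealizable("A needs >=1 trunk driver")
        for c in clones:
            set_clone_stroma(c, atten * c.ccf_neoplasm)
    elif target_subtype == "B":
        if not trunk_drivers:
            raise SubtypeNotRealizable("B needs >=1 trunk driver")
        lost_candidates = [c for c in clones[1:] if c.mutations]
        if not lost_candidates:
            raise SubtypeNotRealizable("B needs a non-trunk clone with mutations")
        lost = lost_candidates[int(rng.integers(len(lost_candidates)))]
        lost_set = _subtree(clones, lost.index)
        for c in clones:
            set_clone_stroma(
                c, 0.0 if c.index in lost_set else atten * c.ccf_neoplasm
            )
    elif target_subtype == "C":
        for c in clones:
            set_clone_stroma(c, 0.0)
    else:  # D: two printed archetypes, chosen 50/50 when both possible
        mode1_ok = bool(trunk.mutations) and any(c.mutations for c in clones[1:])
        mode2_ok = bool(trunk_drivers) and any(
            not m.is_driver for m in trunk.mutations
        )
        if not mode1_ok and not mode2_ok:
            raise SubtypeNotRealizable("D needs either archetype to be expressible")
        if mode1_ok and mode2_ok:
            mode = 1 if rng.random() < 0.5 else 2
        else:
            mode = 1 if mode1_ok else 2
        if mode == 1:
            # later clone seeded, trunk absent
            candidates = [c for c in clones[1:] if c.mutations]
            kept = candidates[int(rng.integers(len(candidates)))]
            for c in clones:
                set_clone_stroma(
                    c, atten * c.ccf_neoplasm if c.index == kept.index else 0.0
                )
        else:
            # trunk seeded but its driver mutations suppressed below detection
            for c in clones:
                set_clone_stroma(c, 0.0)
            set_clone_stroma(trunk, atten * trunk.ccf_neoplasm)
            for m in trunk.mutations:
                if m.is_driver:
                    m.ccf_stroma = 0.0

    n_private = int(rng.poisson(config.stroma_private_mutation_rate))
    private: list[SimMutation] = []
    for j in range(n_private):
        private.append(
            SimMutation(
                chrom=str(1 + j % 22),
                pos=_PRIVATE_BASE + j * 211,
                ref="C",
                alt="T",
                gene=f"SPG{j:03d}",
                protein_change="",
                effect="missense",
                is_driver=False,
                clone_index=-1,
                ccf_neoplasm=0.0,
                ccf_stroma=float(rng.uniform(0.2, 0.9)),
                stroma_private=True,
            )
        )
    return private


# ---------------------------------------------------------------------------
# read sampling


def _nb_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    r = config.depth_dispersion
    p = r / (r + config.mean_depth)
    return max(int(rng.negative_binomial(r, p)), 30)


def expected_vaf(ccf: float, cell_fraction: float) -> float:
    """Expected VAF of a copy-neutral heterozygous variant.

    ``cell_fraction`` is the fraction of specimen cells belonging to the
    lineage carrying the mutation (tumor cell fraction in the neoplasm;
    neoplasm-derived or resident fraction in the stroma); one mutant
    copy out of two.
    """
    return ccf * cell_fraction / 2.0


def _draw_call(
    patient_id: str,
    component: str,
    mut: SimMutation,
    ccf: float,
    cell_fraction: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Optional[MutationCall]:
    depth = _nb_depth(config, rng)
    evaf = expected_vaf(ccf, cell_fraction)
    alt = int(rng.binomial(depth, min(evaf, 1.0))) if evaf > 0 else 0
    if alt == 0:
        return None
    if mut.effect == "missense":
        if mut.is_driver:
            pp2 = float(rng.uniform(0.9, 1.0))
            sift = float(rng.uniform(0.0, 0.04))
        else:
            pp2 = float(rng.uniform(0.0, 0.8))
            sift = float(rng.uniform(0.1, 1.0))
    else:
        pp2 = sift = None
    return MutationCall(
        patient_id=patient_id,
        specimen_id=f"{patient_id}.{component}",
        component=component,
        chrom=mut.chrom,
        pos=mut.pos,
        ref=mut.ref,
        alt=mut.alt,
        gene=mut.gene,
        protein_change=mut.protein_change,
        effect=mut.effect,
        hq_alt_reads=alt,
        depth=depth,
        vaf=alt / depth,
        pop_af_max=0.0,
        polyphen=pp2,
        sift=sift,
        copy_number=2,
    )


def sample_reads(
    truth: PatientTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    with_noise: bool = True,
) -> dict[str, list[MutationCall]]:
    """Sample per-component mutation call tables for one patient.

    Neoplasm-derived mutations use the patient's TCF as cell fraction in
    the neoplasm and ``stroma_tumor_fraction`` in the stroma;
    stroma-private mutations live in the resident stromal lineage.  With
    ``with_noise``, germline SNPs (present in blood and normal) and
    filter-fodder artifacts (low support, synonymous, sub-1% VAF) are
    added so that the somatic filter cascade has real work to do.
    """
    pid = truth.patient_id
    f_stroma = config.stroma_tumor_fraction
    calls: dict[str, list[MutationCall]] = {
        "stroma": [],
        "neoplasm": [],
        "normal": [],
        "blood": [],
    }
    for mut in (m for c in truth.clones for m in c.mutations):
        call = _draw_call(pid, "neoplasm", mut, mut.ccf_neoplasm, truth.tcf, config, rng)
        if call:
            calls["neoplasm"].append(call)
        call = _draw_call(pid, "stroma", mut, mut.ccf_stroma, f_stroma, config, rng)
        if call:
            calls["stroma"].append(call)
    for mut in truth.stroma_private:
        call = _draw_call(
            pid, "stroma", mut, mut.ccf_stroma, 1.0 - f_stroma, config, rng
        )
        if call:
            calls["stroma"].append(call)

    if with_noise:
        _add_noise_calls(pid, calls, config, rng)
    return calls


def _noise_call(
    pid: str,
    component: str,
    chrom: str,
    pos: int,
    vaf: float,
    effect: str,
    pop_af: Optional[float],
    config: SimulationConfig,
    rng: np.random.Generator,
    alt_override: Optional[int] = None,
) -> MutationCall:
    depth = _nb_depth(config, rng)
    alt = alt_override if alt_override is not None else int(rng.binomial(depth, vaf))
    alt = min(max(alt, 1), depth)
    return MutationCall(
        patient_id=pid,
        specimen_id=f"{pid}.{component}",
        component=component,
        chrom=chrom,
        pos=pos,
        ref="G",
        alt="A",
        gene=f"NSG{pos % 9973:04d}",
        protein_change="",
        effect=effect,
        hq_alt_reads=alt,
        depth=depth,
        vaf=alt / depth,
        pop_af_max=pop_af,
        polyphen=None if effect != "missense" else float(rng.uniform(0, 0.5)),
        sift=None if effect != "missense" else float(rng.uniform(0.2, 1.0)),
        copy_number=2,
    )


def _add_noise_calls(
    pid: str,
    calls: dict[str, list[MutationCall]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    n_germ = int(rng.poisson(config.germline_snps_per_patient))
    for j in range(n_germ):
        pos = _GERMLINE_BASE + j * 97
        chrom = str(1 + j % 22)
        # half the germline SNPs carry a panel frequency (caught by the
        # population rule); the rest rely on matched-control subtraction
        pop_af = float(rng.uniform(0.05, 0.5)) if j % 2 == 0 else None
        for component in ("stroma", "neoplasm", "normal", "blood"):
            vaf = float(np.clip(rng.normal(0.5, 0.03), 0.3, 0.7))
            calls[component].append(
                _noise_call(pid, component, chrom, pos, vaf, "missense", pop_af, config, rng)
            )
    for component in ("stroma", "neoplasm"):
        n_art = int(rng.poisson(config.artifacts_per_specimen))
        for j in range(n_art):
            pos = _ARTIFACT_BASE + j * 61 + (0 if component == "stroma" else 5000)
            kind = int(rng.integers(3))
            if kind == 0:  # low read support
                calls[component].append(
                    _noise_call(
                        pid, component, "2", pos, 0.02, "missense", 0.0, config, rng,
                        alt_override=int(rng.integers(1, 5)),
                    )
                )
            elif kind == 1:  # synonymous
                calls[component].append(
                    _noise_call(pid, component, "3", pos, 0.2, "synonymous", 0.0, config, rng)
                )
            else:  # sub-1% VAF
                depth = 2000
                alt = int(rng.integers(5, 19))  # vaf in (0.25%, 1%)
                call = _noise_call(
                    pid, component, "4", pos, 0.005, "missense", 0.0, config, rng,
                    alt_override=alt,
                )
                call.depth = depth
                call.vaf = alt / depth
                calls[component].append(call)


# ---------------------------------------------------------------------------
# clinical outcomes


def simulate_clinical(
    truths: Sequence[PatientTruth],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ClinicalRecord]:
    """Draw covariates and exponential DFS outcomes for the cohort.

    Relapse hazard is ``baseline_hazard`` times the hazard ratio for
    neoplasm-like patients; follow-up is censored at an independent
    uniform time on [0, horizon].  Age shifts upward for patients with
    stromal KRAS/TP53 mutations, mirroring the observed association.
    """
    records = []
    for truth in truths:
        hazard = config.baseline_hazard * (
            config.neoplasm_like_hazard_ratio if truth.neoplasm_like else 1.0
        )
        t_event = rng.exponential(1.0 / hazard) if hazard > 0 else float("inf")
        c_time = (
            float(rng.uniform(0.0, config.censoring_horizon))
            if config.censoring_horizon > 0
            else 0.0
        )
        dfs = min(t_event, c_time)
        stromal_kt = truth.gene_in_stroma("KRAS") or truth.gene_in_stroma("TP53")
        age = float(np.clip(rng.normal(65.0 + (5.0 if stromal_kt else 0.0), 9.0), 35, 90))
        records.append(
            ClinicalRecord(
                patient_id=truth.patient_id,
                age=age,
                sex="M" if rng.random() < 0.6 else "F",
                stage_ii_iv=bool(rng.random() < 0.5),
                tumor_size_gt4cm=bool(rng.random() < 0.14),
                poor_differentiation=bool(rng.random() < 0.5),
                lymph_node=bool(rng.random() < 0.38),
                nerve_invasion=bool(rng.random() < 0.82),
                vascular_invasion=bool(rng.random() < 0.42),
                adjuvant_chemo=bool(rng.random() < 0.6),
                tcf=truth.tcf,
                dfs_months=float(dfs),
                event=bool(t_event <= c_time),
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort assembly


def generate_patient(
    patient_id: str,
    target_subtype: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_attempts: int = 500,
) -> PatientTruth:
    """Draw clone trees until the target subtype is realizable, then seed it."""
    for _ in range(max_attempts):
        clones = simulate_clone_tree(config, rng)
        if not any(c.mutations for c in clones):
            continue
        try:
            private = seed_stroma(clones, target_subtype, config, rng)
        except SubtypeNotRealizable:
            continue
        has_stromal_mut = any(
            m.ccf_stroma > 0 for c in clones for m in c.mutations
        ) or bool(private)
        a, b = config.tcf_distribution["mutant" if has_stromal_mut else "wildtype"]
        tcf = float(rng.beta(a, b))
        return PatientTruth(
            patient_id=patient_id,
            clones=clones,
            stroma_private=private,
            subtype=target_subtype,
            tcf=tcf,
        )
    raise SubtypeNotRealizable(
        f"could not realize subtype {target_subtype} in {max_attempts} tree draws"
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full paired cohort: calls, clinical table and ground truth.

    Bit-reproducible for a given config: a single top-level seed spawns
    one independent substream per patient plus one for the clinical
    table.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_patients + 1)
    mix = np.asarray(config.subtype_mix)
    truths: list[PatientTruth] = []
    calls: dict[str, dict[str, list[MutationCall]]] = {}
    for i in range(config.n_patients):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i + 1:03d}"
        target = SUBTYPES[int(rng.choice(4, p=mix))]
        truth = generate_patient(pid, target, config, rng)
        truths.append(truth)
        calls[pid] = sample_reads(truth, config, rng)
    clinical = simulate_clinical(truths, config, np.random.default_rng(streams[-1]))
    return SyntheticCohort(config=config, truths=truths, calls=calls, clinical=clinical)


# ---------------------------------------------------------------------------
# on-disk output


def _truth_to_jsonable(truth: PatientTruth) -> dict:
    return {
        "patient_id": truth.patient_id,
        "subtype": truth.subtype,
        "neoplasm_like": truth.neoplasm_like,
        "tcf": truth.tcf,
        "clones": [
            {
                "index": c.index,
                "parent": c.parent,
                "ccf_neoplasm": c.ccf_neoplasm,
                "ccf_stroma": c.ccf_stroma,
                "mutations": [dataclasses.asdict(m) for m in c.mutations],
            }
            for c in truth.clones
        ],
        "stroma_private": [dataclasses.asdict(m) for m in truth.stroma_private],
    }


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write per-specimen VCF+TSV calls, the clinical CSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, by_component in cohort.calls.items():
        for component, component_calls in by_component.items():
            if not component_calls:
                continue
            write_tsv(component_calls, outdir / f"{pid}.{component}.tsv")
            write_vcf(component_calls, outdir / f"{pid}.{component}.vcf")
    import pandas as pd

    pd.DataFrame([vars(r) for r in cohort.clinical]).to_csv(
        outdir / "clinical.csv", index=False
    )
    truth = {t.patient_id: _truth_to_jsonable(t) for t in cohort.truths}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
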