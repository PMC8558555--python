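"""Synthetic reference cohort encoding published summary marginals.

The motivating 50-patient PDAC study released only summary counts, not
per-patient tables, so this module builds a fully synthetic cohort of
retained mutation profiles whose *marginal* statistics match the
published ones exactly: 127 stromal mutations in 39 mutant-stroma
patients, 248 neoplastic mutations in 50 patients, 114 shared / 13
stroma-specific / 134 neoplasm-specific, 71 driver events among the
shared mutations across nine genes, stroma prevalence KRAS 28 / TP53 24
/ CDKN2A 9 (21 co-mutant), neoplasm prevalence KRAS 47 (48 mutations) /
TP53 43 / CDKN2A 12 / SMAD4 9, and normalized-VAF clonality 99/114
shared clonal in stroma (96 clonal in both) and 72/134
neoplasm-specific clonal.

Every patient-level detail beyond those marginals (which patient
carries which passenger, the specific VAF values) is an arbitrary
deterministic choice; only the marginal counts are meaningful.  The
derived percentages are *recomputed* from these profiles by the
analysis functions, never hard-coded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calls import MutationCall, SpecimenProfile

N_PATIENTS = 50
N_MUTANT_STROMA = 39

_VAF_ANCHOR = 0.40
_VAF_CLONAL = 0.30
_VAF_SUBCLONAL = 0.12
_DEPTH = 1000


@dataclass
class _Rec:
    """Planning record for one mutation before materialization."""

    patient: int  # 1-based
    gene: str
    effect: str
    category: str  # shared | stroma_specific | neoplasm_specific
    harmful: bool
    stroma_clonal: bool | None = None  # None when absent from stroma
    neoplasm_clonal: bool | None = None
    tag: str = ""  # disambiguates multiple mutations of one gene in one patient


def _plan() -> list[_Rec]:
    recs: list[_Rec] = []

    def add(patients, gene, effect, category, harmful, tag=""):
        for p in patients:
            recs.append(_Rec(p, gene, effect, category, harmful, tag=tag))

    # --- shared driver events (71 across nine genes) -------------------
    add(range(1, 29), "KRAS", "missense", "shared", True)           # 28
    add(range(8, 32), "TP53", "missense", "shared", True)           # 24
    add(range(1, 10), "CDKN2A", "nonsense", "shared", True)         # 9
    add((10, 11), "ARID1A", "missense", "shared", True)
    add((12, 13), "GNAS", "missense", "shared", True)
    add((14, 15), "KDM6A", "missense", "shared", True)
    add((16, 17), "RNF43", "frameshift", "shared", True)
    add((18,), "SMAD4", "missense", "shared", True)
    add((19,), "TGFBR2", "missense", "shared", True)                # 10 extras

    # --- shared passengers (43) ----------------------------------------
    shared_pass = (
        list(range(1, 10))          # 9
        + list(range(20, 32))       # 12
        + [p for p in range(32, 40) for _ in range(2)]  # 16
        + list(range(36, 40))       # 4
        + [10, 11]                  # 2
    )
    for j, p in enumerate(shared_pass):
        recs.append(_Rec(p, f"PSG{j:03d}", "missense", "shared", False, tag=str(j)))

    # --- stroma-specific (13; two driver events) ------------------------
    recs.append(_Rec(5, "KRAS", "missense", "stroma_specific", True, tag="2nd"))
    recs.append(_Rec(35, "SMAD4", "nonsense", "stroma_specific", True))
    for j, p in enumerate([20] + list(range(29, 35)) + list(range(36, 40))):
        recs.append(
            _Rec(p, f"SSP{j:03d}", "missense", "stroma_specific", False, tag=str(j))
        )

    # --- neoplasm-specific driver events (57) ---------------------------
    add(range(29, 48), "KRAS", "missense", "neoplasm_specific", True)   # 19
    recs.append(_Rec(33, "KRAS", "missense", "neoplasm_specific", True, tag="2nd"))
    add(range(1, 8), "TP53", "missense", "neoplasm_specific", True)     # 7
    add(range(32, 44), "TP53", "missense", "neoplasm_specific", True)   # 12
    add(range(10, 13), "CDKN2A", "nonsense", "neoplasm_specific", True)
    add(range(13, 22), "SMAD4", "nonsense", "neoplasm_specific", True)  # 9
    add(range(22, 25), "RNF43", "frameshift", "neoplasm_specific", True)
    add((25, 26), "ARID1A", "missense", "neoplasm_specific", True)
    add((27,), "GNAS", "missense", "neoplasm_specific", True)

    # --- neoplasm-specific passengers (77) ------------------------------
    neo_pass = [48, 48, 49, 49, 50, 50]
    p = 1
    while len(neo_pass) < 77:
        neo_pass.append(p)
        p = p % 47 + 1
    for j, pat in enumerate(neo_pass):
        recs.append(
            _Rec(pat, f"NPG{j:03d}", "missense", "neoplasm_specific", False, tag=str(j))
        )
    return recs


def _assign_clonality(recs: list[_Rec]) -> None:
    # stromal clonality of shared mutations: 15 subclonal, 99 clonal
    stroma_subclonal = {
        ("KRAS", p) for p in (20, 21, 22)
    } | {("TP53", p) for p in (29, 30, 31)}
    n_pass_sub = 0
    for r in recs:
        if r.category == "shared":
            if (r.gene, r.patient) in stroma_subclonal and not r.tag:
                r.stroma_clonal = False
            elif r.gene.startswith("PSG") and r.patient <= 9 and n_pass_sub < 9:
                r.stroma_clonal = False
                n_pass_sub += 1
            else:
                r.stroma_clonal = True
        elif r.category == "stroma_specific":
            r.stroma_clonal = True

    # neoplastic clonality: 3 of the 99 stroma-clonal shared are
    # neoplasm-subclonal (so 96 are clonal in both)
    neo_subclonal_shared = {("KRAS", 23), ("TP53", 24), ("PSG", 25)}
    for r in recs:
        if r.category == "shared":
            if (r.gene, r.patient) in neo_subclonal_shared and not r.tag:
                r.neoplasm_clonal = False
            elif r.gene.startswith("PSG") and r.patient == 25:
                r.neoplasm_clonal = False
            else:
                r.neoplasm_clonal = True

    # neoplasm-specific: 72 clonal / 62 subclonal, respecting the
    # per-gene clonal fractions for KRAS and TP53
    clonal_driver = {
        "KRAS": lambda r: r.tag != "2nd",      # 19 of 20
        "TP53": lambda r: True,                # 19 of 19
        "CDKN2A": lambda r: r.patient == 10,   # 1 of 3
        "SMAD4": lambda r: r.patient <= 16,    # 4 of 9
        "RNF43": lambda r: r.patient == 22,    # 1 of 3
        "ARID1A": lambda r: r.patient == 25,   # 1 of 2
        "GNAS": lambda r: False,               # 0 of 1
    }
    n_clonal_pass = 0
    for r in recs:
        if r.category != "neoplasm_specific":
            continue
        if r.gene in clonal_driver:
            r.neoplasm_clonal = clonal_driver[r.gene](r)
        else:
            # the first 27 specific passengers are clonal; the list starts
            # with patients 48-50, so every neoplastic specimen keeps a
            # clonal anchor mutation
            r.neoplasm_clonal = n_clonal_pass < 27
            n_clonal_pass += 1


_GENE_POS = {
    "KRAS": ("12", 25_398_284),
    "TP53": ("17", 7_577_120),
    "CDKN2A": ("9", 21_971_186),
    "SMAD4": ("18", 48_591_918),
    "ARID1A": ("1", 27_056_000),
    "GNAS": ("20", 57_484_000),
    "KDM6A": ("X", 44_732_000),
    "RNF43": ("17", 56_435_000),
    "TGFBR2": ("3", 30_691_000),
}


def _materialize(recs: list[_Rec]) -> dict[str, dict[str, SpecimenProfile]]:
    per_patient: dict[int, dict[str, list[MutationCall]]] = {
        p: {"stroma": [], "neoplasm": []} for p in range(1, N_PATIENTS + 1)
    }
    anchored: dict[tuple[int, str], bool] = {}

    def vaf_for(patient: int, component: str, clonal: bool) -> float:
        if not clonal:
            return _VAF_SUBCLONAL
        if not anchored.get((patient, component)):
            anchored[(patient, component)] = True
            return _VAF_ANCHOR
        return _VAF_CLONAL

    _CLASS_BASE = {"PSG": 60_000_000, "SSP": 70_000_000, "NPG": 80_000_000}
    _CAT_OFFSET = {"shared": 0, "stroma_specific": 300, "neoplasm_specific": 600}

    for r in recs:
        if r.gene[:3] in _CLASS_BASE:
            chrom = "5"
            pos = _CLASS_BASE[r.gene[:3]] + int(r.gene[3:]) * 101
        else:
            chrom, base = _GENE_POS[r.gene]
            pos = (
                base
                + 1000 * r.patient
                + _CAT_OFFSET[r.category]
                + (137 if r.tag == "2nd" else 0)
            )
        truncating = r.effect in ("nonsense", "frameshift")
        pp2 = None if truncating else (0.99 if r.harmful else 0.20)
        sift = None if truncating else (0.01 if r.harmful else 0.60)
        components = {
            "shared": ("stroma", "neoplasm"),
            "stroma_specific": ("stroma",),
            "neoplasm_specific": ("neoplasm",),
        }[r.category]
        for component in components:
            clonal = r.stroma_clonal if component == "stroma" else r.neoplasm_clonal
            vaf = vaf_for(r.patient, component, bool(clonal))
            pid = f"P{r.patient:02d}"
            per_patient[r.patient][component].append(
                MutationCall(
                    patient_id=pid,
                    specimen_id=f"{pid}.{component}",
                    component=component,
                    chrom=chrom,
                    pos=pos,
                    ref="C",
                    alt="T",
                    gene=r.gene,
                    protein_change="",
                    effect=r.effect,
                    hq_alt_reads=int(vaf * _DEPTH),
                    depth=_DEPTH,
                    vaf=vaf,
                    pop_af_max=0.0,
                    polyphen=pp2,
                    sift=sift,
                    copy_number=2,
                )
            )

    out: dict[str, dict[str, SpecimenProfile]] = {}
    for p, comps in per_patient.items():
        pid = f"P{p:02d}"
        out[pid] = {
            comp: SpecimenProfile(patient_id=pid, component=comp, mutations=muts)
            for comp, muts in comps.items()
        }
    return out


def _check(cohort: dict[str, dict[str, SpecimenProfile]]) -> None:
    n_stroma = sum(len(c["stroma"]) for c in cohort.values())
    n_neo = sum(len(c["neoplasm"]) for c in cohort.values())
    mutant_stroma = sum(1 for c in cohort.values() if len(c["stroma"]) > 0)
    shared = sum(
        len(c["stroma"].keys() & c["neoplasm"].keys()) for c in cohort.values()
    )
    if (n_stroma, n_neo, mutant_stroma, shared) != (127, 248, 39, 114):
        raise AssertionError(
            f"fixture marginals off: {(n_stroma, n_neo, mutant_stroma, shared)}"
        )
    for c in cohort.values():
        for comp in ("stroma", "neoplasm"):
            prof = c[comp]
            if prof.mutations and prof.max_vaf != _VAF_ANCHOR:
                raise AssertionError(
                    f"{prof.patient_id}/{comp}: missing anchor mutation"
                )


def synthetic_reference_cohort() -> dict[str, dict[str, SpecimenProfile]]:
    """Build the synthetic marginal-matched cohort.

    Returns ``{patient_id: {"stroma": SpecimenProfile, "neoplasm":
    SpecimenProfile}}`` of *retained* (post-filter) mutation sets.
    Deterministic; raises if the construction ever drifts off the
    encoded marginals.
    """
    recs = _plan()
    _assign_clonality(recs)
    cohort = _materialize(recs)
    _check(cohort)
    return cohort
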