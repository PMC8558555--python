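"""Reading, writing and somatic filtering of per-specimen mutation calls.

Specimens are microdissected components of one resected tumor: the
neoplastic cell nests, the fibrotic stroma, adjacent normal tissue, and
blood lymphocytes (germline control).  Calls arrive either as a minimal
single-sample VCF 4.2 or as a flat TSV; both dialects carry the same
per-variant payload (gene, effect, read support, population frequency,
PolyPhen-2/SIFT scores, copy number).

The somatic filter is a fixed five-rule cascade applied to each tumor
component with matched blood/normal subtraction:

1. fewer than five high-quality supporting reads (BQ>=30, MQ>=30);
2. population allele frequency above 1% in the configured SNP panels;
3. synonymous effect;
4. variant allele frequency below 1%;
5. the same (chrom, pos, ref, alt) seen in matched blood or normal tissue.

Attribution is first-match: a call violating several rules is counted
once, under the earliest rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

COMPONENTS = ("stroma", "neoplasm", "normal", "blood")
EFFECTS = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice",
    "synonymous",
    "other",
)
TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift", "splice"})

#: canonical column order of the TSV dialect
TSV_COLUMNS = [
    "patient_id",
    "specimen_id",
    "component",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "effect",
    "hq_alt_reads",
    "depth",
    "vaf",
    "pop_af_max",
    "polyphen",
    "sift",
    "copy_number",
]

FILTER_RULES = [
    "low_read_support",
    "population_snp",
    "synonymous",
    "low_vaf",
    "matched_control",
]


class MutationTableError(ValueError):
    """Raised when an input table or record cannot be interpreted."""


@dataclass
class MutationCall:
    """One somatic variant observed in one specimen.

    ``hq_alt_reads`` counts supporting reads with base quality >= 30 and
    mapping quality >= 30; ``vaf`` is the variant allele frequency in
    [0, 1].  ``pop_af_max`` is the maximum population allele frequency
    across the configured SNP panels (``None`` when not annotated).
    PolyPhen-2 and SIFT scores are ``None`` when the effect class is not
    scorable (e.g. truncating variants) or the annotation is missing.
    """

    patient_id: str
    specimen_id: str
    component: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    protein_change: str = ""
    effect: str = "other"
    hq_alt_reads: int = 0
    depth: int = 0
    vaf: float = 0.0
    pop_af_max: Optional[float] = None
    polyphen: Optional[float] = None
    sift: Optional[float] = None
    copy_number: int = 2

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise MutationTableError(
                f"unknown component {self.component!r} for {self.patient_id}"
            )
        if self.effect not in EFFECTS:
            raise MutationTableError(
                f"unknown effect {self.effect!r} at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise MutationTableError(f"position must be 1-based, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise MutationTableError(f"vaf out of range: {self.vaf}")
        if self.hq_alt_reads > self.depth:
            raise MutationTableError(
                f"alt reads exceed depth at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity used for cross-specimen matching."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SpecimenProfile:
    """Retained mutation set for one component of one patient.

    ``tcf`` is the microimaging tumor-cell-fraction estimate for the
    specimen (metadata; NaN when unknown).
    """

    patient_id: str
    component: str
    mutations: list[MutationCall] = field(default_factory=list)
    tcf: float = float("nan")

    def __post_init__(self) -> None:
        for m in self.mutations:
            if m.patient_id != self.patient_id or m.component != self.component:
                raise MutationTableError(
                    "profile members must share patient_id and component"
                )

    @property
    def max_vaf(self) -> float:
        """Maximum VAF over retained mutations (NaN for an empty profile)."""
        if not self.mutations:
            return float("nan")
        return max(m.vaf for m in self.mutations)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {m.key for m in self.mutations}

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass
class FilterReport:
    """Per-rule removal accounting for one filter run."""

    input_count: int
    removed: dict[str, int]
    retained_count: int
    fates: dict[tuple[str, int, str, str], str]

    def __post_init__(self) -> None:
        if sum(self.removed.values()) + self.retained_count != self.input_count:
            raise ValueError("removals + retained must equal input count")


# ---------------------------------------------------------------------------
# TSV dialect


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", ".", "NA"):
        return None
    return float(value)


def read_tsv(path: str | Path) -> list[MutationCall]:
    """Read mutation calls from the flat TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise MutationTableError(f"TSV is missing columns: {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            calls.append(
                MutationCall(
                    patient_id=str(row.patient_id),
                    specimen_id=str(row.specimen_id),
                    component=str(row.component),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    protein_change="" if pd.isna(row.protein_change) else str(row.protein_change),
                    effect=str(row.effect),
                    hq_alt_reads=int(row.hq_alt_reads),
                    depth=int(row.depth),
                    vaf=float(row.vaf),
                    pop_af_max=_opt_float(row.pop_af_max),
                    polyphen=_opt_float(row.polyphen),
                    sift=_opt_float(row.sift),
                    copy_number=2 if pd.isna(row.copy_number) else int(row.copy_number),
                )
            )
        except (TypeError, ValueError) as exc:
            raise MutationTableError(f"bad TSV record on data line {i + 1}: {exc}") from exc
    return calls


def calls_to_frame(calls: Sequence[MutationCall]) -> pd.DataFrame:
    """Tabulate calls in the canonical TSV column order."""
    rows = []
    for m in calls:
        rows.append(
            {
                "patient_id": m.patient_id,
                "specimen_id": m.specimen_id,
                "component": m.component,
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "gene": m.gene,
                "protein_change": m.protein_change,
                "effect": m.effect,
                "hq_alt_reads": m.hq_alt_reads,
                "depth": m.depth,
                "vaf": m.vaf,
                "pop_af_max": m.pop_af_max,
                "polyphen": m.polyphen,
                "sift": m.sift,
                "copy_number": m.copy_number,
            }
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_tsv(calls: Sequence[MutationCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal VCF 4.2 dialect
#
# Single-specimen files; the sample column is named "<patient>.<component>".
# Per-variant annotations travel in INFO (GENE, PCHANGE, EFFECT, PP2, SIFT,
# CN, POPAF, optional VAF), read support in FORMAT DP/AD.

_VCF_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change (HGVS-p)">',
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class">',
    '##INFO=<ID=PP2,Number=1,Type=Float,Description="PolyPhen-2 score">',
    '##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">',
    '##INFO=<ID=CN,Number=1,Type=Integer,Description="Local copy number">',
    '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Max population allele frequency">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
]


def write_vcf(calls: Sequence[MutationCall], path: str | Path) -> None:
    """Write a single-specimen minimal VCF 4.2 file."""
    if not calls:
        raise MutationTableError("cannot write an unnamed empty VCF; need >=1 call")
    patient = calls[0].patient_id
    component = calls[0].component
    for m in calls:
        if (m.patient_id, m.component) != (patient, component):
            raise MutationTableError("write_vcf expects calls from one specimen")

    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for chrom in dict.fromkeys(m.chrom for m in calls):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(f"##specimen_id={calls[0].specimen_id}")
    header.add_sample(f"{patient}.{component}")

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            rec = vcf.new_record(
                contig=m.chrom,
                start=m.pos - 1,
                stop=m.pos - 1 + len(m.ref),
                alleles=(m.ref, m.alt),
            )
            rec.info["GENE"] = m.gene
            if m.protein_change:
                rec.info["PCHANGE"] = m.protein_change
            rec.info["EFFECT"] = m.effect
            if m.polyphen is not None:
                rec.info["PP2"] = m.polyphen
            if m.sift is not None:
                rec.info["SIFT"] = m.sift
            rec.info["CN"] = m.copy_number
            if m.pop_af_max is not None:
                rec.info["POPAF"] = m.pop_af_max
            rec.info["VAF"] = m.vaf
            rec.samples[0]["DP"] = m.depth
            rec.samples[0]["AD"] = (m.depth - m.hq_alt_reads, m.hq_alt_reads)
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[MutationCall]:
    """Read mutation calls from the single-specimen VCF dialect.

    FORMAT DP/AD map to depth and high-quality alt reads.  An explicit
    INFO VAF wins; otherwise VAF is recomputed as AD_alt / DP.  Missing
    annotations stay missing rather than defaulting to zero.
    """
    path = Path(path)
    calls: list[MutationCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise MutationTableError(
                f"{path.name}: expected a single-specimen VCF, found {len(samples)} samples"
            )
        patient, _, component = samples[0].rpartition(".")
        if not patient or component not in COMPONENTS:
            raise MutationTableError(
                f"{path.name}: sample name must be '<patient>.<component>', got {samples[0]!r}"
            )
        specimen_id = samples[0]
        for line in str(vcf.header).splitlines():
            if line.startswith("##specimen_id="):
                specimen_id = line.split("=", 1)[1]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise MutationTableError(
                    f"{path.name}: record at {rec.chrom}:{rec.pos} is not biallelic"
                )
            fmt = rec.samples[0]
            depth = fmt.get("DP")
            ad = fmt.get("AD")
            if depth is None or ad is None:
                raise MutationTableError(
                    f"{path.name}: record at {rec.chrom}:{rec.pos} lacks DP/AD"
                )
            alt_reads = int(ad[1])
            info = rec.info

            def info_get(key, default=None):
                # pysam raises when a key is absent from the header itself
                try:
                    return info.get(key, default)
                except (KeyError, ValueError):
                    return default

            vaf = info_get("VAF")
            if vaf is None:
                vaf = alt_reads / depth if depth else 0.0
            try:
                calls.append(
                    MutationCall(
                        patient_id=patient,
                        specimen_id=specimen_id,
                        component=component,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        gene=info_get("GENE", ""),
                        protein_change=info_get("PCHANGE", "") or "",
                        effect=info_get("EFFECT", "other"),
                        hq_alt_reads=alt_reads,
                        depth=int(depth),
                        vaf=float(vaf),
                        pop_af_max=_opt_float(info_get("POPAF")),
                        polyphen=_opt_float(info_get("PP2")),
                        sift=_opt_float(info_get("SIFT")),
                        copy_number=int(info_get("CN", 2)),
                    )
                )
            except MutationTableError as exc:
                raise MutationTableError(
                    f"{path.name}: bad record at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return calls


def read_calls(path: str | Path, format: str = "auto") -> list[MutationCall]:
    """Read mutation calls from a VCF or TSV file.

    ``format`` may be ``"vcf"``, ``"tsv"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Somatic filter cascade


def apply_filters(
    calls: Sequence[MutationCall],
    matched_normal: Optional[SpecimenProfile] = None,
    matched_blood: Optional[SpecimenProfile] = None,
    pop_af_cutoff: float = 0.01,
    min_hq_reads: int = 5,
    min_vaf: float = 0.01,
    tcf: float = float("nan"),
) -> tuple[SpecimenProfile, FilterReport]:
    """Apply the five-rule somatic filter to one specimen's calls.

    Rules run in a fixed order with first-match attribution; the matched
    blood/normal subtraction keys on exact (chrom, pos, ref, alt).  The
    retained set is independent of the input ordering, and the cascade
    is idempotent.
    """
    if not calls:
        return (
            SpecimenProfile(patient_id="", component="neoplasm", mutations=[], tcf=tcf),
            FilterReport(0, {r: 0 for r in FILTER_RULES}, 0, {}),
        )
    specimen = {(m.patient_id, m.specimen_id, m.component) for m in calls}
    if len(specimen) != 1:
        raise MutationTableError("apply_filters expects calls from a single specimen")

    control_keys: set[tuple[str, int, str, str]] = set()
    for profile in (matched_blood, matched_normal):
        if profile is not None:
            control_keys |= profile.keys()

    removed = {rule: 0 for rule in FILTER_RULES}
    fates: dict[tuple[str, int, str, str], str] = {}
    retained: list[MutationCall] = []
    for m in calls:
        if m.hq_alt_reads < min_hq_reads:
            rule = "low_read_support"
        elif m.pop_af_max is not None and m.pop_af_max > pop_af_cutoff:
            rule = "population_snp"
        elif m.effect == "synonymous":
            rule = "synonymous"
        elif m.vaf < min_vaf:
            rule = "low_vaf"
        elif m.key in control_keys:
            rule = "matched_control"
        else:
            rule = "retained"
            retained.append(m)
        fates[m.key] = rule
        if rule != "retained":
            removed[rule] += 1

    patient_id, _, component = next(iter(specimen))
    profile = SpecimenProfile(
        patient_id=patient_id, component=component, mutations=retained, tcf=tcf
    )
    report = FilterReport(
        input_count=len(calls),
        removed=removed,
        retained_count=len(retained),
        fates=fates,
    )
    return profile, report
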