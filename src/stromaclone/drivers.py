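"""Driver-event annotation.

A retained mutation is a *driver event* when two conditions hold: the
gene is on a curated driver-gene list, and the mutation is predicted
harmful.  Harmfulness uses functional-impact scores: PolyPhen-2 > 0.85
or SIFT < 0.05 (both cutoffs strict, as stated).  Truncating effects —
nonsense, frameshift, splice — are harmful regardless of scores, since
the impact predictors do not score them.  A missense mutation with both
scores missing is flagged unscorable and treated as not harmful.
Everything that is not a driver event is a passenger event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .calls import TRUNCATING_EFFECTS, MutationCall, SpecimenProfile

logger = logging.getLogger(__name__)

PP2_CUTOFF = 0.85
SIFT_CUTOFF = 0.05


@dataclass(frozen=True)
class DriverGeneList:
    """Uppercase-normalized driver gene symbols with per-entry provenance."""

    genes: frozenset[str]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("driver gene list must be non-empty")

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


@dataclass(frozen=True)
class DriverCall:
    """Driver/passenger classification of one mutation."""

    key: tuple[str, int, str, str]
    gene: str
    in_driver_gene: bool
    harmful: bool
    unscorable: bool

    @property
    def is_driver_event(self) -> bool:
        return self.in_driver_gene and self.harmful


def load_driver_genes(path: Optional[str | Path] = None) -> DriverGeneList:
    """Load a driver gene list (one symbol per line, ``#`` comments).

    With no path, the packaged pancreatic-cancer list is used: the nine
    genes recurrently shared between stroma and neoplasm in the
    motivating cohort plus pan-PDAC consensus drivers.
    """
    if path is None:
        text = (
            resources.files("stromaclone").joinpath("data/driver_genes.txt").read_text()
        )
    else:
        text = Path(path).read_text()
    genes: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        genes[parts[0].upper()] = parts[1] if len(parts) > 1 else "user"
    return DriverGeneList(genes=frozenset(genes), provenance=genes)


def classify_harmful(
    mutation: MutationCall,
    pp2_cutoff: float = PP2_CUTOFF,
    sift_cutoff: float = SIFT_CUTOFF,
) -> tuple[bool, bool]:
    """Return ``(harmful, unscorable)`` for one mutation.

    Truncating effects are always harmful.  Score-bearing effects are
    harmful when PolyPhen-2 > ``pp2_cutoff`` or SIFT < ``sift_cutoff``.
    A score-dependent mutation with both scores missing is unscorable
    and counted as not harmful (logged).
    """
    if mutation.effect in TRUNCATING_EFFECTS:
        return True, False
    if mutation.polyphen is None and mutation.sift is None:
        logger.warning(
            "unscorable %s mutation %s %s at %s:%d; treated as passenger",
            mutation.effect,
            mutation.gene,
            mutation.protein_change,
            mutation.chrom,
            mutation.pos,
        )
        return False, True
    harmful = (mutation.polyphen is not None and mutation.polyphen > pp2_cutoff) or (
        mutation.sift is not None and mutation.sift < sift_cutoff
    )
    return harmful, False


def classify_driver_events(
    profile: SpecimenProfile,
    genes: Optional[DriverGeneList] = None,
    pp2_cutoff: float = PP2_CUTOFF,
    sift_cutoff: float = SIFT_CUTOFF,
) -> list[DriverCall]:
    """Classify every retained mutation in a profile as driver or passenger."""
    if genes is None:
        genes = load_driver_genes()
    out = []
    for m in profile.mutations:
        harmful, unscorable = classify_harmful(m, pp2_cutoff, sift_cutoff)
        out.append(
            DriverCall(
                key=m.key,
                gene=m.gene,
                in_driver_gene=m.gene in genes,
                harmful=harmful,
                unscorable=unscorable,
            )
        )
    return out


def driver_event_keys(
    calls: Sequence[DriverCall],
) -> set[tuple[str, int, str, str]]:
    """Variant keys of the driver events among classified calls."""
    return {c.key for c in calls if c.is_driver_event}
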