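"""Taxonomic distribution summaries of the final classifications.

Turns per-protein final calls into per-species presence/absence of
SbmA/BacA and BclA, then into per-taxon counts and percentages at any
rank of the species table.  Percentages are rounded half-up to one
decimal (82% in running text is the zero-decimal display of 81.8).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .classify import FinalCall
from .io_formats import ProteinRecord, SpeciesMeta

RANKS = ("genus", "order", "class", "phylum")


def pct_round(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ndigits."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    q = Decimal(100 * numerator) / Decimal(denominator)
    step = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(step, rounding=ROUND_HALF_UP))


@dataclass
class PresenceAbsence:
    """Per-species counts of final SbmA/BacA and BclA proteins."""

    per_species: dict[str, tuple[int, int]]  # species_id -> (n_bacA, n_bclA)

    def has_bacA(self, species_id: str) -> bool:
        return self.per_species[species_id][0] >= 1

    def has_bclA(self, species_id: str) -> bool:
        return self.per_species[species_id][1] >= 1


@dataclass
class TaxonSummary:
    rank: str
    taxon: str
    n_species: int
    n_with_bacA: int
    n_with_bclA: int
    n_with_either: int
    n_with_both: int
    pct_either: float

    def __post_init__(self) -> None:
        ok = (
            self.n_with_both
            <= min(self.n_with_bacA, self.n_with_bclA)
            <= self.n_with_either
            <= self.n_species
        )
        if not ok:
            raise ValueError(f"inconsistent counts for {self.rank}={self.taxon}")


def presence_absence(
    finals: Sequence[FinalCall],
    proteins: Sequence[ProteinRecord],
    species: Sequence[SpeciesMeta],
) -> PresenceAbsence:
    """Count final BacA/BclA proteins per species (zeros included)."""
    species_of = {p.protein_id: p.species_id for p in proteins}
    known = {sp.species_id for sp in species}
    counts = {sp.species_id: [0, 0] for sp in species}
    for f in finals:
        if f.final_label == "excluded":
            continue
        sp = species_of.get(f.protein_id)
        if sp is None or sp not in known:
            raise ValueError(f"protein {f.protein_id!r} maps to unknown species {sp!r}")
        counts[sp][0 if f.final_label == "BacA" else 1] += 1
    return PresenceAbsence({sp: (c[0], c[1]) for sp, c in counts.items()})


def taxon_summary(
    pa: PresenceAbsence,
    species: Sequence[SpeciesMeta],
    rank: str,
) -> list[TaxonSummary]:
    """Grouped presence counts at one rank, sorted by taxon name."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    attr = "class_" if rank == "class" else rank
    groups: dict[str, list[SpeciesMeta]] = {}
    for sp in species:
        groups.setdefault(getattr(sp, attr), []).append(sp)
    out = []
    for taxon in sorted(groups):
        members = groups[taxon]
        a = sum(1 for sp in members if pa.has_bacA(sp.species_id))
        b = sum(1 for sp in members if pa.has_bclA(sp.species_id))
        either = sum(
            1 for sp in members if pa.has_bacA(sp.species_id) or pa.has_bclA(sp.species_id)
        )
        both = sum(
            1 for sp in members if pa.has_bacA(sp.species_id) and pa.has_bclA(sp.species_id)
        )
        out.append(
            TaxonSummary(
                rank, taxon, len(members), a, b, either, both,
                pct_round(either, len(members)),
            )
        )
    return out


def cooccurrence(pa: PresenceAbsence) -> tuple[int, int, float]:
    """(n_either, n_both, pct of either-species that encode both)."""
    n_either = sum(
        1 for sp in pa.per_species if pa.has_bacA(sp) or pa.has_bclA(sp)
    )
    n_both = sum(1 for sp in pa.per_species if pa.has_bacA(sp) and pa.has_bclA(sp))
    pct = pct_round(n_both, n_either) if n_either else float("nan")
    return n_either, n_both, pct


def write_taxon_summary(summaries: Sequence[TaxonSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "rank\ttaxon\tn_species\tn_with_bacA\tn_with_bclA\tn_with_either\tn_with_both\tpct_either\n"
        )
        for s in summaries:
            fh.write(
                f"{s.rank}\t{s.taxon}\t{s.n_species}\t{s.n_with_bacA}\t{s.n_with_bclA}\t"
                f"{s.n_with_either}\t{s.n_with_both}\t{s.pct_either:.1f}\n"
            )


def write_presence_absence(pa: PresenceAbsence, path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\thas_bacA\thas_bclA\tn_bacA\tn_bclA\n")
        for sp in sorted(pa.per_species):
            n_a, n_b = pa.per_species[sp]
            fh.write(f"{sp}\t{int(n_a >= 1)}\t{int(n_b >= 1)}\t{n_a}\t{n_b}\n")
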